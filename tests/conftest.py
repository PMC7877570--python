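"""Shared fixtures: small seeded cohorts reused across test modules."""

import numpy as np
import pandas as pd
import pytest

import admixkit as ak


@pytest.fixture(scope="session")
def small_cohort():
    """120 individuals, 2 x 50 Mb, 400 markers, ancestry-driven traits."""
    cfg = ak.SimulationConfig(
        n_individuals=120, n_markers=400, seed=11,
        phenotypes=[
            ak.PhenotypeModel("bmi", intercept=27.0,
                              beta_ancestry={"PNS": 2.0},
                              covariate_betas={"age": 0.05}, sigma=4.0),
            ak.PhenotypeModel("t2d", kind="binary", prevalence=0.171,
                              beta_ancestry={"PNS": 0.8}),
        ])
    la, ga = ak.simulate_local_ancestry(cfg)
    freqs = ak.uniform_variant_freqs(la.gmap, 150, seed=11)
    dm = ak.simulate_genotypes(la, freqs, seed=11, info_dist=(0.5, 1.0))
    cohort = ak.simulate_phenotypes(ga, dm, cfg)
    return {"cfg": cfg, "la": la, "ga": ga, "dm": dm, "cohort": cohort,
            "freqs": freqs}


@pytest.fixture()
def tiny_tracts():
    """One individual, one 10 Mb chromosome, PNS/EUR split haplotypes."""
    gmap = ak.GenomicMap.constant_rate({"1": 10_000_000}, 20)
    tr = pd.DataFrame({
        "individual": ["i1"] * 2,
        "haplotype": [0, 1],
        "chrom": ["1", "1"],
        "spos": [1, 1],
        "epos": [10_000_000, 10_000_000],
        "ancestry": ["PNS", "EUR"],
        "posterior": [1.0, 1.0],
    })
    return ak.LocalAncestrySet(tr, gmap)


def brute_force_ols(y, x, covs):
    """Per-marker normal-equations fit: beta, se, two-sided t P."""
    import scipy.stats as st

    X = np.column_stack([x, np.ones_like(y)] + list(covs))
    XtX = X.T @ X
    b = np.linalg.solve(XtX, X.T @ y)
    r = y - X @ b
    dof = len(y) - X.shape[1]
    s2 = r @ r / dof
    cov = s2 * np.linalg.inv(XtX)
    se = np.sqrt(cov[0, 0])
    t = b[0] / se
    return b[0], se, 2 * st.t.sf(abs(t), dof)
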