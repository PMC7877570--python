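"""Synthetic admixed cohorts for end-to-end pipeline testing.

The generator follows the standard pulse-admixture tract model: each
individual draws global ancestry proportions ``q`` from a Dirichlet; each
haplotype is broken by a Poisson process of ancestry switches at rate ``g``
per Morgan (``g`` = generations since admixture) and every tract's ancestry
is drawn i.i.d. from ``q``. Genotypes are drawn per haplotype from
ancestry-specific allele frequencies, and phenotypes from linear or
logistic models driven by global ancestry, an optional local causal
variant, questionnaire-style covariates, and census-tract clustering.

Defaults emulate a four-way admixed Polynesian cohort: mean proportions
(PNS, EUR, EAS, AFR) = (0.402, 0.296, 0.290, 0.012) and ~10 generations
since admixture under a constant 1 cM/Mb map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .datatypes import (DEFAULT_ANCESTRIES, AdmixkitError, CohortTable,
                        DosageMatrix, GenomicMap, GlobalAncestry,
                        LocalAncestrySet, BINARY, QUANTITATIVE)

#: Dirichlet concentration 10 x mean proportions of the four components.
DEFAULT_ALPHA = (4.02, 2.96, 2.90, 0.12)
DEFAULT_CHROM_LENGTHS = {"1": 50_000_000, "2": 50_000_000}


@dataclass
class PhenotypeModel:
    """Generative model for one trait.

    Effects are on the trait scale (quantitative) or log-odds scale
    (binary). ``beta_ancestry`` maps ancestry code to the effect of one
    unit of global proportion; ``causal_variant``/``beta_locus`` add a
    per-dosage-unit local effect; ``tract_sd`` is the s.d. of a
    census-tract random intercept.
    """

    name: str
    kind: str = QUANTITATIVE
    intercept: float = 0.0
    beta_ancestry: dict = field(default_factory=dict)
    causal_variant: int | None = None
    beta_locus: float = 0.0
    covariate_betas: dict = field(default_factory=dict)
    sigma: float = 1.0
    prevalence: float | None = None
    tract_sd: float = 0.0


@dataclass
class SimulationConfig:
    """Cohort-level simulation parameters (defaults = desk-scale cohort)."""

    n_individuals: int = 500
    ancestries: tuple = DEFAULT_ANCESTRIES
    dirichlet_alpha: tuple = DEFAULT_ALPHA
    generations: float = 10.0
    chrom_lengths: dict = field(default_factory=lambda: dict(
        DEFAULT_CHROM_LENGTHS))
    n_markers: int = 2000
    rate_cm_per_mb: float = 1.0
    frac_low_posterior: float = 0.0
    n_census_tracts: int = 40
    phenotypes: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if any(a <= 0 for a in self.dirichlet_alpha):
            raise AdmixkitError("dirichlet_alpha must be positive")
        if self.generations <= 0:
            raise AdmixkitError("generations must be positive")
        if any(L <= 0 for L in self.chrom_lengths.values()):
            raise AdmixkitError("zero-length chromosome")

    def build_map(self) -> GenomicMap:
        return GenomicMap.constant_rate(self.chrom_lengths, self.n_markers,
                                        self.rate_cm_per_mb)


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    """Independent stream per pipeline stage so, e.g., re-drawing
    phenotypes never perturbs genotypes."""
    return np.random.default_rng(np.random.SeedSequence([seed, stage]))


def simulate_local_ancestry(config: SimulationConfig,
                            seed: int | None = None
                            ) -> tuple[LocalAncestrySet, GlobalAncestry]:
    """Draw tracts for every haplotype; returns the set and the true
    per-individual global proportions used to draw them."""
    rng = _stage_rng(config.seed if seed is None else seed, 0)
    gmap = config.build_map()
    K = len(config.ancestries)
    q = rng.dirichlet(config.dirichlet_alpha, size=config.n_individuals)
    inds = [f"ind{i:04d}" for i in range(config.n_individuals)]

    rows = []
    for i, ind in enumerate(inds):
        for hap in (0, 1):
            for chrom, L in config.chrom_lengths.items():
                morgans = L / 1e6 * config.rate_cm_per_mb / 100.0
                n_sw = rng.poisson(config.generations * morgans)
                cuts = np.sort(rng.uniform(0, L, size=n_sw)).astype(np.int64)
                cuts = cuts[(cuts >= 1) & (cuts < L)]
                bounds = np.concatenate(([0], np.unique(cuts), [L]))
                anc = rng.choice(K, size=len(bounds) - 1, p=q[i])
                for k in range(len(bounds) - 1):
                    rows.append((ind, hap, chrom, int(bounds[k]) + 1,
                                 int(bounds[k + 1]),
                                 config.ancestries[anc[k]], 1.0))
    tracts = pd.DataFrame(rows, columns=["individual", "haplotype", "chrom",
                                         "spos", "epos", "ancestry",
                                         "posterior"])
    if config.frac_low_posterior > 0:
        n_low = int(round(config.frac_low_posterior * len(tracts)))
        idx = rng.choice(len(tracts), size=n_low, replace=False)
        tracts.loc[idx, "posterior"] = rng.uniform(0.5, 0.9, size=n_low)
    la = LocalAncestrySet(tracts, gmap, tuple(config.ancestries))
    ga = GlobalAncestry(pd.DataFrame(q, index=inds,
                                     columns=list(config.ancestries)))
    return la, ga


def simulate_genotypes(la: LocalAncestrySet, freqs: pd.DataFrame,
                       seed: int = 0,
                       info_dist: Callable | tuple | None = None
                       ) -> DosageMatrix:
    """Draw hard genotypes from ancestry-specific allele frequencies.

    ``freqs`` needs columns chrom, pos plus one frequency column per
    ancestry code; variant positions must sit on the marker grid of
    ``la``. ``info_dist`` assigns imputation INFO scores: a ``(lo, hi)``
    uniform range, a callable ``f(rng, n)``, or None for 1.0.
    """
    rng = _stage_rng(seed, 1)
    for a in la.ancestries:
        if a not in freqs.columns:
            raise AdmixkitError(f"freqs missing ancestry column {a!r}")
        f = freqs[a].to_numpy(float)
        if np.any((f < 0) | (f > 1)):
            raise AdmixkitError(f"allele frequency outside [0,1] for {a}")

    # map variant -> marker index by exact (chrom, pos) match
    key = pd.MultiIndex.from_arrays([la.gmap.chrom, la.gmap.pos])
    want = pd.MultiIndex.from_arrays(
        [freqs["chrom"].astype(str), freqs["pos"].astype(np.int64)])
    locs = key.get_indexer(want)
    if np.any(locs < 0):
        bad = want[np.nonzero(locs < 0)[0][0]]
        raise AdmixkitError(f"variant {bad} outside map marker grid")

    inds, codes = la._hap_ancestry_at_markers()  # (n, 2, M), posterior unused
    codes = codes[:, :, locs]  # (n, 2, V)
    fmat = freqs[list(la.ancestries)].to_numpy(float)  # (V, K)
    V = len(freqs)
    pro = np.take_along_axis(
        fmat.T[None, None, :, :],  # (1,1,K,V)
        codes[:, :, None, :].astype(np.int64), axis=2)[:, :, 0, :]
    alleles = rng.random(pro.shape) < pro
    dos = alleles.sum(axis=1).astype(float)  # (n, V)

    if info_dist is None:
        info = np.ones(V)
    elif callable(info_dist):
        info = np.asarray(info_dist(rng, V), dtype=float)
    else:
        lo, hi = info_dist
        info = rng.uniform(lo, hi, size=V)
    variants = pd.DataFrame({
        "chrom": freqs["chrom"].astype(str).to_numpy(),
        "pos": freqs["pos"].to_numpy(np.int64),
        "id": [f"var{j:05d}" for j in range(V)],
        "ref": "A", "alt": "T", "info": info})
    return DosageMatrix(variants, inds, dos)


def simulate_covariates(n: int, rng: np.random.Generator,
                        n_census_tracts: int = 40,
                        tract_ses_sd: float = 1.0) -> pd.DataFrame:
    """Questionnaire-style covariates with census-tract clustering.

    Individuals are assigned to census tracts; each tract carries a latent
    SES score whose quintile becomes the shared nSES value, and education
    is drawn with probabilities shifted by the same score, so SES-like
    covariates cluster spatially as they do in area-based designs.
    """
    tract = rng.integers(0, n_census_tracts, size=n)
    ses_score = rng.normal(0.0, tract_ses_sd, size=n_census_tracts)
    qs = np.quantile(ses_score, [0.2, 0.4, 0.6, 0.8])
    nses = (np.digitize(ses_score, qs) + 1)[tract]
    z = ses_score[tract] + rng.normal(0, 1, size=n)
    edu = np.clip(np.digitize(z, [-1.0, 0.0, 1.0]) + 1, 1, 4)
    return pd.DataFrame({
        "age": np.round(rng.normal(60, 8, size=n)).clip(30, 90),
        "sex": rng.choice(["M", "F"], size=n),
        "education": edu.astype(int),
        "smoking": rng.choice(["never", "former", "current"], size=n,
                              p=[0.5, 0.3, 0.2]),
        "nses": nses.astype(int),
        "census_tract": [f"ct{t:03d}" for t in tract],
    })


def _linear_predictor(model: PhenotypeModel, ga: GlobalAncestry,
                      dosages: DosageMatrix | None,
                      cov: pd.DataFrame) -> np.ndarray:
    q = ga.proportions
    eta = np.zeros(len(q))
    for anc, b in model.beta_ancestry.items():
        eta += b * q[anc].to_numpy(float)
    if model.causal_variant is not None:
        if dosages is None:
            raise AdmixkitError("causal variant requested but no dosages")
        eta += model.beta_locus * dosages.dosages[:, model.causal_variant]
    for name, b in model.covariate_betas.items():
        if name == "sex":
            x = (cov["sex"] == "M").to_numpy(float)
        elif name not in cov.columns:
            raise AdmixkitError(f"phenotype model references unknown "
                                f"covariate {name!r}")
        else:
            x = pd.to_numeric(cov[name]).to_numpy(float)
        eta += b * x
    return eta


def simulate_phenotypes(ga: GlobalAncestry,
                        dosages: DosageMatrix | None,
                        config: SimulationConfig,
                        seed: int | None = None) -> CohortTable:
    """Generate covariates and all configured traits.

    Quantitative traits add Normal(0, sigma) noise; binary traits use a
    logistic link whose intercept is solved numerically so the expected
    prevalence matches the target.
    """
    rng = _stage_rng(config.seed if seed is None else seed, 2)
    inds = list(ga.proportions.index)
    n = len(inds)
    cov = simulate_covariates(n, rng, config.n_census_tracts)
    cov.index = pd.Index(inds, name="individual")
    tract_codes = pd.factorize(cov["census_tract"])[0]

    trait_types = {}
    for model in config.phenotypes:
        eta = _linear_predictor(model, ga, dosages, cov)
        if model.tract_sd > 0:
            u = rng.normal(0, model.tract_sd, size=tract_codes.max() + 1)
            eta = eta + u[tract_codes]
        if model.kind == QUANTITATIVE:
            y = model.intercept + eta + rng.normal(0, model.sigma, size=n)
        elif model.kind == BINARY:
            if model.prevalence is None or not 0 < model.prevalence < 1:
                raise AdmixkitError(
                    f"binary trait {model.name!r} needs target prevalence "
                    "strictly inside (0, 1)")
            c = _solve_prevalence_intercept(eta, model.prevalence)
            y = (rng.random(n) < expit(c + eta)).astype(int)
        else:
            raise AdmixkitError(f"unknown trait kind {model.kind!r}")
        cov[model.name] = y
        trait_types[model.name] = model.kind
    return CohortTable(cov, trait_types)


def _solve_prevalence_intercept(eta: np.ndarray, target: float) -> float:
    f = lambda c: expit(c + eta).mean() - target
    lo, hi = -30.0, 30.0
    return brentq(f, lo, hi, xtol=1e-10)


def simulate_cohort(config: SimulationConfig,
                    freqs: pd.DataFrame | None = None,
                    info_dist=None) -> dict:
    """One-call end-to-end simulation.

    Returns a dict with keys ``la`` (LocalAncestrySet), ``ga_true``
    (GlobalAncestry as drawn), ``dosages`` (DosageMatrix or None), and
    ``cohort`` (CohortTable).
    """
    la, ga = simulate_local_ancestry(config)
    dm = (simulate_genotypes(la, freqs, seed=config.seed,
                             info_dist=info_dist)
          if freqs is not None else None)
    cohort = simulate_phenotypes(ga, dm, config)
    return {"la": la, "ga_true": ga, "dosages": dm, "cohort": cohort}


def uniform_variant_freqs(gmap: GenomicMap, n_variants: int,
                          ancestries: Sequence[str] = DEFAULT_ANCESTRIES,
                          seed: int = 0, lo: float = 0.05,
                          hi: float = 0.95) -> pd.DataFrame:
    """Convenience: random ancestry-specific frequencies on a subset of
    the marker grid (evenly spaced)."""
    rng = _stage_rng(seed, 3)
    take = np.linspace(0, gmap.n_markers - 1, n_variants).astype(int)
    take = np.unique(take)
    out = pd.DataFrame({"chrom": gmap.chrom[take], "pos": gmap.pos[take]})
    for a in ancestries:
        out[a] = rng.uniform(lo, hi, size=len(take))
    return out
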