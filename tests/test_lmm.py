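"""GRM, principal components, and EMMAX mixed-model association."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import admixkit as ak
from admixkit.lmm import reml_variance_components


def _random_dosages(n, m, seed, p_lo=0.1, p_hi=0.9):
    rng = np.random.default_rng(seed)
    p = rng.uniform(p_lo, p_hi, size=m)
    dos = rng.binomial(2, p, size=(n, m)).astype(float)
    variants = pd.DataFrame({"chrom": "1", "pos": np.arange(1, m + 1),
                             "ref": "A", "alt": "T", "info": 1.0})
    return ak.DosageMatrix(variants, [f"s{i}" for i in range(n)], dos)


def test_grm_matches_bruteforce_double_loop():
    dm = _random_dosages(10, 100, seed=1)
    K = ak.compute_grm(dm).values
    X = dm.dosages
    p = X.mean(axis=0) / 2
    poly = [k for k in range(X.shape[1]) if 0 < p[k] < 1]
    want = np.zeros((10, 10))
    for i in range(10):
        for j in range(10):
            acc = 0.0
            for k in poly:
                zi = (X[i, k] - 2 * p[k]) / np.sqrt(2 * p[k] * (1 - p[k]))
                zj = (X[j, k] - 2 * p[k]) / np.sqrt(2 * p[k] * (1 - p[k]))
                acc += zi * zj
            want[i, j] = acc / len(poly)
    np.testing.assert_allclose(K, want, atol=1e-10)


def test_grm_twin_duplicates_match_diagonal():
    dm = _random_dosages(12, 300, seed=2)
    dup = dm.dosages.copy()
    dup[1] = dup[0]  # duplicated individual
    dm2 = ak.DosageMatrix(dm.variants, dm.samples, dup)
    K = ak.compute_grm(dm2).values
    assert K[0, 1] == pytest.approx(K[0, 0], rel=1e-12)


def test_grm_unrelated_offdiagonal_moments():
    n, m = 60, 2000
    dm = _random_dosages(n, m, seed=3)
    K = ak.compute_grm(dm).values
    off = K[np.triu_indices(n, 1)]
    assert abs(off.mean()) < 3 / np.sqrt(m)
    assert abs(off.std() * np.sqrt(m) - 1) < 0.25


def test_grm_requires_enough_variants():
    dm = _random_dosages(10, 30, seed=4)
    with pytest.raises(ak.AdmixkitError, match="50"):
        ak.compute_grm(dm)


def test_monomorphic_variants_excluded(caplog):
    dm = _random_dosages(10, 80, seed=5)
    dos = dm.dosages.copy()
    dos[:, 0] = 0.0
    dm2 = ak.DosageMatrix(dm.variants, dm.samples, dos)
    with caplog.at_level("INFO", logger="admixkit"):
        ak.compute_grm(dm2)
    assert "monomorphic" in caplog.text


def _two_pop_dosages(n_per, m, seed):
    rng = np.random.default_rng(seed)
    p1 = rng.uniform(0.1, 0.9, size=m)
    shift = rng.choice([-0.25, 0.25], size=m)
    p2 = np.clip(p1 + shift, 0.05, 0.95)
    d1 = rng.binomial(2, p1, size=(n_per, m))
    d2 = rng.binomial(2, p2, size=(n_per, m))
    dos = np.vstack([d1, d2]).astype(float)
    variants = pd.DataFrame({"chrom": "1", "pos": np.arange(1, m + 1),
                             "ref": "A", "alt": "T", "info": 1.0})
    return ak.DosageMatrix(variants, [f"s{i}" for i in range(2 * n_per)],
                           dos)


def test_pc1_separates_two_populations():
    dm = _two_pop_dosages(40, 500, seed=6)
    pcs = ak.top_pcs(ak.compute_grm(dm), k=5)
    label = np.r_[np.zeros(40), np.ones(40)]
    r = np.corrcoef(pcs["PC1"], label)[0, 1]
    assert abs(r) > 0.9


def test_pcs_orthogonal_and_sign_stable():
    dm = _random_dosages(30, 200, seed=7)
    kin = ak.compute_grm(dm)
    pcs1 = ak.top_pcs(kin, k=8)
    pcs2 = ak.top_pcs(kin, k=8)
    pd.testing.assert_frame_equal(pcs1, pcs2)
    V = pcs1.to_numpy()
    G = V.T @ V
    off = G - np.diag(np.diag(G))
    assert np.abs(off).max() < 1e-8
    # sign convention: largest-magnitude loading positive
    for j in range(V.shape[1]):
        assert V[np.argmax(np.abs(V[:, j])), j] > 0


def test_top_pcs_k_exceeding_n_rejected():
    dm = _random_dosages(10, 100, seed=8)
    with pytest.raises(ak.AdmixkitError, match="exceeds"):
        ak.top_pcs(ak.compute_grm(dm), k=11)


def test_emmax_identity_kinship_equals_ols():
    dm = _random_dosages(80, 100, seed=9)
    region = dm.subset(np.arange(dm.n_variants) < 15)
    rng = np.random.default_rng(9)
    y = pd.Series(rng.standard_normal(80), index=dm.samples)
    kin = ak.KinshipMatrix(np.eye(80), list(dm.samples))
    scan = ak.emmax_assoc(y, region, kin)
    for j in range(15):
        X = sm.add_constant(region.dosages[:, j])
        res = sm.OLS(y.to_numpy(), X).fit()
        assert scan.table.loc[j, "beta"] == pytest.approx(res.params[1],
                                                          abs=1e-6)
        assert scan.table.loc[j, "p"] == pytest.approx(res.pvalues[1],
                                                       abs=1e-6)


def test_emmax_pvalues_invariant_to_affine_rescaling():
    dm = _random_dosages(60, 120, seed=10)
    region = dm.subset(np.arange(dm.n_variants) < 10)
    kin = ak.compute_grm(dm)
    rng = np.random.default_rng(10)
    y = pd.Series(rng.standard_normal(60), index=dm.samples)
    s1 = ak.emmax_assoc(y, region, kin)
    s2 = ak.emmax_assoc(3.7 * y + 11.0, region, kin)
    nl1 = -np.log10(s1.table["p"].to_numpy(float))
    nl2 = -np.log10(s2.table["p"].to_numpy(float))
    np.testing.assert_allclose(nl1, nl2, atol=1e-8)


def test_zero_variance_variant_gives_na():
    dm = _random_dosages(40, 100, seed=11)
    dos = dm.dosages.copy()
    dos[:, 2] = 1.0
    dm2 = ak.DosageMatrix(dm.variants, dm.samples, dos)
    region = dm2.subset(np.arange(dm2.n_variants) < 5)
    kin = ak.KinshipMatrix(np.eye(40), list(dm.samples))
    y = pd.Series(np.random.default_rng(11).standard_normal(40),
                  index=dm.samples)
    scan = ak.emmax_assoc(y, region, kin)
    assert np.isnan(scan.table.loc[2, "beta"])
    assert scan.table.loc[0, "beta"] == scan.table.loc[0, "beta"]


def _family_blocks(n_fam, m, seed):
    """Sibling pairs sharing parental transmissions."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.2, 0.8, size=m)
    # parental haplotypes per family: (n_fam, 4, m)
    par = rng.random((n_fam, 4, m)) < p
    sib = []
    for s in range(2):
        t1 = rng.integers(0, 2, size=(n_fam, m))
        t2 = rng.integers(0, 2, size=(n_fam, m))
        h1 = np.take_along_axis(par[:, 0:2, :], t1[:, None, :],
                                axis=1)[:, 0, :]
        h2 = np.take_along_axis(par[:, 2:4, :], t2[:, None, :],
                                axis=1)[:, 0, :]
        sib.append((h1.astype(int) + h2.astype(int)).astype(float))
    dos = np.empty((2 * n_fam, m))
    dos[0::2] = sib[0]
    dos[1::2] = sib[1]
    variants = pd.DataFrame({"chrom": "1", "pos": np.arange(1, m + 1),
                             "ref": "A", "alt": "T", "info": 1.0})
    return ak.DosageMatrix(variants, [f"s{i}" for i in range(2 * n_fam)],
                           dos)


def test_lambda_recovery_with_known_variance_ratio():
    """REML lambda close to truth when simulating from the model."""
    dm = _family_blocks(150, 400, seed=12)
    kin = ak.compute_grm(dm)
    w, U = np.linalg.eigh(kin.values + 1e-6 * np.eye(300))
    rng = np.random.default_rng(12)
    lam_true = 1.5
    ests = []
    for rep in range(10):
        g = U @ (np.sqrt(np.maximum(w, 0) * lam_true)
                 * rng.standard_normal(300))
        y = g + rng.standard_normal(300)
        vc, _ = reml_variance_components(
            y, np.ones((300, 1)), kin)
        ests.append(vc.lam)
    est = np.median(ests)
    assert 0.7 < est < 3.0
    assert np.mean(ests) == pytest.approx(lam_true, rel=0.5)


def test_emmax_calibrated_ols_inflated_under_relatedness():
    """Sibling blocks + polygenic background: EMMAX holds its level,
    naive OLS does not. The GRM uses the background variants only
    (leave-out kinship), avoiding proximal contamination of the tests."""
    dm = _family_blocks(120, 600, seed=13)
    n = 240
    kin = ak.compute_grm(dm.subset(np.arange(dm.n_variants) < 300))
    rng = np.random.default_rng(13)
    back = dm.dosages[:, :300]
    test = dm.subset(np.arange(dm.n_variants) >= 300)
    eff = rng.standard_normal(300) * 0.2
    rej_emmax = rej_ols = 0
    n_tests = 0
    for rep in range(4):
        y_raw = back @ eff + rng.standard_normal(n)
        y = pd.Series(y_raw, index=dm.samples)
        scan = ak.emmax_assoc(y, test, kin)
        p_em = scan.table["p"].to_numpy(float)
        # naive OLS on the same variants
        p_ols = np.empty(test.n_variants)
        for j in range(test.n_variants):
            X = sm.add_constant(test.dosages[:, j])
            p_ols[j] = sm.OLS(y_raw, X).fit().pvalues[1]
        rej_emmax += (p_em < 0.05).sum()
        rej_ols += (p_ols < 0.05).sum()
        n_tests += len(p_em)
    rate_em = rej_emmax / n_tests
    rate_ols = rej_ols / n_tests
    assert rate_ols > rate_em
    assert abs(rate_em - 0.05) < 0.03


def test_regional_threshold_single_variant_equals_level():
    dm = _random_dosages(100, 60, seed=14)
    region = dm.subset(np.arange(dm.n_variants) < 1)
    kin = ak.KinshipMatrix(np.eye(100), list(dm.samples))
    y = pd.Series(np.random.default_rng(14).standard_normal(100),
                  index=dm.samples)
    est = ak.regional_threshold(y, region, kin, n_perm=1500, seed=14)
    assert est.threshold == pytest.approx(0.05, abs=0.02)


def test_regional_threshold_sidak_for_independent_variants():
    dm = _random_dosages(150, 80, seed=15)
    region = dm.subset(np.arange(dm.n_variants) < 10)
    kin = ak.KinshipMatrix(np.eye(150), list(dm.samples))
    y = pd.Series(np.random.default_rng(15).standard_normal(150),
                  index=dm.samples)
    est = ak.regional_threshold(y, region, kin, n_perm=1500, seed=15)
    sidak = 1 - 0.95 ** (1 / 10)
    assert abs(est.threshold - sidak) / sidak < 0.35


def test_regional_threshold_reproducible():
    dm = _random_dosages(50, 60, seed=16)
    region = dm.subset(np.arange(dm.n_variants) < 5)
    kin = ak.KinshipMatrix(np.eye(50), list(dm.samples))
    y = pd.Series(np.random.default_rng(16).standard_normal(50),
                  index=dm.samples)
    e1 = ak.regional_threshold(y, region, kin, n_perm=150, seed=7)
    e2 = ak.regional_threshold(y, region, kin, n_perm=150, seed=7)
    np.testing.assert_array_equal(e1.min_p, e2.min_p)


def test_qc_filter_applies_info_and_maf():
    dm = _random_dosages(100, 50, seed=17)
    v = dm.variants.copy()
    v.loc[0, "info"] = 0.2  # fails INFO >= 0.4
    dos = dm.dosages.copy()
    dos[:, 1] = 0.0
    dos[0, 1] = 1.0  # MAF = 0.005 < 1%
    dm2 = ak.DosageMatrix(v, dm.samples, dos)
    out = ak.qc_filter(dm2)
    assert out.n_variants == 48


def test_report_top_variant_flags_significance():
    dm = _random_dosages(120, 60, seed=18)
    region = dm.subset(np.arange(dm.n_variants) < 8)
    kin = ak.KinshipMatrix(np.eye(120), list(dm.samples))
    rng = np.random.default_rng(18)
    y = pd.Series(0.8 * region.dosages[:, 3]
                  + rng.standard_normal(120), index=dm.samples)
    scan = ak.emmax_assoc(y, region, kin)
    est = ak.regional_threshold(y, region, kin, n_perm=200, seed=18)
    top = scan.table["p"].idxmin()
    rep = ak.report_top_variant(scan, est)
    assert rep["pos"] == int(region.variants.loc[top, "pos"])
    assert rep["significant"] == (rep["p"] < est.threshold)
    assert rep["or"] == pytest.approx(np.exp(rep["beta"]))
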