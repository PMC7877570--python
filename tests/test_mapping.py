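"""Admixture scan, permutation threshold, regions, conditional analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import admixkit as ak
from admixkit.mapping import quantile_threshold
from conftest import brute_force_ols


@pytest.fixture(scope="module")
def scan_fixture():
    cfg = ak.SimulationConfig(n_individuals=50, n_markers=20, seed=101)
    la, ga = ak.simulate_local_ancestry(cfg)
    rng = np.random.default_rng(101)
    y = pd.Series(rng.standard_normal(50), index=ga.proportions.index)
    return la, ga, y


def test_scan_matches_bruteforce_normal_equations(scan_fixture):
    """Vectorized scan equals per-marker least squares to 1e-8."""
    la, ga, y = scan_fixture
    scan = ak.admixture_scan(y, la, ga)
    _, D = la.dosage("PNS")
    q = ga.proportions.loc[y.index]
    covs = [q["EUR"].to_numpy(), q["EAS"].to_numpy(),
            q["AFR"].to_numpy()]
    for j in range(D.shape[1]):
        if np.isnan(scan.table.loc[j, "beta"]):
            continue
        b, se, p = brute_force_ols(y.to_numpy(), D[:, j], covs)
        assert scan.table.loc[j, "beta"] == pytest.approx(b, abs=1e-8)
        assert scan.table.loc[j, "se"] == pytest.approx(se, abs=1e-8)
        assert scan.table.loc[j, "p"] == pytest.approx(p, abs=1e-8)


def test_collinear_marker_gives_na(scan_fixture):
    """Dosage exactly 2*q_PNS is collinear with the covariate block."""
    la, ga, y = scan_fixture
    # constant-dosage degenerate case: all tracts one ancestry
    cfg = ak.SimulationConfig(n_individuals=30, ancestries=("PNS",),
                              dirichlet_alpha=(1.0,), n_markers=10,
                              seed=7)
    la1, _ = ak.simulate_local_ancestry(cfg)
    ga1 = ak.GlobalAncestry(pd.DataFrame(
        {"PNS": np.ones(30)}, index=la1.individuals))
    y1 = pd.Series(np.random.default_rng(0).standard_normal(30),
                   index=la1.individuals)
    scan = ak.admixture_scan(y1, la1, ga1)
    assert scan.table["beta"].isna().all()


def test_constant_phenotype_rejected(scan_fixture):
    la, ga, y = scan_fixture
    with pytest.raises(ak.ModelError, match="constant"):
        ak.admixture_scan(pd.Series(1.0, index=y.index), la, ga)


def test_null_scan_pvalues_uniform():
    """Marker-level P under a null phenotype is exactly t-distributed;
    pooled across replicates it should look uniform."""
    cfg = ak.SimulationConfig(n_individuals=100, n_markers=100,
                              generations=200.0, seed=103)
    la, ga = ak.simulate_local_ancestry(cfg)
    rng = np.random.default_rng(103)
    ps = []
    for _ in range(20):
        y = pd.Series(rng.standard_normal(100),
                      index=ga.proportions.index)
        scan = ak.admixture_scan(y, la, ga)
        ps.append(scan.table["p"].dropna().to_numpy())
    _, p = stats.kstest(np.concatenate(ps), "uniform")
    assert p > 0.01


def test_threshold_quantile_on_known_list():
    minp = np.array([0.01 * k for k in range(1, 101)])
    est = quantile_threshold(minp, level=0.05)
    assert est.threshold == pytest.approx(0.05)
    assert est.n_permutations == 100


def test_threshold_matches_sidak_for_independent_markers():
    """Near-independent markers (huge g): permutation threshold within
    20% of the Sidak closed form."""
    cfg = ak.SimulationConfig(n_individuals=300, n_markers=40,
                              generations=2000.0, seed=104)
    la, ga = ak.simulate_local_ancestry(cfg)
    est = ak.permutation_threshold(la, ga, n_perm=4000, seed=104)
    M = 40
    sidak = 1 - (1 - 0.05) ** (1 / M)
    assert abs(est.threshold - sidak) / sidak < 0.2


def test_stronger_correlation_never_lowers_threshold():
    """Fewer generations -> longer tracts -> fewer effective tests ->
    a larger (more permissive) threshold, over paired seeds."""
    for seed in (1, 2, 3):
        thr = {}
        for g in (2.0, 50.0):
            cfg = ak.SimulationConfig(n_individuals=150, n_markers=150,
                                      generations=g, seed=seed)
            la, ga = ak.simulate_local_ancestry(cfg)
            thr[g] = ak.permutation_threshold(la, ga, n_perm=400,
                                              seed=seed).threshold
        assert thr[2.0] >= thr[50.0]


def test_threshold_requires_minimum_permutations(scan_fixture):
    la, ga, _ = scan_fixture
    with pytest.raises(ak.AdmixkitError, match="100"):
        ak.permutation_threshold(la, ga, n_perm=10)


def _toy_scan(neglog10, spacing_bp=1_000_000, chrom="1"):
    p = 10.0 ** (-np.asarray(neglog10, dtype=float))
    pos = np.arange(1, len(p) + 1) * spacing_bp
    t = pd.DataFrame({"chrom": chrom, "pos": pos, "beta": 0.1,
                      "se": 0.1, "p": p, "n": 100})
    return ak.ScanResult(t)


def test_region_from_toy_vector():
    """[1,5,6,5,1] at 1 Mb spacing, threshold -log10 = 4.65 ->
    one signal region spanning markers 2-4."""
    scan = _toy_scan([1, 5, 6, 5, 1])
    rs = ak.define_regions(scan, gw_threshold=10 ** -4.65)
    sig = rs.of_kind("signal")
    assert len(sig) == 1
    assert sig.loc[0, "start"] == 2_000_000
    assert sig.loc[0, "stop"] == 4_000_000
    assert sig.loc[0, "peak_neglog10p"] == pytest.approx(6.0)


def test_no_significant_marker_empty_regions():
    scan = _toy_scan([1, 2, 3])
    rs = ak.define_regions(scan, gw_threshold=1e-5)
    assert len(rs.regions) == 0


def test_single_significant_marker_point_region():
    scan = _toy_scan([1, 8, 1])
    rs = ak.define_regions(scan, gw_threshold=1e-5)
    sig = rs.of_kind("signal")
    assert len(sig) == 1
    assert sig.loc[0, "start"] == sig.loc[0, "stop"] == 2_000_000


def test_broad_region_extends_and_merges():
    """Suggestive markers within 5 Mb chain into the broad region; a far
    marker does not."""
    # markers every 1 Mb: sig at 10; suggestive at 13, 17 (chained);
    # suggestive at 25 (beyond 5 Mb of the grown region)
    nl = np.ones(30)
    nl[9] = 8.0   # significant
    nl[12] = 4.5  # suggestive, 3 Mb away
    nl[16] = 4.5  # suggestive, 4 Mb from marker 13
    nl[24] = 4.5  # 8 Mb from marker 17 -> excluded
    scan = _toy_scan(nl)
    rs = ak.define_regions(scan, gw_threshold=1e-5)
    broad = rs.of_kind("broad")
    assert len(broad) == 1
    assert broad.loc[0, "start"] == 10_000_000
    assert broad.loc[0, "stop"] == 17_000_000
    sig = rs.of_kind("signal")
    assert sig.loc[0, "start"] == sig.loc[0, "stop"] == 10_000_000


def test_regions_match_bruteforce_enumeration():
    """Signal runs agree with a direct enumeration over random scans."""
    rng = np.random.default_rng(7)
    for _ in range(20):
        nl = rng.uniform(0, 6, size=40)
        thr = 1e-5
        scan = _toy_scan(nl)
        rs = ak.define_regions(scan, gw_threshold=thr)
        sig_mask = (10.0 ** -nl) < thr
        runs = []
        start = None
        for i, s in enumerate(sig_mask):
            if s and start is None:
                start = i
            if not s and start is not None:
                runs.append((start, i - 1))
                start = None
        if start is not None:
            runs.append((start, len(sig_mask) - 1))
        sig = rs.of_kind("signal")
        assert len(sig) == len(runs)
        for (a, b), (_, row) in zip(runs, sig.iterrows()):
            assert row["start"] == (a + 1) * 1_000_000
            assert row["stop"] == (b + 1) * 1_000_000


def test_regions_idempotent_and_order_invariant():
    rng = np.random.default_rng(8)
    nl = rng.uniform(0, 7, size=50)
    scan = _toy_scan(nl)
    rs1 = ak.define_regions(scan, 1e-5)
    # shuffle rows then restore sort order: same regions
    t = scan.table.sample(frac=1.0, random_state=1).sort_values(
        ["chrom", "pos"]).reset_index(drop=True)
    rs2 = ak.define_regions(ak.ScanResult(t), 1e-5)
    pd.testing.assert_frame_equal(rs1.regions, rs2.regions)
    # signal nested in broad
    for _, sig in rs1.of_kind("signal").iterrows():
        b = rs1.of_kind("broad").set_index("region_id").loc[
            sig["region_id"]]
        assert b["start"] <= sig["start"] <= sig["stop"] <= b["stop"]


def test_unsorted_scan_rejected():
    t = pd.DataFrame({"chrom": "1", "pos": [3, 1, 2], "beta": 0.1,
                      "se": 0.1, "p": 0.5, "n": 10})
    with pytest.raises(ak.FormatError, match="sorted"):
        ak.define_regions(ak.ScanResult(t), 1e-5)


@pytest.fixture(scope="module")
def causal_sim():
    """Trait driven by a single ancestry-differentiated local variant."""
    cfg = ak.SimulationConfig(n_individuals=600, n_markers=300, seed=105)
    la, ga = ak.simulate_local_ancestry(cfg)
    freqs = ak.uniform_variant_freqs(la.gmap, 60, seed=105,
                                     lo=0.2, hi=0.4)
    # causal variant: common on the PNS background, rare elsewhere
    j = 15
    freqs.loc[j, ["PNS", "EUR", "EAS", "AFR"]] = [0.6, 0.05, 0.05, 0.05]
    dm = ak.simulate_genotypes(la, freqs, seed=105)
    rng = np.random.default_rng(105)
    y = pd.Series(1.0 * dm.dosages[:, j]
                  + rng.standard_normal(600) * 1.0,
                  index=ga.proportions.index)
    y = (y - y.mean()) / y.std()
    return la, ga, dm, y, j


def test_conditioning_on_driver_attenuates_peak(causal_sim):
    la, ga, dm, y, j = causal_sim
    chrom = dm.variants.loc[j, "chrom"]
    pos = int(dm.variants.loc[j, "pos"])
    region = (chrom, max(1, pos - 10_000_000), pos + 10_000_000)
    base = ak.conditional_scan(y, la, ga,
                               pd.DataFrame(index=y.index), region)
    assert base.min_p() < 1e-4  # admixture signal present
    cond = pd.DataFrame({"driver": dm.dosages[:, j]}, index=y.index)
    after = ak.conditional_scan(y, la, ga, cond, region)
    assert after.min_p() > 1e-3


def test_conditioning_on_independent_variant_leaves_peak(causal_sim):
    la, ga, dm, y, j = causal_sim
    chrom = dm.variants.loc[j, "chrom"]
    pos = int(dm.variants.loc[j, "pos"])
    region = (chrom, max(1, pos - 10_000_000), pos + 10_000_000)
    base = ak.conditional_scan(y, la, ga,
                               pd.DataFrame(index=y.index), region)
    rng = np.random.default_rng(1)
    indep = pd.DataFrame(
        {"rand": rng.binomial(2, 0.3, size=len(y)).astype(float)},
        index=y.index)
    after = ak.conditional_scan(y, la, ga, indep, region)
    peak0 = -np.log10(base.min_p())
    peak1 = -np.log10(after.min_p())
    assert abs(peak1 - peak0) / peak0 < 0.10


def test_duplicate_conditioning_column_dropped(causal_sim, caplog):
    la, ga, dm, y, j = causal_sim
    cond = pd.DataFrame({"a": dm.dosages[:, j], "b": dm.dosages[:, j]},
                        index=y.index)
    with caplog.at_level("WARNING", logger="admixkit"):
        scan = ak.conditional_scan(y, la, ga, cond)
    assert scan.conditioning == ("a",)
    assert "collinear" in caplog.text
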