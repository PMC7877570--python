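"""Haplotype-based selection statistics and a matched empirical null.

``compute_nsl`` implements the nSL statistic ("number of segregating
sites by length"): around a focal variant, haplotype pairs carrying the
derived allele and pairs carrying the ancestral allele are compared by
the number of consecutive markers over which each pair is identical;
unusually long shared haplotypes around one allele class indicate recent
positive selection. Lengths are counted in markers (no genetic map), the
defining feature of nSL versus iHS.

Significance is assessed empirically against a null set of variants
matched on derived allele frequency and imputation quality, with the
add-one estimator P = (r + 1)/(n + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import AdmixkitError, ModelError

logger = logging.getLogger("admixkit")

DEFAULT_MAX_EXTEND = 100


@dataclass
class HaplotypeMatrix:
    """Phased binary haplotypes: rows = haplotypes, columns = variants.

    0 = ancestral allele, 1 = derived allele; no missing values.
    """

    values: np.ndarray
    positions: np.ndarray | None = None

    def __post_init__(self):
        v = np.asarray(self.values)
        if not np.isin(v, (0, 1)).all():
            raise AdmixkitError("haplotype values must be 0/1")
        self.values = v.astype(np.int8)

    @property
    def n_haplotypes(self) -> int:
        return self.values.shape[0]

    @property
    def n_variants(self) -> int:
        return self.values.shape[1]

    def daf(self) -> np.ndarray:
        return self.values.mean(axis=0)


def _pair_lengths(X: np.ndarray, focal: int, max_extend: int) -> np.ndarray:
    """Shared-run length (markers) around ``focal`` for every pair.

    For a pair, the run extends left and right from the focal site while
    the two haplotypes agree, each direction capped at ``max_extend``;
    length = left + right + 1 (the focal site itself).
    """
    k, m = X.shape
    lo = max(0, focal - max_extend)
    hi = min(m, focal + max_extend + 1)
    left = X[:, lo:focal][:, ::-1]  # columns ordered outward from focal
    right = X[:, focal + 1:hi]
    out = []
    for i in range(k - 1):
        dl = left[i + 1:] != left[i]  # (k-i-1, width)
        dr = right[i + 1:] != right[i]
        # run length = index of first mismatch (or full width)
        if dl.shape[1]:
            ll = np.where(dl.any(axis=1), dl.argmax(axis=1), dl.shape[1])
        else:
            ll = np.zeros(dl.shape[0], dtype=np.int64)
        if dr.shape[1]:
            rr = np.where(dr.any(axis=1), dr.argmax(axis=1), dr.shape[1])
        else:
            rr = np.zeros(dr.shape[0], dtype=np.int64)
        out.append(ll + rr + 1)
    return np.concatenate(out) if out else np.empty(0)


def compute_nsl(haps: HaplotypeMatrix, focal: int,
                max_extend: int = DEFAULT_MAX_EXTEND,
                derived_positive: bool = True) -> float:
    """Unstandardized nSL at one focal variant.

    With ``derived_positive`` (default), nSL = ln(mean shared length among
    derived-allele pairs / mean among ancestral-allele pairs), so positive
    values mean the derived allele sits on longer shared haplotypes; the
    opposite orientation is available and the choice is logged. Returns
    NaN when either allele class has fewer than two haplotypes.
    """
    X = haps.values
    alleles = X[:, focal]
    n_der = int(alleles.sum())
    if n_der == 0 or n_der == len(alleles):
        raise ModelError("focal variant is monomorphic")
    if n_der < 2 or len(alleles) - n_der < 2:
        return float("nan")
    Ld = _pair_lengths(X[alleles == 1], focal, max_extend)
    La = _pair_lengths(X[alleles == 0], focal, max_extend)
    val = float(np.log(Ld.mean() / La.mean()))
    if not derived_positive:
        val = -val
    logger.debug("compute_nsl: focal=%d orientation=%s value=%.4f", focal,
                 "derived+" if derived_positive else "ancestral+", val)
    return val


def nsl_scan(haps: HaplotypeMatrix,
             max_extend: int = DEFAULT_MAX_EXTEND,
             derived_positive: bool = True) -> np.ndarray:
    """nSL at every variant with both alleles at count >= 2 (else NaN)."""
    out = np.full(haps.n_variants, np.nan)
    counts = haps.values.sum(axis=0)
    n = haps.n_haplotypes
    for j in range(haps.n_variants):
        if 2 <= counts[j] <= n - 2:
            out[j] = compute_nsl(haps, j, max_extend, derived_positive)
    return out


def af_difference(f_a: float, f_b: float) -> float:
    """Derived-allele frequency difference between two cohorts."""
    for f in (f_a, f_b):
        if not 0 <= f <= 1:
            raise AdmixkitError("frequency outside [0, 1]")
    return f_a - f_b


@dataclass
class MatchedNull:
    """Empirical null for one focal variant.

    ``null_values`` are the statistics of all non-focal variants whose
    derived allele frequency and INFO score fall inside the matching
    windows; ``p`` is the add-one empirical P in the chosen tail.
    """

    focal_value: float
    null_values: np.ndarray
    daf_window: tuple
    info_window: tuple
    tail: str
    n_matched: int
    n_extreme: int
    p: float


def matched_null_empirical_p(focal_value: float, variants: pd.DataFrame,
                             daf_window: tuple[float, float],
                             info_window: tuple[float, float],
                             tail: str = "upper",
                             value_col: str = "nsl",
                             min_matched: int = 100,
                             focal_index=None) -> MatchedNull:
    """Empirical P of a focal statistic against DAF/INFO-matched variants.

    ``variants`` needs columns ``daf``, ``info`` and ``value_col``. The
    null set is every (non-focal) variant inside both windows; the
    empirical P is (r + 1)/(n + 1) with r = count of null statistics at
    least as extreme as the focal value in ``tail``.
    """
    if tail not in ("upper", "lower"):
        raise AdmixkitError("tail must be 'upper' or 'lower'")
    df = variants
    if focal_index is not None:
        df = df.drop(index=focal_index)
    daf = df["daf"].to_numpy(float)
    info = df["info"].to_numpy(float)
    vals = df[value_col].to_numpy(float)
    inwin = ((daf >= daf_window[0]) & (daf <= daf_window[1])
             & (info >= info_window[0]) & (info <= info_window[1])
             & np.isfinite(vals))
    null = vals[inwin]
    if len(null) < min_matched:
        raise AdmixkitError(
            f"only {len(null)} matched variants in the windows "
            f"(need >= {min_matched})")
    if tail == "upper":
        r = int((null >= focal_value).sum())
    else:
        r = int((null <= focal_value).sum())
    p = (r + 1) / (len(null) + 1)
    return MatchedNull(float(focal_value), null, tuple(daf_window),
                       tuple(info_window), tail, len(null), r, p)


def standardize_nsl(values, dafs, n_bins: int = 50,
                    min_per_bin: int = 20) -> np.ndarray:
    """Z-score nSL values within derived-allele-frequency bins.

    Equal-width bins over the observed DAF range; bins with fewer than
    ``min_per_bin`` finite values are merged with their left neighbor
    (the leftmost merges rightward). A constant bin yields z = 0 with a
    warning.
    """
    v = np.asarray(values, dtype=float)
    d = np.asarray(dafs, dtype=float)
    fin = np.isfinite(v)
    edges = np.linspace(d[fin].min(), d[fin].max(), n_bins + 1)
    bin_id = np.clip(np.digitize(d, edges[1:-1]), 0, n_bins - 1)
    # merge sparse bins leftward
    order = list(range(n_bins))
    counts = np.bincount(bin_id[fin], minlength=n_bins)
    remap = np.arange(n_bins)
    occupied = [b for b in order if counts[b] > 0]
    merged: list[list[int]] = []
    for b in occupied:
        if merged and counts[b] < min_per_bin:
            merged[-1].append(b)
        else:
            merged.append([b])
    # a sparse leading group merges into the following one
    while len(merged) > 1 and sum(counts[b] for b in merged[0]) < \
            min_per_bin:
        merged[1] = merged[0] + merged[1]
        merged.pop(0)
    for gi, grp in enumerate(merged):
        for b in grp:
            remap[b] = gi
    grp_id = remap[bin_id]
    out = np.full_like(v, np.nan)
    for gi in range(len(merged)):
        m = (grp_id == gi) & fin
        if not m.any():
            continue
        mu = v[m].mean()
        sd = v[m].std(ddof=1) if m.sum() > 1 else 0.0
        if sd == 0:
            logger.warning("standardize_nsl: constant bin group %d; z=0",
                           gi)
            out[m] = 0.0
        else:
            out[m] = (v[m] - mu) / sd
    return out
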