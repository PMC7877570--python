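"""Genome-wide admixture mapping of local Polynesian ancestry dosage.

At every marker the trait is regressed on the local ancestry dosage while
controlling for the other three global ancestry proportions (plus
individual-level covariates for binary traits). Genome-wide significance
is calibrated by permutation: repeated scans of standard-normal phenotypes
drawn independently of the data, taking the lower ``level``-quantile of
the per-scan minimum P-values. Signal regions are maximal runs of markers
below the genome-wide threshold; broad regions extend them with
suggestive markers (-log10 P above a softer cut) within a flanking
distance, merging qualifying segments.

The linear scan uses the Frisch-Waugh-Lovell reduction: with a shared
covariate block, per-marker OLS coefficients, standard errors and Wald
P-values are computed for all markers at once and are numerically
identical to marker-by-marker least squares.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datatypes import (BINARY, QUANTITATIVE, AdmixkitError, FormatError,
                        GlobalAncestry, LocalAncestrySet, ModelError,
                        RegionSet, ScanResult)

logger = logging.getLogger("admixkit")

#: Genome-wide admixture significance preset (permutation-derived).
GENOME_WIDE_P = 2.2e-5

ANCESTRY_OF_INTEREST = "PNS"


@dataclass
class ThresholdEstimate:
    """Permutation-calibrated significance threshold.

    ``threshold`` is the ``level`` lower quantile of ``min_p`` (one
    genome-wide minimum P per permutation).
    """

    threshold: float
    n_permutations: int
    min_p: np.ndarray
    level: float = 0.05

    def __post_init__(self):
        if len(self.min_p) != self.n_permutations:
            raise AdmixkitError("min_p list length != n_permutations")
        q = float(np.quantile(self.min_p, self.level,
                              method="inverted_cdf"))
        if not np.isclose(q, self.threshold):
            raise AdmixkitError("threshold inconsistent with min-P list")


def quantile_threshold(min_p, level: float = 0.05) -> ThresholdEstimate:
    """Build a ThresholdEstimate from a list of per-scan minimum P-values."""
    min_p = np.asarray(min_p, dtype=float)
    thr = float(np.quantile(min_p, level, method="inverted_cdf"))
    return ThresholdEstimate(thr, len(min_p), min_p, level)


class ScanContext:
    """Precomputed design pieces shared across scans of one cohort.

    Holds the local-ancestry dosage matrix and the covariate block
    (intercept + non-focal global ancestries + optional extra columns),
    with the dosage residualized against the covariates so repeated
    linear scans (e.g. permutations) cost one matrix-vector product.
    """

    def __init__(self, la: LocalAncestrySet, ga: GlobalAncestry,
                 individuals=None, ancestry: str = ANCESTRY_OF_INTEREST,
                 min_posterior: float | None = None,
                 extra_covariates: pd.DataFrame | None = None):
        inds, D = la.dosage(ancestry, min_posterior)
        order = pd.Index(inds)
        if individuals is not None:
            sel = order.get_indexer(pd.Index(individuals))
            if np.any(sel < 0):
                raise AdmixkitError("individual without local ancestry")
            D = D[sel]
            order = pd.Index(individuals)
        self.individuals = order
        self.D = D
        q = ga.proportions.loc[order]
        covs = [a for a in ga.ancestries if a != ancestry]
        C = q[covs].to_numpy(float)
        names = list(covs)
        if extra_covariates is not None:
            E = extra_covariates.loc[order]
            C = np.hstack([C, E.to_numpy(float)])
            names += list(E.columns)
        self.C = np.hstack([np.ones((len(order), 1)), C])
        self.covariate_names = tuple(names)
        self.chrom = la.gmap.chrom
        self.pos = la.gmap.pos
        self._complete = not np.isnan(D).any()
        if self._complete:
            # residualize dosage on the covariate block once
            Q, _ = np.linalg.qr(self.C)
            self._Q = Q
            self.ED = D - Q @ (Q.T @ D)
            self.dd = np.einsum("ij,ij->j", self.ED, self.ED)
            self._degenerate = self.dd <= 1e-9 * np.maximum(
                np.einsum("ij,ij->j", D, D), 1.0)

    @property
    def n_markers(self) -> int:
        return self.D.shape[1]

    def linear_scan(self, y: np.ndarray):
        """Vectorized per-marker OLS of y on dosage + covariates.

        Returns (beta, se, p, n) arrays over markers; degenerate markers
        (constant or collinear dosage) are NA.
        """
        y = np.asarray(y, dtype=float)
        if np.std(y) == 0:
            raise ModelError("phenotype is constant")
        if not self._complete:
            return self._linear_scan_masked(y)
        n, p_cov = self.C.shape
        ey = y - self._Q @ (self._Q.T @ y)
        dy = self.ED.T @ ey
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = dy / self.dd
            rss = ey @ ey - beta * dy
            dof = n - p_cov - 1
            sigma2 = np.maximum(rss, 0.0) / dof
            se = np.sqrt(sigma2 / self.dd)
            tstat = beta / se
        pval = 2.0 * stats.t.sf(np.abs(tstat), dof)
        pval = np.maximum(pval, np.finfo(float).tiny)
        bad = self._degenerate | ~np.isfinite(se) | (se <= 0)
        beta = np.where(bad, np.nan, beta)
        se = np.where(bad, np.nan, se)
        pval = np.where(bad, np.nan, pval)
        return beta, se, pval, np.full(self.n_markers, n)

    def _linear_scan_masked(self, y: np.ndarray):
        """Marker-by-marker OLS with per-marker complete cases (slow path,
        used when posterior masking introduces missing dosages)."""
        M = self.n_markers
        beta = np.full(M, np.nan)
        se = np.full(M, np.nan)
        pval = np.full(M, np.nan)
        nn = np.zeros(M, dtype=int)
        for j in range(M):
            d = self.D[:, j]
            ok = np.isfinite(d) & np.isfinite(y)
            nn[j] = ok.sum()
            if nn[j] <= self.C.shape[1] + 1 or np.std(d[ok]) == 0:
                continue
            X = np.hstack([d[ok, None], self.C[ok]])
            try:
                res = sm.OLS(y[ok], X).fit()
            except np.linalg.LinAlgError:
                continue
            if res.bse[0] > 0 and np.isfinite(res.bse[0]):
                beta[j], se[j] = res.params[0], res.bse[0]
                pval[j] = max(res.pvalues[0], np.finfo(float).tiny)
        return beta, se, pval, nn

    def logistic_scan(self, y: np.ndarray):
        """Marker-by-marker logistic regression (binary traits)."""
        y = np.asarray(y, dtype=float)
        if len(np.unique(y[np.isfinite(y)])) < 2:
            raise ModelError("phenotype is constant")
        M = self.n_markers
        beta = np.full(M, np.nan)
        se = np.full(M, np.nan)
        pval = np.full(M, np.nan)
        nn = np.zeros(M, dtype=int)
        for j in range(M):
            d = self.D[:, j]
            ok = np.isfinite(d) & np.isfinite(y)
            nn[j] = ok.sum()
            if nn[j] <= self.C.shape[1] + 1 or np.std(d[ok]) == 0:
                continue
            X = np.hstack([d[ok, None], self.C[ok]])
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = sm.Logit(y[ok], X).fit(disp=0, maxiter=100)
                if not res.mle_retvals.get("converged", True):
                    continue
            except Exception:
                continue
            if res.bse[0] > 0 and np.isfinite(res.bse[0]):
                beta[j], se[j] = res.params[0], res.bse[0]
                pval[j] = max(res.pvalues[0], np.finfo(float).tiny)
        return beta, se, pval, nn


def admixture_scan(y: pd.Series, la: LocalAncestrySet, ga: GlobalAncestry,
                   trait_type: str = QUANTITATIVE,
                   covariates: pd.DataFrame | None = None,
                   min_posterior: float | None = None,
                   ancestry: str = ANCESTRY_OF_INTEREST) -> ScanResult:
    """Genome-wide local-ancestry association scan.

    ``y`` is a transformed quantitative trait or 0/1 binary trait indexed
    by individual. For binary traits, individual-level ``covariates`` are
    included in each logistic fit.
    """
    extra = covariates if trait_type == BINARY else None
    ctx = ScanContext(la, ga, individuals=y.index, ancestry=ancestry,
                      min_posterior=min_posterior, extra_covariates=extra)
    if trait_type == BINARY:
        beta, se, p, n = ctx.logistic_scan(y.to_numpy(float))
        model = "logistic-admixture"
    else:
        beta, se, p, n = ctx.linear_scan(y.to_numpy(float))
        model = "linear-admixture"
    table = pd.DataFrame({"chrom": ctx.chrom, "pos": ctx.pos, "beta": beta,
                          "se": se, "p": p, "n": n})
    return ScanResult(table, model=model,
                      covariates=ctx.covariate_names)


def permutation_threshold(la: LocalAncestrySet, ga: GlobalAncestry,
                          n_perm: int = 1000, level: float = 0.05,
                          seed: int = 0,
                          individuals=None,
                          min_posterior: float | None = None,
                          ancestry: str = ANCESTRY_OF_INTEREST
                          ) -> ThresholdEstimate:
    """Permutation-calibrated genome-wide significance threshold.

    Each permutation draws a phenotype from a standard normal
    independently of all data, runs the linear admixture scan, and
    records the genome-wide minimum P; the threshold is the ``level``
    lower quantile of those minima (family-wise control at ``level``).
    """
    if n_perm < 100:
        raise AdmixkitError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    ctx = ScanContext(la, ga, individuals=individuals, ancestry=ancestry,
                      min_posterior=min_posterior)
    n = len(ctx.individuals)
    min_p = np.empty(n_perm)
    k = 0
    while k < n_perm:
        y = rng.standard_normal(n)
        _, _, p, _ = ctx.linear_scan(y)
        if np.isnan(p).all():
            logger.warning("permutation produced an all-NA scan; redrawn")
            continue
        min_p[k] = np.nanmin(p)
        k += 1
    return quantile_threshold(min_p, level)


def define_regions(scan: ScanResult, gw_threshold: float,
                   broad_neglog10: float = 4.0,
                   flank_mb: float = 5.0) -> RegionSet:
    """Signal and broad regions from a scan.

    Signal regions are maximal runs of consecutive markers with
    P strictly below ``gw_threshold`` (boundaries at the first/last such
    marker). Each is extended into a broad region by folding in markers
    with -log10 P > ``broad_neglog10`` lying within ``flank_mb`` of the
    growing region, merging qualifying segments that chain to within the
    same distance; overlapping broad regions are merged.
    """
    flank = int(flank_mb * 1e6)
    rows = []
    rid = 0
    t = scan.table
    for chrom, g in t.groupby("chrom", sort=False):
        pos = g["pos"].to_numpy(np.int64)
        if np.any(np.diff(pos) < 0):
            raise FormatError(f"scan not sorted by position on {chrom}")
        p = g["p"].to_numpy(float)
        with np.errstate(divide="ignore"):
            nl10 = -np.log10(p)
        sig = np.nan_to_num(p, nan=np.inf) < gw_threshold
        if not sig.any():
            continue
        # maximal runs of significant markers
        idx = np.nonzero(sig)[0]
        breaks = np.nonzero(np.diff(idx) > 1)[0]
        runs = np.split(idx, breaks + 1)
        signal_iv = [(int(pos[r[0]]), int(pos[r[-1]])) for r in runs]
        # suggestive chains: markers above the soft cut, chained <= flank
        sug = np.nonzero(np.nan_to_num(nl10, nan=-1.0) > broad_neglog10)[0]
        chains = []
        if len(sug):
            br = np.nonzero(np.diff(pos[sug]) > flank)[0]
            for c in np.split(sug, br + 1):
                chains.append((int(pos[c[0]]), int(pos[c[-1]])))
        broads = []
        for lo, hi in signal_iv:
            changed = True
            while changed:
                changed = False
                for clo, chi in chains:
                    if clo <= hi + flank and chi >= lo - flank and \
                            (clo < lo or chi > hi):
                        lo, hi = min(lo, clo), max(hi, chi)
                        changed = True
            broads.append([lo, hi, [(slo, shi) for slo, shi in signal_iv
                                    if lo <= slo and shi <= hi]])
        # merge overlapping / adjacent broad regions
        broads.sort()
        merged = [broads[0]]
        for b in broads[1:]:
            if b[0] <= merged[-1][1] + flank:
                merged[-1][1] = max(merged[-1][1], b[1])
                for s in b[2]:
                    if s not in merged[-1][2]:
                        merged[-1][2].append(s)
            else:
                merged.append(b)
        for lo, hi, sigs in merged:
            inb = (pos >= lo) & (pos <= hi)
            peak = float(np.nanmax(nl10[inb]))
            rows.append((chrom, lo, hi, "broad", peak, f"r{rid}"))
            for slo, shi in sigs:
                ins = (pos >= slo) & (pos <= shi)
                rows.append((chrom, slo, shi, "signal",
                             float(np.nanmax(nl10[ins])), f"r{rid}"))
            rid += 1
    cols = ["chrom", "start", "stop", "kind", "peak_neglog10p", "region_id"]
    return RegionSet(pd.DataFrame(rows, columns=cols))


def conditional_scan(y: pd.Series, la: LocalAncestrySet,
                     ga: GlobalAncestry, conditioning,
                     region: tuple | None = None,
                     trait_type: str = QUANTITATIVE,
                     covariates: pd.DataFrame | None = None,
                     min_posterior: float | None = None,
                     ancestry: str = ANCESTRY_OF_INTEREST) -> ScanResult:
    """Admixture scan with variant dosages appended as covariates.

    ``conditioning`` is a DataFrame of dosage columns indexed by
    individual (e.g. GWAS-catalog variants in the region). Duplicated or
    covariate-collinear conditioning columns are dropped with a warning.
    ``region`` restricts the scan to ``(chrom, start_bp, stop_bp)``.
    """
    cond = conditioning.loc[y.index].astype(float)
    base = [pd.DataFrame(
        {a: ga.proportions.loc[y.index, a]
         for a in ga.ancestries if a != ancestry})]
    if trait_type == BINARY and covariates is not None:
        base.append(covariates.loc[y.index])
    kept = []
    B = np.hstack([np.ones((len(y), 1))]
                  + [b.to_numpy(float) for b in base])
    for name in cond.columns:
        x = cond[name].to_numpy(float)[:, None]
        aug = np.hstack([B] + [cond[k].to_numpy(float)[:, None]
                               for k in kept] + [x])
        if np.linalg.matrix_rank(aug, tol=1e-8) <= np.linalg.matrix_rank(
                aug[:, :-1], tol=1e-8):
            logger.warning("conditioning variant %s collinear with "
                           "covariates; dropped", name)
            continue
        kept.append(name)
    ctx = ScanContext(la, ga, individuals=y.index, ancestry=ancestry,
                      min_posterior=min_posterior,
                      extra_covariates=pd.concat(
                          base[1:] + [cond[kept]], axis=1)
                      if (base[1:] or kept) else None)
    if trait_type == BINARY:
        beta, se, p, n = ctx.logistic_scan(y.to_numpy(float))
        model = "logistic-admixture-conditional"
    else:
        beta, se, p, n = ctx.linear_scan(y.to_numpy(float))
        model = "linear-admixture-conditional"
    table = pd.DataFrame({"chrom": ctx.chrom, "pos": ctx.pos, "beta": beta,
                          "se": se, "p": p, "n": n})
    if region is not None:
        chrom, start, stop = region
        keep = (table["chrom"] == str(chrom)) & \
            table["pos"].between(start, stop)
        table = table[keep].reset_index(drop=True)
    return ScanResult(table, model=model,
                      covariates=ctx.covariate_names,
                      conditioning=tuple(kept))
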