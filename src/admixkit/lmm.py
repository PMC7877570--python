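"""Single-variant fine-mapping with an EMMAX-style linear mixed model.

Relatedness is captured by an empirical genomic relationship matrix (GRM,
VanRaden form) and population structure by its top principal components.
The mixed model ``y = Xb + u + e`` with ``cov(u) = sigma_g^2 K`` is fit in
two steps: (1) REML estimation of the variance components under the null
(no variant) by one-dimensional optimization of the restricted likelihood
over the ratio lambda = sigma_g^2/sigma_e^2 on the eigenbasis of K;
(2) per-variant generalized least squares Wald tests with the fitted
covariance held fixed, computed for all variants at once on whitened
data. Binary traits are coded 0/1 and analyzed on the linear scale.

Regional significance is calibrated by residual permutation: residuals
from the null fixed-effects fit are shuffled, the scan re-run, and the
lower quantile of the per-permutation minimum P taken as the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .datatypes import (AdmixkitError, DosageMatrix, ModelError, ScanResult)
from .mapping import ThresholdEstimate, quantile_threshold

logger = logging.getLogger("admixkit")

GRM_RIDGE = 1e-6
MIN_GRM_VARIANTS = 50


@dataclass
class KinshipMatrix:
    """Symmetric genetic relatedness matrix bound to a sample order."""

    values: np.ndarray
    samples: list

    def __post_init__(self):
        K = np.asarray(self.values, dtype=float)
        if K.shape != (len(self.samples), len(self.samples)):
            raise AdmixkitError("kinship shape does not match sample list")
        if not np.allclose(K, K.T, atol=1e-10):
            raise AdmixkitError("kinship matrix not symmetric")
        self.values = (K + K.T) / 2.0


@dataclass
class VarianceComponents:
    """REML variance components of the null mixed model."""

    sigma_g2: float
    sigma_e2: float
    reml_loglik: float = np.nan

    def __post_init__(self):
        if self.sigma_g2 < 0 or self.sigma_e2 <= 0:
            raise ModelError("variance components must be non-negative "
                             "(residual strictly positive)")

    @property
    def lam(self) -> float:
        """Heritability ratio sigma_g^2 / sigma_e^2."""
        return self.sigma_g2 / self.sigma_e2


def compute_grm(dm: DosageMatrix,
                min_variants: int = MIN_GRM_VARIANTS) -> KinshipMatrix:
    """VanRaden GRM: frequency-standardized dosage cross-product.

    Monomorphic variants are excluded (logged). Entries are ~1 on the
    diagonal for non-inbred individuals and ~0 off-diagonal for unrelated
    ones.
    """
    X = np.asarray(dm.dosages, dtype=float)
    p = np.nanmean(X, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    n_mono = int((~poly).sum())
    if n_mono:
        logger.info("compute_grm: excluded %d monomorphic variant(s)",
                    n_mono)
    X = X[:, poly]
    p = p[poly]
    if X.shape[1] < min_variants:
        raise AdmixkitError(
            f"GRM needs at least {min_variants} polymorphic variants, "
            f"got {X.shape[1]}")
    Z = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
    K = Z @ Z.T / Z.shape[1]
    return KinshipMatrix(K, list(dm.samples))


def top_pcs(kinship: KinshipMatrix, k: int = 10) -> pd.DataFrame:
    """Top-k principal component scores from the GRM.

    Eigenvectors scaled by root eigenvalues; each column's sign is fixed
    so its largest-magnitude loading is positive.
    """
    n = len(kinship.samples)
    if k > n:
        raise AdmixkitError(f"k={k} exceeds sample size {n}")
    w, v = np.linalg.eigh(kinship.values)
    order = np.argsort(w)[::-1][:k]
    w, v = w[order], v[:, order]
    scores = v * np.sqrt(np.maximum(w, 0.0))
    for j in range(scores.shape[1]):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    return pd.DataFrame(scores, index=pd.Index(kinship.samples),
                        columns=[f"PC{i + 1}" for i in range(k)])


def _reml_profile(y, X, xi, Uty, UtX):
    """Restricted log-likelihood profile over lambda (up to a constant)."""
    n, p = X.shape

    def nll(loglam: float) -> float:
        lam = np.exp(loglam)
        w = lam * xi + 1.0
        sw = 1.0 / np.sqrt(w)
        Xw = UtX * sw[:, None]
        yw = Uty * sw
        beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        if rank < p:
            return np.inf
        r = yw - Xw @ beta
        rss = float(r @ r)
        _, logdet_xwx = np.linalg.slogdet(Xw.T @ Xw)
        return 0.5 * ((n - p) * np.log(rss / (n - p)) + np.sum(np.log(w))
                      + logdet_xwx)

    return nll


def reml_variance_components(y: np.ndarray, X: np.ndarray,
                             kinship: KinshipMatrix,
                             ridge: float = GRM_RIDGE
                             ) -> tuple[VarianceComponents, dict]:
    """One-dimensional REML over lambda on the GRM eigenbasis.

    Returns the fitted components and a dict with the eigendecomposition
    (reusable for the per-variant step and for permutations).
    """
    K = kinship.values + ridge * np.eye(len(kinship.samples))
    xi, U = np.linalg.eigh(K)
    if xi.min() < -1e-8:
        raise ModelError("kinship not PSD even after ridge")
    xi = np.maximum(xi, 0.0)
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    Uty = U.T @ y
    UtX = U.T @ X
    nll = _reml_profile(y, X, xi, Uty, UtX)
    # coarse grid then local refinement over log-lambda
    grid = np.linspace(-12.0, 8.0, 41)
    vals = [nll(g) for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-6})
    lam = float(np.exp(res.x))
    # lambda -> 0 limit: no genetic variance
    if nll(-12.0) <= res.fun:
        lam = 0.0
    n, p = X.shape
    w = lam * xi + 1.0
    sw = 1.0 / np.sqrt(w)
    Xw = UtX * sw[:, None]
    yw = Uty * sw
    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    r = yw - Xw @ beta
    sigma_e2 = float(r @ r) / (n - p)
    vc = VarianceComponents(lam * sigma_e2, sigma_e2,
                            reml_loglik=-float(nll(np.log(lam) if lam > 0
                                                   else -12.0)))
    return vc, {"xi": xi, "U": U, "lam": lam, "nll": nll}


def emmax_assoc(y: pd.Series, dosages: DosageMatrix,
                kinship: KinshipMatrix, pcs: pd.DataFrame | None = None,
                covariates: pd.DataFrame | None = None,
                vc: dict | None = None) -> ScanResult:
    """Two-step mixed-model association for every variant in a region.

    Step 1 estimates the variance components under the null; step 2 tests
    each variant by GLS with the fitted covariance held fixed (Wald t).
    Binary traits enter coded 0/1 on the linear scale. Variants with zero
    dosage variance give NA rows. Pass ``vc`` (the eigen-dict returned by
    :func:`reml_variance_components`) to skip step 1.
    """
    order = list(y.index)
    if order != list(kinship.samples):
        raise AdmixkitError("phenotype and kinship sample order differ")
    parts = [np.ones((len(order), 1))]
    names = ["const"]
    if pcs is not None:
        parts.append(pcs.loc[order].to_numpy(float))
        names += list(pcs.columns)
    if covariates is not None:
        parts.append(covariates.loc[order].to_numpy(float))
        names += list(covariates.columns)
    X0 = np.hstack(parts)
    yv = y.to_numpy(float)
    if vc is None:
        _, vc = reml_variance_components(yv, X0, kinship)
    xi, U, lam = vc["xi"], vc["U"], vc["lam"]
    sw = 1.0 / np.sqrt(lam * xi + 1.0)
    T = (U * sw[None, :]).T  # whitening: T V T' propto I
    yw = T @ yv
    Xw = T @ X0
    Dw = T @ dosages.dosages
    n, p = Xw.shape
    Q, _ = np.linalg.qr(Xw)
    ey = yw - Q @ (Q.T @ yw)
    ED = Dw - Q @ (Q.T @ Dw)
    dd = np.einsum("ij,ij->j", ED, ED)
    raw_var = np.nanvar(dosages.dosages, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dy = ED.T @ ey
        beta = dy / dd
        rss = ey @ ey - beta * dy
        dof = n - p - 1
        se = np.sqrt(np.maximum(rss, 0.0) / dof / dd)
        tstat = beta / se
    pval = 2.0 * stats.t.sf(np.abs(tstat), dof)
    pval = np.maximum(pval, np.finfo(float).tiny)
    bad = (raw_var <= 0) | (dd <= 1e-10) | ~np.isfinite(se) | (se <= 0)
    beta = np.where(bad, np.nan, beta)
    se = np.where(bad, np.nan, se)
    pval = np.where(bad, np.nan, pval)
    table = dosages.variants[["chrom", "pos"]].copy()
    if "id" in dosages.variants.columns:
        table["id"] = dosages.variants["id"]
    table["beta"] = beta
    table["se"] = se
    table["p"] = pval
    table["n"] = n
    return ScanResult(table, model="emmax", covariates=tuple(names[1:]))


def regional_threshold(y: pd.Series, dosages: DosageMatrix,
                       kinship: KinshipMatrix,
                       pcs: pd.DataFrame | None = None,
                       covariates: pd.DataFrame | None = None,
                       n_perm: int = 1000, level: float = 0.05,
                       seed: int = 0) -> ThresholdEstimate:
    """Regional significance by residual permutation.

    Residuals of the null fixed-effects fit are permuted, added back to
    the fitted values, and the mixed-model scan re-run; the threshold is
    the ``level`` lower quantile of per-permutation minimum P.
    """
    if dosages.n_variants < 1:
        raise AdmixkitError("region must contain at least one variant")
    rng = np.random.default_rng(seed)
    order = list(y.index)
    parts = [np.ones((len(order), 1))]
    if pcs is not None:
        parts.append(pcs.loc[order].to_numpy(float))
    if covariates is not None:
        parts.append(covariates.loc[order].to_numpy(float))
    X0 = np.hstack(parts)
    yv = y.to_numpy(float)
    Q, _ = np.linalg.qr(X0)
    fit = Q @ (Q.T @ yv)
    resid = yv - fit
    min_p = np.empty(n_perm)
    k = 0
    while k < n_perm:
        yp = pd.Series(fit + rng.permutation(resid), index=y.index)
        scan = emmax_assoc(yp, dosages, kinship, pcs, covariates)
        p = scan.table["p"].to_numpy(float)
        if np.isnan(p).all():
            logger.warning("permutation produced all-NA scan; redrawn")
            continue
        min_p[k] = np.nanmin(p)
        k += 1
    return quantile_threshold(min_p, level)


def qc_filter(dm: DosageMatrix, min_info: float = 0.4,
              min_maf: float = 0.01) -> DosageMatrix:
    """Imputation-quality and minor-allele-frequency filters."""
    f = dm.allele_freq()
    maf = np.minimum(f, 1 - f)
    keep = (dm.variants["info"].to_numpy(float) >= min_info) & \
        (maf >= min_maf)
    logger.info("qc_filter: kept %d / %d variants", int(keep.sum()),
                dm.n_variants)
    return dm.subset(keep)


def report_top_variant(scan: ScanResult,
                       threshold: ThresholdEstimate) -> dict:
    """Minimum-P variant in the region with its regional-significance flag
    and odds-ratio-scale effect (exp(beta) for 0/1 traits)."""
    t = scan.table.dropna(subset=["p"])
    if t.empty:
        raise ModelError("no testable variant in region")
    row = t.loc[t["p"].idxmin()]
    return {"id": row.get("id", f"{row['chrom']}:{row['pos']}"),
            "chrom": row["chrom"], "pos": int(row["pos"]),
            "beta": float(row["beta"]), "or": float(np.exp(row["beta"])),
            "se": float(row["se"]), "p": float(row["p"]),
            "significant": bool(row["p"] < threshold.threshold)}
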