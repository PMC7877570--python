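"""Global-ancestry association of quantitative and binary traits.

The workflow mirrors a two-stage covariate-adjusted ancestry regression:

1. screen candidate covariates one at a time against the trait, retaining
   age and sex unconditionally plus every nominally significant candidate,
   and collapsing non-significant levels of retained categorical
   covariates into the reference group;
2. for quantitative traits, residualize on the retained covariates and
   rank-inverse-normalize the residuals; for binary traits keep the
   covariates in the joint logistic model;
3. regress the outcome jointly on the Polynesian, East Asian, and African
   global proportions, leaving European ancestry as the baseline.

Effects are reported per unit of ancestry proportion; ``per_10pct_effect``
rescales them to the per-10%-ancestry quantities used for headline
reporting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm, rankdata

from .datatypes import (BINARY, QUANTITATIVE, CohortTable, GlobalAncestry,
                        ModelError)

logger = logging.getLogger("admixkit")

ALWAYS_KEPT = ("age", "sex")
#: Covariates treated as categorical in the screening step.
CATEGORICAL = ("sex", "smoking", "education", "nses")

#: Number of traits behind the Bonferroni reporting flag.
N_TRAITS_TESTED = 14


@dataclass
class CovariateModelSpec:
    """Outcome of covariate selection for one trait.

    ``codings`` maps each retained covariate to either ``"continuous"`` or
    a level->group dict for a collapsed categorical (group 0 = reference).
    """

    trait: str
    trait_type: str
    codings: dict = field(default_factory=dict)
    alpha: float = 0.05


@dataclass
class AncestryEffects:
    """K-1 joint ancestry coefficients (baseline omitted).

    ``table`` is indexed by ancestry code with columns beta, se, p.
    """

    table: pd.DataFrame
    model: str = ""
    baseline: str = "EUR"
    extra: dict = field(default_factory=dict)

    def significant_14traits(self, ancestry: str) -> bool:
        """Bonferroni reporting flag for a 14-trait study."""
        return bool(self.table.loc[ancestry, "p"] < 0.05 / N_TRAITS_TESTED)


def obesity_from_bmi(bmi, cutoff: float = 32.0) -> np.ndarray:
    """Obesity case status from BMI using the Polynesian-specific 32 kg/m2
    cut-off (higher lean-to-fat ratio at a given BMI than Europeans)."""
    bmi = np.asarray(bmi, dtype=float)
    return (bmi >= cutoff).astype(float)


def _is_categorical(cohort: CohortTable, name: str) -> bool:
    return (name in CATEGORICAL
            or cohort.data[name].dtype == object)


def _dummies(series: pd.Series, drop_level=None) -> pd.DataFrame:
    levels = sorted(series.dropna().unique())
    ref = levels[0] if drop_level is None else drop_level
    cols = {f"{series.name}_{lv}": (series == lv).astype(float)
            for lv in levels if lv != ref}
    return pd.DataFrame(cols, index=series.index)


def _fit(y, X, trait_type):
    Xc = sm.add_constant(X, has_constant="add")
    if trait_type == BINARY:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", True):
            raise ModelError("logistic fit did not converge (separation?)")
        return res
    return sm.OLS(y, Xc).fit()


def select_covariates(cohort: CohortTable, trait: str,
                      candidates: list[str],
                      alpha: float = 0.05) -> CovariateModelSpec:
    """Univariate screen of candidate covariates for one trait.

    Age and sex are always retained. A candidate is retained when its
    univariate association P (overall Wald test for categorical blocks)
    is below ``alpha``; retained categorical covariates have levels whose
    level-vs-reference contrast P >= alpha merged into the reference.
    """
    trait_type = cohort.trait_types.get(trait, QUANTITATIVE)
    yfull = pd.to_numeric(cohort.data[trait])
    if yfull.dropna().nunique() < 2:
        raise ModelError(f"trait {trait!r} is constant")
    codings: dict = {}
    for cand in dict.fromkeys(list(ALWAYS_KEPT) + list(candidates)):
        if cand == trait:
            continue
        col = cohort.data[cand]
        obs = yfull.notna() & col.notna()
        y = yfull[obs]
        if _is_categorical(cohort, cand):
            if col[obs].nunique() < 2:
                logger.warning("covariate %s has one observed level; "
                               "dropped", cand)
                continue
            X = _dummies(col[obs])
            res = _fit(y, X, trait_type)
            overall_p = float(res.f_pvalue) if trait_type == QUANTITATIVE \
                else float(res.llr_pvalue)
            if cand not in ALWAYS_KEPT and not overall_p < alpha:
                continue
            levels = sorted(col.dropna().unique())
            ref = levels[0]
            if cand in ALWAYS_KEPT:  # kept unconditionally, never collapsed
                codings[cand] = {lv: i for i, lv in enumerate(levels)}
                continue
            mapping = {ref: 0}
            grp = 1
            for lv in levels[1:]:
                p = float(res.pvalues[f"{cand}_{lv}"])
                if p < alpha:
                    mapping[lv] = grp
                    grp += 1
                else:
                    mapping[lv] = 0  # merged into reference
            if len(set(mapping.values())) < 2 and cand not in ALWAYS_KEPT:
                continue
            codings[cand] = mapping
        else:
            x = pd.to_numeric(col[obs]).to_numpy(float)
            if np.nanstd(x) == 0:
                logger.warning("covariate %s constant; dropped", cand)
                continue
            res = _fit(y, pd.DataFrame({cand: x}, index=y.index),
                       trait_type)
            if cand in ALWAYS_KEPT or float(res.pvalues[cand]) < alpha:
                codings[cand] = "continuous"
    return CovariateModelSpec(trait, trait_type, codings, alpha)


def design_matrix(cohort: CohortTable,
                  spec: CovariateModelSpec) -> pd.DataFrame:
    """Numeric design for the retained covariates (no intercept column).

    Collapsed categoricals become dummy columns per non-reference group.
    """
    cols = {}
    for name, coding in spec.codings.items():
        col = cohort.data[name]
        if coding == "continuous":
            cols[name] = pd.to_numeric(col).astype(float)
        else:
            grouped = col.map(coding)
            for g in sorted(set(coding.values())):
                if g == 0:
                    continue
                cols[f"{name}_g{g}"] = (grouped == g).astype(float)
    return pd.DataFrame(cols, index=cohort.data.index)


def inverse_normal(values: np.ndarray, offset: float = 3.0 / 8.0
                   ) -> np.ndarray:
    """Rank-based inverse-normal transform (Blom offset 3/8)."""
    v = np.asarray(values, dtype=float)
    r = rankdata(v)
    return norm.ppf((r - offset) / (len(v) + 1 - 2 * offset))


def transform_quantitative(cohort: CohortTable, spec: CovariateModelSpec,
                           standardize_only: bool = False) -> pd.Series:
    """Residualize the trait on its retained covariates, then
    inverse-normalize (default) or z-score the residuals.

    Returns a Series indexed by the complete-case individuals.
    """
    X = design_matrix(cohort, spec)
    y = pd.to_numeric(cohort.data[spec.trait])
    obs = y.notna() & X.notna().all(axis=1)
    X, y = X[obs], y[obs]
    if len(y) <= X.shape[1] + 1:
        raise ModelError("fewer observations than model parameters")
    resid = sm.OLS(y, sm.add_constant(X)).fit().resid.to_numpy()
    if standardize_only:
        out = (resid - resid.mean()) / resid.std(ddof=1)
    else:
        out = inverse_normal(resid)
    return pd.Series(out, index=y.index, name=spec.trait)


def fit_global_ancestry_model(y: pd.Series, ga: GlobalAncestry,
                              trait_type: str = QUANTITATIVE,
                              spec: CovariateModelSpec | None = None,
                              cohort: CohortTable | None = None,
                              adjust_bmi: bool = False,
                              baseline: str = "EUR") -> AncestryEffects:
    """Joint regression of a trait on K-1 global ancestry proportions.

    Quantitative traits are expected pre-transformed (covariates already
    residualized out); binary traits keep the retained covariates in the
    joint logistic model. ``adjust_bmi`` appends BMI as a covariate.
    """
    if baseline not in ga.ancestries:
        raise ModelError(f"baseline {baseline!r} not among ancestries; "
                         "drop one ancestry as the reference to avoid "
                         "collinearity")
    anc_cols = [a for a in ga.ancestries if a != baseline]
    X = ga.proportions.loc[y.index, anc_cols].copy()
    if X.isna().any().any():
        raise ModelError("individual missing global ancestry")
    parts = [X]
    if trait_type == BINARY and spec is not None and cohort is not None:
        parts.append(design_matrix(cohort, spec).loc[y.index])
    if adjust_bmi:
        if cohort is None or "bmi" not in cohort.data.columns:
            raise ModelError("adjust_bmi requires a cohort with a bmi column")
        parts.append(pd.to_numeric(
            cohort.data.loc[y.index, "bmi"]).rename("bmi"))
    Xfull = pd.concat(parts, axis=1)
    res = _fit(y, Xfull, trait_type)
    table = pd.DataFrame({"beta": res.params[anc_cols],
                          "se": res.bse[anc_cols],
                          "p": res.pvalues[anc_cols]})
    tag = ("logistic" if trait_type == BINARY else "linear") + \
        ("+bmi" if adjust_bmi else "")
    return AncestryEffects(table, model=tag, baseline=baseline,
                           extra={"n": int(res.nobs)})


def per_10pct_effect(beta: float, trait_type: str) -> dict:
    """Rescale a per-unit-ancestry effect to per-10%-ancestry reporting.

    Quantitative: s.d. change per 10% ancestry. Binary: odds ratio
    exp(0.1*beta) and the percent increase in odds.
    """
    if not np.isfinite(beta):
        raise ModelError("beta must be finite")
    if trait_type == QUANTITATIVE:
        return {"per10_sd": 0.1 * beta}
    orr = float(np.exp(0.1 * beta))
    return {"per10_or": orr, "per10_pct_odds": 100.0 * (orr - 1.0)}


def fit_nses_mixed_model(y: pd.Series, ga: GlobalAncestry,
                         cohort: CohortTable,
                         trait_type: str = QUANTITATIVE,
                         spec: CovariateModelSpec | None = None,
                         baseline: str = "EUR") -> AncestryEffects:
    """Ancestry association adjusted for neighborhood SES.

    Adds the nSES quintile as a fixed effect and the census tract as a
    random intercept (individuals in one tract share the same nSES by
    design). Linear traits use REML via MixedLM; binary traits use a
    variational Bayes binomial mixed model. With a single census tract the
    model degenerates to fixed effects, with a warning.
    """
    anc_cols = [a for a in ga.ancestries if a != baseline]
    X = ga.proportions.loc[y.index, anc_cols].copy()
    X["nses"] = pd.to_numeric(cohort.data.loc[y.index, "nses"]).astype(float)
    if trait_type == BINARY and spec is not None:
        X = pd.concat([X, design_matrix(cohort, spec).loc[y.index]], axis=1)
    groups = cohort.data.loc[y.index, "census_tract"]
    if groups.nunique() < 2:
        logger.warning("single census tract; falling back to fixed effects")
        res = _fit(y, X, trait_type)
        table = pd.DataFrame({"beta": res.params[anc_cols],
                              "se": res.bse[anc_cols],
                              "p": res.pvalues[anc_cols]})
        return AncestryEffects(table, model="fixed-fallback",
                               baseline=baseline)
    if trait_type == QUANTITATIVE:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = sm.MixedLM(y, sm.add_constant(X), groups=groups)
            res = md.fit(reml=True)
        table = pd.DataFrame({"beta": res.params[anc_cols],
                              "se": res.bse[anc_cols],
                              "p": res.pvalues[anc_cols]})
        ri_sd = float(np.sqrt(res.cov_re.iloc[0, 0]))
        return AncestryEffects(table, model="lmm+nses", baseline=baseline,
                               extra={"random_intercept_sd": ri_sd})
    # binary: variational Bayes binomial GLMM with tract random intercept
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    Xc = sm.add_constant(X)
    exog_vc = pd.get_dummies(groups).to_numpy(float)
    ident = np.zeros(exog_vc.shape[1], dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = BinomialBayesMixedGLM(y.to_numpy(float), Xc.to_numpy(float),
                                   exog_vc, ident,
                                   fe_p=2.5, vcp_p=2.5)
        res = md.fit_vb()
    names = list(Xc.columns)
    beta = pd.Series(res.fe_mean, index=names)
    sd = pd.Series(res.fe_sd, index=names)
    z = beta / sd
    table = pd.DataFrame({"beta": beta[anc_cols], "se": sd[anc_cols],
                          "p": 2 * norm.sf(np.abs(z[anc_cols]))})
    ri_sd = float(np.exp(res.vcp_mean[0]))
    return AncestryEffects(table, model="glmm-vb+nses", baseline=baseline,
                           extra={"random_intercept_sd": ri_sd})


def stratified_and_interaction(y: pd.Series, ga: GlobalAncestry,
                               stratifier: pd.Series,
                               trait_type: str = QUANTITATIVE,
                               baseline: str = "EUR") -> dict:
    """Per-stratum ancestry fits plus a pooled ancestry x stratum model.

    ``stratifier`` is a 0/1 Series aligned with ``y``. Returns a dict with
    per-stratum :class:`AncestryEffects` (NA table if a stratum is too
    small) and the pooled fit's interaction coefficients.
    """
    strat = pd.to_numeric(stratifier.loc[y.index])
    anc_cols = [a for a in ga.ancestries if a != baseline]
    if strat.nunique() < 2:
        raise ModelError("stratifier has a single observed level")
    out: dict = {"strata": {}}
    for s in (0, 1):
        idx = y.index[strat == s]
        k = len(anc_cols) + 1
        if len(idx) <= k + 1:
            out["strata"][s] = AncestryEffects(
                pd.DataFrame(np.nan, index=anc_cols,
                             columns=["beta", "se", "p"]),
                model=f"stratum{s}-NA", baseline=baseline)
            continue
        out["strata"][s] = fit_global_ancestry_model(
            y.loc[idx], ga, trait_type, baseline=baseline)
        out["strata"][s].model = f"stratum{s}"
    X = ga.proportions.loc[y.index, anc_cols].copy()
    X["stratum"] = strat.to_numpy(float)
    for a in anc_cols:
        X[f"{a}:stratum"] = X[a] * X["stratum"]
    res = _fit(y, X, trait_type)
    inter = pd.DataFrame({
        "beta": [res.params[f"{a}:stratum"] for a in anc_cols],
        "se": [res.bse[f"{a}:stratum"] for a in anc_cols],
        "p": [res.pvalues[f"{a}:stratum"] for a in anc_cols]},
        index=anc_cols)
    out["interaction"] = inter
    out["pooled_main"] = pd.DataFrame({
        "beta": res.params[anc_cols], "se": res.bse[anc_cols],
        "p": res.pvalues[anc_cols]})
    return out
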