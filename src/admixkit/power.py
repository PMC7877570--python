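"""Analytic one-stage case-control power for an allelic association test.

Follows the GAS/CaTS one-stage computation: Hardy-Weinberg genotype
frequencies, a multiplicative per-allele genotype relative risk scaled so
the population prevalence matches, expected risk-allele frequencies in
cases and in unaffected controls, and a two-sided two-proportion test on
allele counts (2N alleles per group). Power uses the normal approximation
with the standard error evaluated at the alternative frequencies, which
is the calculator's formulation; at GRR = 1 it returns exactly alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .datatypes import AdmixkitError


@dataclass
class PowerParams:
    """Design parameters of the replication power calculation."""

    n_cases: int
    n_controls: int
    prevalence: float
    risk_allele_freq: float
    grr: float
    alpha: float = 0.05

    def __post_init__(self):
        if not 0 < self.prevalence < 1:
            raise AdmixkitError("prevalence must be in (0, 1)")
        if not 0 < self.risk_allele_freq < 1:
            raise AdmixkitError("risk allele frequency must be in (0, 1)")
        if self.grr <= 0:
            raise AdmixkitError("genotype relative risk must be positive")
        if not 0 < self.alpha < 1:
            raise AdmixkitError("alpha must be in (0, 1)")
        if min(self.n_cases, self.n_controls) < 1:
            raise AdmixkitError("need at least one case and one control")


def expected_allele_freqs(p: PowerParams) -> tuple[float, float]:
    """Risk-allele frequency among cases and among unaffected controls.

    Penetrances follow the multiplicative model f_g = f0 * grr^g with f0
    solved so the population prevalence matches the target; genotype
    frequencies are Hardy-Weinberg.
    """
    q = p.risk_allele_freq
    g = np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])
    rr = np.array([1.0, p.grr, p.grr ** 2])
    f0 = p.prevalence / float(g @ rr)
    f = f0 * rr
    if np.any(f > 1):
        raise AdmixkitError(
            "parameters imply genotype penetrance above 1")
    p_case = float((g[1] * f[1] + 2 * g[2] * f[2]) / (2 * p.prevalence))
    p_ctrl = float((g[1] * (1 - f[1]) + 2 * g[2] * (1 - f[2]))
                   / (2 * (1 - p.prevalence)))
    return p_case, p_ctrl


def gas_power(p: PowerParams) -> float:
    """Power of the two-sided allele-count test at the design parameters."""
    p_case, p_ctrl = expected_allele_freqs(p)
    n1, n2 = 2 * p.n_cases, 2 * p.n_controls
    se = np.sqrt(p_case * (1 - p_case) / n1 + p_ctrl * (1 - p_ctrl) / n2)
    z = norm.ppf(1 - p.alpha / 2)
    d = p_case - p_ctrl
    return float(norm.cdf(-z + d / se) + norm.cdf(-z - d / se))


def simulate_power(p: PowerParams, n_rep: int = 20_000,
                   seed: int = 0) -> float:
    """Monte-Carlo rejection rate of the level-alpha allele test.

    Case and control allele counts are drawn binomially at the expected
    frequencies; the fixed rejection region |p1 - p2| > z * SE uses the
    design standard error, i.e. the test whose power the analytic formula
    computes. Serves as the simulation oracle for ``gas_power``.
    """
    rng = np.random.default_rng(seed)
    p_case, p_ctrl = expected_allele_freqs(p)
    n1, n2 = 2 * p.n_cases, 2 * p.n_controls
    x1 = rng.binomial(n1, p_case, size=n_rep) / n1
    x2 = rng.binomial(n2, p_ctrl, size=n_rep) / n2
    se = np.sqrt(p_case * (1 - p_case) / n1 + p_ctrl * (1 - p_ctrl) / n2)
    z = norm.ppf(1 - p.alpha / 2)
    return float(np.mean(np.abs(x1 - x2) > z * se))
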