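"""Noncentral-t power for paired designs under multiple-testing correction.

For a two-sided paired t-test with n pairs, effect delta (log2 fold change)
and within-subject SD sigma, the test statistic under the alternative follows
a noncentral t distribution with df = n - 1 and noncentrality
ncp = (delta / sigma) * sqrt(n).  Power is the probability mass of that
distribution beyond the two-sided critical values at level alpha — both
rejection tails are counted.

Multiplicity enters through the alpha actually applied per test:
Bonferroni uses alpha/m; the Benjamini–Hochberg procedure, when about k of m
tests are expected to be discoveries at FDR q, applies an effective
per-test threshold of (k/m)*q (the BH step-up boundary at rank k).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError


@dataclass
class PowerSpec:
    n: int
    delta: float
    sigma: float = 0.45
    alpha: float = 0.05
    m: int = 500
    k_expected: int = 30
    fdr_q: float = 0.05

    def validate(self) -> None:
        if self.n < 2:
            raise ConfigError("n must be >= 2")
        if self.sigma <= 0:
            raise ConfigError("sigma must be > 0")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.m < 1:
            raise ConfigError("m must be >= 1")


def paired_t_power(spec: PowerSpec) -> float:
    """Exact two-sided power of the paired t-test via the noncentral t."""
    spec.validate()
    df = spec.n - 1
    ncp = (spec.delta / spec.sigma) * np.sqrt(spec.n)
    tcrit = stats.t.ppf(1 - spec.alpha / 2, df)
    if ncp == 0:
        # central case: both tails sum exactly to alpha
        return float(spec.alpha)
    power = stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp)
    if not np.isfinite(power):
        # scipy's noncentral-t tails underflow for very large |ncp|; fall back
        # to the Gaussian approximation T' ~ N(ncp, 1 + ncp^2/(2 df))
        sd = np.sqrt(1 + ncp ** 2 / (2 * df))
        power = (stats.norm.sf((tcrit - ncp) / sd)
                 + stats.norm.cdf((-tcrit - ncp) / sd))
    return float(power)


def bonferroni_alpha(m: int, family_alpha: float = 0.05) -> float:
    if m < 1:
        raise ConfigError("m must be >= 1")
    return family_alpha / m


def bh_effective_alpha(m: int, k_expected: int, fdr_q: float = 0.05) -> float:
    """Per-test threshold implied by BH when k of m discoveries are expected."""
    if m < 1:
        raise ConfigError("m must be >= 1")
    if not 1 <= k_expected <= m:
        raise ConfigError("k_expected must lie in [1, m]")
    return (k_expected / m) * fdr_q


def fold_change_of_delta(delta: float) -> float:
    """Linear fold change corresponding to a log2 effect size."""
    return float(2.0 ** delta)


def power_table(
    cohorts: dict[str, int],
    deltas,
    sigma: float = 0.45,
    alpha: float = 0.05,
    m: int = 500,
    k_expected: int = 30,
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Power grid: one row per (cohort, delta, alpha-variant).

    ``cohorts`` maps cohort name to paired sample size, e.g.
    ``{"prostate": 26, "bladder": 22, "head_neck": 11}``.
    """
    variants = {
        "nominal": alpha,
        "bh_eff": bh_effective_alpha(m, k_expected, fdr_q),
        "bonferroni": bonferroni_alpha(m, alpha),
    }
    rows = []
    for cohort, n in cohorts.items():
        for delta in deltas:
            for variant, a in variants.items():
                spec = PowerSpec(n=n, delta=float(delta), sigma=sigma, alpha=a,
                                 m=m, k_expected=k_expected, fdr_q=fdr_q)
                rows.append(
                    {
                        "cohort": cohort,
                        "n": n,
                        "delta": float(delta),
                        "fold_change": fold_change_of_delta(delta),
                        "alpha_variant": variant,
                        "alpha": a,
                        "power": paired_t_power(spec),
                    }
                )
    return pd.DataFrame(rows)
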