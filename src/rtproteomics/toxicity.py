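"""Linking factor space to late-toxicity outcomes.

Patients are clustered on their factor-score vectors (data-driven, no
labels), cluster membership is tested against the binary toxicity outcome
with Fisher's exact test, the factor separating the clusters is mined for
its top-weight proteins, and candidate biomarkers are vetted with a
permutation null on loadings, a two-fold-change criterion, and per-protein
predictive statistics (Cohen's d, Mann-Whitney, AUC with bootstrap CI,
logistic odds ratio with Wald CI).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .dea import bh_adjust
from .errors import ConfigError


# ---------------------------------------------------------------------------
# Patient clustering and association
# ---------------------------------------------------------------------------


def cluster_patients(z_scores: pd.DataFrame, method: str = "ward",
                     weights=None, standardise: bool = False) -> pd.Series:
    """Two-group agglomerative clustering of patients on factor scores.

    Ward linkage by default, with complete linkage behind the ``method``
    flag.  Factor-analysis scores are unit-scale by construction (factor
    strength lives in the loadings), so Euclidean clustering on raw scores
    weights every factor equally; passing each factor's variance explained
    as ``weights`` clusters patients in signal space instead (columns scaled
    by sqrt(weight), the analogue of PCA scores carrying their eigenvalues).
    ``standardise`` forces unit variance per factor for the equal-weight
    variant.
    """
    if len(z_scores) < 4:
        raise ConfigError("need at least 4 patients to cluster")
    arr = z_scores.to_numpy(dtype=float)
    if standardise:
        sd = arr.std(axis=0)
        sd[sd == 0] = 1.0
        arr = (arr - arr.mean(axis=0)) / sd
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.shape != (arr.shape[1],) or (w < 0).any():
            raise ConfigError("weights must be one nonnegative value per factor")
        arr = arr * np.sqrt(w)[None, :]
    Z = linkage(pdist(arr), method=method)
    labels = fcluster(Z, t=2, criterion="maxclust")
    return pd.Series(labels, index=z_scores.index, name="cluster")


def fisher_association(clusters: pd.Series, toxicity: pd.Series):
    """Two-sided Fisher exact test of cluster membership vs toxicity.

    Returns ``(p, table)`` with the 2×2 contingency table
    rows = clusters, columns = (non-toxic, toxic).
    """
    clusters, toxicity = clusters.align(toxicity, join="inner")
    labs = sorted(clusters.unique())
    toks = sorted(toxicity.unique())
    if len(labs) != 2:
        raise ConfigError("expected exactly two clusters")
    table = np.array(
        [[int(((clusters == c) & (toxicity == t)).sum()) for t in (0, 1)] for c in labs]
    )
    if len(toks) < 2:
        warnings.warn("degenerate outcome margin (single class); p = 1", stacklevel=2)
        return 1.0, table
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p), table


def factor_cluster_difference(z_scores: pd.DataFrame, clusters: pd.Series) -> pd.DataFrame:
    """Per-factor Welch t-test between the two clusters, Bonferroni-adjusted."""
    clusters = clusters.reindex(z_scores.index)
    labs = sorted(clusters.unique())
    a = z_scores.loc[clusters == labs[0]]
    b = z_scores.loc[clusters == labs[1]]
    if len(a) < 2 or len(b) < 2:
        raise ConfigError("each cluster needs at least 2 patients")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    t = np.where(np.isnan(t), 0.0, t)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance factors: no evidence
    K = z_scores.shape[1]
    return pd.DataFrame(
        {"t_stat": t, "p": p, "p_bonferroni": np.minimum(1.0, p * K)},
        index=z_scores.columns,
    )


# ---------------------------------------------------------------------------
# Loading-based biomarker selection
# ---------------------------------------------------------------------------


def top_weight_proteins(W: pd.DataFrame, factor: str, fraction: float = 0.05) -> pd.DataFrame:
    """The ceil(fraction·m) proteins with the largest absolute loadings.

    Ties are broken by protein identifier (and flagged with a warning);
    rank and loading sign are retained in the output.
    """
    if not 0 < fraction <= 1:
        raise ConfigError("fraction must lie in (0, 1]")
    if factor not in W.columns:
        raise KeyError(f"factor {factor!r} not in loadings; have {list(W.columns)}")
    w = W[factor]
    n_top = math.ceil(fraction * len(w))
    ranked = w.reindex(
        sorted(w.index, key=lambda pid: (-abs(w[pid]), str(pid)))
    )
    cut = abs(ranked.iloc[n_top - 1])
    if n_top < len(ranked) and abs(ranked.iloc[n_top]) == cut:
        warnings.warn("tied absolute loadings at the selection boundary", stacklevel=2)
    top = ranked.iloc[:n_top]
    return pd.DataFrame(
        {"loading": top, "rank": np.arange(1, n_top + 1),
         "sign": np.where(top >= 0, "up", "down")}
    )


def permutation_loading_test(W: pd.DataFrame, factor: str, B: int = 1000,
                             seed: int = 0) -> pd.Series:
    """Empirical permutation p-value per protein for its loading magnitude.

    Each permutation shuffles the observed loading values across protein
    labels; a protein's p is the (add-one smoothed) proportion of
    permutations in which the loading it receives strictly exceeds its
    observed one: p = (1 + #{|w*| > |w|}) / (B + 1), so the top-magnitude
    protein sits at the floor 1/(B+1).
    """
    if B < 100:
        raise ConfigError("B must be >= 100")
    w = W[factor].to_numpy(dtype=float)
    absw = np.abs(w)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(w), dtype=int)
    for _ in range(B):
        perm = rng.permutation(absw)
        exceed += perm > absw
    p = (1.0 + exceed) / (B + 1.0)
    return pd.Series(p, index=W.index, name="perm_p")


def fold_change_validation(matrix_values: pd.DataFrame, toxicity: pd.Series,
                           proteins=None) -> pd.DataFrame:
    """Toxic-vs-non-toxic mean log2 difference with strict two-fold flags.

    ``matrix_values`` is protein × sample (log2 scale) restricted to one
    timepoint; ``toxicity`` maps each sample (column) to 0/1.
    """
    toxicity = toxicity.reindex(matrix_values.columns)
    tox_cols = toxicity.index[toxicity == 1]
    non_cols = toxicity.index[toxicity == 0]
    if len(tox_cols) == 0 or len(non_cols) == 0:
        raise ConfigError("both outcome groups must be non-empty")
    vals = matrix_values if proteins is None else matrix_values.loc[list(proteins)]
    fc = vals[tox_cols].mean(axis=1) - vals[non_cols].mean(axis=1)
    flag = np.where(fc > 1, "up", np.where(fc < -1, "down", ""))
    return pd.DataFrame({"log2_fc": fc, "two_fold": flag})


# ---------------------------------------------------------------------------
# Univariable screening statistics
# ---------------------------------------------------------------------------


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Standardised mean difference with pooled SD (x minus y)."""
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (nx + ny - 2)
    if sp2 == 0:
        return 0.0
    return float((np.mean(x) - np.mean(y)) / np.sqrt(sp2))


def d_category(d: float) -> str:
    ad = abs(d)
    if ad >= 0.8:
        return "large"
    if ad >= 0.5:
        return "moderate"
    return "small"


def auc_from_u(values: np.ndarray, outcome: np.ndarray) -> float:
    """AUC as the normalised Mann-Whitney U statistic (ties count half)."""
    pos = values[outcome == 1]
    neg = values[outcome == 0]
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u / (len(pos) * len(neg)))


@dataclass
class ScreenRow:
    cohens_d: float
    d_category: str
    u_p: float
    auc: float
    n_pos: int
    n_neg: int


def univariable_screen(values, outcome) -> ScreenRow:
    """Effect size, Mann-Whitney p and AUC for one predictor vs toxicity.

    The U-test is exact when both groups have <= 10 untied observations and
    uses the tie-corrected normal approximation otherwise.
    """
    values = np.asarray(values, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    pos, neg = values[outcome == 1], values[outcome == 0]
    if len(pos) < 2 or len(neg) < 2:
        raise ConfigError("need at least 2 observations per outcome group")
    ties = len(np.unique(values)) < len(values)
    method = "exact" if (len(pos) <= 10 and len(neg) <= 10 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(pos, neg, alternative="two-sided", method=method)
    auc = float(res.statistic / (len(pos) * len(neg)))
    d = cohens_d(pos, neg)
    return ScreenRow(d, d_category(d), float(res.pvalue), auc, len(pos), len(neg))


def toxicity_screen(scores_by_timepoint: dict[str, pd.DataFrame],
                    toxicity_by_patient: pd.Series,
                    bootstrap_B: int = 2000, seed: int = 0) -> pd.DataFrame:
    """Per (factor, timepoint) screen: d, U-test p/q (BH within screen), AUC + CI."""
    rows = []
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(sum(Z.shape[1] for Z in scores_by_timepoint.values())))
    for tp, Z in scores_by_timepoint.items():
        tox = toxicity_by_patient.reindex(Z.index).to_numpy(dtype=int)
        for f in Z.columns:
            vals = Z[f].to_numpy(dtype=float)
            row = univariable_screen(vals, tox)
            lo, hi = bootstrap_auc_ci(
                vals, tox, B=bootstrap_B, seed=next(children)
            )
            rows.append(
                {"timepoint": tp, "factor": f, "cohens_d": row.cohens_d,
                 "d_category": row.d_category, "u_p": row.u_p, "auc": row.auc,
                 "auc_ci_low": lo, "auc_ci_high": hi, "bootstrap_B": bootstrap_B}
            )
    out = pd.DataFrame(rows)
    out["u_q"] = bh_adjust(out["u_p"].to_numpy())
    return out


def bootstrap_auc_ci(values, outcome, B: int = 2000, seed=0,
                     level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap CI for the univariable AUC.

    Patients are resampled with replacement; resamples that lose one outcome
    class entirely are redrawn.
    """
    values = np.asarray(values, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    if outcome.min() == outcome.max():
        raise ConfigError("both outcome classes must be present")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(values)
    aucs = np.empty(B)
    for b in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            o = outcome[idx]
            if o.min() != o.max():
                break
        aucs[b] = _fast_auc(values[idx], o)
    alpha = (1 - level) / 2
    return (float(np.quantile(aucs, alpha)), float(np.quantile(aucs, 1 - alpha)))


def _fast_auc(values: np.ndarray, outcome: np.ndarray) -> float:
    """Rank-based AUC (midranks handle ties), equal to U/(n1*n0)."""
    r = stats.rankdata(values)
    n1 = int(outcome.sum())
    n0 = len(outcome) - n1
    u = r[outcome == 1].sum() - n1 * (n1 + 1) / 2
    return u / (n1 * n0)


# ---------------------------------------------------------------------------
# Logistic odds ratios
# ---------------------------------------------------------------------------


@dataclass
class LogisticOr:
    or_per_log2: float
    ci_low: float
    ci_high: float
    slope: float
    se: float
    separable: bool  # True when perfect separation made the OR non-estimable


def logistic_or(values_log2, outcome) -> LogisticOr:
    """Univariable logistic OR per log2 unit with a 95% Wald CI.

    Perfect separation is detected up front and reported as a flagged,
    non-estimable result rather than letting the fit silently diverge.
    """
    x = np.asarray(values_log2, dtype=float)
    y = np.asarray(outcome, dtype=int)
    if y.min() == y.max():
        raise ConfigError("both outcome classes must be present")
    if x[y == 1].min() > x[y == 0].max() or x[y == 1].max() < x[y == 0].min():
        warnings.warn("perfect separation: odds ratio non-estimable", stacklevel=2)
        return LogisticOr(np.inf, np.nan, np.nan, np.inf, np.inf, True)
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    slope = float(fit.params[1])
    se = float(fit.bse[1])
    if not np.isfinite(se) or se > 1e3:
        warnings.warn("quasi-separation: odds ratio non-estimable", stacklevel=2)
        return LogisticOr(np.inf, np.nan, np.nan, slope, se, True)
    return LogisticOr(
        or_per_log2=float(np.exp(slope)),
        ci_low=float(np.exp(slope - 1.96 * se)),
        ci_high=float(np.exp(slope + 1.96 * se)),
        slope=slope,
        se=se,
        separable=False,
    )


# ---------------------------------------------------------------------------
# Biomarker table assembly
# ---------------------------------------------------------------------------


def biomarker_table(
    W: pd.DataFrame,
    factor: str,
    matrix_values: pd.DataFrame,
    toxicity: pd.Series,
    fraction: float = 0.05,
    perm_B: int = 1000,
    perm_p_threshold: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-protein biomarker records for one factor at one timepoint.

    Combines top-|loading| selection, the permutation loading null, the
    toxic-vs-non-toxic fold change, and per-protein OR / AUC into one table
    (the volcano-ready biomarker summary).
    """
    top = top_weight_proteins(W, factor, fraction)
    perm_p = permutation_loading_test(W, factor, B=perm_B, seed=seed)
    fc = fold_change_validation(matrix_values, toxicity, proteins=top.index)
    toxicity = toxicity.reindex(matrix_values.columns)
    rows = []
    for prot in top.index:
        vals = matrix_values.loc[prot].to_numpy(dtype=float)
        tox = toxicity.to_numpy(dtype=int)
        lr = logistic_or(vals, tox)
        rows.append(
            {
                "protein": prot,
                "loading": top.loc[prot, "loading"],
                "perm_p": perm_p[prot],
                "significant": perm_p[prot] <= perm_p_threshold,
                "log2_fc": fc.loc[prot, "log2_fc"],
                "two_fold": fc.loc[prot, "two_fold"],
                "or_per_log2": lr.or_per_log2,
                "or_ci_low": lr.ci_low,
                "or_ci_high": lr.ci_high,
                "or_separable": lr.separable,
                "auc": _fast_auc(vals, tox),
            }
        )
    return pd.DataFrame(rows).set_index("protein")
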