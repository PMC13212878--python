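"""Paired within-subject differential abundance between timepoints.

Contrasts follow a complete-case design: a patient enters a t_a vs t_b
contrast only when both samples are present (and the protein measured in
both), so every protein in a contrast is tested on the same pairs.  Per
protein we report the mean paired log2 difference (the primary fold-change
statistic), the paired-t statistic and two-sided p, the Benjamini–Hochberg
q, and the direction of change.  A linear-scale ratio-of-means fold change
("max fold change" in vendor exports) is carried alongside for comparison.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import IntegrityError
from .preprocess import AbundanceMatrix

#: two-sided p reported when paired differences are a nonzero constant
#: (zero sample variance, unbounded t); documented convention.
P_DEGENERATE = float(np.finfo(float).tiny)


@dataclass
class DeaResult:
    """Per-protein paired differential-abundance statistics for one contrast."""

    table: pd.DataFrame  # log2_fc, t_stat, p, q, n_pairs, direction, ratio_fc
    t_a: str
    t_b: str
    n_pairs: int
    name: str = ""

    def significant(self, q_threshold: float = 0.05) -> set:
        return set(self.table.index[self.table["q"] < q_threshold])


def paired_t_contrast(matrix: AbundanceMatrix, t_a: str, t_b: str,
                      name: str = "") -> DeaResult:
    """Paired t-test of t_b vs t_a per protein on complete pairs."""
    meta = matrix.meta
    a_samples = meta.index[meta["timepoint"] == t_a]
    b_samples = meta.index[meta["timepoint"] == t_b]
    pa = meta.loc[a_samples, "patient_id"]
    pb = meta.loc[b_samples, "patient_id"]
    common = [p for p in pa if p in set(pb)]
    a_by_patient = {p: s for s, p in pa.items()}
    b_by_patient = {p: s for s, p in pb.items()}
    cols_a = [a_by_patient[p] for p in common]
    cols_b = [b_by_patient[p] for p in common]
    A = matrix.values[cols_a].to_numpy(dtype=float)
    B = matrix.values[cols_b].to_numpy(dtype=float)
    ok = ~(np.isnan(A).any(axis=0) | np.isnan(B).any(axis=0))
    A, B = A[:, ok], B[:, ok]
    n = A.shape[1]
    if n < 2:
        raise IntegrityError(
            f"contrast {t_a} vs {t_b}: {n} complete pair(s); need at least 2"
        )
    d = B - A
    mean_d = d.mean(axis=1)
    sd_d = d.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = mean_d / (sd_d / np.sqrt(n))
    p = 2 * stats.t.sf(np.abs(t_stat), df=n - 1)
    zero_var = sd_d == 0
    all_zero = zero_var & (mean_d == 0)
    const_shift = zero_var & (mean_d != 0)
    t_stat[all_zero] = 0.0
    p[all_zero] = 1.0
    t_stat[const_shift] = np.sign(mean_d[const_shift]) * np.inf
    p[const_shift] = P_DEGENERATE
    q = bh_adjust(p)

    if matrix.log_scale:
        lin_a, lin_b = np.exp2(A), np.exp2(B)
    else:  # pragma: no cover - contrasts normally run on log2 data
        lin_a, lin_b = A, B
    ratio = lin_b.mean(axis=1) / lin_a.mean(axis=1)
    ratio_fc = np.maximum(ratio, 1.0 / ratio)

    table = pd.DataFrame(
        {
            "log2_fc": mean_d,
            "t_stat": t_stat,
            "p": p,
            "q": q,
            "n_pairs": n,
            "direction": np.where(mean_d >= 0, "up", "down"),
            "ratio_fc": ratio_fc,
        },
        index=matrix.proteins,
    )
    return DeaResult(table, t_a, t_b, n, name or f"{t_a}_vs_{t_b}")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def rm_anova(matrix: AbundanceMatrix, timepoints) -> pd.DataFrame:
    """One-way repeated-measures ANOVA over the listed timepoints, per protein.

    Patients lacking any of the timepoints (or with a missing value at one)
    are excluded from the whole analysis; the complete-case count is reported
    in the ``n_complete`` column.  When every patient is flat across time the
    F statistic is 0 and p is 1 by convention.
    """
    timepoints = list(timepoints)
    meta = matrix.meta
    by_tp = {}
    for t in timepoints:
        sel = meta.index[meta["timepoint"] == t]
        by_tp[t] = dict(zip(meta.loc[sel, "patient_id"], sel))
    complete = [p for p in matrix.patients if all(p in by_tp[t] for t in timepoints)]
    cube = np.stack(
        [matrix.values[[by_tp[t][p] for p in complete]].to_numpy(float)
         for t in timepoints],
        axis=2,
    )  # proteins × patients × timepoints
    ok = ~np.isnan(cube).any(axis=(1, 2))
    nT = len(timepoints)
    nS = cube.shape[1]
    grand = cube.mean(axis=(1, 2), keepdims=True)
    subj = cube.mean(axis=2, keepdims=True)
    time = cube.mean(axis=1, keepdims=True)
    ss_time = nS * ((time - grand) ** 2).sum(axis=(1, 2))
    ss_subj = nT * ((subj - grand) ** 2).sum(axis=(1, 2))
    ss_tot = ((cube - grand) ** 2).sum(axis=(1, 2))
    ss_err = np.maximum(ss_tot - ss_time - ss_subj, 0.0)
    df_time, df_err = nT - 1, (nT - 1) * (nS - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_time / df_time) / (ss_err / df_err)
    p = stats.f.sf(F, df_time, df_err)
    flat = ss_time <= 1e-12 * np.maximum(ss_tot, 1.0)
    F = np.where(flat, 0.0, F)
    p = np.where(flat, 1.0, p)
    out = pd.DataFrame({"F": F, "p": p, "n_complete": nS}, index=matrix.proteins)
    out.loc[~ok, ["F", "p"]] = np.nan
    return out


def dap_sets(results: list[DeaResult], q_threshold: float = 0.05) -> dict:
    """Significant-protein sets per contrast plus every Venn region.

    Returns ``{"sets": {name: set}, "regions": {membership-tuple: set},
    "region_counts": {...}}`` where a membership tuple like ``("A", "B")``
    is the region of proteins significant in exactly those contrasts.
    """
    if not results:
        raise ValueError("no contrasts supplied")
    universe = set(results[0].table.index)
    for r in results[1:]:
        if set(r.table.index) != universe:
            raise IntegrityError(
                f"contrast {r.name!r} tests a different protein universe"
            )
    sets = {r.name: r.significant(q_threshold) for r in results}
    names = list(sets)
    regions: dict[tuple, set] = {}
    for k in range(1, len(names) + 1):
        for members in itertools.combinations(names, k):
            inside = set.intersection(*(sets[n] for n in members))
            outside = set.union(set(), *(sets[n] for n in names if n not in members))
            regions[members] = inside - outside
    return {
        "sets": sets,
        "regions": regions,
        "region_counts": {k: len(v) for k, v in regions.items()},
    }
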