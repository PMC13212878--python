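"""Unbiased predictive-performance estimation by nested cross-validation.

The outer loop is stratified k-fold CV: each held-out fold estimates
out-of-sample AUC and is never touched during feature selection or model
training.  Inside each outer-training partition, every candidate feature is
scored by univariable AUC over repeated stratified CV (5-fold × 50 repeats
by default); the top-ranked features (or those clearing an AUC threshold)
enter a ridge-penalised logistic model trained on the outer-training set and
scored on the held-out fold.  Selection frequency over all inner iterations
measures feature stability, and a composite score combines predictive
strength, significance and stability into one ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold

from .errors import ConfigError
from .toxicity import _fast_auc

STABILITY_BANDS = (("highly_reproducible", 0.8), ("moderately_stable", 0.5))


def stability_band(freq: float) -> str:
    for name, cut in STABILITY_BANDS:
        if freq >= cut:
            return name
    return "unstable"


@dataclass
class NestedCvResult:
    outer_auc: float                 # mean over outer folds
    pooled_auc: float                # AUC of pooled out-of-fold scores
    fold_aucs: list[float]
    selection_freq: pd.Series        # per-feature, over all inner iterations
    stability: pd.Series
    chosen_features: list[list[str]]  # per outer fold
    outer_folds: int
    inner_folds: int
    inner_repeats: int
    seed: int
    fold_assignments: pd.Series = field(default=None, repr=False)


def _directional_auc(values: np.ndarray, outcome: np.ndarray) -> float:
    """Univariable discriminative AUC, direction-free: max(auc, 1-auc)."""
    a = _fast_auc(values, outcome)
    return max(a, 1.0 - a)


def nested_cv(
    features: pd.DataFrame,
    outcome: pd.Series,
    outer_folds: int = 10,
    inner_folds: int = 5,
    inner_repeats: int = 50,
    seed: int = 0,
    n_select: int = 3,
    auc_threshold: float | None = None,
    ridge_c: float = 1.0,
    outer_splits=None,
) -> NestedCvResult:
    """Nested CV with inner univariable-AUC stability selection.

    ``features`` is patients × candidate features; ``outcome`` binary 0/1 per
    patient.  Features are selected per inner split as the ``n_select`` best
    by validation-fold AUC (or all clearing ``auc_threshold`` when given);
    the outer-training ranking (mean inner AUC) picks the final set for the
    logistic model evaluated on the held-out fold.

    ``outer_splits`` (list of (train_idx, test_idx) pairs) overrides the
    stratified outer partition; it exists so fold assignments can be frozen
    and replayed — e.g. to demonstrate that held-out labels never influence
    feature selection.
    """
    X = features.to_numpy(dtype=float)
    y = outcome.reindex(features.index).to_numpy(dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ConfigError("need at least 2 patients per outcome class")
    if counts.min() < outer_folds:
        warnings.warn(
            f"smallest class has {counts.min()} patients; reducing outer folds "
            f"from {outer_folds} to {counts.min()}",
            stacklevel=2,
        )
        outer_folds = int(counts.min())

    ss = np.random.SeedSequence(seed)
    s_outer, s_inner = ss.spawn(2)
    outer = StratifiedKFold(
        n_splits=outer_folds, shuffle=True,
        random_state=int(s_outer.generate_state(1)[0] % (2 ** 31)),
    )
    inner_state = int(s_inner.generate_state(1)[0] % (2 ** 31))
    splits = (list(outer_splits) if outer_splits is not None
              else list(outer.split(X, y)))

    feat_names = list(features.columns)
    sel_counts = np.zeros(len(feat_names))
    n_inner_iter = 0
    fold_aucs, chosen_all = [], []
    oof_scores = np.full(len(y), np.nan)
    fold_of = np.empty(len(y), dtype=int)

    for fold_i, (tr, te) in enumerate(splits):
        fold_of[te] = fold_i
        Xtr, ytr = X[tr], y[tr]
        n_inner_splits = min(inner_folds, np.bincount(ytr).min())
        inner = RepeatedStratifiedKFold(
            n_splits=n_inner_splits, n_repeats=inner_repeats,
            random_state=inner_state,
        )
        # one selection per repeat: features ranked by their mean
        # validation-fold AUC across that repeat's folds (a per-split pick
        # on 2-5 patient folds would be pure noise)
        mean_auc = np.zeros(len(feat_names))
        repeat_auc = np.zeros(len(feat_names))
        n_splits_done = n_rep_splits = 0
        for split_i, (itr, ival) in enumerate(inner.split(Xtr, ytr)):
            yv = ytr[ival]
            if yv.min() != yv.max():
                aucs = np.array(
                    [_directional_auc(Xtr[ival, j], yv) for j in range(len(feat_names))]
                )
                repeat_auc += aucs
                mean_auc += aucs
                n_splits_done += 1
                n_rep_splits += 1
            if (split_i + 1) % n_inner_splits == 0:  # repeat complete
                if n_rep_splits:
                    rep = repeat_auc / n_rep_splits
                    if auc_threshold is not None:
                        picked = np.flatnonzero(rep >= auc_threshold)
                    else:
                        picked = np.argsort(-rep, kind="stable")[:n_select]
                    sel_counts[picked] += 1
                    n_inner_iter += 1
                repeat_auc[:] = 0.0
                n_rep_splits = 0
        mean_auc /= max(n_splits_done, 1)
        if auc_threshold is not None:
            final = np.flatnonzero(mean_auc >= auc_threshold)
            if final.size == 0:
                final = np.argsort(-mean_auc, kind="stable")[:1]
        else:
            final = np.argsort(-mean_auc, kind="stable")[:n_select]
        chosen = [feat_names[j] for j in final]
        chosen_all.append(chosen)

        clf = LogisticRegression(C=ridge_c, max_iter=2000)
        clf.fit(Xtr[:, final], ytr)
        scores = clf.predict_proba(X[te][:, final])[:, 1]
        oof_scores[te] = scores
        yte = y[te]
        if yte.min() != yte.max():
            fold_aucs.append(_fast_auc(scores, yte))

    freq = pd.Series(sel_counts / max(n_inner_iter, 1), index=feat_names,
                     name="selection_freq")
    return NestedCvResult(
        outer_auc=float(np.mean(fold_aucs)),
        pooled_auc=float(_fast_auc(oof_scores, y)),
        fold_aucs=[float(a) for a in fold_aucs],
        selection_freq=freq,
        stability=freq.map(stability_band),
        chosen_features=chosen_all,
        outer_folds=outer_folds,
        inner_folds=inner_folds,
        inner_repeats=inner_repeats,
        seed=seed,
        fold_assignments=pd.Series(fold_of, index=features.index, name="outer_fold"),
    )


def composite_rank(auc: pd.Series, p_value: pd.Series, stability: pd.Series) -> pd.DataFrame:
    """Mean of min-max-normalised [AUC, -log10 p, selection frequency].

    The aggregation rule is a documented default (configurable by
    pre-transforming the inputs); ranking is descending with ties broken by
    feature identifier.
    """
    if not (len(auc) == len(p_value) == len(stability)):
        raise ConfigError("auc, p_value and stability must be aligned per-feature")
    df = pd.DataFrame({"auc": auc, "neglog10_p": -np.log10(p_value),
                       "stability": stability})

    def minmax(col):
        rng = col.max() - col.min()
        if rng == 0:
            return pd.Series(0.5, index=col.index)
        return (col - col.min()) / rng

    norm = df.apply(minmax)
    score = norm.mean(axis=1)
    if score.duplicated().any():
        warnings.warn("tied composite scores; ties broken by feature identifier",
                      stacklevel=2)
    out = df.assign(composite_score=score)
    out = out.loc[
        sorted(out.index, key=lambda f: (-out.loc[f, "composite_score"], str(f)))
    ]
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def bootstrap_refit_auc(
    features: pd.DataFrame,
    outcome: pd.Series,
    B: int = 1000,
    seed: int = 0,
    ridge_c: float = 1.0,
) -> dict:
    """Apparent AUC under patient-level bootstrap refitting (optimism-prone).

    Each resample draws patients with replacement (single-class resamples
    are redrawn), refits the logistic model, and evaluates AUC on the same
    resample — an in-sample estimate, flagged as such in the output.
    """
    X = features.to_numpy(dtype=float)
    y = outcome.reindex(features.index).to_numpy(dtype=int)
    if y.min() == y.max():
        raise ConfigError("both outcome classes must be present")
    rng = np.random.default_rng(seed)
    n = len(y)
    aucs = np.empty(B)
    for b in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            if y[idx].min() != y[idx].max():
                break
        clf = LogisticRegression(C=ridge_c, max_iter=2000)
        clf.fit(X[idx], y[idx])
        aucs[b] = _fast_auc(clf.predict_proba(X[idx])[:, 1], y[idx])
    return {
        "auc": float(np.median(aucs)),
        "ci_low": float(np.quantile(aucs, 0.025)),
        "ci_high": float(np.quantile(aucs, 0.975)),
        "B": B,
        "in_sample": True,  # optimism-prone by construction
    }
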