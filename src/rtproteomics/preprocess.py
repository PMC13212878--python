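"""Abundance tables and the normalisation / missing-data pipeline.

The central container is :class:`AbundanceMatrix`: a protein × sample grid of
intensities with per-sample metadata (patient, cohort, timepoint, optional
binary toxicity label).  Samples are longitudinal draws from patients at
ordered timepoints ``t0, t1, ...``.

The preprocessing chain for model-based analyses is

    interpolate_missing  →  quantile_normalise  →  log2_and_zscore

Linear interpolation fills only *interior* gaps of each patient's time course
(measured endpoints are never altered, missing endpoints are never invented);
quantile normalisation equalises per-sample intensity distributions; z-scoring
is per protein across samples.  TIC normalisation (equal total intensity per
sample) operates on linear-scale intensities and is therefore applied before
the log2 transform.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import IntegrityError, SchemaError

META_COLUMNS = ("patient_id", "cohort", "timepoint")

_TP_RE = re.compile(r"^t(\d+)$")


def timepoint_index(label: str) -> int:
    """Map a timepoint label 't<k>' to its integer index k."""
    m = _TP_RE.match(str(label))
    if not m:
        raise SchemaError(f"unknown timepoint label {label!r}; expected 't<integer>'")
    return int(m.group(1))


def order_timepoints(labels) -> list[str]:
    return sorted(set(map(str, labels)), key=timepoint_index)


@dataclass
class AbundanceMatrix:
    """Protein × sample intensity grid with per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by protein identifier with one column per sample.
        NaN marks a missing measurement.
    meta
        DataFrame indexed by sample identifier with columns
        ``patient_id, cohort, timepoint`` and optionally ``toxicity``.
    log_scale
        True when ``values`` is on the log2 scale (the pipeline default).
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    log_scale: bool = True
    timepoints: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise SchemaError(f"metadata missing required column(s): {', '.join(missing)}")
        if list(self.values.columns) != list(self.meta.index):
            self.meta = self.meta.reindex(self.values.columns)
            if self.meta["patient_id"].isna().any():
                raise IntegrityError("metadata does not cover every sample column")
        pt = self.meta[["patient_id", "timepoint"]]
        dup = pt.duplicated()
        if dup.any():
            pairs = pt[dup].itertuples(index=False)
            raise IntegrityError(
                "duplicate (patient, timepoint) pairs: "
                + ", ".join(f"({p}, {t})" for p, t in pairs)
            )
        for lab in self.meta["timepoint"]:
            timepoint_index(lab)  # raises on unknown labels
        if not self.timepoints:
            self.timepoints = order_timepoints(self.meta["timepoint"])

    # -- basic views --------------------------------------------------------

    @property
    def proteins(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def patients(self) -> list:
        return list(pd.unique(self.meta["patient_id"]))

    def samples_at(self, timepoint: str) -> pd.Index:
        return self.meta.index[self.meta["timepoint"] == timepoint]

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(
            self.values.copy(), self.meta.copy(), self.log_scale, list(self.timepoints)
        )


# ---------------------------------------------------------------------------
# I/O: long-format TSV (sample_id, protein_id, log2_intensity) + metadata TSV
# ---------------------------------------------------------------------------

LONG_COLUMNS = ("sample_id", "protein_id", "intensity")


def read_abundance(path, meta_path, log_scale: bool = True) -> AbundanceMatrix:
    """Assemble an AbundanceMatrix from a long-format table and a metadata table."""
    long = pd.read_csv(path, sep="\t")
    for col in LONG_COLUMNS:
        if col not in long.columns:
            raise SchemaError(f"abundance table {path} missing column {col!r}")
    meta = pd.read_csv(meta_path, sep="\t")
    if "sample_id" not in meta.columns:
        raise SchemaError(f"metadata table {meta_path} missing column 'sample_id'")
    for col in META_COLUMNS:
        if col not in meta.columns:
            raise SchemaError(f"metadata table {meta_path} missing column {col!r}")
    if long.duplicated(["sample_id", "protein_id"]).any():
        raise IntegrityError("duplicate (sample, protein) measurements in abundance table")
    values = long.pivot(index="protein_id", columns="sample_id", values="intensity")
    meta = meta.set_index("sample_id").reindex(values.columns)
    return AbundanceMatrix(values, meta, log_scale=log_scale)


def write_abundance(matrix: AbundanceMatrix, path, meta_path) -> None:
    long = (
        matrix.values.rename_axis(index="protein_id", columns="sample_id")
        .stack(future_stack=True)
        .rename("intensity")
        .reset_index()[["sample_id", "protein_id", "intensity"]]
        .dropna(subset=["intensity"])
    )
    long.to_csv(path, sep="\t", index=False)
    matrix.meta.rename_axis(index="sample_id").reset_index().to_csv(
        meta_path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Normalisation steps
# ---------------------------------------------------------------------------


def tic_normalise(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Scale each sample so its total intensity equals the grand mean total.

    Operates on linear-scale, nonnegative intensities (total-ion-current
    normalisation); apply before any log transform.
    """
    if matrix.log_scale:
        raise ValueError("tic_normalise expects linear-scale intensities (log_scale=False)")
    vals = matrix.values
    totals = vals.sum(axis=0, skipna=True)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"sample(s) with zero total intensity: {', '.join(map(str, zero))}")
    scaled = vals * (totals.mean() / totals)
    out = matrix.copy()
    out.values = scaled
    return out


def quantile_normalise(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Force every sample onto the common distribution of row-wise sorted means."""
    vals = matrix.values
    if vals.isna().any().any():
        raise ValueError(
            "quantile_normalise requires a complete matrix; run interpolate_missing first"
        )
    arr = vals.to_numpy(dtype=float)
    order = np.argsort(arr, axis=0, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(arr.shape[0])[:, None]
    ranks[order, np.arange(arr.shape[1])[None, :]] = rows
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = matrix.copy()
    out.values = pd.DataFrame(ref[ranks], index=vals.index, columns=vals.columns)
    return out


def interpolate_missing(matrix: AbundanceMatrix, report: dict | None = None) -> AbundanceMatrix:
    """Fill interior missing patient-timepoints by linear interpolation in time.

    Timepoints are treated as equally spaced integer indices (weekly sampling).
    Measured endpoints are never altered and missing endpoints are never
    imputed.  Proteins missing at every sample are dropped.  A protein with
    fewer than two observations for a patient cannot be interpolated for that
    patient and is left missing; such (patient, protein) pairs are counted in
    ``report['uninterpolable']`` when a dict is supplied.
    """
    tps = matrix.timepoints
    tp_pos = {t: i for i, t in enumerate(tps)}
    vals = matrix.values
    all_missing = vals.isna().all(axis=1)
    if all_missing.any():
        vals = vals.loc[~all_missing]

    meta = matrix.meta
    new_cols: dict = {}
    new_meta_rows: dict = {}
    uninterpolable = 0
    for patient, pmeta in meta.groupby("patient_id", sort=False):
        pmeta = pmeta.sort_values("timepoint", key=lambda s: s.map(tp_pos))
        observed = list(pmeta["timepoint"])
        sample_of = dict(zip(observed, pmeta.index))
        lo, hi = tp_pos[observed[0]], tp_pos[observed[-1]]
        grid = [tps[i] for i in range(lo, hi + 1)]
        block = pd.DataFrame(
            {t: vals[sample_of[t]] if t in sample_of else np.nan for t in grid}
        )
        block.columns = [tp_pos[t] for t in grid]
        n_before = int(block.isna().sum().sum())
        filled = block.T.interpolate(method="index", limit_area="inside").T
        uninterpolable += int(filled.isna().sum().sum())
        del n_before
        for t in grid:
            col = filled[tp_pos[t]]
            if t in sample_of:
                new_cols[sample_of[t]] = col
            elif col.notna().any():
                sid = f"{patient}_{t}"
                new_cols[sid] = col
                template = pmeta.iloc[0].copy()
                template["timepoint"] = t
                new_meta_rows[sid] = template
    values = pd.DataFrame(new_cols)
    meta_out = pd.concat([meta.loc[meta.index.intersection(values.columns)],
                          pd.DataFrame(new_meta_rows).T])
    meta_out = meta_out.reindex(values.columns)
    if report is not None:
        report["uninterpolable"] = uninterpolable
        report["proteins_dropped"] = int(all_missing.sum())
    return AbundanceMatrix(values, meta_out, matrix.log_scale, list(tps))


def log2_and_zscore(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """log2-transform (when still linear) then z-score each protein across samples.

    Zero-variance proteins get an all-zero row and a warning rather than being
    dropped, so protein universes stay aligned across contrasts.
    """
    vals = matrix.values
    if not matrix.log_scale:
        if (vals <= 0).any().any():
            raise ValueError("log2 transform requires strictly positive intensities")
        vals = np.log2(vals)
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance protein(s) z-scored to 0", stacklevel=2
        )
    sd = sd.where(~flat, 1.0)
    z = vals.sub(mean, axis=0).div(sd, axis=0)
    z.loc[flat.index[flat]] = 0.0
    out = matrix.copy()
    out.values = z
    out.log_scale = True
    return out
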