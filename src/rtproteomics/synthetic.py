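"""Synthetic longitudinal plasma-proteomics cohorts with planted structure.

The generator emulates the design of a weekly radiotherapy sampling study:
patients contribute a baseline sample (t0) and weekly on-treatment samples,
protein intensities live on the log2 scale with a within-subject noise SD of
about 0.45 log2 units, and a binary late-toxicity outcome is linked to one
latent factor of between-patient variation.

Generative model (log2 scale), for protein j, patient i, timepoint t:

    x[j, i, t] = mu_j + b[i, j] + g_cls(j)(t) + sum_k W[j, k] * Z[i, t, k] + e

* ``mu_j`` — baseline protein mean, Normal on the log2 scale (log-normal
  linear intensities, mimicking the dynamic range of plasma).
* ``b[i, j]`` — patient random intercept, Normal(0, intercept_sd**2).
* ``g_cls`` — planted kinetic trajectory (monotone up, monotone down, or a
  non-monotone bump) for a subset of proteins.
* ``Z`` — latent factor scores: per-patient Normal(0, 1) base plus a linear
  per-patient temporal drift; toxic patients are shifted by
  ``toxicity_effect`` (Cohen's d units) on the designated toxicity factor.
* ``W`` — sparse loadings; proteins with nonzero loading on the toxicity
  factor are the planted biomarkers.
* ``e`` — Normal(0, sigma_within**2) within-subject measurement noise.

All randomness flows from one seed through ``numpy.random.SeedSequence``
spawning, so every output is bit-identical for a given configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigError
from .preprocess import AbundanceMatrix, order_timepoints, timepoint_index

KINETIC_CLASSES = ("increasing", "decreasing", "nonmonotone")


@dataclass
class CohortConfig:
    """Study-design parameters for one simulated cohort.

    Defaults mirror the prostate cohort: 26 patients sampled weekly t0–t4,
    ~500 quantified proteins, within-subject SD 0.45 log2 units, and 17/26
    patients developing late toxicity.
    """

    n_patients: int = 26
    n_proteins: int = 500
    timepoints: tuple[str, ...] = ("t0", "t1", "t2", "t3", "t4")
    sigma_within: float = 0.45
    n_factors_true: int = 3
    toxicity_factor_index: int = 0
    toxicity_effect: float = 2.0
    frac_toxic: float = 17 / 26
    missing_rate: float = 0.0
    seed: int = 0
    cohort: str = "prostate"
    intercept_sd: float = 0.3
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0
    loading_density: float = 0.05
    loading_sd: float = 0.5
    temporal_drift_sd: float = 0.3
    secondary_score_sd: float = 0.6
    kinetic_fraction: float = 0.3
    kinetic_amplitude: float = 1.0
    toxicity_profile: str = "constant"  # or "growing": shift ramps 0 -> effect

    def validate(self) -> None:
        if self.n_patients < 4:
            raise ConfigError("n_patients must be >= 4")
        if len(self.timepoints) < 3:
            raise ConfigError("timepoints must contain at least 3 labels")
        for t in self.timepoints:
            timepoint_index(t)
        if not 0 <= self.missing_rate < 0.5:
            raise ConfigError("missing_rate must lie in [0, 0.5)")
        if self.sigma_within <= 0:
            raise ConfigError("sigma_within must be > 0")
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be >= 1")
        if not 0 < self.frac_toxic < 1:
            raise ConfigError("frac_toxic must lie in (0, 1)")
        if self.n_factors_true < 1:
            raise ConfigError("n_factors_true must be >= 1")
        if not 0 <= self.toxicity_factor_index < self.n_factors_true:
            raise ConfigError("toxicity_factor_index must index a true factor")
        if self.toxicity_profile not in ("constant", "growing"):
            raise ConfigError("toxicity_profile must be 'constant' or 'growing'")


@dataclass
class GroundTruth:
    """Planted parameters for recovery tests."""

    true_scores: np.ndarray        # patients × timepoints × factors
    true_loadings: np.ndarray      # proteins × factors
    toxic_patients: list[str]
    planted_biomarkers: list[str]
    planted_kinetic_class: dict[str, str]
    config: CohortConfig = field(repr=False, default=None)

    def to_json(self, path) -> None:
        payload = {
            "true_scores": self.true_scores.tolist(),
            "true_loadings": self.true_loadings.tolist(),
            "toxic_patients": self.toxic_patients,
            "planted_biomarkers": self.planted_biomarkers,
            "planted_kinetic_class": self.planted_kinetic_class,
            "config": asdict(self.config) if self.config else None,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _kinetic_curve(cls: str, n_t: int, amplitude: float) -> np.ndarray:
    s = np.linspace(0.0, 1.0, n_t)
    if cls == "increasing":
        return amplitude * s
    if cls == "decreasing":
        return -amplitude * s
    return amplitude * np.sin(np.pi * s)  # bump: up then down


def simulate_cohort(config: CohortConfig):
    """Draw one cohort; returns (AbundanceMatrix, metadata table, GroundTruth)."""
    config.validate()
    tps = order_timepoints(config.timepoints)
    n, m, T, K = config.n_patients, config.n_proteins, len(tps), config.n_factors_true

    ss = np.random.SeedSequence(config.seed)
    (s_base, s_load, s_scores, s_tox, s_kin, s_noise, s_miss) = ss.spawn(7)
    rng_base = np.random.default_rng(s_base)
    rng_load = np.random.default_rng(s_load)
    rng_scores = np.random.default_rng(s_scores)
    rng_tox = np.random.default_rng(s_tox)
    rng_kin = np.random.default_rng(s_kin)
    rng_noise = np.random.default_rng(s_noise)

    patients = [f"P{i:02d}" for i in range(1, n + 1)]
    proteins = [f"PROT{j:04d}" for j in range(1, m + 1)]

    # baseline means: log-normal linear intensities == normal on log2 scale
    mu = rng_base.normal(config.baseline_mean, config.baseline_sd, size=m)

    # sparse loadings; at least 10 proteins per factor
    W = np.zeros((m, K))
    per_factor = max(10, int(round(config.loading_density * m)))
    per_factor = min(per_factor, m)
    for k in range(K):
        idx = rng_load.choice(m, size=per_factor, replace=False)
        W[idx, k] = rng_load.normal(0.0, config.loading_sd, size=per_factor)

    tox_k = config.toxicity_factor_index
    planted_biomarkers = [proteins[j] for j in np.flatnonzero(W[:, tox_k])]

    # factor scores: patient base + linear temporal drift; the toxicity-linked
    # factor is the dominant patient-level axis (unit SD), secondary factors
    # weaker, mirroring an outcome-linked primary factor of variation
    score_sd = np.full(K, config.secondary_score_sd)
    score_sd[config.toxicity_factor_index] = 1.0
    base = rng_scores.normal(0.0, 1.0, size=(n, K)) * score_sd[None, :]
    drift = rng_scores.normal(0.0, config.temporal_drift_sd, size=(n, K))
    s = np.linspace(0.0, 1.0, T)
    Z = base[:, None, :] + drift[:, None, :] * s[None, :, None]  # n × T × K

    n_toxic = int(round(config.frac_toxic * n))
    toxic_idx = np.sort(rng_tox.choice(n, size=n_toxic, replace=False))
    toxic_patients = [patients[i] for i in toxic_idx]
    if config.toxicity_profile == "constant":
        shift = np.full(T, config.toxicity_effect)
    else:
        shift = config.toxicity_effect * s
    Z[toxic_idx, :, tox_k] += shift[None, :]

    # planted kinetic trajectories
    n_kinetic = int(round(config.kinetic_fraction * m))
    kin_idx = rng_kin.choice(m, size=n_kinetic, replace=False)
    classes = np.array(KINETIC_CLASSES)[np.arange(n_kinetic) % 3]
    rng_kin.shuffle(classes)
    planted_kinetic_class = {proteins[j]: c for j, c in zip(kin_idx, classes)}
    G = np.zeros((m, T))
    for j, c in zip(kin_idx, classes):
        G[j] = _kinetic_curve(c, T, config.kinetic_amplitude)

    intercept = rng_noise.normal(0.0, config.intercept_sd, size=(n, m))
    noise = rng_noise.normal(0.0, config.sigma_within, size=(n, T, m))

    # assemble log2 abundances: proteins × (patient, timepoint)
    signal = np.einsum("itk,jk->itj", Z, W)  # n × T × m
    x = mu[None, None, :] + intercept[:, None, :] + G.T[None, :, :] + signal + noise

    sample_ids = [f"{p}_{t}" for p in patients for t in tps]
    values = pd.DataFrame(
        x.reshape(n * T, m).T, index=pd.Index(proteins, name="protein_id"),
        columns=pd.Index(sample_ids, name="sample_id"),
    )
    meta = pd.DataFrame(
        {
            "patient_id": [p for p in patients for _ in tps],
            "cohort": config.cohort,
            "timepoint": [t for _ in patients for t in tps],
            "toxicity": [int(p in toxic_patients) for p in patients for _ in tps],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    matrix = AbundanceMatrix(values, meta, log_scale=True, timepoints=list(tps))
    if config.missing_rate > 0:
        matrix = inject_missingness(
            matrix, config.missing_rate, seed=np.random.default_rng(s_miss)
        )
    truth = GroundTruth(
        true_scores=Z,
        true_loadings=W,
        toxic_patients=toxic_patients,
        planted_biomarkers=planted_biomarkers,
        planted_kinetic_class=planted_kinetic_class,
        config=config,
    )
    return matrix, matrix.meta.copy(), truth


def inject_missingness(matrix: AbundanceMatrix, rate: float, seed=0) -> AbundanceMatrix:
    """Remove ``round(rate × eligible)`` intermediate patient-timepoint samples.

    The first and last observed timepoint of each patient are never removed,
    matching an interpolation-only missing-data model where endpoints must be
    measured.
    """
    if not 0 <= rate < 0.5:
        raise ConfigError("missing_rate must lie in [0, 0.5)")
    if rate == 0:
        return matrix.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos = {t: i for i, t in enumerate(matrix.timepoints)}
    eligible = []
    for patient, pmeta in matrix.meta.groupby("patient_id", sort=False):
        tps = sorted(pmeta["timepoint"], key=pos.get)
        interior = set(tps[1:-1])
        eligible.extend(
            sid for sid, t in zip(pmeta.index, pmeta["timepoint"]) if t in interior
        )
    k = int(round(rate * len(eligible)))
    drop = rng.choice(len(eligible), size=k, replace=False)
    drop_ids = {eligible[i] for i in drop}
    keep = [c for c in matrix.values.columns if c not in drop_ids]
    return AbundanceMatrix(
        matrix.values[keep], matrix.meta.loc[keep], matrix.log_scale,
        list(matrix.timepoints),
    )
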