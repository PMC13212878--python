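"""End-to-end orchestration: YAML config, deterministic seeding, provenance.

``run_pipeline`` executes the stages in dependency order —
simulate → preprocess → differential abundance → power table → kinetic
clustering → factor model → toxicity stratification → nested CV →
(optional) enrichment — writing per-stage TSV/JSON outputs plus a manifest
recording the config hash, the run seed, package versions and per-stage row
counts.  Every stochastic stage draws its seed from the run seed through a
``numpy.random.SeedSequence`` spawn with a fixed stage order, so identical
config + inputs reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError
from .preprocess import (AbundanceMatrix, interpolate_missing, log2_and_zscore,
                         quantile_normalise, write_abundance)
from .synthetic import CohortConfig, simulate_cohort
from . import dea as dea_mod
from . import power as power_mod
from . import kinetics as kin_mod
from . import factors as fac_mod
from . import toxicity as tox_mod
from . import predictive as pred_mod
from . import enrichment as enr_mod

# fixed stage order for seed spawning: changing it would change every run
STAGES = ("simulate", "dea", "factorize", "toxicity", "nestedcv")


@dataclass
class RunConfig:
    """Pipeline parameters; every threshold is a default, never hard-coded."""

    seed: int = 0
    out_dir: str = "run"
    cohort: dict = field(default_factory=dict)        # CohortConfig overrides
    contrasts: list = field(default_factory=lambda: [["t0", "t1"], ["t0", "t3"], ["t0", "t4"]])
    q_threshold: float = 0.05
    n_clusters: int = 3
    k_factors: int = 10
    retain_pct: float = 2.0
    temporal: bool = False
    screen_timepoint: str = "t0"
    top_fraction: float = 0.05
    perm_B: int = 1000
    bootstrap_B: int = 2000
    outer_folds: int = 10
    inner_folds: int = 5
    inner_repeats: int = 50
    power_deltas: tuple = (0.4, 0.7, 1.0)
    power_m: int = 500
    power_k_expected: int = 30
    gmt_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {', '.join(sorted(unknown))}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def validate(self) -> None:
        if not 0 < self.q_threshold < 1:
            raise ConfigError("q_threshold must lie in (0, 1)")
        if self.k_factors < 1:
            raise ConfigError("k_factors must be >= 1")
        if not 0 < self.top_fraction <= 1:
            raise ConfigError("top_fraction must lie in (0, 1]")
        for pair in self.contrasts:
            if len(pair) != 2:
                raise ConfigError(f"contrasts entries must be [t_a, t_b]; got {pair}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def stage_seeds(seed: int) -> dict[str, np.random.SeedSequence]:
    """One child SeedSequence per stochastic stage, in fixed order."""
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return dict(zip(STAGES, children))


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_pipeline(config: RunConfig, matrix: AbundanceMatrix | None = None) -> dict:
    """Execute the full pipeline; returns the manifest dict.

    When ``matrix`` is None a cohort is simulated from ``config.cohort``.
    Stage outputs land under ``config.out_dir``; any stage failure raises
    with the stage name while earlier outputs are retained on disk.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest: dict = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    config.to_yaml(out / "config.yaml")

    stage = "simulate"
    try:
        truth = None
        if matrix is None:
            cohort_cfg = CohortConfig(**config.cohort)
            cohort_cfg.seed = _seed_int(seeds["simulate"])
            matrix, meta, truth = simulate_cohort(cohort_cfg)
            write_abundance(matrix, out / "abundance.tsv", out / "metadata.tsv")
            truth.to_json(out / "truth.json")
        manifest["stages"]["simulate"] = {
            "n_samples": int(matrix.values.shape[1]),
            "n_proteins": int(matrix.values.shape[0]),
        }

        stage = "preprocess"
        matrix = interpolate_missing(matrix)
        matrix = quantile_normalise(matrix)
        matrix = log2_and_zscore(matrix)
        write_abundance(matrix, out / "abundance_preprocessed.tsv",
                        out / "metadata_preprocessed.tsv")
        manifest["stages"]["preprocess"] = {
            "n_samples": int(matrix.values.shape[1]),
            "n_proteins": int(matrix.values.shape[0]),
        }

        stage = "dea"
        results = []
        for t_a, t_b in config.contrasts:
            res = dea_mod.paired_t_contrast(matrix, t_a, t_b)
            res.table.to_csv(out / f"dea_{res.name}.tsv", sep="\t")
            results.append(res)
        venn = dea_mod.dap_sets(results, config.q_threshold)
        (out / "dap_regions.json").write_text(json.dumps(
            {"|".join(k): sorted(v) for k, v in venn["regions"].items()}
        ))
        manifest["stages"]["dea"] = {
            r.name: int(len(r.significant(config.q_threshold))) for r in results
        }

        stage = "power"
        cohorts = {"prostate": 26, "bladder": 22, "head_neck": 11}
        ptab = power_mod.power_table(
            cohorts, config.power_deltas, m=config.power_m,
            k_expected=config.power_k_expected,
        )
        ptab.to_csv(out / "power_table.tsv", sep="\t", index=False)
        manifest["stages"]["power"] = {"rows": int(len(ptab))}

        stage = "kinetics"
        shared = set.intersection(*(r.significant(config.q_threshold) for r in results))
        manifest["stages"]["kinetics"] = {"shared_daps": len(shared)}
        if len(shared) >= config.n_clusters:
            prof = kin_mod.mean_trajectories(matrix, sorted(shared))
            clus = kin_mod.correlation_cluster(prof, config.n_clusters)
            labels = clus.labels.to_frame()
            labels["archetype"] = [
                kin_mod.cluster_archetypes(prof, clus.labels)[c] for c in clus.labels
            ]
            labels.to_csv(out / "kinetic_clusters.tsv", sep="\t")
            manifest["stages"]["kinetics"]["silhouette"] = clus.silhouette

        stage = "factorize"
        fit = fac_mod.fit_temporal_model if config.temporal else fac_mod.fit_factor_model
        model = fit(matrix, config.k_factors, seed=_seed_int(seeds["factorize"]))
        model = fac_mod.retain_factors(model, config.retain_pct)
        model.save(out / "factor_model")
        manifest["stages"]["factorize"] = {
            "k_retained": model.K,
            "var_explained": [float(v) for v in model.var_explained],
        }

        stage = "toxicity"
        z0 = fac_mod.factor_scores_at(model, config.screen_timepoint)
        tox = matrix.meta.drop_duplicates("patient_id").set_index("patient_id")["toxicity"]
        clusters = tox_mod.cluster_patients(z0, weights=model.var_explained)
        fisher_p, table = tox_mod.fisher_association(clusters, tox.reindex(z0.index))
        fdiff = tox_mod.factor_cluster_difference(z0, clusters)
        lead_factor = fdiff["p_bonferroni"].idxmin()
        samples0 = matrix.samples_at(config.screen_timepoint)
        vals0 = matrix.values[samples0]
        tox_by_sample = matrix.meta.loc[samples0, "toxicity"]
        bio = tox_mod.biomarker_table(
            model.W, lead_factor, vals0, tox_by_sample,
            fraction=config.top_fraction, perm_B=config.perm_B,
            seed=_seed_int(seeds["toxicity"]),
        )
        bio.to_csv(out / "biomarkers.tsv", sep="\t")
        screen = tox_mod.toxicity_screen(
            {t: fac_mod.factor_scores_at(model, t) for t in matrix.timepoints},
            tox, bootstrap_B=config.bootstrap_B, seed=_seed_int(seeds["toxicity"]) + 1,
        )
        screen.to_csv(out / "toxicity_screen.tsv", sep="\t", index=False)
        manifest["stages"]["toxicity"] = {
            "fisher_p": fisher_p,
            "table": table.tolist(),
            "lead_factor": str(lead_factor),
            "n_biomarkers": int(bio["significant"].sum()),
        }

        stage = "nestedcv"
        cv = pred_mod.nested_cv(
            z0, tox.reindex(z0.index), outer_folds=config.outer_folds,
            inner_folds=config.inner_folds, inner_repeats=config.inner_repeats,
            seed=_seed_int(seeds["nestedcv"]),
        )
        (out / "nestedcv.json").write_text(json.dumps(
            {
                "outer_auc": cv.outer_auc, "pooled_auc": cv.pooled_auc,
                "fold_aucs": cv.fold_aucs,
                "selection_freq": cv.selection_freq.to_dict(),
                "stability": cv.stability.to_dict(),
                "chosen_features": cv.chosen_features,
            }
        ))
        manifest["stages"]["nestedcv"] = {"outer_auc": cv.outer_auc}

        if config.gmt_path:
            stage = "enrich"
            lib = enr_mod.read_gmt(config.gmt_path)
            hits = enr_mod.ora(set(bio.index), set(matrix.proteins), lib,
                               q_threshold=config.q_threshold)
            hits.to_csv(out / "enrichment.tsv", sep="\t")
            manifest["stages"]["enrich"] = {"n_enriched": int(len(hits))}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
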