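import numpy as np
import pandas as pd
import pytest

from rtproteomics.preprocess import AbundanceMatrix
from rtproteomics.synthetic import CohortConfig, simulate_cohort


def make_matrix(values: np.ndarray, patients, timepoints, proteins=None,
                toxicity=None, log_scale=True) -> AbundanceMatrix:
    """Assemble an AbundanceMatrix from a (protein, patient, timepoint) cube."""
    m = values.shape[0]
    proteins = proteins or [f"PROT{j}" for j in range(m)]
    samples, meta_rows, cols = [], [], []
    for i, p in enumerate(patients):
        for t_i, t in enumerate(timepoints):
            sid = f"{p}_{t}"
            samples.append(sid)
            meta_rows.append(
                {"patient_id": p, "cohort": "test", "timepoint": t,
                 "toxicity": 0 if toxicity is None else toxicity[i]}
            )
            cols.append(values[:, i, t_i])
    df = pd.DataFrame(np.column_stack(cols), index=proteins, columns=samples)
    meta = pd.DataFrame(meta_rows, index=samples)
    return AbundanceMatrix(df, meta, log_scale=log_scale)


@pytest.fixture(scope="session")
def prostate_cohort():
    """Default prostate-like cohort: 26 patients, t0-t4, 17 toxic."""
    cfg = CohortConfig(n_patients=26, n_proteins=150, seed=7)
    matrix, meta, truth = simulate_cohort(cfg)
    return matrix, meta, truth


@pytest.fixture()
def three_factor_config():
    """A clean planted 3-factor cohort (no kinetics/intercepts/drift)."""
    def _make(seed=0, n_proteins=200):
        return CohortConfig(
            n_patients=26, n_proteins=n_proteins, seed=seed,
            kinetic_fraction=0.0, intercept_sd=0.0, temporal_drift_sd=0.0,
            toxicity_effect=0.0, secondary_score_sd=1.0,
            loading_density=0.1, loading_sd=0.45 * np.sqrt(3.0),
        )
    return _make
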