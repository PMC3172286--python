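import numpy as np
import pandas as pd
import pytest

from marrownet.io import ExpressionMatrix
from marrownet.simulate import SimConfig, simulate_timecourse

TIMEPOINTS = (0, 3, 7, 11, 21)


def make_matrix(values: np.ndarray, genes: list[str], n_replicates: int,
                timepoints=TIMEPOINTS) -> ExpressionMatrix:
    """Build an ExpressionMatrix from a (genes x samples) intensity array
    laid out timepoint-major with n_replicates chips per timepoint."""
    columns = [f"t{tp}_r{r}" for tp in timepoints for r in range(1, n_replicates + 1)]
    frame = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=columns)
    samples = pd.DataFrame(
        {
            "timepoint_days": [tp for tp in timepoints for _ in range(n_replicates)],
            "replicate": [r for _ in timepoints for r in range(1, n_replicates + 1)],
            "group": ["baseline" if tp == 0 else "irradiated"
                      for tp in timepoints for _ in range(n_replicates)],
        },
        index=pd.Index(columns, name="sample_id"),
    )
    return ExpressionMatrix(frame, samples)


def matrix_from_log2(log2_values: np.ndarray, genes: list[str], n_replicates: int,
                     timepoints=TIMEPOINTS) -> ExpressionMatrix:
    return make_matrix(2.0 ** np.asarray(log2_values, float), genes, n_replicates, timepoints)


@pytest.fixture(scope="session")
def small_sim():
    """A 500-gene / 100-DE synthetic experiment with one planted module."""
    cfg = SimConfig(n_genes=500, n_de=100, noise_sd=0.2, effect_log2=1.0, seed=7)
    matrix, truth = simulate_timecourse(cfg)
    return cfg, matrix, truth
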