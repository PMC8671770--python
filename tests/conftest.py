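import numpy as np
import pytest

from edmood.instruments import score_record
from edmood.synthetic_data import GeneratorConfig, GroupSpec, IntakeSpec, generate_cohort

#: published per-cluster (n, mean, sd) summaries used as recomputation inputs
ANXIETY_SUMMARY = [(609, 1.84, 1.45), (567, 6.61, 1.32), (371, 12.30, 1.69), (245, 18.89, 1.92)]
DEPRESSION_SUMMARY = [(609, 0.56, 0.83), (567, 1.45, 1.17), (371, 2.42, 1.15), (245, 3.49, 1.63)]
EATING_CONCERN_SUMMARY = [(609, 1.54, 0.79), (567, 2.01, 1.09), (371, 2.58, 1.46), (245, 3.28, 1.78)]
WEIGHT_CONCERN_SUMMARY = [(609, 2.21, 1.30), (567, 2.85, 1.47), (371, 3.52, 1.66), (245, 4.14, 1.79)]
SHAPE_CONCERN_SUMMARY = [(609, 2.11, 1.00), (567, 2.67, 1.14), (371, 3.23, 1.26), (245, 3.73, 1.32)]
BINGE_SUMMARY = [(609, 2.75, 2.87), (567, 3.58, 3.48), (371, 4.76, 4.71), (245, 5.08, 5.59)]
EXERCISE_SUMMARY = [(609, 1.60, 1.28), (567, 1.59, 1.09), (371, 1.89, 1.42), (245, 1.76, 1.30)]

#: per-cluster GAD-7 / PHQ-2 generating means of the default config
GAD_TARGETS = [1.84, 6.61, 12.30, 18.89]
PHQ_TARGETS = [0.56, 1.45, 2.42, 3.49]


def small_config(seed: int = 7, n_per_group: int = 40) -> GeneratorConfig:
    """Scaled-down four-group config for fast unit tests."""
    cfg = GeneratorConfig.default(seed=seed)
    for g in cfg.groups:
        g.n = n_per_group
    cfg.intake = IntakeSpec(n_duplicates=5, n_incomplete=8, n_over_age=3,
                            n_foreign_hs=4, n_graduate=2)
    return cfg


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config())


@pytest.fixture(scope="session")
def small_scores(small_cohort):
    return [score_record(r) for r in small_cohort]


@pytest.fixture(scope="session")
def small_points(small_scores):
    return np.array([[s.gad7_total, s.phq2_total] for s in small_scores], dtype=float)


def two_blobs(n_per_blob: int = 30, seed: int = 0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    a = rng.normal([0.0, 0.0], 0.5, size=(n_per_blob, 2))
    b = rng.normal([20.0, 5.0], 0.5, size=(n_per_blob, 2))
    return np.vstack([a, b])


def four_blobs(n_per_blob: int = 50, seed: int = 3) -> np.ndarray:
    rng = np.random.default_rng(seed)
    centers = [(2.0, 0.5), (7.0, 1.5), (12.0, 2.5), (19.0, 3.5)]
    return np.vstack(
        [rng.normal(c, 0.6, size=(n_per_blob, 2)) for c in centers]
    )
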