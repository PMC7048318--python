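import numpy as np
import pytest

from goalweaver.task import TaskConfig
from goalweaver.planner import backward_induction
from goalweaver.cohort import CohortSpec, generate_dataset

#: initial points whose optimal-agent two-goal success probabilities
#: (exact forward recursion: 0.7504, 0.3553, 0.0707) sit on the
#: 75/35/7% difficulty targets; used where re-running the calibration
#: search would only add noise.
REFERENCE_CONDITIONS = {"easy": (7, 7), "medium": (7, 5), "hard": (6, 4)}


@pytest.fixture(scope="session")
def config():
    return TaskConfig()


@pytest.fixture(scope="session")
def tables():
    """Optimal-agent value tables (gamma=1, kappa=1) for the default task."""
    return backward_induction(TaskConfig(), gamma=1.0, kappa=1.0)


@pytest.fixture(scope="session")
def conditions():
    return dict(REFERENCE_CONDITIONS)


@pytest.fixture(scope="session")
def small_cohort():
    """10 subjects x 12 blocks drawn from the default population model."""
    spec = CohortSpec(n_subjects=10, n_blocks=12,
                      blocks_per_condition=(4, 4, 4), seed=2024)
    records, truth = generate_dataset(spec, conditions=REFERENCE_CONDITIONS)
    return records, truth
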