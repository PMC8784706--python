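import numpy as np
import pandas as pd
import pytest

from etioscope.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def triangle_data():
    """300 points drawn inside a triangle, vertices included, zero noise."""
    rng = np.random.default_rng(0)
    vertices = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    weights = rng.dirichlet([1.0, 1.0, 1.0], size=300)
    weights[:3] = np.eye(3)
    return weights @ vertices, vertices


@pytest.fixture(scope="session")
def small_cohort():
    """300-subject synthetic cohort with ground truth."""
    config = CohortConfig(n_subjects=300, seed=11)
    matrix, truth = generate_cohort(config)
    return config, matrix, truth


@pytest.fixture(scope="session")
def truth_scores(small_cohort):
    _, matrix, truth = small_cohort
    return pd.DataFrame(truth.weights, index=matrix.subject_ids,
                        columns=list("ABCD"))
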