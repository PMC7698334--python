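import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mrsidh as m

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def axis() -> m.PpmAxis:
    return m.default_invivo_axis()


@pytest.fixture(scope="session")
def basis():
    return m.default_basis()


@pytest.fixture(scope="session")
def default_cohort(basis):
    """One default-size cohort (22 mut + 12 wt) shared across tests."""
    return m.simulate_cohort(basis, m.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_matrix(default_cohort):
    return m.preprocess_cohort(default_cohort)


def make_cv_result(true_labels, predicted_labels, decision_values,
                   positive_class=m.IDHMUT) -> m.CVResult:
    """Assemble a minimal CVResult for metric tests."""
    n = len(true_labels)
    return m.CVResult(
        sample_ids=[f"s{i}" for i in range(n)],
        true_labels=list(true_labels),
        predicted_labels=list(predicted_labels),
        decision_values=np.asarray(decision_values, dtype=float),
        fold_k=[1] * n,
        fold_selected=[np.array([0])] * n,
        fold_models=[None] * n,
        selection_counts=np.array([n]),
        n_features=1,
        positive_class=positive_class,
    )
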