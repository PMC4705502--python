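import numpy as np
import pytest

import danp_select as ds


@pytest.fixture(scope="session")
def case_study():
    """Case-study network plus the two embedded elicitation examples."""
    return ds.case_study_fixture()


@pytest.fixture(scope="session")
def synth_bundle():
    """Noisy study-shaped synthetic model with aggregated group judgments."""
    result = ds.synthesize(ds.SynthesisSpec(seed=11))
    group = ds.aggregate_judgments(result.judgment_sets)
    return result, group


@pytest.fixture(scope="session")
def clean_bundle():
    """Zero-noise study-shaped synthetic model (ground truth recoverable)."""
    result = ds.synthesize(ds.SynthesisSpec(seed=5, noise_anp=0.0, noise_dematel=0.0))
    group = ds.aggregate_judgments(result.judgment_sets)
    return result, group


def random_reciprocal(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random Saaty-scale reciprocal matrix (test helper)."""
    A = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            A[i, j] = float(rng.choice(ds.synth_fixtures.SAATY_SCALE))
            A[j, i] = 1.0 / A[i, j]
    return A
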