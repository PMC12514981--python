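import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def cohort306():
    """One default synthetic cohort (306 eyes, 153 subjects)."""
    from cycloref.cohort import generate_cohort

    return generate_cohort(seed=7)


@pytest.fixture()
def physiologic_grid():
    """100 random but physiologically plausible (AL, ACD, LT, Km, SE) points."""
    rng = np.random.default_rng(20240915)
    n = 100
    return {
        "al": rng.uniform(21.0, 26.5, n),
        "acd": rng.uniform(2.8, 4.2, n),
        "lt": rng.uniform(3.0, 4.4, n),
        "km": rng.uniform(40.0, 46.0, n),
        "se": rng.uniform(-6.0, 3.0, n),
    }
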