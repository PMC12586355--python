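import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from mycolink.pipeline import RunConfig, run_pipeline
from mycolink.simulate import default_design, generate_dataset


@pytest.fixture(scope="session")
def dataset():
    """One default synthetic study (seed 1)."""
    return generate_dataset(default_design(), seed=1)


@pytest.fixture(scope="session")
def pipeline_result():
    """Full pipeline run on the default design (seed 1)."""
    return run_pipeline(RunConfig(design=default_design(), seed=1))


@pytest.fixture
def toy_counts():
    """Tiny ASV table: 5 ASVs x 6 samples with easy hand-checkable structure."""
    rng = np.random.default_rng(7)
    data = rng.integers(0, 50, size=(5, 6))
    return pd.DataFrame(
        data,
        index=[f"ASV{i}" for i in range(1, 6)],
        columns=[f"S{j}" for j in range(1, 7)],
    )
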