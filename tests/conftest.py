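import numpy as np
import pytest

from regrowth import ChapmanRichardsModel, SyntheticConfig, chapman_richards, simulate_scene
from regrowth.pipeline import run_synthetic_pipeline


@pytest.fixture(scope="session")
def default_scene():
    """One simulated landscape at the default study configuration."""
    return simulate_scene(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def pipeline_result():
    """Full pipeline run on the default configuration (seed 11)."""
    return run_synthetic_pipeline(seed=11)


@pytest.fixture(scope="session")
def results_from_params():
    """Factory for an exact ChapmanRichardsResults at given (A, k, c).

    Fits the curve to its own noise-free evaluations, so predictions
    equal the closed form to high precision.
    """

    def make(A: float, k: float, c: float):
        ages = np.arange(1, 16, dtype=float)
        model = ChapmanRichardsModel(ages, chapman_richards(ages, A, k, c), asymptote=A)
        res = model.fit(k0=k, c0=c)
        assert abs(res.k - k) / k < 1e-6 and abs(res.c - c) / c < 1e-6
        return res

    return make
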