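import numpy as np
import pytest

from splitbelt import FitConfig, SimulationSpec, SymmetrySeries, ThetaSingle


@pytest.fixture
def single_truth() -> ThetaSingle:
    """A realistic adaptation-scale single-exponential truth."""
    return ThetaSingle(a=0.1, b=-0.02, c=0.02)


@pytest.fixture
def noisy_single_series(single_truth):
    from splitbelt import simulate_series

    spec = SimulationSpec(theta=single_truth, sigma=0.006, n_strides=750)
    return simulate_series(spec, seed=20)


@pytest.fixture
def fast_config() -> FitConfig:
    return FitConfig(seed=7)


def make_series(values, label="") -> SymmetrySeries:
    return SymmetrySeries(values=np.asarray(values, dtype=float), label=label)
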