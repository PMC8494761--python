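import numpy as np
import pytest

from pulsesharp.segment import EnsemblePulse, normalize_amplitude, resample_to_duration
from pulsesharp.synth import PulseModelParams, generate_single_pulse

U800 = np.linspace(0.0, 1.0, 800)


def gauss_pulse(center: float, sigma: float, n: int = 800) -> EnsemblePulse:
    """A bare-Gaussian ensemble pulse on the standard template grid."""
    u = np.linspace(0.0, 1.0, n)
    return EnsemblePulse(normalize_amplitude(np.exp(-0.5 * ((u - center) / sigma) ** 2)))


def ensemble_of(params: PulseModelParams) -> EnsemblePulse:
    """Noise-free single beat of the generator, normalized and resampled."""
    return resample_to_duration(
        normalize_amplitude(generate_single_pulse(params)),
        source_hr=params.heart_rate,
    )


@pytest.fixture
def default_params() -> PulseModelParams:
    return PulseModelParams()


@pytest.fixture
def default_ensemble(default_params) -> EnsemblePulse:
    return ensemble_of(default_params)
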