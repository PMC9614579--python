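import numpy as np
import pytest

from crywatch.synth import CohortSpec, CrySynthesisParams, generate_cohort


@pytest.fixture(scope="session")
def flat_params() -> CrySynthesisParams:
    """Clean, flat-pitch synthesis parameters for oracle tests."""
    return CrySynthesisParams(
        f0_base=400.0,
        f0_contour=((0.0, 1.0), (1.0, 1.0)),
        hyperphonation_prob=0.0,
        fricative_prob=0.0,
        noise_snr_db=60.0,
    )


@pytest.fixture(scope="session")
def table_cohort():
    """Default-sized feature-table cohort (65 infants, strong effects)."""
    return generate_cohort(CohortSpec(mode="feature_table", seed=11, n_noise_features=8))


def autocorr_f0(x: np.ndarray, sr: int, fmin: float = 150.0, fmax: float = 2500.0) -> float:
    """Independent f0 oracle: global autocorrelation peak of the waveform."""
    ac = np.correlate(x, x, mode="full")[x.size - 1 :]
    lo, hi = int(sr / fmax), int(sr / fmin)
    lag = lo + int(np.argmax(ac[lo:hi]))
    return sr / lag
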