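import numpy as np
import pytest

from vigilance import synthetic
from vigilance.hrv import RRSeries


@pytest.fixture(scope="session")
def profile():
    return synthetic.default_profile()


@pytest.fixture(scope="session")
def constant_rr_800():
    """76 beats, exactly 800 ms apart, starting at t=0."""
    return RRSeries.from_peaks(np.arange(0, 60.01, 0.8))


@pytest.fixture(scope="session")
def planted_gsr(profile):
    """Noiseless skin-conductance trace with 3 planted SCRs."""
    return synthetic.generate_gsr(
        profile, "focused", 300, seed=0,
        events=[(30.0, 0.2), (120.0, 0.3), (210.0, 0.4)],
        noise_sd=0.0, drift_amp=0.0,
    )


@pytest.fixture(scope="session")
def planted_decomposition(planted_gsr):
    from vigilance import eda

    gsr, truth = planted_gsr
    decomp = eda.decompose_cda(gsr)
    events = eda.detect_scrs(decomp, gsr)
    return gsr, truth, decomp, events


@pytest.fixture(scope="session")
def noiseless_session(profile):
    """One synthetic ECG session without noise, plus its truth channel."""
    rr = synthetic.generate_rr(profile, "focused", 300, seed=7)
    ecg, truth = synthetic.synthesize_ecg(
        rr, fs=250, snr_db=np.inf, seed=7, wander_amp=0.0, powerline_amp=0.0
    )
    return rr, ecg, truth
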