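import numpy as np
import pytest

from sapphire_t1.cardiac_timing import generate_rr_series, schedule_diastolic
from sapphire_t1.phantom import PhantomSpec, build_cardiac_phantom, synthesize_series


@pytest.fixture(scope="session")
def diastolic_timings():
    """The default 10-frame diastolic schedule (TD 805 ms, constant RR)."""
    rr = generate_rr_series(1000.0, 0.0, n=11, seed=0)
    return schedule_diastolic(rr)


@pytest.fixture(scope="session")
def small_cardiac_truth():
    """Diastolic cardiac phantom at a small desk-scale grid."""
    return build_cardiac_phantom(PhantomSpec(grid=128), "diastole")


@pytest.fixture(scope="session")
def noiseless_cardiac_series(small_cardiac_truth, diastolic_timings):
    return synthesize_series(small_cardiac_truth, diastolic_timings, snr=np.inf)
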