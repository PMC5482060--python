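import numpy as np
import pytest

from smtrack import AcquisitionConfig, KineticParams, ks_compare


@pytest.fixture
def kinetics():
    """Reference two-population kinetics (fast 0.5 s, slow 5 s, 80/20)."""
    return KineticParams()


@pytest.fixture
def acq_small():
    """A small, quick-to-simulate acquisition (128 px, 200 frames, 200 ms)."""
    return AcquisitionConfig(image_shape=(128, 128), n_frames=200)


@pytest.fixture(scope="session")
def ks_null_rejection_rate():
    """Fraction of two-sample KS tests rejecting at alpha=0.05 under the null.

    Computed once per session: 2000 repeats of equal-mean exponential
    samples (n = 500 per arm).  Used both by the comparison-statistics
    calibration test and the oracle-equivalence acceptance test.
    """
    rng = np.random.default_rng(0)
    n_repeats, n = 2000, 500
    rejections = 0
    for _ in range(n_repeats):
        a = rng.exponential(5.0, n)
        b = rng.exponential(5.0, n)
        _, p = ks_compare(a, b)
        if p < 0.05:
            rejections += 1
    return rejections / n_repeats
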