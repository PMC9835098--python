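import numpy as np
import pytest

from cdcs import AcquisitionSpec, OpticalProperties


@pytest.fixture
def acq8() -> AcquisitionSpec:
    """Canonical acquisition: 8 BCD channels, 1 MHz clock, 100 ms frames."""
    return AcquisitionSpec(1e6, 0.1)


@pytest.fixture
def acq1() -> AcquisitionSpec:
    """Single-channel variant for correlator/simulator tests."""
    return AcquisitionSpec(1e6, 0.1, n_channels=1)


@pytest.fixture
def liquid_phantom_optics() -> OpticalProperties:
    """Intralipid liquid phantom: mu_a=0.1/cm, mu_s'=10/cm at 785 nm."""
    return OpticalProperties.from_nm(0.1, 10.0, 785.0)


def brute_force_g2(counts: np.ndarray, max_lag: int) -> np.ndarray:
    """O(N*L) double-loop reference estimator with symmetric normalization.

    Deliberately naive (explicit Python loops over shift and index) so it is
    independent of the vectorized implementation it checks.
    """
    n = [float(v) for v in counts]
    N = len(n)
    out = []
    for d in range(1, max_lag + 1):
        m = N - d
        acc = 0.0
        left = 0.0
        right = 0.0
        for i in range(m):
            acc += n[i] * n[i + d]
            left += n[i]
            right += n[i + d]
        denom = (left / m) * (right / m)
        out.append((acc / m) / denom if denom > 0 else float("nan"))
    return np.array(out)
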