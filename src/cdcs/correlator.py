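"""Digital intensity autocorrelator for binned photon counts.

The normalized intensity autocorrelation function of a count stream n(i)
sampled at f_s is estimated at integer lags Δn (delay τ = Δn / f_s) as

    g2(Δn) = < n(i) n(i+Δn) >  /  ( <n(i)>_left <n(i+Δn)>_right )

where all averages run over the overlapping index range only (no padding, no
circular wrap) and the denominator uses the *symmetric* normalization: the
separate means of the leading and trailing segments.  This estimator is
asymptotically unbiased at lags much shorter than the frame and tends to 1
for uncorrelated light, which is the behaviour a static (non-decaying)
sample must show.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .acquisition import AcquisitionSpec
from .exceptions import DegenerateInputError, GridError, InsufficientDataError


@dataclass
class G2Curve:
    """One autocorrelation estimate on a linear lag grid.

    ``lags`` are integer sample shifts (strictly increasing, >= 1);
    ``delays_s`` = lags / f_s.
    """

    lags: np.ndarray
    delays_s: np.ndarray
    g2: np.ndarray
    mean_count_rate_hz: float
    integration_time_s: float
    n_frames_averaged: int = 1
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=np.int64)
        self.delays_s = np.asarray(self.delays_s, dtype=float)
        self.g2 = np.asarray(self.g2, dtype=float)
        if not (self.lags.shape == self.delays_s.shape == self.g2.shape):
            raise ValueError("lags, delays_s and g2 must share one shape")
        if self.lags.size and (self.lags[0] < 1 or (np.diff(self.lags) <= 0).any()):
            raise ValueError("lags must be strictly increasing and >= 1")


def compute_g2(
    counts: np.ndarray,
    max_lag: int,
    spec: AcquisitionSpec,
    lags: Sequence[int] | None = None,
) -> G2Curve:
    """Autocorrelation of a single-channel count vector.

    Parameters
    ----------
    counts:
        Non-negative integer counts, one entry per sample bin.
    max_lag:
        Largest sample shift; the default grid is 1..max_lag (τ = 1/f_s to
        max_lag/f_s, i.e. 1-250 µs for the canonical 250-lag, 1 MHz setup).
    """
    n = np.asarray(counts)
    if n.ndim != 1:
        raise ValueError("counts must be one-dimensional")
    if (n < 0).any():
        raise ValueError("counts must be non-negative")
    N = n.size
    if max_lag < 1 or max_lag >= N:
        raise ValueError(f"max_lag must satisfy 1 <= max_lag < {N}")
    if not n.any():
        raise DegenerateInputError("all-zero count stream: g2 undefined")

    lag_arr = np.arange(1, max_lag + 1) if lags is None else np.asarray(lags, np.int64)
    x = n.astype(np.float64)
    csum = np.concatenate(([0.0], np.cumsum(x)))
    total = csum[-1]
    g2 = np.empty(lag_arr.size)
    for j, d in enumerate(lag_arr):
        m = N - d
        num = x[:m] @ x[d:] / m
        mean_left = csum[m] / m
        mean_right = (total - csum[d]) / m
        denom = mean_left * mean_right
        g2[j] = num / denom if denom > 0 else np.nan
    if np.isnan(g2).any():
        warnings.warn("zero overlap mean at some lags; g2 set to NaN there", stacklevel=2)
    fs = spec.sampling_frequency_hz
    return G2Curve(
        lags=lag_arr,
        delays_s=lag_arr / fs,
        g2=g2,
        mean_count_rate_hz=float(x.mean() * fs),
        integration_time_s=N / fs,
        n_frames_averaged=1,
    )


def _common_grid(curves: Sequence[G2Curve]) -> None:
    first = curves[0]
    for c in curves[1:]:
        if c.lags.shape != first.lags.shape or (c.lags != first.lags).any():
            raise GridError("curves do not share a common lag grid")


def average_curves(curves: Sequence[G2Curve]) -> G2Curve:
    """Point-wise mean of curves sharing one lag grid.

    Used both for channel averaging within a source-detector separation and
    for frame averaging over time; ``n_frames_averaged`` accumulates.
    """
    if not curves:
        raise InsufficientDataError("no curves to average")
    _common_grid(curves)
    g2 = np.mean([c.g2 for c in curves], axis=0)
    return replace(
        curves[0],
        g2=g2,
        mean_count_rate_hz=float(np.mean([c.mean_count_rate_hz for c in curves])),
        n_frames_averaged=int(sum(c.n_frames_averaged for c in curves)),
        sigma=None,
    )


def empirical_noise(curves: Sequence[G2Curve]) -> np.ndarray:
    """Sample standard deviation σ(τ) of g2 across curves (n−1 convention)."""
    if len(curves) < 2:
        raise InsufficientDataError("need at least 2 curves for a standard deviation")
    _common_grid(curves)
    return np.std([c.g2 for c in curves], axis=0, ddof=1)


def empirical_snr(curves: Sequence[G2Curve]) -> np.ndarray:
    """SNR ζ(τ) = (mean g2(τ) − 1) / σ(τ) across curves.

    Lags where σ = 0 are reported as +inf with a warning.
    """
    sigma = empirical_noise(curves)
    signal = np.mean([c.g2 for c in curves], axis=0) - 1.0
    zeta = np.full_like(sigma, np.inf)
    nonzero = sigma > 0
    zeta[nonzero] = signal[nonzero] / sigma[nonzero]
    if (~nonzero).any():
        warnings.warn("zero empirical noise at some lags; SNR reported as +inf", stacklevel=2)
    return zeta
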