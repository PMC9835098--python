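"""Synthetic photon-stream generator emulating the counting hardware.

The chain mirrors the physical signal path: a speckle intensity that
fluctuates with a prescribed field correlation time, Poisson photon
detection, an optional non-paralyzable detector dead time, optional loss of
TTL pulses that straddle the per-sample counter-reset window, and the mod-10
rollover of a 4-bit binary-coded-decimal counter.

Speckle model: each detection mode carries a complex Ornstein-Uhlenbeck
field E(t) with ⟨E*(t)E(t+τ)⟩ = e^{−τ/τc}; the normalized intensity is the
mean of |E|² over n_modes independent modes, so the intensity
autocorrelation is 1 + (1/n_modes) e^{−2τ/τc} and the realized coherence
factor is β = 1/n_modes.  The discrete update is exact (decay factor
e^{−Δt/τc} per sample with stationary initial condition), so there is no
discretization bias in g1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence
import math
import warnings

import numpy as np
import pandas as pd

from .acquisition import AcquisitionSpec
from .bcd import BCD_MAX, ChannelCountMatrix, PackedWordStream, pack_stream
from .correlator import G2Curve
from .flow import OpticalProperties, effective_decay_rate
from .noise import NoiseModelParams, sigma_tau


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated acquisition.

    ``tau_c_s`` is the field correlation time; ``None`` or ``inf`` means a
    static (constant-intensity) sample.  β is realized as 1/n_modes.
    Identical seeds reproduce identical streams bit for bit.
    """

    mean_rate_hz: float
    tau_c_s: float | None
    spec: AcquisitionSpec
    seed: int
    n_modes: int = 1
    dead_time_s: float = 50e-9
    pulse_width_s: float = 25e-9
    reset_window_s: float = 0.0
    n_frames: int = 1

    def __post_init__(self) -> None:
        if self.mean_rate_hz <= 0:
            raise ValueError("mean_rate_hz must be positive")
        if self.n_modes < 1:
            raise ValueError("n_modes must be >= 1")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if min(self.dead_time_s, self.pulse_width_s, self.reset_window_s) < 0:
            raise ValueError("time constants must be non-negative")
        if self.dead_time_s > 0 and self.mean_rate_hz >= 1.0 / self.dead_time_s:
            raise ValueError("mean rate must stay below the dead-time-limited maximum")

    @property
    def is_static(self) -> bool:
        return self.tau_c_s is None or not np.isfinite(self.tau_c_s)

    @property
    def n_samples(self) -> int:
        return self.spec.samples_per_frame * self.n_frames

    @classmethod
    def from_flow(
        cls,
        mean_rate_hz: float,
        optics: OpticalProperties,
        F: float,
        rho_cm: float,
        spec: AcquisitionSpec,
        seed: int,
        **kwargs,
    ) -> "SimulationSpec":
        """Model-driven correlation time: τc = 1/Γ where Γ is the best
        single-exponential decay rate of the semi-infinite model g1."""
        gamma = effective_decay_rate(rho_cm, optics, F)
        return cls(mean_rate_hz, 1.0 / gamma, spec, seed, **kwargs)


def _speckle_intensity(sim: SimulationSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    """Normalized intensity trace (mean 1) of length n."""
    if sim.is_static:
        return np.ones(n)
    dt = sim.spec.sample_time_s
    if sim.tau_c_s < 2.0 * dt:
        warnings.warn(
            "correlation time under-resolved by the sampling clock (tau_c < 2/f_s)",
            stacklevel=3,
        )
    a = math.exp(-dt / sim.tau_c_s)
    innov = math.sqrt((1.0 - a * a) / 2.0)
    intensity = np.zeros(n)
    from scipy.signal import lfilter

    for _ in range(sim.n_modes):
        for _part in range(2):  # real and imaginary quadratures
            w = rng.standard_normal(n) * innov
            x0 = rng.standard_normal() * math.sqrt(0.5)
            comp, _ = lfilter([1.0], [1.0, -a], w, zi=np.array([a * x0]))
            intensity += comp**2
    return intensity / sim.n_modes


def simulate_speckle_counts(sim: SimulationSpec) -> ChannelCountMatrix:
    """Poisson-binned photon counts driven by fluctuating speckle intensity.

    Each channel observes an independent speckle realization with the same
    statistics; the expected autocorrelation of any channel is
    g2(τ) = 1 + (1/n_modes) e^{−2τ/τc}.  Dead time and reset loss are not
    applied on this fast path (see :func:`simulate_arrivals_with_dead_time`).
    """
    rng = np.random.default_rng(sim.seed)
    n = sim.n_samples
    mean_per_bin = sim.mean_rate_hz * sim.spec.sample_time_s
    counts = np.empty((sim.spec.n_channels, n), dtype=np.int64)
    for ch in range(sim.spec.n_channels):
        counts[ch] = rng.poisson(mean_per_bin * _speckle_intensity(sim, rng, n))
    return ChannelCountMatrix(counts, sim.spec)


@dataclass
class LossReport:
    """Book-keeping of the arrival-level loss mechanisms, per channel."""

    n_arrivals: np.ndarray
    n_lost_dead_time: np.ndarray
    n_lost_reset: np.ndarray

    @property
    def fraction_dead_time(self) -> np.ndarray:
        return self.n_lost_dead_time / np.maximum(self.n_arrivals, 1)

    @property
    def fraction_reset(self) -> np.ndarray:
        return self.n_lost_reset / np.maximum(self.n_arrivals, 1)


def _dead_time_filter(times: np.ndarray, dead: float) -> np.ndarray:
    """Non-paralyzable dead time: keep arrivals >= dead after the last kept."""
    keep = np.zeros(times.size, dtype=bool)
    last = -np.inf
    for i, t in enumerate(times):
        if t - last >= dead:
            keep[i] = True
            last = t
    return keep


def simulate_arrivals_with_dead_time(
    sim: SimulationSpec,
) -> tuple[ChannelCountMatrix, LossReport]:
    """Exact photon arrival times with dead-time and reset-window loss.

    Arrivals follow an inhomogeneous Poisson process (thinning of a
    homogeneous process at the peak rate) driven by the per-bin speckle
    intensity.  A detection blocks the detector for ``dead_time_s``
    (non-paralyzable).  A TTL pulse spanning ``[t, t + pulse_width_s]`` that
    overlaps a counter-reset window ``[k/f_s, k/f_s + reset_window_s)`` is
    dropped.  Survivors are binned at f_s.
    """
    rng = np.random.default_rng(sim.seed)
    spec = sim.spec
    n = sim.n_samples
    dt = spec.sample_time_s
    duration = n * dt
    counts = np.zeros((spec.n_channels, n), dtype=np.int64)
    n_arr = np.zeros(spec.n_channels, dtype=np.int64)
    n_dead = np.zeros(spec.n_channels, dtype=np.int64)
    n_reset = np.zeros(spec.n_channels, dtype=np.int64)

    for ch in range(spec.n_channels):
        intensity = _speckle_intensity(sim, rng, n)
        lam_max = sim.mean_rate_hz * intensity.max()
        n_cand = rng.poisson(lam_max * duration)
        times = np.sort(rng.uniform(0.0, duration, n_cand))
        bins = np.minimum((times / dt).astype(np.int64), n - 1)
        accept = rng.uniform(0.0, 1.0, n_cand) < intensity[bins] * (
            sim.mean_rate_hz / lam_max
        )
        times = times[accept]
        n_arr[ch] = times.size

        if sim.dead_time_s > 0 and times.size:
            keep = _dead_time_filter(times, sim.dead_time_s)
            n_dead[ch] = times.size - keep.sum()
            times = times[keep]

        if sim.reset_window_s > 0 and times.size:
            # pulse [t, t+w] overlaps reset window [kΔ, kΔ+r) at a boundary
            phase = times % dt
            hit = (phase < sim.reset_window_s) | (phase > dt - sim.pulse_width_s)
            n_reset[ch] = hit.sum()
            times = times[~hit]

        if times.size:
            bins = np.minimum((times / dt).astype(np.int64), n - 1)
            np.add.at(counts[ch], bins, 1)

    return (
        ChannelCountMatrix(counts, spec),
        LossReport(n_arr, n_dead, n_reset),
    )


def apply_bcd_rollover(
    matrix: ChannelCountMatrix,
) -> tuple[ChannelCountMatrix, np.ndarray]:
    """Mod-10 wrap of a 4-bit decimal counter.

    Returns the wrapped matrix and a boolean overflow-flag array of the same
    shape marking every bin whose true count was >= 10 (the lossy regime the
    hardware must stay out of).
    """
    flags = matrix.counts > BCD_MAX
    wrapped = np.where(flags, matrix.counts % (BCD_MAX + 1), matrix.counts)
    return ChannelCountMatrix(wrapped.astype(np.int64), matrix.spec), flags


def simulate_g2_frames(
    model_curve: G2Curve,
    noise: NoiseModelParams,
    n_frames: int,
    seed: int,
) -> list[G2Curve]:
    """Fast surrogate for frame-level Monte Carlo.

    Each frame is the model curve plus independent Gaussian noise with the
    analytic per-lag standard deviation σ(τ) — the correct magnitude of
    correlator noise without simulating photons, useful for fitter studies.
    """
    rng = np.random.default_rng(seed)
    sig = np.atleast_1d(sigma_tau(model_curve.delays_s, noise))
    frames = []
    for _ in range(n_frames):
        frames.append(
            replace(
                model_curve,
                g2=model_curve.g2 + sig * rng.standard_normal(sig.size),
                n_frames_averaged=1,
                sigma=None,
            )
        )
    return frames


def simulate_occlusion_series(
    baseline_F: float,
    occluded_F: float,
    segment_durations_s: Sequence[float],
    acquisition: AcquisitionSpec,
    seed: int,
    optics: OpticalProperties | None = None,
    rho_by_channel: Sequence[float] | None = None,
    mean_rate_hz: float = 100e3,
    n_modes: int = 2,
) -> tuple[PackedWordStream, pd.DataFrame]:
    """Piecewise-stationary packed stream emulating an arm-cuff occlusion.

    Three segments — baseline, occlusion, recovery — with flow indices
    (baseline_F, occluded_F, baseline_F).  Each channel's correlation time
    per segment is derived from the semi-infinite model g1 at that channel's
    source-detector separation.  Returns the packed stream and a truth table
    of segment boundaries for recovery testing.
    """
    if baseline_F <= 0 or occluded_F <= 0:
        raise ValueError("flow indices must be positive")
    if len(segment_durations_s) != 3 or any(d <= 0 for d in segment_durations_s):
        raise ValueError("need three positive segment durations")
    if optics is None:
        optics = OpticalProperties.from_nm(0.1, 10.0, 785.0)
    if rho_by_channel is None:
        # canonical probe: 3 channels at 1 cm, remaining channels at 2.5 cm
        rho_by_channel = [1.0] * min(3, acquisition.n_channels) + [2.5] * max(
            0, acquisition.n_channels - 3
        )
    if len(rho_by_channel) != acquisition.n_channels:
        raise ValueError("rho_by_channel length must equal n_channels")

    flows = [baseline_F, occluded_F, baseline_F]
    labels = ["baseline", "occlusion", "recovery"]
    tau_c = {
        (rho, F): 1.0 / effective_decay_rate(rho, optics, F)
        for rho in sorted(set(rho_by_channel))
        for F in set(flows)
    }

    ss = np.random.SeedSequence(seed)
    blocks = []
    truth_rows = []
    t0 = 0.0
    for label, F, dur in zip(labels, flows, segment_durations_s):
        n_frames = max(1, round(dur / acquisition.integration_time_s))
        seg_counts = np.empty(
            (acquisition.n_channels, n_frames * acquisition.samples_per_frame),
            dtype=np.int64,
        )
        child = ss.spawn(1)[0]
        rng_seeds = child.generate_state(acquisition.n_channels)
        for ch, rho in enumerate(rho_by_channel):
            sim = SimulationSpec(
                mean_rate_hz=mean_rate_hz,
                tau_c_s=tau_c[(rho, F)],
                spec=replace_channels(acquisition, 1),
                seed=int(rng_seeds[ch]),
                n_modes=n_modes,
                n_frames=n_frames,
            )
            seg_counts[ch] = simulate_speckle_counts(sim).counts[0]
        blocks.append(seg_counts)
        t1 = t0 + n_frames * acquisition.integration_time_s
        truth_rows.append(
            {"segment": label, "t_start_s": t0, "t_end_s": t1, "F_cm2_s": F}
        )
        t0 = t1

    counts = np.concatenate(blocks, axis=1)
    stream = pack_stream(ChannelCountMatrix(counts, acquisition))
    return stream, pd.DataFrame(truth_rows)


def replace_channels(spec: AcquisitionSpec, n_channels: int) -> AcquisitionSpec:
    """Copy of an acquisition spec with a different channel count."""
    return AcquisitionSpec(
        spec.sampling_frequency_hz,
        spec.integration_time_s,
        n_channels,
        spec.bits_per_channel,
        spec.word_bits,
    )
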