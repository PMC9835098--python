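"""Photon-stream simulator: determinism, calibration, closed-form speckle
statistics, and the hardware loss mechanisms with their renewal/geometric
oracles."""

import numpy as np
import pytest

from cdcs import (
    AcquisitionSpec,
    ChannelCountMatrix,
    NoiseModelParams,
    SimulationSpec,
    apply_bcd_rollover,
    average_curves,
    compute_g2,
    simulate_arrivals_with_dead_time,
    simulate_g2_frames,
    simulate_occlusion_series,
    simulate_speckle_counts,
)
from cdcs.bcd import pack_stream
from cdcs.correlator import G2Curve
from cdcs.io import write_packed_file


def test_seeded_determinism(acq1):
    sim = SimulationSpec(100e3, 50e-6, acq1, seed=9, n_modes=2)
    a = simulate_speckle_counts(sim)
    b = simulate_speckle_counts(sim)
    np.testing.assert_array_equal(a.counts, b.counts)
    c = simulate_speckle_counts(SimulationSpec(100e3, 50e-6, acq1, seed=10, n_modes=2))
    assert (a.counts != c.counts).any()


def test_mean_rate_calibration():
    """Realized count rate matches the target within 1% over 1 s."""
    acq = AcquisitionSpec(1e6, 1.0, n_channels=1)
    sim = SimulationSpec(200e3, 10e-6, acq, seed=2, n_modes=4)
    m = simulate_speckle_counts(sim)
    assert m.mean_rate_hz[0] == pytest.approx(200e3, rel=0.01)


def test_static_sample_gives_flat_g2():
    """Constant intensity -> i.i.d. Poisson counts -> g2 = 1 at all lags."""
    acq = AcquisitionSpec(1e6, 0.5, n_channels=1)
    m = simulate_speckle_counts(SimulationSpec(200e3, None, acq, seed=3))
    curve = compute_g2(m.counts[0], 100, acq)
    # shot-noise standard error of the estimator for Poisson(mu) counts:
    # SD[n(i)n(i+d)] = sqrt(mu^2 + 2 mu^3), normalized by mu^2 and sqrt(N)
    mu = m.counts.mean()
    se = np.sqrt(1 / mu**2 + 2 / mu) / np.sqrt(m.counts.size)
    assert np.abs(curve.g2 - 1.0).max() < 5 * se


@pytest.mark.parametrize("n_modes", [1, 2, 4])
def test_beta_equals_inverse_mode_count(n_modes):
    """The short-lag intercept of g2 - 1 realizes beta = 1/n_modes."""
    acq = AcquisitionSpec(1e6, 1.0, n_channels=1)
    tau_c = 100e-6
    sim = SimulationSpec(200e3, tau_c, acq, seed=4 + n_modes, n_modes=n_modes)
    m = simulate_speckle_counts(sim)
    curve = compute_g2(m.counts[0], 5, acq)
    expected = np.exp(-2 * curve.delays_s / tau_c) / n_modes
    np.testing.assert_allclose(curve.g2 - 1.0, expected, rtol=0.12)


def test_high_rate_counts_match_bin_occupancy():
    """At 2 MHz on a 1 MHz clock, bins hold small integers with mean 2."""
    acq = AcquisitionSpec(1e6, 0.1, n_channels=1)
    m = simulate_speckle_counts(SimulationSpec(2e6, None, acq, seed=5, dead_time_s=0))
    assert m.counts.mean() == pytest.approx(2.0, rel=0.01)
    assert np.quantile(m.counts, 0.95) <= 5


def test_count_conservation_without_losses():
    acq = AcquisitionSpec(1e6, 0.2, n_channels=1)
    sim = SimulationSpec(500e3, 100e-6, acq, seed=6, dead_time_s=0, reset_window_s=0)
    m, report = simulate_arrivals_with_dead_time(sim)
    assert m.counts.sum() == report.n_arrivals.sum()
    assert report.n_lost_dead_time.sum() == 0
    assert report.n_lost_reset.sum() == 0


def test_dead_time_renewal_oracle():
    """Non-paralyzable dead time: accepted rate = lambda / (1 + lambda*tau_d)."""
    acq = AcquisitionSpec(1e6, 0.5, n_channels=1)
    lam, td = 1e6, 50e-9
    sim = SimulationSpec(lam, None, acq, seed=7, dead_time_s=td)
    m, report = simulate_arrivals_with_dead_time(sim)
    accepted_rate = m.counts.sum() / 0.5
    assert accepted_rate == pytest.approx(lam / (1 + lam * td), rel=0.01)
    assert report.fraction_dead_time[0] > 0


def test_reset_window_geometric_oracle():
    """A pulse whose span straddles a reset window is lost with probability
    (pulse_width + reset_window) / sample period for uniform arrival phase."""
    acq = AcquisitionSpec(1e6, 0.5, n_channels=1)
    sim = SimulationSpec(
        1e6, None, acq, seed=8, dead_time_s=0, reset_window_s=25e-9, pulse_width_s=25e-9
    )
    _, report = simulate_arrivals_with_dead_time(sim)
    assert report.fraction_reset[0] == pytest.approx(50e-9 / 1e-6, rel=0.1)


def test_bcd_rollover(acq8):
    counts = np.zeros((8, 4), dtype=np.int64)
    counts[0] = [3, 9, 12, 25]
    matrix = ChannelCountMatrix(counts, acq8)
    wrapped, flags = apply_bcd_rollover(matrix)
    np.testing.assert_array_equal(wrapped.counts[0], [3, 9, 2, 5])
    np.testing.assert_array_equal(flags[0], [False, False, True, True])
    assert not flags[1:].any()


def test_rollover_never_triggers_at_typical_rates():
    """Poisson(0.1) essentially never reaches 10: a 100 kHz channel on a
    1 MHz clock stays in the lossless regime over 10^6 bins."""
    acq = AcquisitionSpec(1e6, 1.0, n_channels=1)
    m = simulate_speckle_counts(SimulationSpec(100e3, None, acq, seed=9))
    _, flags = apply_bcd_rollover(m)
    assert not flags.any()


def test_g2_frame_surrogate_noise_magnitude():
    params = NoiseModelParams(1e4, 0.5, 0.1, 1e-6, 0.01)
    tau = np.arange(1, 51) * 1e-6
    model = G2Curve(np.arange(1, 51), tau, 1 + 0.5 * np.exp(-2e4 * tau), 100e3, 0.01)
    frames = simulate_g2_frames(model, params, 10_000, seed=10)
    emp = np.std([f.g2 for f in frames], axis=0, ddof=1)
    from cdcs import sigma_tau

    np.testing.assert_allclose(emp, sigma_tau(tau, params), rtol=0.03)
    # zero-noise limit degenerates to the model curve
    tiny = NoiseModelParams(1e4, 1e-9, 1e9, 1e-6, 1e6)
    (only,) = simulate_g2_frames(model, tiny, 1, seed=0)
    np.testing.assert_allclose(only.g2, model.g2, atol=1e-6)


def test_occlusion_series_determinism_and_truth(tmp_path):
    acq = AcquisitionSpec(1e6, 0.05, n_channels=2)
    args = dict(
        baseline_F=1e-8,
        occluded_F=1e-10,
        segment_durations_s=[0.1, 0.1, 0.1],
        acquisition=acq,
        seed=123,
        rho_by_channel=[1.0, 2.5],
    )
    s1, truth = simulate_occlusion_series(**args)
    s2, _ = simulate_occlusion_series(**args)
    np.testing.assert_array_equal(s1.words, s2.words)
    p1, p2 = tmp_path / "a.cdcs", tmp_path / "b.cdcs"
    write_packed_file(s1, p1)
    write_packed_file(s2, p2)
    assert p1.read_bytes() == p2.read_bytes()
    assert list(truth.segment) == ["baseline", "occlusion", "recovery"]
    assert truth.t_end_s.iloc[-1] == pytest.approx(0.3)


def test_occlusion_null_case_is_stationary():
    """Equal flows in all segments: segment-wise g2 at 20 us agree within
    the frame-to-frame scatter."""
    acq = AcquisitionSpec(1e6, 0.05, n_channels=1)
    stream, truth = simulate_occlusion_series(
        1e-8, 1e-8, [0.25, 0.25, 0.25], acq, seed=77, rho_by_channel=[1.0]
    )
    from cdcs import unpack_stream

    counts = unpack_stream(stream).counts[0]
    spf = acq.samples_per_frame
    n_frames = counts.size // spf
    vals = np.array(
        [compute_g2(counts[i * spf : (i + 1) * spf], 20, acq).g2[19] for i in range(n_frames)]
    )
    seg = np.array_split(vals, 3)
    pooled_se = vals.std(ddof=1) / np.sqrt(len(seg[0]))
    assert abs(seg[0].mean() - seg[1].mean()) < 4 * pooled_se

def test_rate_above_dead_time_limit_rejected(acq1):
    with pytest.raises(ValueError, match="dead-time"):
        SimulationSpec(30e6, None, acq1, seed=0, dead_time_s=50e-9)
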