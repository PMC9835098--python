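# Methods

## Scope and data model

The package reproduces, entirely in software, the data path of a
compressed multi-channel DCS instrument: per-channel photon counts binned
at a sampling clock f_s (default 1 MHz), packed one 32-bit word per bin
with 4 bits per channel, accumulated into integration frames of duration
t_int (default 100 ms, i.e. 10 Hz flow estimates), autocorrelated over a
linear lag grid of 1–250 samples (τ = 1–250 µs at 1 MHz), and fitted to
the semi-infinite correlation-diffusion model. All lengths are cm, times
s, flow indices cm²/s; wavelengths are accepted in nm at the constructor
and converted once.

## BCD codec

Channel c occupies bits [4c, 4c+4) of the word — channel 0 is the
least-significant nibble. The bit order is a convention of this package's
file format (hardware shift-register order is not otherwise constrained)
and is frozen in the packed-file header documented in `cdcs/io.py`.
The codec is lossless by construction: counts above the nibble range (or
above 9 in strict BCD mode) raise rather than wrap. Mod-10 counter
rollover is a hardware loss mechanism and lives in the simulator
(`apply_bcd_rollover`), which flags any bin whose true count reached 10 —
at typical DCS rates (≤ a few hundred kHz on a 1 MHz clock, Poisson mean
≤ 0.3/bin) the flag probability is ~1e-10 per bin, which is why 4 bits
suffice. Permissive decoding (non-BCD nibbles pass through with a warning
and recorded indices) exists for auditing recorded streams. Compression
efficiency is 1 − bits_per_channel/32 (87.5 % at 4 bits, 93.75 % at the
2-bit variant); bandwidth is words/s × 4 bytes, with the binary-MB
convenience value dividing by 2²⁰ (4 × 10⁶ B/s ≈ 3.81 MB/s).

## Correlator

The estimator uses overlap-only sums with *symmetric* normalization: the
denominator is the product of the means of the leading and trailing
overlap segments. The naive normalization by ⟨n²⟩ does not converge to 1
for uncorrelated light (⟨n²⟩ ≠ ⟨n⟩² for Poisson counts), whereas the
symmetric form is asymptotically unbiased at lags ≪ N and makes a static
sample read flat at 1 — the behaviour any physical baseline must show.
No zero-padding and no circular wrap-around are used; frames are
correlated independently (the hardware resets every bin and every frame).
Lags where an overlap mean is zero yield NaN with a warning; an all-zero
frame raises a degenerate-input error that the pipeline records and
skips. Empirical noise σ(τ) across frames uses the sample (n−1)
convention; SNR ζ(τ) = (mean g₂ − 1)/σ, with +inf sentinels where σ = 0.

## Diffusion model and fitting

R_eff defaults to the Fresnel-integral effective reflection coefficient
(angular integrals of the unpolarized Fresnel reflectance with total
internal reflection beyond the critical angle), giving 0.4935 at
n_rel = 1.4; it is user-overridable and only shifts the extrapolated
boundary z_b slightly. k₀ = 2π/λ uses the vacuum wavelength.

The fitter minimizes Σ[g₂_meas − (1 + β g₁²)]² over (log₁₀F, β) with
`scipy.optimize.least_squares`, bounds F ∈ [1e−12, 1e−4] cm²/s
(phantom-to-in-vivo range) and β ∈ (0, 1], initialized at F₀ = 1e−8 cm²/s
and β₀ = mean(g₂ at the 3 smallest lags) − 1 clipped into range. Fitting
F on a log scale conditions the problem across its four-decade dynamic
range. The default objective is unweighted (per-lag weighting is optional
via a σ(τ) vector) and the default window is the full 1–250 µs grid; both
are configurable. Non-convergence is flagged on the result rather than
raised; a curve whose plateau never rises 1 % above 1 is flagged
degenerate. Noiseless self-consistency recovers (F, β) to optimizer
tolerance (≲ 0.1 %).

## Noise model

σ(τ) follows the Koppel-type estimator variance for single-exponential
field dynamics, with bin time T, integration time t, mean counts per bin
⟨n⟩ and decay rate Γ (formula in `cdcs/noise.py`). Three terms: speckle
(β²), shot–speckle cross (∝ 1/⟨n⟩) and pure shot (∝ 1/⟨n⟩²); the √(T/t)
prefactor gives the exact 1/√t averaging law that the SNR sweep tests
(ζ ∝ √t_int). 1 − e^(−2ΓT) is evaluated with expm1 for small ΓT. The
diffusion g₁ is not exactly exponential; Γ is defined as the best
least-squares single-exponential rate of the model g₁ over the fit window
(`effective_decay_rate`), which is how this noise model is conventionally
applied. Because normalization conventions for this variance differ
across the literature, agreement with Monte Carlo is expected at the
10–20 % level, and that is the tolerance the tests assert (measured ratio
≈ 0.95–0.99 at the 20 µs delay, 100 kHz, 10 ms frames).

## Photon-stream simulator

Each detection mode carries a complex Ornstein–Uhlenbeck field updated
exactly per sample (decay factor e^(−Δt/τc), stationary start), so
⟨E*(t)E(t+τ)⟩ = e^(−τ/τc) with no discretization bias; τc < 2/f_s warns
of under-resolved dynamics. The normalized intensity averages n_modes
independent modes, realizing β = 1/n_modes (β is restricted to
reciprocals of integers on the physical path; arbitrary β is exercised
through the Gaussian frame surrogate `simulate_g2_frames`, whose per-lag
noise magnitude is the analytic σ(τ)). Counts are Poisson with per-bin
mean (rate/f_s)·I(t). Model-driven streams set τc = 1/Γ from the
diffusion g₁, i.e. they are single-exponential surrogates of the exact
model decay.

The arrival-time path generates exact arrivals by thinning a homogeneous
Poisson process at the peak rate, applies a *non-paralyzable* dead time
(default 50 ns; matches TTL photon-counting modules and has the
closed-form accepted rate λ/(1+λτ_d) used as a test oracle), then drops
pulses of width 25 ns whose span overlaps a reset window at a sample
boundary — the reset-window duration defaults to 0 because the hardware
value is unspecified; with width w and reset r the loss probability is
(w+r)/Δt for uniform phase, the geometric oracle the tests check. Whether
real counters miss pulses paralyzably during the read/reset microcycle is
unknown, so the mechanism is parameterized and off by default, and the
instrument-level "<2 % count loss" figure is treated as descriptive, not
as a test target. All simulation is seeded; identical specs give
bit-identical streams.

What the simulator does *not* emulate: photon-transport Monte Carlo
(the diffusion model is taken as the truth generating τc), afterpulsing,
dark counts, laser drift, and exact multi-exponential decays. Passing
tests therefore demonstrate correctness of the estimators, codec and
fitting chain under the stated signal model, not instrument-level
absolute accuracy on tissue.

## Pipeline

`run_pipeline` processes a packed stream frame by frame: per-channel g₂,
arithmetic averaging of channels within each source-detector group
(canonically 3 channels at 1 cm and 5 at 2.5 cm), one fit per integration
window by default (optional N-frame pre-averaging), CSV outputs with
frozen column names. Frame errors are logged and skipped unless strict
mode is set. The time-course smoother is a centered 20-point-style moving
average with symmetrically shrinking edge windows. The packed-file header
stores f_s, channel count and bit width but not t_int, so a reader
defaults to treating the whole record as one frame until the caller or
config imposes the frame length. End-to-end runs are deterministic:
fixed config plus fixed input bytes give byte-identical outputs.

## Problem sizes in the validation suite

The statistical checks use 1 s speckle streams (10⁶ bins) for
closed-form recovery, 500 × 10 ms frames for the noise Monte Carlo,
100 replicates of 70-frame averages for flow recovery, and 2 s segments
(60 frames at 10 Hz, 8 channels) for the occlusion pipeline — sizes at
which the asserted tolerances (3–5 standard errors; 5 % median flow
error; 20 % noise-model band; ≥ 90 % measured occlusion drop against a
99 % truth) hold with comfortable margins while keeping the whole suite
in tens of seconds.
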