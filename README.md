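# cdcs — the compressed diffuse-correlation-spectroscopy data path

Diffuse Correlation Spectroscopy (DCS) measures deep-tissue blood flow from
the temporal intensity fluctuations of multiply scattered coherent light:
photon-counting detectors emit one TTL pulse per photon, a correlator bins
the pulses at ~1 MHz and estimates the normalized intensity autocorrelation
g₂(τ), and a correlation-diffusion model fit converts the decay of g₂ into a
blood-flow index *F*. Conventional instruments burn a 32-bit counter per
channel even though a microsecond bin almost never holds more than a few
photons. The *compressed* counting scheme this package implements in
software records eight channels with eight 4-bit binary-coded-decimal (BCD)
counters whose outputs concatenate into a single 32-bit word per sample bin
— lossless, and 87.5 % more bandwidth-efficient per channel.

`cdcs` is the complete data path for people building or analysing such
instruments: the bit-exact BCD codec and packed-stream file format, a
digital autocorrelator, the semi-infinite correlation-diffusion forward
model and flow-index fitter, an analytic correlation-noise/SNR model, and a
seeded photon-stream simulator (correlated speckle, Poisson detection,
detector dead time, counter-reset loss, mod-10 rollover) standing in for
the counting hardware.

## The model

Counts n(i) binned at f_s give, at lag Δn (delay τ = Δn/f_s),

    g₂(Δn) = ⟨n(i) n(i+Δn)⟩ / (⟨n⟩_left ⟨n⟩_right)

(overlap-only sums, symmetric normalization). The Siegert relation
g₂ = 1 + β|g₁|² connects it to the field autocorrelation, modelled for a
semi-infinite homogeneous medium as g₁ = G₁(τ)/G₁(0) with

    G₁(ρ,τ) = (3/4π l_tr) [exp(−K r₁)/r₁ − exp(−K r_b)/r_b],
    K(τ) = √(3 μ_a (μ_a+μ_s′) (1 + 2 μ_s′ k₀² F τ / μ_a)),

l_tr = 1/(μ_a+μ_s′), r₁ = √(l_tr²+ρ²), r_b = √((2z_b+l_tr)²+ρ²),
z_b = 2l_tr(1+R_eff)/3(1−R_eff), k₀ = 2π/λ. Fitting (F, β) to a measured
curve by bounded least squares yields the flow index. Noise is predicted by
the Koppel-type estimator variance σ(τ) with SNR ζ(τ) = (g₂−1)/σ(τ).

## Worked example

`python examples/03_fit_flow_index.py` builds the model curve for a liquid
phantom (μ_a = 0.1 cm⁻¹, μ_s′ = 10 cm⁻¹, 785 nm) at ρ = 1 cm, adds
correlator noise of the analytic magnitude for 100 ms frames at a 100 kHz
count rate, averages 70 frames and inverts:

```
effective decay rate of model g1: 6195 1/s (tau_c = 161 us)
true  F = 1.000e-08 cm^2/s, beta = 0.5
fitted F = 9.996e-09 cm^2/s, beta = 0.499
converged = True, residual = 6.66e-03
```

The fitted flow index lands within 0.1 % of the truth; across 100 noisy
replicates the median error stays well under 5 %. The other examples cover
the codec (`01`), the correlator against the closed-form speckle g₂ (`02`),
the noise/SNR sweep over integration times (`04`), and a scaled-down
arm-cuff occlusion run through the full pipeline (`05`), which recovers the
hundredfold flow drop:

```
rho = 1.0 cm (60 frames at 10 Hz):
  baseline   true F = 1.0e-08  median fitted F = 1.00e-08 cm^2/s
  occlusion  true F = 1.0e-10  median fitted F = 1.36e-10 cm^2/s
  recovery   true F = 1.0e-08  median fitted F = 1.01e-08 cm^2/s
  measured occlusion drop: 98.6%
```

A thin CLI wraps the same calls:

```sh
cdcs simulate --rate 100e3 --tau-c 100e-6 --tint 0.1 --frames 10 --out run.cdcs
cdcs correlate run.cdcs --max-lag 250 --out g2/
cdcs fit run.cdcs --config run.cfg --out fits/
cdcs noise --rate 100e3 --tint 10e-3 --gamma 1e4 --out sigma.csv
```

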