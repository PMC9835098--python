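"""Analytic correlation-noise model for photon-count autocorrelators.

Variance of the g2 estimator for single-exponential field dynamics
(g1 = e^{−Γτ}) measured with bin time T, integration time t and mean counts
per bin ⟨n⟩ — the Koppel-type estimator variance used throughout the dynamic
light scattering / DCS literature.  At delay τ = mT:

    σ(τ) = √(T/t) · [ β² ((1+e^{−2ΓT})(1+e^{−2Γτ}) + 2m(1−e^{−2ΓT})e^{−2Γτ})
                          / (1−e^{−2ΓT})
                      + 2⟨n⟩^{−1} β (1+e^{−2Γτ})
                      + ⟨n⟩^{−2} (1+β e^{−Γτ}) ]^{1/2}

The three brackets are the speckle (field) noise, the cross shot-speckle
term, and the pure shot-noise term; the √(T/t) prefactor carries the
averaging over t/T independent-ish samples, so σ scales exactly as 1/√t.
The diffusion-model g1 is not exactly exponential; Γ is taken as its best
single-exponential decay rate (:func:`cdcs.flow.effective_decay_rate`),
which is how this noise model is conventionally applied.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .exceptions import GridError, InsufficientDataError


@dataclass(frozen=True)
class NoiseModelParams:
    """Inputs of the analytic σ(τ) prediction."""

    gamma_decay: float  # effective field decay rate Γ (1/s)
    beta: float  # coherence factor
    mean_counts_per_bin: float  # ⟨n⟩ (photons per bin)
    bin_time_s: float  # T (s)
    integration_time_s: float  # t (s)

    def __post_init__(self) -> None:
        vals = (
            self.gamma_decay,
            self.beta,
            self.mean_counts_per_bin,
            self.bin_time_s,
            self.integration_time_s,
        )
        if any(v <= 0 for v in vals):
            raise ValueError("all noise-model parameters must be positive")
        if self.beta > 1.0:
            raise ValueError("beta must not exceed 1")
        if self.bin_time_s > self.integration_time_s:
            raise ValueError("bin time cannot exceed integration time")


def sigma_tau(tau_s, params: NoiseModelParams):
    """Predicted standard deviation σ(τ) of g2; vectorized over τ.

    τ must sit on the bin grid (τ = m·T, integer m ≥ 1).
    """
    tau = np.atleast_1d(np.asarray(tau_s, dtype=float))
    T, t = params.bin_time_s, params.integration_time_s
    m = tau / T
    m_round = np.round(m)
    if (m_round < 1).any() or (np.abs(m - m_round) > 1e-6 * np.maximum(m_round, 1)).any():
        raise GridError("tau must be a positive integer multiple of the bin time")
    m = m_round
    G, b, nbar = params.gamma_decay, params.beta, params.mean_counts_per_bin
    e2T = np.exp(-2.0 * G * T)
    one_minus_e2T = -np.expm1(-2.0 * G * T)  # stable for small ΓT
    e2tau = np.exp(-2.0 * G * tau)
    e1tau = np.exp(-G * tau)
    speckle = b**2 * ((1.0 + e2T) * (1.0 + e2tau) + 2.0 * m * one_minus_e2T * e2tau) / one_minus_e2T
    cross = 2.0 / nbar * b * (1.0 + e2tau)
    shot = (1.0 + b * e1tau) / nbar**2
    out = np.sqrt(T / t) * np.sqrt(speckle + cross + shot)
    return out if np.ndim(tau_s) else float(out[0])


def snr_tau(tau_s, params: NoiseModelParams, g2_minus_1):
    """SNR ζ(τ) = (g2(τ) − 1) / σ(τ); +inf where σ = 0."""
    sig = np.atleast_1d(sigma_tau(tau_s, params))
    signal = np.atleast_1d(np.asarray(g2_minus_1, dtype=float))
    zeta = np.where(sig > 0, signal / np.where(sig > 0, sig, 1.0), np.inf)
    return zeta if np.ndim(tau_s) else float(zeta[0])


@dataclass
class NoiseFitResult:
    params: NoiseModelParams
    converged: bool
    residual_norm: float


def fit_noise_model(
    empirical_sigma: np.ndarray,
    tau_s: np.ndarray,
    initial: NoiseModelParams,
    fit_beta: bool = False,
) -> NoiseFitResult:
    """Fit Γ (optionally also β) of the noise model to an empirical σ(τ).

    Acquisition-determined parameters (⟨n⟩, T, t) are held at their known
    values.  Non-convergence is flagged on the result.
    """
    sig = np.asarray(empirical_sigma, dtype=float)
    tau = np.asarray(tau_s, dtype=float)
    if sig.size != tau.size:
        raise GridError("sigma and tau grids differ in length")
    if sig.size < 5:
        raise InsufficientDataError("need at least 5 lag points to fit the noise model")

    def params_from(x):
        kw = {"gamma_decay": float(np.exp(x[0]))}
        if fit_beta:
            kw["beta"] = float(np.clip(x[1], 1e-6, 1.0))
        return replace(initial, **kw)

    def resid(x):
        return sigma_tau(tau, params_from(x)) - sig

    x0 = [np.log(initial.gamma_decay)] + ([initial.beta] if fit_beta else [])
    lower = [-np.inf] + ([1e-6] if fit_beta else [])
    upper = [np.inf] + ([1.0] if fit_beta else [])
    res = least_squares(resid, x0, bounds=(lower, upper), xtol=1e-14, ftol=1e-14)
    return NoiseFitResult(
        params=params_from(res.x),
        converged=bool(res.success),
        residual_norm=float(2.0 * res.cost),
    )
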