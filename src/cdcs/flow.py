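"""Semi-infinite correlation-diffusion model and blood-flow-index fitting.

For coherent light multiply scattered by a homogeneous semi-infinite medium,
the unnormalized field autocorrelation at source-detector separation ρ is

    G1(ρ, τ) = (3 / 4π l_tr) [ exp(−K(τ) r1)/r1 − exp(−K(τ) rb)/rb ]

with transport mean free path l_tr = 1/(μa + μs′), image-source distances
r1 = √(l_tr² + ρ²) and rb = √((2 z_b + l_tr)² + ρ²), extrapolated boundary
z_b = 2 l_tr (1 + R_eff) / (3 (1 − R_eff)), and dynamic wave vector

    K(τ) = √( 3 μa (μa + μs′) (1 + 2 μs′ k0² F τ / μa) ),   k0 = 2π/λ.

F (cm²/s) is the blood-flow index: an effective Brownian diffusion
coefficient of the moving scatterers.  Measured intensity autocorrelations
relate to g1 = G1(τ)/G1(0) through the Siegert relation
g2(τ) = 1 + β |g1(τ)|², with β the instrumentation coherence factor.

Units: lengths in cm, times in s, F in cm²/s.  Wavelengths may be given in
nm at the constructor and are converted once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.integrate import quad
from scipy.optimize import least_squares

from .correlator import G2Curve
from .exceptions import ModelDomainError

# fit bounds for the blood-flow index, covering phantom and in-vivo ranges
F_BOUNDS = (1e-12, 1e-4)


@lru_cache(maxsize=64)
def effective_reflection_coefficient(n_rel: float) -> float:
    """Fresnel effective reflection coefficient R_eff of a refractive boundary.

    Angular integrals of the unpolarized Fresnel reflectance for light leaving
    a medium of relative index ``n_rel`` (tissue/air ≈ 1.4 gives ≈ 0.493):

        R_phi = ∫ 2 sinθ cosθ R_F(θ) dθ,  R_j = ∫ 3 sinθ cos²θ R_F(θ) dθ,
        R_eff = (R_phi + R_j) / (2 − R_phi + R_j),

    with total internal reflection (R_F = 1) beyond the critical angle.
    """
    n = float(n_rel)
    if n <= 0:
        raise ValueError("relative refractive index must be positive")
    if n == 1.0:
        return 0.0

    def fresnel(theta: float) -> float:
        s = n * np.sin(theta)
        if s >= 1.0:
            return 1.0
        theta_t = np.arcsin(s)
        ci, ct = np.cos(theta), np.cos(theta_t)
        rs = ((n * ci - ct) / (n * ci + ct)) ** 2
        rp = ((n * ct - ci) / (n * ct + ci)) ** 2
        return 0.5 * (rs + rp)

    r_phi = quad(lambda t: 2.0 * np.sin(t) * np.cos(t) * fresnel(t), 0, np.pi / 2)[0]
    r_j = quad(lambda t: 3.0 * np.sin(t) * np.cos(t) ** 2 * fresnel(t), 0, np.pi / 2)[0]
    return (r_phi + r_j) / (2.0 - r_phi + r_j)


@dataclass(frozen=True)
class OpticalProperties:
    """Tissue optical parameters entering the diffusion model.

    ``r_eff`` defaults to the Fresnel integral value for ``n_rel``; pass a
    number to override.
    """

    mu_a: float  # absorption coefficient (1/cm)
    mu_s_prime: float  # reduced scattering coefficient (1/cm)
    wavelength_cm: float
    n_rel: float = 1.4
    r_eff: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if min(self.mu_a, self.mu_s_prime, self.wavelength_cm) <= 0:
            raise ValueError("mu_a, mu_s_prime and wavelength must be positive")
        if self.r_eff is None:
            object.__setattr__(
                self, "r_eff", effective_reflection_coefficient(self.n_rel)
            )
        if not 0.0 <= self.r_eff < 1.0:
            raise ValueError("R_eff must lie in [0, 1)")

    @classmethod
    def from_nm(
        cls,
        mu_a: float,
        mu_s_prime: float,
        wavelength_nm: float,
        n_rel: float = 1.4,
        r_eff: float | None = None,
    ) -> "OpticalProperties":
        return cls(mu_a, mu_s_prime, wavelength_nm * 1e-7, n_rel, r_eff)

    @property
    def k0(self) -> float:
        """Vacuum wavenumber 2π/λ (1/cm)."""
        return 2.0 * np.pi / self.wavelength_cm


@dataclass(frozen=True)
class SemiInfiniteGeometry:
    """Derived distances of the extrapolated-boundary image-source solution."""

    rho_cm: float
    l_tr: float
    z_b: float
    r1: float
    rb: float

    @classmethod
    def from_optics(cls, optics: OpticalProperties, rho_cm: float) -> "SemiInfiniteGeometry":
        if rho_cm < 0:
            raise ValueError("source-detector separation must be non-negative")
        l_tr = 1.0 / (optics.mu_a + optics.mu_s_prime)
        z_b = 2.0 * l_tr * (1.0 + optics.r_eff) / (3.0 * (1.0 - optics.r_eff))
        r1 = np.hypot(l_tr, rho_cm)
        rb = np.hypot(2.0 * z_b + l_tr, rho_cm)
        return cls(rho_cm, l_tr, z_b, float(r1), float(rb))


@dataclass
class FlowFitResult:
    """Outcome of fitting (F, β) to a measured g2 curve."""

    F: float
    beta: float
    residual_norm: float
    converged: bool
    n_points_fit: int
    fit_window_s: tuple[float, float]
    degenerate: bool = False


def wave_vector_K(tau_s, optics: OpticalProperties, F: float):
    """Dynamic wave vector K(τ) (1/cm); vectorized over τ."""
    tau = np.asarray(tau_s, dtype=float)
    if (tau < 0).any() or F < 0:
        raise ValueError("tau and F must be non-negative")
    bracket = 1.0 + 2.0 * optics.mu_s_prime * optics.k0**2 * F * tau / optics.mu_a
    out = np.sqrt(3.0 * optics.mu_a * (optics.mu_a + optics.mu_s_prime) * bracket)
    return out if out.ndim else float(out)


def _g1_unnormalized(K, geom: SemiInfiniteGeometry):
    return (3.0 / (4.0 * np.pi * geom.l_tr)) * (
        np.exp(-K * geom.r1) / geom.r1 - np.exp(-K * geom.rb) / geom.rb
    )


def g1_semi_infinite(tau_s, rho_cm: float, optics: OpticalProperties, F: float):
    """Normalized field autocorrelation g1(τ) = G1(τ)/G1(0); g1(0) = 1."""
    geom = SemiInfiniteGeometry.from_optics(optics, rho_cm)
    K0 = wave_vector_K(0.0, optics, F)
    G1_0 = _g1_unnormalized(K0, geom)
    if not G1_0 > 0:
        raise ModelDomainError("G1(0) <= 0: non-physical optics/geometry")
    K = wave_vector_K(tau_s, optics, F)
    return _g1_unnormalized(K, geom) / G1_0


def g2_model(tau_s, rho_cm: float, optics: OpticalProperties, F: float, beta: float):
    """Siegert relation: g2(τ) = 1 + β g1(τ)², bounded in [1, 1+β]."""
    if not 0.0 < beta <= 1.0:
        raise ValueError("beta must lie in (0, 1]")
    return 1.0 + beta * g1_semi_infinite(tau_s, rho_cm, optics, F) ** 2


def effective_decay_rate(
    rho_cm: float,
    optics: OpticalProperties,
    F: float,
    tau_grid_s: np.ndarray | None = None,
) -> float:
    """Best single-exponential decay rate Γ of the model g1 (1/s).

    Least-squares fit of exp(−Γτ) to g1(τ) over the given delay grid
    (default 1-250 µs).  Used to drive the single-exponential speckle
    simulator and the correlation noise model.
    """
    tau = (
        np.arange(1, 251) * 1e-6 if tau_grid_s is None else np.asarray(tau_grid_s, float)
    )
    g1 = g1_semi_infinite(tau, rho_cm, optics, F)
    # crude initialiser: delay where g1 crosses 1/e (or grid edge)
    below = np.flatnonzero(g1 < np.exp(-1.0))
    tau0 = tau[below[0]] if below.size else tau[-1]
    res = least_squares(
        lambda lg: np.exp(-np.exp(lg[0]) * tau) - g1,
        x0=[np.log(1.0 / tau0)],
    )
    return float(np.exp(res.x[0]))


def fit_flow(
    curve: G2Curve,
    rho_cm: float,
    optics: OpticalProperties,
    tau_min_s: float | None = None,
    tau_max_s: float | None = None,
    sigma: np.ndarray | None = None,
    noise_floor: float = 0.01,
) -> FlowFitResult:
    """Fit the blood-flow index F and coherence factor β to a measured curve.

    Unweighted least squares over the fit window (all lags by default);
    pass per-lag ``sigma`` for a 1/σ-weighted fit.  F is optimised on a log
    scale within ``F_BOUNDS``; β within (0, 1].  Non-convergence is flagged
    on the result, not raised.  A curve whose plateau never rises above
    ``1 + noise_floor`` is flagged degenerate.
    """
    mask = np.isfinite(curve.g2)
    if tau_min_s is not None:
        mask &= curve.delays_s >= tau_min_s
    if tau_max_s is not None:
        mask &= curve.delays_s <= tau_max_s
    tau = curve.delays_s[mask]
    g2 = curve.g2[mask]
    if tau.size < 10:
        raise ValueError("need at least 10 lags inside the fit window")
    window = (float(tau[0]), float(tau[-1]))
    degenerate = bool(np.max(g2) < 1.0 + noise_floor)

    w = np.ones_like(tau)
    if sigma is not None:
        s = np.asarray(sigma, float)[mask]
        w = 1.0 / np.where(s > 0, s, np.inf)

    g1 = lambda F: g1_semi_infinite(tau, rho_cm, optics, F)  # noqa: E731

    beta0 = float(np.clip(np.mean(g2[:3]) - 1.0, 1e-3, 1.0))
    x0 = [np.log10(1e-8), beta0]

    def resid(x):
        F, beta = 10.0 ** x[0], x[1]
        return w * (1.0 + beta * g1(F) ** 2 - g2)

    res = least_squares(
        resid,
        x0,
        bounds=([np.log10(F_BOUNDS[0]), 1e-6], [np.log10(F_BOUNDS[1]), 1.0]),
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
    )
    return FlowFitResult(
        F=float(10.0 ** res.x[0]),
        beta=float(res.x[1]),
        residual_norm=float(2.0 * res.cost),
        converged=bool(res.success),
        n_points_fit=int(tau.size),
        fit_window_s=window,
        degenerate=degenerate,
    )
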