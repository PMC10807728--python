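"""Secular dipolar coupling, powder-averaged form factors and related kernels.

The electron-electron magnetic dipolar interaction between two S=1/2 centres,
truncated to its secular part, oscillates at

    omega_dd(r, theta) = 2*pi * C_dd / r**3 * (1 - 3*cos(theta)**2)

with ``r`` the inter-spin distance (nm), ``theta`` the angle between the
inter-spin vector and the static field, and ``C_dd`` the free-electron dipolar
constant in MHz*nm^3.  All frequencies in this package are angular
(rad/us); conversions to/from MHz happen only at I/O boundaries.

Averages over an isotropic powder (uniform in cos(theta)) and over a distance
distribution yield the time-domain Pake signal ("form factor")

    F(t) = < cos(omega_dd(r, theta) * t) >,

the sine-product artefact kernel Fs(tau1, tau2) = <sin(w*tau1) sin(w*tau2)>
and the fixed-sum constant K(tau0) = <cos(w*(tau1+tau2))> = F(tau0), which is
independent of the trace coordinate t = tau1 - tau2 at fixed tau0 = tau1+tau2.

Orientation averages use deterministic Gauss-Legendre quadrature in
cos(theta); distance averages use trapezoidal integration on the
distribution's grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import constants as _const

__all__ = [
    "DIPOLAR_CONSTANT_MHZ_NM3",
    "DipolarParameters",
    "DistanceDistribution",
    "dipolar_frequency",
    "powder_form_factor",
    "sine_product_term",
    "fixed_sum_cosine",
]

_G_FREE = 2.0023  # electron g-value used for both spins


def _dipolar_constant_mhz_nm3(g: float = _G_FREE) -> float:
    """mu0 g^2 muB^2 / (4 pi h), expressed in MHz * nm^3 (~52.04 for g=2.0023)."""
    si = _const.mu_0 / (4.0 * np.pi) * (g * _const.value("Bohr magneton")) ** 2 / _const.h
    # Hz*m^3 -> MHz*nm^3: 1e-6 * 1e27
    return si * 1e21


DIPOLAR_CONSTANT_MHZ_NM3 = _dipolar_constant_mhz_nm3()


@dataclass(frozen=True)
class DipolarParameters:
    """Physical constant entering omega_dd; override only for testing."""

    coupling_constant_mhz_nm3: float = DIPOLAR_CONSTANT_MHZ_NM3

    def __post_init__(self) -> None:
        if not (self.coupling_constant_mhz_nm3 > 0):
            raise ValueError("dipolar coupling constant must be positive")

    @property
    def angular_constant(self) -> float:
        """2*pi*C_dd in rad/us * nm^3."""
        return 2.0 * np.pi * self.coupling_constant_mhz_nm3


_DEFAULT_PARAMS = DipolarParameters()


def dipolar_frequency(r_nm, theta_rad, params: DipolarParameters | None = None):
    """Secular dipolar angular frequency (rad/us) at distance r and angle theta."""
    params = params or _DEFAULT_PARAMS
    r = np.asarray(r_nm, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distance must be positive")
    cos2 = np.cos(theta_rad) ** 2
    return params.angular_constant / r**3 * (1.0 - 3.0 * cos2)


def dipolar_frequency_from_vector(vec_nm: np.ndarray, params: DipolarParameters | None = None):
    """omega_dd for Cartesian inter-spin vector(s); the field defines the z axis."""
    params = params or _DEFAULT_PARAMS
    vec = np.asarray(vec_nm, dtype=float)
    r2 = np.sum(vec**2, axis=-1)
    if np.any(r2 <= 0):
        raise ValueError("zero-length inter-spin vector")
    cos2 = vec[..., 2] ** 2 / r2
    return params.angular_constant * r2**-1.5 * (1.0 - 3.0 * cos2)


@dataclass(frozen=True)
class DistanceDistribution:
    """Distance distribution P(r) on r > 0, normalized to unit integral.

    Construct via :meth:`gaussian`, :meth:`delta` or :meth:`tabulated`.
    ``r_nm`` / ``weights`` form a quadrature rule: sum(weights) == 1 and
    <g> = sum(weights * g(r_nm)) approximates the distribution average.
    """

    r_nm: np.ndarray
    weights: np.ndarray
    mean: float = field(default=float("nan"))
    sigma: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        r = np.asarray(self.r_nm, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if r.ndim != 1 or r.shape != w.shape or r.size == 0:
            raise ValueError("r grid and weights must be matching 1-D arrays")
        if np.any(r <= 0):
            raise ValueError("distance support must be strictly positive")
        if np.any(w < -1e-12):
            raise ValueError("distribution density must be non-negative")
        total = float(np.sum(w))
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"weights must sum to 1 (got {total:.8f})")
        object.__setattr__(self, "r_nm", r)
        object.__setattr__(self, "weights", np.clip(w, 0.0, None) / total)

    # -- constructors -----------------------------------------------------

    @classmethod
    def gaussian(cls, mean_nm: float, sigma_nm: float, n_points: int = 513) -> "DistanceDistribution":
        if mean_nm <= 0 or sigma_nm <= 0:
            raise ValueError("Gaussian distance distribution needs mean, sigma > 0")
        # support floored at 0.8 nm: shorter distances are below molecular
        # contact and their ~1/r^3 frequencies are numerically hostile
        lo = max(mean_nm - 6.0 * sigma_nm, 0.8)
        hi = mean_nm + 6.0 * sigma_nm
        r = np.linspace(lo, hi, n_points)
        dens = np.exp(-0.5 * ((r - mean_nm) / sigma_nm) ** 2)
        w = _trapezoid_weights(r) * dens
        w /= w.sum()
        return cls(r, w, mean=mean_nm, sigma=sigma_nm)

    @classmethod
    def delta(cls, r_nm: float) -> "DistanceDistribution":
        if r_nm <= 0:
            raise ValueError("delta distance must be positive")
        return cls(np.array([r_nm]), np.array([1.0]), mean=r_nm, sigma=0.0)

    @classmethod
    def tabulated(cls, r_nm: np.ndarray, density: np.ndarray) -> "DistanceDistribution":
        r = np.asarray(r_nm, dtype=float)
        d = np.asarray(density, dtype=float)
        if np.any(np.diff(r) <= 0):
            raise ValueError("tabulated r grid must be strictly increasing")
        if np.any(d < 0):
            raise ValueError("tabulated density must be non-negative")
        w = _trapezoid_weights(r) * d
        total = w.sum()
        if total <= 0:
            raise ValueError("tabulated density integrates to zero")
        w = w / total
        mean = float(np.sum(w * r))
        sigma = float(np.sqrt(max(np.sum(w * (r - mean) ** 2), 0.0)))
        return cls(r, w, mean=mean, sigma=sigma)

    @classmethod
    def from_file(cls, path) -> "DistanceDistribution":
        """Two-column ASCII (r_nm, density); '#' comment lines allowed."""
        data = np.loadtxt(path)
        if data.ndim != 2 or data.shape[1] < 2:
            raise ValueError(f"{path}: expected two columns (r_nm, density)")
        return cls.tabulated(data[:, 0], data[:, 1])

    # -- sampling ---------------------------------------------------------

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw n distances; exact for delta/Gaussian, inverse-CDF otherwise."""
        if self.sigma == 0.0:
            return np.full(n, self.mean)
        if np.isfinite(self.mean) and np.isfinite(self.sigma) and self.sigma > 0:
            # truncated-at-zero Gaussian by rejection (truncation negligible
            # for mean >> sigma, which holds for labelled biradicals)
            out = rng.normal(self.mean, self.sigma, size=n)
            bad = out <= 0
            while np.any(bad):
                out[bad] = rng.normal(self.mean, self.sigma, size=int(bad.sum()))
                bad = out <= 0
            return out
        cdf = np.cumsum(self.weights)
        return np.interp(rng.random(n), cdf, self.r_nm)


def _trapezoid_weights(x: np.ndarray) -> np.ndarray:
    if x.size == 1:
        return np.ones(1)
    w = np.empty_like(x)
    dx = np.diff(x)
    w[0] = dx[0] / 2
    w[-1] = dx[-1] / 2
    w[1:-1] = (dx[:-1] + dx[1:]) / 2
    return w


def _orientation_nodes(n_theta: int):
    # powder average: uniform in cos(theta); by symmetry of cos^2, the
    # average over [0, 1] equals the average over [-1, 1]
    x, w = np.polynomial.legendre.leggauss(n_theta)
    u = 0.5 * (x + 1.0)
    return u, 0.5 * w


def _frequency_quadrature(dist: DistanceDistribution,
                          params: DipolarParameters,
                          n_theta: int):
    """Flattened (omega, weight) nodes for the joint (r, cos theta) average."""
    u, wu = _orientation_nodes(n_theta)
    omega_perp = params.angular_constant / dist.r_nm**3  # (n_r,)
    omega = omega_perp[:, None] * (1.0 - 3.0 * u[None, :] ** 2)
    weight = dist.weights[:, None] * wu[None, :]
    return omega.ravel(), weight.ravel()


def powder_form_factor(dist: DistanceDistribution,
                       t_grid_us,
                       params: DipolarParameters | None = None,
                       n_theta: int = 401) -> np.ndarray:
    """Time-domain Pake signal F(t) = <cos(omega_dd t)>; F(0) = 1 exactly."""
    params = params or _DEFAULT_PARAMS
    t = np.atleast_1d(np.asarray(t_grid_us, dtype=float))
    if t.size == 0:
        raise ValueError("empty time grid")
    omega, weight = _frequency_quadrature(dist, params, n_theta)
    return np.cos(np.multiply.outer(t, omega)) @ weight


def sine_product_term(dist: DistanceDistribution,
                      tau1_us,
                      tau2_us,
                      params: DipolarParameters | None = None,
                      n_theta: int = 401) -> np.ndarray | float:
    """Artefact kernel Fs(tau1, tau2) = <sin(omega tau1) sin(omega tau2)>.

    Identity with the cosine averages:
    Fs = F(tau2 - tau1)/2 - <cos(omega (tau1+tau2))>/2.
    """
    params = params or _DEFAULT_PARAMS
    t1 = np.asarray(tau1_us, dtype=float)
    t2 = np.asarray(tau2_us, dtype=float)
    if np.any(t1 < 0) or np.any(t2 < 0):
        raise ValueError("delays must be non-negative")
    omega, weight = _frequency_quadrature(dist, params, n_theta)
    val = (np.sin(np.multiply.outer(t1, omega)) * np.sin(np.multiply.outer(t2, omega))) @ weight
    return val if val.ndim else float(val)


def fixed_sum_cosine(dist: DistanceDistribution,
                     tau0_us: float,
                     params: DipolarParameters | None = None,
                     n_theta: int = 401) -> float:
    """K(tau0) = <cos(omega_dd tau0)>, constant along a fixed-tau0 trace."""
    if tau0_us < 0:
        raise ValueError("tau0 must be non-negative")
    return float(powder_form_factor(dist, [tau0_us], params, n_theta)[0])
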