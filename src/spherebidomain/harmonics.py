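"""Special-function layer: modified spherical Bessel functions, tesseral
spherical harmonics with their angular-derivative identity, and the radial
Green's-function terms of the point-source expansion.

Conventions
-----------
Harmonics are orthonormal complex spherical harmonics *with* the
Condon-Shortley phase, so that ``Y_mu^{-nu} = (-1)^nu * conj(Y_mu^nu)``
and the addition theorem reads

    sum_nu Y_mu^nu(th, ph) conj(Y_mu^nu(th', ph')) = (2 mu + 1)/(4 pi) P_mu(cos g)

with ``g`` the angle between the two directions.  The polar angle ``theta``
is measured from the +z axis.

Only the modified spherical Bessel function of the first kind ``i_mu`` is
provided: the tissue domain contains the origin, where the second kind is
singular.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import eval_legendre, sph_harm_y, sph_harm_y_all, spherical_in

__all__ = [
    "HarmonicIndex",
    "RadialGreensTerm",
    "mod_sph_bessel_i",
    "tesseral_harmonic",
    "theta_derivative_factor",
    "theta_derivative",
    "harmonic_table",
    "greens_radial",
    "greens_radial_value",
    "greens_radial_derivative",
    "legendre",
    "indices",
]


@dataclass(frozen=True)
class HarmonicIndex:
    """Degree/order pair (mu, nu) with the separation constant alpha = mu(mu+1)."""

    mu: int
    nu: int
    alpha: int = field(init=False)

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError(f"degree mu must be >= 0, got {self.mu}")
        if abs(self.nu) > self.mu:
            raise ValueError(f"order nu={self.nu} outside [-mu, mu] for mu={self.mu}")
        object.__setattr__(self, "alpha", self.mu * (self.mu + 1))


def indices(mu_max: int, nu_min: int | None = None):
    """Yield HarmonicIndex over 0 <= mu <= mu_max, nu_min(mu) <= nu <= mu.

    By default all orders are generated; pass ``nu_min=0`` to iterate the
    non-negative orders only (negative orders follow from conjugation).
    """
    for mu in range(mu_max + 1):
        lo = -mu if nu_min is None else nu_min
        for nu in range(lo, mu + 1):
            yield HarmonicIndex(mu, nu)


def _mu_nu(idx, nu=None):
    if nu is None:
        return idx.mu, idx.nu
    return int(idx), int(nu)


def mod_sph_bessel_i(mu, x):
    """Modified spherical Bessel function of the first kind i_mu(x).

    Regular at the origin: i_0(0) = 1 and i_mu(0) = 0 for mu >= 1.
    Accepts array ``x``; requires x >= 0 and mu >= 0.
    """
    mu = int(mu)
    if mu < 0:
        raise ValueError(f"order mu must be >= 0, got {mu}")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("argument x must be non-negative")
    out = spherical_in(mu, x)
    return out if out.shape else float(out)


def tesseral_harmonic(idx, *args):
    """Orthonormal complex spherical harmonic Y_mu^nu(theta, phi).

    Call either as ``tesseral_harmonic(HarmonicIndex(mu, nu), theta, phi)``
    or as ``tesseral_harmonic(mu, nu, theta, phi)`` (positional degree/order).
    """
    if isinstance(idx, HarmonicIndex):
        mu, order = idx.mu, idx.nu
        theta, phi = args
    else:
        mu, (order, theta, phi) = int(idx), args
        order = int(order)
    if abs(order) > mu:
        raise ValueError(f"order nu={order} outside [-mu, mu] for mu={mu}")
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    out = sph_harm_y(mu, order, theta, phi)
    return out if np.ndim(out) else complex(out)


def theta_derivative_factor(idx, nu=None):
    """Coupling coefficient tau(mu, nu) = sqrt((mu - nu)(mu + nu + 1)).

    This is the factor multiplying ``exp(-i phi) Y_mu^{nu+1}`` in the
    polar-derivative identity

        dY_mu^nu/dtheta = nu cot(theta) Y_mu^nu + tau exp(-i phi) Y_mu^{nu+1}.

    For nu = mu the companion harmonic does not exist and tau = 0 (the
    equivalent Gamma-ratio form hits a pole of the denominator which
    annihilates the term).
    """
    mu, order = _mu_nu(idx, nu)
    if abs(order) > mu:
        raise ValueError(f"order nu={order} outside [-mu, mu] for mu={mu}")
    if order == mu:
        return 0.0
    return float(np.sqrt((mu - order) * (mu + order + 1)))


def theta_derivative(idx, *args):
    """Analytic dY_mu^nu/dtheta via the cot/coupling identity.

    Not valid exactly at the poles (cot singularity); the series gradient
    code handles theta in {0, pi} through the explicit polar limits instead.
    """
    if isinstance(idx, HarmonicIndex):
        mu, order = idx.mu, idx.nu
        theta, phi = args
    else:
        mu, (order, theta, phi) = int(idx), args
        order = int(order)
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    out = order / np.tan(theta) * sph_harm_y(mu, order, theta, phi)
    tau = theta_derivative_factor(mu, nu=order)
    if tau != 0.0:
        out = out + tau * np.exp(-1j * phi) * sph_harm_y(mu, order + 1, theta, phi)
    return out if np.ndim(out) else complex(out)


def harmonic_table(mu_max: int, theta, phi):
    """All Y_mu^nu for 0 <= mu <= mu_max, |nu| <= mu, at an array of angles.

    Returns a complex array of shape ``(mu_max+1, 2*mu_max+1) + theta.shape``
    with wrap-around order indexing (``table[mu, nu]`` valid for negative nu).
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    return sph_harm_y_all(mu_max, mu_max, theta, phi)


def legendre(mu: int, x):
    """Legendre polynomial P_mu(x) (used by addition-theorem checks)."""
    return eval_legendre(mu, np.asarray(x, dtype=float))


@dataclass(frozen=True)
class RadialGreensTerm:
    """Radial factor min(r, r_src)^mu / max(r, r_src)^(mu+1) of the 1/R expansion."""

    g_less: float
    g_greater: float
    value: float


def greens_radial(mu: int, r: float, r_src: float) -> RadialGreensTerm:
    """Radial Green's-function term for the interior/exterior 1/R expansion.

    ``value = min(r, r_src)^mu / max(r, r_src)^(mu+1)``; continuous across
    r = r_src.  At r = 0 the value is 1/r_src for mu = 0 and 0 for mu >= 1.
    """
    mu = int(mu)
    if mu < 0:
        raise ValueError("mu must be >= 0")
    if r < 0 or r_src < 0:
        raise ValueError("radii must be non-negative")
    if r == 0.0 and r_src == 0.0:
        raise ValueError("both radii zero: 1/R expansion undefined")
    g_less, g_greater = min(r, r_src), max(r, r_src)
    if g_less == 0.0:
        value = 1.0 / g_greater if mu == 0 else 0.0
    else:
        value = g_less**mu / g_greater ** (mu + 1)
    return RadialGreensTerm(g_less=g_less, g_greater=g_greater, value=value)


def greens_radial_value(mu: int, r, r_src: float):
    """Vectorized ``greens_radial(...).value`` over an array of field radii."""
    r = np.asarray(r, dtype=float)
    g_less = np.minimum(r, r_src)
    g_greater = np.maximum(r, r_src)
    with np.errstate(divide="ignore", invalid="ignore"):
        value = np.where(
            (g_less == 0.0) & (mu > 0), 0.0, g_less**mu / g_greater ** (mu + 1)
        )
    return value if value.shape else float(value)


def greens_radial_derivative(mu: int, r, r_src: float):
    """d/dr of the radial Green's term, branchwise.

    mu r^(mu-1)/r_src^(mu+1) for r < r_src, -(mu+1) r_src^mu / r^(mu+2) for
    r > r_src.  The derivative jumps at r = r_src, where evaluation is an
    error (the caller must not sit exactly on the source radius).
    """
    mu = int(mu)
    if mu < 0:
        raise ValueError("mu must be >= 0")
    r = np.asarray(r, dtype=float)
    if np.any(r == r_src):
        raise ValueError(f"radial Green's derivative undefined at r == r_src = {r_src}")
    inner = mu * r ** (mu - 1) / r_src ** (mu + 1) if mu > 0 else np.zeros_like(r)
    outer = -(mu + 1) * r_src**mu / r ** (mu + 2)
    out = np.where(r < r_src, inner, outer)
    return out if out.shape else float(out)
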