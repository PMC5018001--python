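"""Analytic current densities J = -rho^{-1} grad(phi) and grid sampling.

Gradients of the series potentials are term-wise analytic (radial factors
differentiated in closed form, polar derivatives through the harmonic
coupling identity, azimuthal derivatives by i*nu); the free monopole
contribution to the bath current is differentiated in closed form, so no
finite differencing enters the field evaluation anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._series import HarmonicSeries
from .bidomain_solver import (
    CoefficientSet,
    bath_series,
    psi_series,
    vm_series,
)
from .parameters import ModelConfig, SourcePair, TissueParameters

__all__ = [
    "SphericalVector",
    "CartesianVectorGrid",
    "MASK_TISSUE",
    "MASK_BATH",
    "MASK_EXCLUDED",
    "gradient_spherical",
    "current_density_i",
    "current_density_o",
    "current_density_e",
    "to_cartesian",
    "from_cartesian",
    "cartesian_to_spherical_coords",
    "sample_grid",
]

MASK_TISSUE, MASK_BATH, MASK_EXCLUDED = 0, 1, 2


@dataclass(frozen=True)
class SphericalVector:
    """Vector field value(s) on the local orthonormal (r, theta, phi) frame."""

    v_r: np.ndarray
    v_theta: np.ndarray
    v_phi: np.ndarray

    @property
    def magnitude(self):
        return np.sqrt(self.v_r**2 + self.v_theta**2 + self.v_phi**2)

    def __add__(self, other: "SphericalVector") -> "SphericalVector":
        return SphericalVector(
            self.v_r + other.v_r,
            self.v_theta + other.v_theta,
            self.v_phi + other.v_phi,
        )

    def scaled(self, factor: float) -> "SphericalVector":
        return SphericalVector(
            factor * self.v_r, factor * self.v_theta, factor * self.v_phi
        )


def gradient_spherical(series: HarmonicSeries, r, theta, phi) -> SphericalVector:
    """+grad of a truncated harmonic series, spherical components (V/m)."""
    g_r, g_t, g_p = series.gradient(r, theta, phi)
    return SphericalVector(g_r, g_t, g_p)


def _combined_gradient(weights_series, r, theta, phi) -> SphericalVector:
    """Gradient of a weighted sum of series, sharing nothing but the points."""
    total = None
    for w, s in weights_series:
        g = gradient_spherical(s, r, theta, phi).scaled(w)
        total = g if total is None else total + g
    return total


def current_density_i(
    r, theta, phi, coeffs: CoefficientSet, params: TissueParameters
) -> SphericalVector:
    """Intracellular current density J_i = -rho_i^{-1} grad(phi_i), A/m^2 (r <= a)."""
    _check_tissue(r, coeffs.tissue_radius)
    ri, ro = params.rho_i, params.rho_o
    grad = _combined_gradient(
        [(ri / (ri + ro), vm_series(coeffs)), (1.0, psi_series(coeffs))], r, theta, phi
    )
    return grad.scaled(-1.0 / ri)


def current_density_o(
    r, theta, phi, coeffs: CoefficientSet, params: TissueParameters
) -> SphericalVector:
    """Interstitial current density J_o = -rho_o^{-1} grad(phi_o), A/m^2 (r <= a)."""
    _check_tissue(r, coeffs.tissue_radius)
    ri, ro = params.rho_i, params.rho_o
    grad = _combined_gradient(
        [(-ro / (ri + ro), vm_series(coeffs)), (1.0, psi_series(coeffs))], r, theta, phi
    )
    return grad.scaled(-1.0 / ro)


def _monopole_current(r, theta, phi, sources: SourcePair) -> SphericalVector:
    """Free-medium current of the electrode pair, spherical components.

    J = I_0/(4 pi) [ (x - p+)/R+^3 - (x - p-)/R-^3 ]; the bath resistivity
    cancels between the potential and Ohm's law.
    """
    x, y, z = _sph_to_cart(r, theta, phi)
    jx = jy = jz = 0.0
    for sign, p in ((1.0, sources.p_plus), (-1.0, sources.p_minus)):
        px, py, pz = p.cartesian
        dx, dy, dz = x - px, y - py, z - pz
        R3 = (dx**2 + dy**2 + dz**2) ** 1.5
        with np.errstate(divide="ignore", invalid="ignore"):
            f = sign * sources.I_0 / (4.0 * np.pi) / R3
        jx = jx + f * dx
        jy = jy + f * dy
        jz = jz + f * dz
    return from_cartesian(jx, jy, jz, theta, phi)


def current_density_e(
    r,
    theta,
    phi,
    coeffs: CoefficientSet,
    sources: SourcePair,
    params: TissueParameters,
    exclusion_radius: float = 0.0,
) -> SphericalVector:
    """Bath current density J_e = -rho_e^{-1} grad(phi_e), A/m^2 (r >= a).

    Secondary-field gradient from the series; monopole gradients in closed
    form.  Far from the sphere this tends to the free two-monopole field.
    """
    _check_bath(r, coeffs.tissue_radius)
    if exclusion_radius > 0.0:
        from .bidomain_solver import check_exclusion

        check_exclusion(r, theta, phi, sources, exclusion_radius)
    grad = gradient_spherical(bath_series(coeffs), r, theta, phi)
    return grad.scaled(-1.0 / params.rho_e) + _monopole_current(r, theta, phi, sources)


def _check_tissue(r, a):
    if np.any(np.asarray(r) > a * (1 + 1e-12)):
        raise ValueError("tissue current density requested outside the sphere")


def _check_bath(r, a):
    if np.any(np.asarray(r) < a * (1 - 1e-12)):
        raise ValueError("bath current density requested inside the sphere")


# ---- frame conversions -------------------------------------------------


def _sph_to_cart(r, theta, phi):
    r = np.asarray(r, dtype=float)
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    st = np.sin(theta)
    return r * st * np.cos(phi), r * st * np.sin(phi), r * np.cos(theta)


def cartesian_to_spherical_coords(x, y, z):
    """(x, y, z) -> (r, theta, phi) with theta from +z, phi in (-pi, pi]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    r = np.sqrt(x**2 + y**2 + z**2)
    with np.errstate(invalid="ignore"):
        theta = np.where(r > 0, np.arccos(np.clip(np.divide(z, np.where(r > 0, r, 1.0)), -1, 1)), 0.0)
    phi = np.arctan2(y, x)
    return r, theta, phi


def to_cartesian(v: SphericalVector, theta, phi):
    """Rotate spherical components to Cartesian; the norm is preserved."""
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    st, ct = np.sin(theta), np.cos(theta)
    sp, cp = np.sin(phi), np.cos(phi)
    vx = v.v_r * st * cp + v.v_theta * ct * cp - v.v_phi * sp
    vy = v.v_r * st * sp + v.v_theta * ct * sp + v.v_phi * cp
    vz = v.v_r * ct - v.v_theta * st
    return vx, vy, vz


def from_cartesian(vx, vy, vz, theta, phi) -> SphericalVector:
    """Project Cartesian components onto the local spherical frame."""
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    st, ct = np.sin(theta), np.cos(theta)
    sp, cp = np.sin(phi), np.cos(phi)
    v_r = vx * st * cp + vy * st * sp + vz * ct
    v_t = vx * ct * cp + vy * ct * sp - vz * st
    v_p = -vx * sp + vy * cp
    return SphericalVector(v_r, v_t, v_p)


# ---- grid sampling -----------------------------------------------------


@dataclass
class CartesianVectorGrid:
    """Vector field sampled on a regular Cartesian grid.

    ``Jx/Jy/Jz`` have shape ``dims = (nx, ny, nz)``; node i,j,k sits at
    ``origin + (i dx, j dy, k dz)``.  ``mask`` labels nodes as tissue (0),
    bath (1) or excluded (2); excluded nodes (within the source exclusion
    balls or on the one-cell interface shell where the J definition
    switches) carry zero field values.
    """

    origin: tuple
    spacing: tuple
    dims: tuple
    Jx: np.ndarray
    Jy: np.ndarray
    Jz: np.ndarray
    mask: np.ndarray

    @property
    def axes(self):
        return tuple(
            self.origin[i] + self.spacing[i] * np.arange(self.dims[i]) for i in range(3)
        )

    def meshgrid(self):
        ax = self.axes
        return np.meshgrid(*ax, indexing="ij")

    def magnitude(self):
        return np.sqrt(self.Jx**2 + self.Jy**2 + self.Jz**2)

    def to_dataframe(self):
        import pandas as pd

        X, Y, Z = self.meshgrid()
        return pd.DataFrame(
            {
                "x": X.ravel(),
                "y": Y.ravel(),
                "z": Z.ravel(),
                "Jx": self.Jx.ravel(),
                "Jy": self.Jy.ravel(),
                "Jz": self.Jz.ravel(),
                "mask": self.mask.ravel(),
            }
        )


def sample_grid(
    config: ModelConfig,
    params: TissueParameters,
    sources: SourcePair,
    coeffs: CoefficientSet,
    extent: float = 3e-3,
    dims: tuple = (128, 128, 13),
    chunk: int = 65536,
) -> CartesianVectorGrid:
    """Sample the total current density on a centered Cartesian cube.

    Interior nodes (r < a) carry J_i + J_o, the plotted tissue current;
    bath nodes carry J_e.  Nodes exactly on r = a evaluate on the bath
    side; nodes within half the largest spacing of the interface, or inside
    an electrode exclusion ball, are masked and zeroed.
    """
    axes = tuple(
        np.linspace(-extent / 2.0, extent / 2.0, n) if n > 1 else np.zeros(1)
        for n in dims
    )
    spacing = tuple(ax[1] - ax[0] if len(ax) > 1 else extent for ax in axes)
    origin = tuple(ax[0] for ax in axes)
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    x, y, z = X.ravel(), Y.ravel(), Z.ravel()
    r, theta, phi = cartesian_to_spherical_coords(x, y, z)

    a = config.a
    live = [s for s, n in zip(spacing, dims) if n > 1]
    shell = 0.5 * max(live) if live else 0.0
    mask = np.where(r < a, MASK_TISSUE, MASK_BATH).astype(np.int8)
    mask[np.abs(r - a) <= shell] = MASK_EXCLUDED
    for which in ("+", "-"):
        mask[sources.distance(r, theta, phi, which) < config.exclusion_radius] = (
            MASK_EXCLUDED
        )

    Jx = np.zeros(r.shape)
    Jy = np.zeros(r.shape)
    Jz = np.zeros(r.shape)
    for sel, evaluate in (
        (mask == MASK_TISSUE, _tissue_current),
        (mask == MASK_BATH, _bath_current),
    ):
        idx = np.flatnonzero(sel)
        for start in range(0, idx.size, chunk):
            sl = idx[start : start + chunk]
            v = evaluate(r[sl], theta[sl], phi[sl], coeffs, sources, params)
            vx, vy, vz = to_cartesian(v, theta[sl], phi[sl])
            Jx[sl], Jy[sl], Jz[sl] = vx, vy, vz

    return CartesianVectorGrid(
        origin=origin,
        spacing=spacing,
        dims=dims,
        Jx=Jx.reshape(dims),
        Jy=Jy.reshape(dims),
        Jz=Jz.reshape(dims),
        mask=mask.reshape(dims),
    )


def _tissue_current(r, theta, phi, coeffs, sources, params):
    return current_density_i(r, theta, phi, coeffs, params) + current_density_o(
        r, theta, phi, coeffs, params
    )


def _bath_current(r, theta, phi, coeffs, sources, params):
    return current_density_e(r, theta, phi, coeffs, sources, params)
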