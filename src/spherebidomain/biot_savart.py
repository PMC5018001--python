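"""Magnetic flux density from a sampled current density grid.

The Biot-Savart volume integral over the sampled cube is discretized as a
Riemann sum, which is a discrete linear convolution of the current
components with the kernel G = x_i / |x|^3.  ``bz_fft`` evaluates it with
zero-padded FFTs (linear, not circular, convolution); ``bz_direct`` is the
same sum evaluated naively and serves as the oracle.  Only the sampled
volume contributes: currents flowing outside the cube are not integrated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft

from .current_fields import CartesianVectorGrid

__all__ = ["MU_0", "BiotSavartKernel", "BFieldGrid", "build_kernel", "bz_fft", "b_field_fft", "bz_direct", "b_direct"]

MU_0 = 4.0e-7 * np.pi  # T m / A


@dataclass(frozen=True)
class BiotSavartKernel:
    """Kernel samples G_i = x_i/|x|^3 on the lattice of relative displacements.

    Arrays have shape (2 nx - 1, 2 ny - 1, 2 nz - 1), centered on the zero
    displacement, whose (singular) voxel is set to 0: the kernels are odd,
    so the principal value of the self-term vanishes.
    """

    Gx: np.ndarray
    Gy: np.ndarray
    Gz: np.ndarray
    spacing: tuple


@dataclass
class BFieldGrid:
    """Magnetic flux density (tesla) on the same lattice as the current grid."""

    origin: tuple
    spacing: tuple
    dims: tuple
    Bz: np.ndarray
    Bx: np.ndarray | None = None
    By: np.ndarray | None = None


def build_kernel(dims: tuple, spacing: tuple) -> BiotSavartKernel:
    """Sample the Biot-Savart kernels on the padded displacement lattice."""
    if any(s <= 0 for s in spacing):
        raise ValueError("grid spacings must be positive")
    axes = [s * np.arange(-(n - 1), n) for n, s in zip(dims, spacing)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    R3 = (X**2 + Y**2 + Z**2) ** 1.5
    center = tuple(n - 1 for n in dims)
    R3[center] = 1.0  # divisor placeholder; kernels zeroed there below
    Gx, Gy, Gz = X / R3, Y / R3, Z / R3
    for G in (Gx, Gy, Gz):
        G[center] = 0.0
    return BiotSavartKernel(Gx=Gx, Gy=Gy, Gz=Gz, spacing=tuple(spacing))


def _linear_convolve(field: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """(field * kernel)(r_i) = sum_j field(r_j) kernel(r_i - r_j), via FFT.

    The kernel is sampled on the full displacement lattice (2n-1 per axis),
    so padding the transforms to the full linear-convolution length removes
    circular wrap-around entirely; the output window aligned with the field
    lattice is returned.
    """
    dims = field.shape
    full = [d + k - 1 for d, k in zip(dims, kernel.shape)]
    fast = [sp_fft.next_fast_len(n) for n in full]
    F = sp_fft.rfftn(field, fast)
    G = sp_fft.rfftn(kernel, fast)
    conv = sp_fft.irfftn(F * G, fast)
    start = tuple(n - 1 for n in dims)  # kernel center offset
    window = tuple(slice(s, s + d) for s, d in zip(start, dims))
    return conv[window]


def bz_fft(grid: CartesianVectorGrid, kernel: BiotSavartKernel | None = None) -> BFieldGrid:
    """B_z = mu0/(4 pi) [ (Jx * Gy) - (Jy * Gx) ] dV via zero-padded FFTs."""
    _check_finite(grid)
    if kernel is None:
        kernel = build_kernel(grid.dims, grid.spacing)
    dV = float(np.prod(grid.spacing))
    bz = (
        MU_0
        / (4.0 * np.pi)
        * dV
        * (_linear_convolve(grid.Jx, kernel.Gy) - _linear_convolve(grid.Jy, kernel.Gx))
    )
    return BFieldGrid(origin=grid.origin, spacing=grid.spacing, dims=grid.dims, Bz=bz)


def b_field_fft(grid: CartesianVectorGrid) -> BFieldGrid:
    """All three components of B through the same convolution machinery."""
    _check_finite(grid)
    kernel = build_kernel(grid.dims, grid.spacing)
    dV = float(np.prod(grid.spacing))
    pref = MU_0 / (4.0 * np.pi) * dV
    bx = pref * (_linear_convolve(grid.Jy, kernel.Gz) - _linear_convolve(grid.Jz, kernel.Gy))
    by = pref * (_linear_convolve(grid.Jz, kernel.Gx) - _linear_convolve(grid.Jx, kernel.Gz))
    bz = pref * (_linear_convolve(grid.Jx, kernel.Gy) - _linear_convolve(grid.Jy, kernel.Gx))
    return BFieldGrid(
        origin=grid.origin, spacing=grid.spacing, dims=grid.dims, Bz=bz, Bx=bx, By=by
    )


def bz_direct(grid: CartesianVectorGrid, eval_indices=None) -> np.ndarray:
    """Direct Riemann-sum B_z at selected grid nodes (oracle; O(N^2) cost).

    ``eval_indices`` is an (M, 3) integer array of node indices (all nodes
    when omitted -- only sensible for small grids).  The self-voxel is
    skipped, matching the principal-value regularization of the kernel.
    """
    return _direct(grid, eval_indices, component="z")


def b_direct(grid: CartesianVectorGrid, eval_indices=None) -> dict:
    """Direct-quadrature Bx, By, Bz at selected nodes (solenoidality checks)."""
    return {c: _direct(grid, eval_indices, component=c) for c in ("x", "y", "z")}


def _direct(grid: CartesianVectorGrid, eval_indices, component: str) -> np.ndarray:
    _check_finite(grid)
    X, Y, Z = grid.meshgrid()
    xs, ys, zs = X.ravel(), Y.ravel(), Z.ravel()
    jx, jy, jz = grid.Jx.ravel(), grid.Jy.ravel(), grid.Jz.ravel()
    dV = float(np.prod(grid.spacing))
    if eval_indices is None:
        pts = np.stack([xs, ys, zs], axis=1)
    else:
        eval_indices = np.asarray(eval_indices)
        flat = np.ravel_multi_index(eval_indices.T, grid.dims)
        pts = np.stack([xs[flat], ys[flat], zs[flat]], axis=1)
    out = np.empty(len(pts))
    for k, (px, py, pz) in enumerate(pts):
        dx, dy, dz = px - xs, py - ys, pz - zs
        r2 = dx**2 + dy**2 + dz**2
        with np.errstate(divide="ignore", invalid="ignore"):
            inv_r3 = np.where(r2 > 0.0, r2**-1.5, 0.0)
        if component == "z":
            num = jx * dy - jy * dx
        elif component == "x":
            num = jy * dz - jz * dy
        else:
            num = jz * dx - jx * dz
        out[k] = MU_0 / (4.0 * np.pi) * dV * np.sum(num * inv_r3)
    return out


def _check_finite(grid: CartesianVectorGrid) -> None:
    for name in ("Jx", "Jy", "Jz"):
        if not np.all(np.isfinite(getattr(grid, name))):
            raise ValueError(f"non-finite values in current grid component {name}")
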