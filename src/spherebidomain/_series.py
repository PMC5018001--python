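"""Evaluation engine for truncated spherical-harmonic series.

A field is represented as

    f(r, theta, phi) = sum_mu R_mu(r) sum_nu K[mu, nu] Y_mu^nu(theta, phi)

with one of three radial families: ``i_mu(r/lam)`` (Helmholtz, regular at
the origin), ``r^mu`` (Laplace, interior) or ``r^(-mu-1)`` (Laplace,
exterior).  Coefficients are stored for nu >= 0 only; negative orders are
implied by the conjugate symmetry ``K[mu,-nu] = (-1)^nu conj(K[mu,nu])`` of
real-valued fields, so the assembled value is the nu = 0 term plus twice
the real part of the nu > 0 terms.

Gradients are term-wise analytic.  The polar-angle derivative uses the
identity  dY/dtheta = nu cot(theta) Y_mu^nu + tau e^{-i phi} Y_mu^{nu+1}
with tau = sqrt((mu-nu)(mu+nu+1)); at theta in {0, pi} the cot/csc
singularities cancel and only the nu = +-1 terms survive, which is coded
as an explicit limit rather than an epsilon offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import sph_harm_y_all, spherical_in

_POLE_TOL = 1e-9


@dataclass(frozen=True)
class HarmonicSeries:
    """Truncated series with coefficients for non-negative orders.

    ``coeffs[mu, nu]`` (complex, shape (mu_max+1, mu_max+1), entries with
    nu > mu ignored) and a radial family: kind in {"bessel", "power",
    "inv_power"}, with ``scale`` the length constant for the Bessel family.
    """

    coeffs: np.ndarray
    kind: str
    scale: float = 1.0

    @property
    def mu_max(self) -> int:
        return self.coeffs.shape[0] - 1

    # ---- radial factors ------------------------------------------------
    def _radial(self, r: np.ndarray) -> np.ndarray:
        mu = np.arange(self.mu_max + 1)[:, None]
        if self.kind == "bessel":
            return spherical_in(mu, r[None, :] / self.scale)
        if self.kind == "power":
            return r[None, :] ** mu
        if self.kind == "inv_power":
            return r[None, :] ** (-mu - 1)
        raise ValueError(f"unknown radial family {self.kind!r}")

    def _radial_derivative(self, r: np.ndarray) -> np.ndarray:
        mu = np.arange(self.mu_max + 1)[:, None]
        if self.kind == "bessel":
            x = r[None, :] / self.scale
            i_mu = spherical_in(mu, x)
            i_mu1 = spherical_in(mu + 1, x)
            with np.errstate(divide="ignore", invalid="ignore"):
                term = np.where(mu == 0, 0.0, mu * i_mu / r[None, :])
            # r -> 0 limit: only mu = 1 has a finite nonzero (mu/r) i_mu term
            if np.any(r == 0.0):
                zero = r == 0.0
                term[:, zero] = 0.0
                if self.mu_max >= 1:
                    term[1, zero] = 1.0 / (3.0 * self.scale)
            return term + i_mu1 / self.scale
        if self.kind == "power":
            with np.errstate(divide="ignore", invalid="ignore"):
                out = mu * r[None, :] ** (mu - 1)
            out[0] = 0.0
            return out
        if self.kind == "inv_power":
            return -(mu + 1) * r[None, :] ** (-mu - 2)
        raise ValueError(f"unknown radial family {self.kind!r}")

    # ---- angular assembly ----------------------------------------------
    def _tables(self, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
        return sph_harm_y_all(self.mu_max, self.mu_max, theta, phi)

    def values(self, r, theta, phi):
        """Real field values at arrays of spherical points."""
        r, theta, phi, shape = _ravel(r, theta, phi)
        Y = self._tables(theta, phi)
        R = self._radial(r)
        out = np.zeros(r.shape)
        for mu in range(self.mu_max + 1):
            ang = (self.coeffs[mu, 0] * Y[mu, 0]).real
            for nu in range(1, mu + 1):
                ang = ang + 2.0 * (self.coeffs[mu, nu] * Y[mu, nu]).real
            out += R[mu] * ang
        return out.reshape(shape) if shape else float(out[0])

    def gradient(self, r, theta, phi):
        """(+grad f) in the local spherical orthonormal frame, real components."""
        r, theta, phi, shape = _ravel(r, theta, phi)
        Y = self._tables(theta, phi)
        R = self._radial(r)
        Rp = self._radial_derivative(r)

        at_pole = np.minimum(theta, np.pi - theta) < _POLE_TOL
        sin_t = np.where(at_pole, 1.0, np.sin(theta))
        cot_t = np.cos(theta) / sin_t

        g_r = np.zeros(r.shape)
        g_t = np.zeros(r.shape)
        g_p = np.zeros(r.shape)
        for mu in range(self.mu_max + 1):
            ang = (self.coeffs[mu, 0] * Y[mu, 0]).real
            d_ang = np.zeros(r.shape)
            p_ang = np.zeros(r.shape)
            for nu in range(mu + 1):
                K = self.coeffs[mu, nu]
                if K == 0.0:
                    continue
                w = 1.0 if nu == 0 else 2.0
                if nu:
                    ang = ang + w * (K * Y[mu, nu]).real
                dY = nu * cot_t * Y[mu, nu]
                if nu < mu:
                    tau = np.sqrt((mu - nu) * (mu + nu + 1))
                    dY = dY + tau * np.exp(-1j * phi) * Y[mu, nu + 1]
                d_ang = d_ang + w * (K * dY).real
                if nu:
                    p_ang = p_ang - w * nu * (K * Y[mu, nu]).imag
            g_r += Rp[mu] * ang
            g_t += R[mu] * d_ang
            g_p += R[mu] * p_ang
        with np.errstate(divide="ignore", invalid="ignore"):
            g_t = g_t / r
            g_p = g_p / (r * sin_t)

        if np.any(at_pole):
            self._polar_limit(r, theta, phi, at_pole, R, g_t, g_p)
        return tuple(
            g.reshape(shape) if shape else float(g[0]) for g in (g_r, g_t, g_p)
        )

    def _polar_limit(self, r, theta, phi, mask, R, g_t, g_p) -> None:
        """Overwrite angular gradient components at theta in {0, pi}.

        Only the nu = +-1 coefficient pair contributes; with
        E_mu = sqrt((2mu+1) mu (mu+1) / (16 pi)) and z = K[mu,1] e^{i phi},
        the north-pole limits are  (1/r)(-2 E_mu Re z)  for the theta
        component and  (1/r)(2 E_mu Im z)  for the phi component; at the
        south pole they pick up parities (-1)^mu and (-1)^(mu+1).
        """
        south = theta[mask] > np.pi / 2
        gt = np.zeros(mask.sum())
        gp = np.zeros(mask.sum())
        if self.mu_max >= 1:
            e_iphi = np.exp(1j * phi[mask])
            for mu in range(1, self.mu_max + 1):
                K = self.coeffs[mu, 1]
                if K == 0.0:
                    continue
                E = np.sqrt((2 * mu + 1) * mu * (mu + 1) / (16.0 * np.pi))
                z = K * e_iphi
                par_t = np.where(south, (-1.0) ** mu, 1.0)
                par_p = np.where(south, (-1.0) ** (mu + 1), 1.0)
                gt += R[mu, mask] * par_t * (-2.0 * E * z.real)
                gp += R[mu, mask] * par_p * (2.0 * E * z.imag)
        g_t[mask] = gt / r[mask]
        g_p[mask] = gp / r[mask]


def _ravel(r, theta, phi):
    scalar = all(np.ndim(x) == 0 for x in (r, theta, phi))
    r = np.atleast_1d(np.asarray(r, dtype=float))
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    r, theta, phi = np.broadcast_arrays(r, theta, phi)
    shape = None if scalar else r.shape
    return r.ravel().copy(), theta.ravel().copy(), phi.ravel().copy(), shape
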