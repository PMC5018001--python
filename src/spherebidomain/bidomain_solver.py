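"""Boundary-condition coefficients and scalar potentials of the model.

The tissue sphere (radius ``a``) is a passive isotropic bidomain; the
transmembrane potential V_m obeys a scalar Helmholtz equation with length
constant lambda, the monodomain potential psi (resistivity-weighted average
of the intra- and extracellular potentials) obeys Laplace's equation, and
the bath carries the two free monopole fields of the electrode pair plus a
harmonic secondary field.  Truncated series:

    V_m      = sum a_{mu nu} i_mu(r/lam) Y_mu^nu        (r <= a)
    psi      = sum b_{mu nu} r^mu        Y_mu^nu        (r <= a)
    phi_bath = sum c_{mu nu} r^(-mu-1)   Y_mu^nu        (r >= a)
    phi_e    = phi_bath + phi_source + phi_sink

with phi_i = rho_i/(rho_i+rho_o) V_m + psi and
phi_o = -rho_o/(rho_i+rho_o) V_m + psi.

The coefficients follow from three interface conditions at r = a:
continuity of potential (phi_e = phi_o), continuity of normal current
between bath and interstitium, and zero intracellular normal current.
Solving them mode-by-mode against the interior expansion of the monopole
fields gives the closed forms implemented below (`aux_p`, `aux_q`,
`coefficients`); a direct per-mode linear solve is kept in the test suite
as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._series import HarmonicSeries
from .harmonics import (
    greens_radial_derivative,
    greens_radial_value,
    mod_sph_bessel_i,
    tesseral_harmonic,
)
from .parameters import ModelConfig, SourcePair, TissueParameters

__all__ = [
    "CoefficientSet",
    "length_constant",
    "aux_p",
    "aux_q",
    "source_mode_coefficient",
    "coefficients",
    "transmembrane_potential",
    "monodomain_potential",
    "bath_secondary_potential",
    "source_sink_potential",
    "source_sink_radial_derivative",
    "domain_potentials",
    "external_potential",
    "vm_series",
    "psi_series",
    "bath_series",
    "check_exclusion",
]


def length_constant(params: TissueParameters) -> float:
    """Membrane length constant lambda = sqrt((R_m/beta)/(rho_i+rho_o)), m."""
    return params.length_constant


@dataclass(frozen=True)
class CoefficientSet:
    """Expansion coefficients for non-negative orders, plus model metadata.

    Arrays are complex with shape (mu_max+1, mu_max+1); ``X[mu, nu]`` is
    meaningful for 0 <= nu <= mu.  Negative orders follow from
    ``X[mu, -nu] = (-1)^nu conj(X[mu, nu])`` (real fields).  ``a_mu_nu``
    scales the dimensionless i_mu(r/lam) terms (volts), ``b_mu_nu`` scales
    r^mu (V m^-mu), ``c_mu_nu`` scales r^(-mu-1) (V m^(mu+1)).
    """

    a_mu_nu: np.ndarray
    b_mu_nu: np.ndarray
    c_mu_nu: np.ndarray
    mu_max: int
    tissue_radius: float
    lam: float

    def order(self, X: np.ndarray, mu: int, nu: int) -> complex:
        """Coefficient at (mu, nu) including negative orders."""
        if nu >= 0:
            return complex(X[mu, nu])
        return (-1) ** nu * np.conj(X[mu, -nu])


def aux_p(mu: int, nu: int, sources: SourcePair) -> complex:
    """Angular source weight of mode (mu, nu).

    p = (2 mu + 1) [ Y_mu^{-nu}(th-, ph-) r_+^{mu+1} - Y_mu^{-nu}(th+, ph+) r_-^{mu+1} ].

    Vanishes identically when the source and sink coincide.
    """
    pp, pm = sources.p_plus, sources.p_minus
    return (2 * mu + 1) * (
        tesseral_harmonic(mu, -nu, pm.theta, pm.phi) * pp.r ** (mu + 1)
        - tesseral_harmonic(mu, -nu, pp.theta, pp.phi) * pm.r ** (mu + 1)
    )


def aux_q(mu: int, params: TissueParameters, a: float) -> float:
    """Per-degree denominator of the interface solve.

    q = lam mu (rho_i+rho_o)(mu rho_e + (mu+1) rho_o) i_mu(a/lam)
        + a i_{mu+1}(a/lam) (mu rho_e (rho_i+rho_o) + (mu+1) rho_i rho_o).

    Strictly positive for physical (positive) parameters and mu >= 0, so the
    mode solve is never singular; a zero is still guarded against.
    """
    lam = params.length_constant
    x = a / lam
    ri, ro, re = params.rho_i, params.rho_o, params.rho_e
    q = lam * mu * (ri + ro) * (mu * re + (mu + 1) * ro) * mod_sph_bessel_i(mu, x) + (
        a
        * mod_sph_bessel_i(mu + 1, x)
        * (mu * re * (ri + ro) + (mu + 1) * ri * ro)
    )
    if q == 0.0:
        raise ZeroDivisionError(
            f"singular interface configuration at mu={mu}: q=0 for {params}"
        )
    return float(q)


def source_mode_coefficient(
    mu: int, nu: int, sources: SourcePair, rho_e: float
) -> complex:
    """Interior-expansion coefficient d_{mu nu} of phi_source + phi_sink.

    For field radii below both electrode radii,
    phi_src+snk = sum d_{mu nu} r^mu Y_mu^nu with

        d = I_0 rho_e (-1)^nu / (2 mu + 1)
            * [ Y_mu^{-nu}(p+) / r_+^{mu+1} - Y_mu^{-nu}(p-) / r_-^{mu+1} ].
    """
    pp, pm = sources.p_plus, sources.p_minus
    return (
        sources.I_0
        * rho_e
        * (-1) ** nu
        / (2 * mu + 1)
        * (
            tesseral_harmonic(mu, -nu, pp.theta, pp.phi) / pp.r ** (mu + 1)
            - tesseral_harmonic(mu, -nu, pm.theta, pm.phi) / pm.r ** (mu + 1)
        )
    )


def coefficients(
    config: ModelConfig, params: TissueParameters, sources: SourcePair
) -> CoefficientSet:
    """Solve the three interface conditions for all modes up to mu_max.

    Closed forms (per mode, with x = a/lam, i = i_mu(x), i' = di_mu/dx(x),
    d the interior source coefficient):

        a_{mu nu} = I_0 (-1)^nu lam mu rho_e rho_o (rho_i+rho_o) a^mu
                    (r_+ r_-)^(-mu-1) p / ((2 mu + 1) q)
        b_{mu nu} = -rho_i a i'(x) a_{mu nu} / ((rho_i+rho_o) lam mu a^mu)
        c_{mu nu} = -rho_o/(rho_i+rho_o) a_{mu nu} i a^(mu+1)
                    + (b_{mu nu} - d_{mu nu}) a^(2 mu + 1)

    with a i'(x) = lam mu i_mu(x) + a i_{mu+1}(x).  Degree 0 carries no
    membrane or secondary response (a_0 = c_0 = 0, b_0 = d_0).
    """
    sources.validate_outside(config.a)
    L = config.mu_max
    a = config.a
    lam = params.length_constant
    ri, ro, re = params.rho_i, params.rho_o, params.rho_e
    x = a / lam

    A = np.zeros((L + 1, L + 1), dtype=complex)
    B = np.zeros((L + 1, L + 1), dtype=complex)
    C = np.zeros((L + 1, L + 1), dtype=complex)

    B[0, 0] = source_mode_coefficient(0, 0, sources, re)
    rp, rm = sources.p_plus.r, sources.p_minus.r
    for mu in range(1, L + 1):
        i_mu = mod_sph_bessel_i(mu, x)
        i_mu1 = mod_sph_bessel_i(mu + 1, x)
        a_iprime = lam * mu * i_mu + a * i_mu1
        q = aux_q(mu, params, a)
        pref = (
            sources.I_0
            * lam
            * mu
            * re
            * ro
            * (ri + ro)
            * a**mu
            * (rp * rm) ** (-mu - 1)
            / ((2 * mu + 1) * q)
        )
        for nu in range(mu + 1):
            p = aux_p(mu, nu, sources)
            A[mu, nu] = (-1) ** nu * pref * p
            B[mu, nu] = -ri * a_iprime * A[mu, nu] / ((ri + ro) * lam * mu * a**mu)
            d = source_mode_coefficient(mu, nu, sources, re)
            C[mu, nu] = (
                -ro / (ri + ro) * A[mu, nu] * i_mu * a ** (mu + 1)
                + (B[mu, nu] - d) * a ** (2 * mu + 1)
            )
    return CoefficientSet(
        a_mu_nu=A, b_mu_nu=B, c_mu_nu=C, mu_max=L, tissue_radius=a, lam=lam
    )


# ---- series views ------------------------------------------------------


def vm_series(coeffs: CoefficientSet) -> HarmonicSeries:
    return HarmonicSeries(coeffs.a_mu_nu, "bessel", coeffs.lam)


def psi_series(coeffs: CoefficientSet) -> HarmonicSeries:
    return HarmonicSeries(coeffs.b_mu_nu, "power")


def bath_series(coeffs: CoefficientSet) -> HarmonicSeries:
    return HarmonicSeries(coeffs.c_mu_nu, "inv_power")


def _check_interior(r, a: float) -> None:
    if np.any(np.asarray(r) > a * (1 + 1e-12)):
        raise ValueError(f"field point outside the tissue sphere (r > a = {a})")


def _check_exterior(r, a: float) -> None:
    if np.any(np.asarray(r) < a * (1 - 1e-12)):
        raise ValueError(f"field point inside the tissue sphere (r < a = {a})")


def check_exclusion(r, theta, phi, sources: SourcePair, exclusion_radius: float):
    """Raise if any field point is within the exclusion ball of an electrode."""
    for which, p in (("source", "+"), ("sink", "-")):
        d = sources.distance(r, theta, phi, p)
        if np.any(d < exclusion_radius):
            raise ValueError(
                f"field point within {exclusion_radius} m of the current {which}"
            )


# ---- potentials --------------------------------------------------------


def transmembrane_potential(r, theta, phi, coeffs: CoefficientSet):
    """V_m = phi_i - phi_o on the tissue (r <= a), volts."""
    _check_interior(r, coeffs.tissue_radius)
    return vm_series(coeffs).values(r, theta, phi)


def monodomain_potential(r, theta, phi, coeffs: CoefficientSet):
    """Monodomain potential psi on the tissue (r <= a), volts."""
    _check_interior(r, coeffs.tissue_radius)
    return psi_series(coeffs).values(r, theta, phi)


def bath_secondary_potential(r, theta, phi, coeffs: CoefficientSet):
    """Secondary (boundary-reaction) bath potential on r >= a, volts."""
    _check_exterior(r, coeffs.tissue_radius)
    return bath_series(coeffs).values(r, theta, phi)


def source_sink_potential(
    r,
    theta,
    phi,
    sources: SourcePair,
    params: TissueParameters,
    mode: str = "closed_form",
    mu_max: int | None = None,
    exclusion_radius: float = 0.0,
):
    """Free-medium potential of the electrode pair, volts.

    ``closed_form`` evaluates I_0 rho_e / (4 pi R_source) minus the sink
    analogue with distances from the spherical law of cosines.  ``series``
    evaluates the same field through the separable 1/R expansion truncated
    at ``mu_max`` (interior and exterior branches via min/max radii); the
    two agree to the truncation tail away from the electrode radii.
    """
    if exclusion_radius > 0.0:
        check_exclusion(r, theta, phi, sources, exclusion_radius)
    scalar = all(np.ndim(x) == 0 for x in (r, theta, phi))
    pref = sources.I_0 * params.rho_e / (4.0 * np.pi)
    if mode == "closed_form":
        with np.errstate(divide="ignore"):
            out = pref / sources.distance(r, theta, phi, "+") - pref / sources.distance(
                r, theta, phi, "-"
            )
        return float(out) if scalar else out
    if mode != "series":
        raise ValueError(f"unknown mode {mode!r}")
    if mu_max is None:
        raise ValueError("series mode requires mu_max")
    r_arr = np.atleast_1d(np.asarray(r, dtype=float))
    out = np.zeros(np.broadcast(r_arr, np.asarray(theta), np.asarray(phi)).shape)
    pp, pm = sources.p_plus, sources.p_minus
    for mu in range(mu_max + 1):
        rad_p = greens_radial_value(mu, r, pp.r)
        rad_m = greens_radial_value(mu, r, pm.r)
        for nu in range(mu + 1):
            w = 1.0 if nu == 0 else 2.0
            term = rad_p * tesseral_harmonic(mu, -nu, pp.theta, pp.phi) - (
                rad_m * tesseral_harmonic(mu, -nu, pm.theta, pm.phi)
            )
            ang = tesseral_harmonic(mu, nu, theta, phi)
            out = out + w * (4.0 * np.pi * pref) / (2 * mu + 1) * (
                (-1) ** nu * term * ang
            ).real
    return float(np.ravel(out)[0]) if scalar else out


def source_sink_radial_derivative(
    r, theta, phi, sources: SourcePair, params: TissueParameters, mu_max: int
):
    """d/dr of the series-mode phi_source + phi_sink (V/m).

    Differentiates the truncated 1/R expansion term by term through the
    branchwise radial Green's factor; not defined exactly at the electrode
    radii.  Used by the boundary-residual checks, where the electrode
    monopoles must be represented at the same truncation as the solved
    coefficients.
    """
    scalar = all(np.ndim(x) == 0 for x in (r, theta, phi))
    pref = sources.I_0 * params.rho_e
    out = 0.0
    pp, pm = sources.p_plus, sources.p_minus
    for mu in range(mu_max + 1):
        dr_p = greens_radial_derivative(mu, r, pp.r)
        dr_m = greens_radial_derivative(mu, r, pm.r)
        for nu in range(mu + 1):
            w = 1.0 if nu == 0 else 2.0
            term = dr_p * tesseral_harmonic(mu, -nu, pp.theta, pp.phi) - (
                dr_m * tesseral_harmonic(mu, -nu, pm.theta, pm.phi)
            )
            ang = tesseral_harmonic(mu, nu, theta, phi)
            out = out + w * pref / (2 * mu + 1) * ((-1) ** nu * term * ang).real
    return float(out) if scalar else out


def domain_potentials(r, theta, phi, coeffs: CoefficientSet, params: TissueParameters):
    """(phi_i, phi_o) on the tissue, volts."""
    _check_interior(r, coeffs.tissue_radius)
    vm = vm_series(coeffs).values(r, theta, phi)
    psi = psi_series(coeffs).values(r, theta, phi)
    ri, ro = params.rho_i, params.rho_o
    return ri / (ri + ro) * vm + psi, -ro / (ri + ro) * vm + psi


def external_potential(
    r,
    theta,
    phi,
    coeffs: CoefficientSet,
    sources: SourcePair,
    params: TissueParameters,
    mode: str = "closed_form",
    exclusion_radius: float = 0.0,
):
    """phi_e = phi_bath + phi_source + phi_sink on r >= a, volts.

    With ``mode="series"`` the monopole pair is expanded to the same
    truncation as the solved coefficients, which is the representation in
    which the truncated solution satisfies the interface conditions
    exactly.
    """
    _check_exterior(r, coeffs.tissue_radius)
    return bath_series(coeffs).values(r, theta, phi) + source_sink_potential(
        r,
        theta,
        phi,
        sources,
        params,
        mode=mode,
        mu_max=coeffs.mu_max,
        exclusion_radius=exclusion_radius,
    )
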