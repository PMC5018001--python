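"""Scenario layer: canonical configurations, validation and study runners.

The canonical scenarios vary the interstitial resistivity against the bath
(ratio rho_e/rho_o in {1, 0.1, 10}) and include the axisymmetric limiting
case with the source moved onto the polar axis.  ``run_scenario`` produces
the potential, current-density and B_z grids together with a validation
report; ``convergence_study`` tracks the stabilization of the potentials
with the series truncation; ``line_profile`` tabulates all potentials
along a diameter for boundary-condition inspection.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import bidomain_solver as solver
from . import biot_savart, current_fields
from .current_fields import MASK_EXCLUDED
from .parameters import (
    ModelConfig,
    SourcePair,
    SphericalPoint,
    TissueParameters,
    default_config,
    default_parameters,
    default_sources,
)

__all__ = [
    "SCENARIO_TAGS",
    "ScenarioConfig",
    "ValidationEntry",
    "ValidationReport",
    "scenario",
    "convergence_probes",
    "interior_probes",
    "boundary_residuals",
    "helmholtz_residual",
    "laplace_residuals",
    "planar_symmetry",
    "azimuthal_variation",
    "source_flux",
    "convergence_study",
    "line_profile",
    "run_scenario",
]

SCENARIO_TAGS = ("rho_ratio_1", "rho_ratio_0.1", "rho_ratio_10", "axisymmetric", "custom")


@dataclass(frozen=True)
class ScenarioConfig:
    """A named, fully specified model configuration plus grid/output choices."""

    tag: str
    config: ModelConfig
    params: TissueParameters
    sources: SourcePair
    extent: float = 3e-3
    dims: tuple = (128, 128, 13)
    outdir: str | None = None


def scenario(tag: str = "rho_ratio_1", mu_max: int = 10, **overrides) -> ScenarioConfig:
    """Build a canonical scenario.

    ``rho_ratio_X`` fixes rho_e/rho_o = X with all other defaults;
    ``axisymmetric`` instead places the electrode pair antipodally on the
    polar axis (source above, sink below the sphere), which removes all
    azimuthal dependence.  ``custom`` starts from the defaults and applies
    overrides (config/params/sources/extent/dims keyword replacements).
    """
    if tag not in SCENARIO_TAGS:
        raise ValueError(f"unknown scenario tag {tag!r}; choose from {SCENARIO_TAGS}")
    params = default_parameters()
    sources = default_sources()
    if tag == "rho_ratio_0.1":
        params = params.with_rho_o(params.rho_e / 0.1)
    elif tag == "rho_ratio_10":
        params = params.with_rho_o(params.rho_e / 10.0)
    elif tag == "axisymmetric":
        sources = SourcePair(
            p_plus=SphericalPoint(5e-3, 0.0, 0.0),
            p_minus=SphericalPoint(5e-3, math.pi, 0.0),
            I_0=sources.I_0,
        )
    cfg = ScenarioConfig(
        tag=tag, config=default_config(mu_max), params=params, sources=sources
    )
    return replace(cfg, **overrides) if overrides else cfg


# ---- deterministic probe sets -----------------------------------------


def _fibonacci_directions(n: int, offset: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """n quasi-uniform directions (theta, phi) on the sphere (golden spiral)."""
    k = np.arange(n) + offset
    z = 1.0 - 2.0 * ((k % max(n, 1)) + 0.5) / n
    theta = np.arccos(np.clip(z, -1.0, 1.0))
    golden = math.pi * (3.0 - math.sqrt(5.0))
    phi = np.mod(k * golden, 2.0 * math.pi)
    return theta, phi


def convergence_probes(a: float) -> pd.DataFrame:
    """50 fixed probe points: 25 interior, 10 on the boundary, 15 near bath.

    Deterministic (golden-spiral directions, stratified radii); the bath
    probes stay well inside the electrode radius of the default geometry.
    """
    rows = []
    th, ph = _fibonacci_directions(25)
    for i, r in enumerate(np.linspace(0.1, 0.9, 25) * a):
        rows.append((r, th[i], ph[i], "tissue"))
    th, ph = _fibonacci_directions(10, offset=3)
    for i in range(10):
        rows.append((a, th[i], ph[i], "boundary"))
    th, ph = _fibonacci_directions(15, offset=7)
    for i, r in enumerate(np.linspace(1.1, 1.6, 15) * a):
        rows.append((r, th[i], ph[i], "bath"))
    return pd.DataFrame(rows, columns=["r", "theta", "phi", "region"])


def interior_probes(a: float, n: int = 50, r_max: float = 0.9) -> pd.DataFrame:
    """n fixed tissue-interior points with r <= r_max * a (for stencil checks)."""
    th, ph = _fibonacci_directions(n)
    r = np.linspace(0.05, r_max, n) * a
    return pd.DataFrame({"r": r, "theta": th, "phi": ph})


# ---- validation pieces -------------------------------------------------


@dataclass
class ValidationEntry:
    name: str
    value: float
    tolerance: float | None = None

    @property
    def passed(self) -> bool | None:
        if self.tolerance is None:
            return None
        return bool(self.value <= self.tolerance)


@dataclass
class ValidationReport:
    entries: list = field(default_factory=list)
    tables: dict = field(default_factory=dict)

    def add(self, name, value, tolerance=None):
        self.entries.append(ValidationEntry(name, float(value), tolerance))

    @property
    def all_passed(self) -> bool:
        return all(e.passed for e in self.entries if e.passed is not None)

    def to_dict(self) -> dict:
        return {
            "entries": [
                {
                    "name": e.name,
                    "value": e.value,
                    "tolerance": e.tolerance,
                    "passed": e.passed,
                }
                for e in self.entries
            ],
            "tables": {k: v.to_dict(orient="list") for k, v in self.tables.items()},
        }

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def boundary_residuals(
    config: ModelConfig,
    params: TissueParameters,
    sources: SourcePair,
    coeffs=None,
    n_theta: int = 64,
    n_phi: int = 128,
) -> dict:
    """Relative residuals of the three interface conditions at r = a.

    The electrode monopoles are represented at the solution's truncation
    (series mode), the representation in which the truncated solution
    satisfies the interface conditions exactly; residuals are then pure
    floating-point noise.  Returns relative potential-continuity and
    normal-current-continuity residuals plus the intracellular normal
    current relative to the bath current scale.
    """
    if coeffs is None:
        coeffs = solver.coefficients(config, params, sources)
    a = config.a
    theta, phi = _angular_grid(n_theta, n_phi)
    ri, ro, re = params.rho_i, params.rho_o, params.rho_e

    phi_i, phi_o = solver.domain_potentials(a, theta, phi, coeffs, params)
    phi_e = solver.external_potential(
        a, theta, phi, coeffs, sources, params, mode="series"
    )
    res_potential = np.max(np.abs(phi_e - phi_o)) / max(np.max(np.abs(phi_e)), 1e-300)

    dr_bath = solver.bath_series(coeffs).gradient(np.full_like(theta, a), theta, phi)[0]
    dr_src = solver.source_sink_radial_derivative(
        np.full_like(theta, a), theta, phi, sources, params, coeffs.mu_max
    )
    dr_phi_e = dr_bath + dr_src
    vm_grad_r = solver.vm_series(coeffs).gradient(np.full_like(theta, a), theta, phi)[0]
    psi_grad_r = solver.psi_series(coeffs).gradient(np.full_like(theta, a), theta, phi)[0]
    dr_phi_o = -ro / (ri + ro) * vm_grad_r + psi_grad_r
    dr_phi_i = ri / (ri + ro) * vm_grad_r + psi_grad_r

    bath_current = dr_phi_e / re
    res_normal = np.max(np.abs(bath_current - dr_phi_o / ro)) / max(
        np.max(np.abs(bath_current)), 1e-300
    )
    j_e = current_fields.current_density_e(
        np.full_like(theta, a), theta, phi, coeffs, sources, params
    )
    res_intra = np.max(np.abs(dr_phi_i / ri)) / max(np.max(j_e.magnitude), 1e-300)
    return {
        "potential_continuity": float(res_potential),
        "normal_current_continuity": float(res_normal),
        "intracellular_normal_current": float(res_intra),
    }


def _angular_grid(n_theta: int, n_phi: int):
    theta = np.linspace(0.0, math.pi, n_theta)
    phi = np.linspace(0.0, 2.0 * math.pi, n_phi, endpoint=False)
    T, P = np.meshgrid(theta, phi, indexing="ij")
    return T.ravel(), P.ravel()


def _fd_laplacian(fn, x, y, z, h: float):
    """Second-order central 7-point Laplacian of a scalar field of (x, y, z)."""
    f0 = fn(x, y, z)
    acc = -6.0 * f0
    for dx, dy, dz in ((h, 0, 0), (-h, 0, 0), (0, h, 0), (0, -h, 0), (0, 0, h), (0, 0, -h)):
        acc = acc + fn(x + dx, y + dy, z + dz)
    return acc / h**2, f0


def _cartesian_eval(series):
    def fn(x, y, z):
        r, th, ph = current_fields.cartesian_to_spherical_coords(x, y, z)
        return series.values(r, th, ph)

    return fn


def helmholtz_residual(coeffs, params, probes: pd.DataFrame, h: float) -> float:
    """Relative finite-difference Helmholtz residual of V_m at probe points.

    max |FD-laplacian(V_m) - V_m / lambda^2| normalized by max|V_m|/lambda^2;
    decays as O(h^2) since the analytic residual is identically zero.
    """
    lam2 = coeffs.lam**2
    x, y, z = _probe_cartesian(probes)
    lap, f0 = _fd_laplacian(_cartesian_eval(solver.vm_series(coeffs)), x, y, z, h)
    scale = max(np.max(np.abs(f0)) / lam2, 1e-300)
    return float(np.max(np.abs(lap - f0 / lam2)) / scale)


def laplace_residuals(coeffs, config, probes: pd.DataFrame, h: float) -> dict:
    """Relative FD Laplace residuals of psi (interior) and phi_bath (exterior)."""
    a = config.a
    x, y, z = _probe_cartesian(probes)
    lap, f0 = _fd_laplacian(_cartesian_eval(solver.psi_series(coeffs)), x, y, z, h)
    res_psi = np.max(np.abs(lap)) / max(np.max(np.abs(f0)) / a**2, 1e-300)

    th, ph = _fibonacci_directions(probes.shape[0], offset=11)
    rb = np.linspace(1.2, 1.8, probes.shape[0]) * a
    st = np.sin(th)
    xb, yb, zb = rb * st * np.cos(ph), rb * st * np.sin(ph), rb * np.cos(th)
    lap_b, f0_b = _fd_laplacian(_cartesian_eval(solver.bath_series(coeffs)), xb, yb, zb, h)
    res_bath = np.max(np.abs(lap_b)) / max(np.max(np.abs(f0_b)) / a**2, 1e-300)
    return {"psi": float(res_psi), "phi_bath": float(res_bath)}


def _probe_cartesian(probes: pd.DataFrame):
    r = probes["r"].to_numpy()
    th = probes["theta"].to_numpy()
    ph = probes["phi"].to_numpy()
    st = np.sin(th)
    return r * st * np.cos(ph), r * st * np.sin(ph), r * np.cos(th)


def planar_symmetry(
    config, params, sources, coeffs, n: int = 64, extent: float = 3e-3
) -> float:
    """max |J_z| / max |J| over an n x n sample of the z = 0 plane.

    Zero (to rounding) whenever both electrodes lie in that plane together
    with the sphere center, since all current then flows in the plane.
    """
    grid = current_fields.sample_grid(
        config, params, sources, coeffs, extent=extent, dims=(n, n, 1)
    )
    ok = grid.mask != MASK_EXCLUDED
    mag = grid.magnitude()
    return float(np.max(np.abs(grid.Jz[ok])) / max(np.max(mag[ok]), 1e-300))


def azimuthal_variation(coeffs, params, config, n_phi: int = 64) -> float:
    """Max relative phi-variation of the potentials at fixed (r, theta) rings.

    Diagnostic for configurations that are symmetric about the polar axis.
    """
    a = config.a
    out = 0.0
    phi = np.linspace(0.0, 2.0 * math.pi, n_phi, endpoint=False)
    for r_frac, theta in ((0.5, 0.9), (0.9, 1.7), (1.0, 2.3)):
        r = np.full_like(phi, r_frac * a)
        th = np.full_like(phi, theta)
        vm = solver.transmembrane_potential(r, th, phi, coeffs)
        psi = solver.monodomain_potential(r, th, phi, coeffs)
        for vals in (vm, psi):
            scale = max(np.max(np.abs(vals)), 1e-300)
            out = max(out, (np.max(vals) - np.min(vals)) / scale)
    return float(out)


def source_flux(
    config: ModelConfig,
    params: TissueParameters,
    sources: SourcePair,
    coeffs=None,
    radius: float = 0.5e-3,
    n_polar: int = 32,
    which: str = "+",
) -> float:
    """Current flux (A) of J_e through a small sphere around one electrode.

    Gauss-Legendre nodes in the polar cosine and a uniform azimuthal rule
    on a sphere of the given radius centered on the electrode; by charge
    conservation the result is +-I_0 to quadrature accuracy.
    """
    if coeffs is None:
        coeffs = solver.coefficients(config, params, sources)
    p = sources.p_plus if which == "+" else sources.p_minus
    center = p.cartesian
    nodes, weights = np.polynomial.legendre.leggauss(n_polar)
    phis = np.linspace(0.0, 2.0 * math.pi, 2 * n_polar, endpoint=False)
    CT, PH = np.meshgrid(nodes, phis, indexing="ij")
    W = np.broadcast_to(weights[:, None], CT.shape)
    st = np.sqrt(1.0 - CT**2)
    nx, ny, nz = st * np.cos(PH), st * np.sin(PH), CT
    x = center[0] + radius * nx
    y = center[1] + radius * ny
    z = center[2] + radius * nz
    r, th, ph = current_fields.cartesian_to_spherical_coords(
        x.ravel(), y.ravel(), z.ravel()
    )
    j = current_fields.current_density_e(r, th, ph, coeffs, sources, params)
    jx, jy, jz = current_fields.to_cartesian(j, th, ph)
    j_dot_n = jx * nx.ravel() + jy * ny.ravel() + jz * nz.ravel()
    dphi = 2.0 * math.pi / (2 * n_polar)
    return float(radius**2 * dphi * np.sum(W.ravel() * j_dot_n))


# ---- studies -----------------------------------------------------------


def _probe_potentials(cfg: ScenarioConfig, mu_max: int, probes: pd.DataFrame):
    """Stacked (V_m & phi_o on tissue/boundary, phi_e on bath) probe values."""
    coeffs = solver.coefficients(
        replace(cfg.config, mu_max=mu_max), cfg.params, cfg.sources
    )
    inside = probes["region"].isin(["tissue", "boundary"]).to_numpy()
    r = probes["r"].to_numpy()
    th = probes["theta"].to_numpy()
    ph = probes["phi"].to_numpy()
    vm = solver.transmembrane_potential(r[inside], th[inside], ph[inside], coeffs)
    _, phi_o = solver.domain_potentials(
        r[inside], th[inside], ph[inside], coeffs, cfg.params
    )
    phi_e = solver.external_potential(
        r[~inside], th[~inside], ph[~inside], coeffs, cfg.sources, cfg.params
    )
    return np.concatenate([vm, phi_o, phi_e])


def convergence_study(cfg: ScenarioConfig, mu_values) -> pd.DataFrame:
    """Max absolute potential change (V) between successive truncations.

    For each mu in ``mu_values`` (ascending), reports
    max_p |f(mu) - f(next mu)| over the fixed 50-point probe set, for the
    stacked V_m / phi_o / phi_e probe values.
    """
    mu_values = list(mu_values)
    if mu_values != sorted(mu_values):
        raise ValueError("mu_values must be ascending")
    probes = convergence_probes(cfg.config.a)
    vals = {mu: _probe_potentials(cfg, mu, probes) for mu in mu_values}
    rows = []
    for mu, mu_next in zip(mu_values[:-1], mu_values[1:]):
        rows.append(
            {
                "mu_max": mu,
                "mu_next": mu_next,
                "max_abs_change_V": float(np.max(np.abs(vals[mu] - vals[mu_next]))),
            }
        )
    return pd.DataFrame(rows)


def line_profile(
    cfg: ScenarioConfig,
    axis: str = "y",
    span: tuple = (-4.5e-3, 4.5e-3),
    num: int = 361,
    coeffs=None,
    mode: str = "closed_form",
) -> pd.DataFrame:
    """Potentials along a coordinate axis through the sphere center.

    Columns: position (m), phi_i, phi_o, V_m, psi (tissue rows), phi_e
    (bath rows) and region.  ``mode`` selects how the electrode monopoles
    enter phi_e; "series" makes the r = a continuity exact at the model's
    truncation.
    """
    t = np.linspace(span[0], span[1], num)
    unit = {"x": (1.0, 0, 0), "y": (0, 1.0, 0), "z": (0, 0, 1.0)}[axis]
    x, y, z = (t * u for u in unit)
    r, th, ph = current_fields.cartesian_to_spherical_coords(x, y, z)
    if coeffs is None:
        coeffs = solver.coefficients(cfg.config, cfg.params, cfg.sources)
    a = cfg.config.a
    inside = r <= a
    out = pd.DataFrame(
        {
            "position": t,
            "phi_i": np.nan,
            "phi_o": np.nan,
            "V_m": np.nan,
            "psi": np.nan,
            "phi_e": np.nan,
            "region": np.where(inside, "tissue", "bath"),
        }
    )
    if inside.any():
        phi_i, phi_o = solver.domain_potentials(
            r[inside], th[inside], ph[inside], coeffs, cfg.params
        )
        out.loc[inside, "phi_i"] = phi_i
        out.loc[inside, "phi_o"] = phi_o
        out.loc[inside, "V_m"] = phi_i - phi_o
        out.loc[inside, "psi"] = solver.monodomain_potential(
            r[inside], th[inside], ph[inside], coeffs
        )
    if (~inside).any():
        out.loc[~inside, "phi_e"] = solver.external_potential(
            r[~inside],
            th[~inside],
            ph[~inside],
            coeffs,
            cfg.sources,
            cfg.params,
            mode=mode,
            exclusion_radius=cfg.config.exclusion_radius,
        )
    return out


# ---- top-level runner --------------------------------------------------


def validation_report(cfg: ScenarioConfig, coeffs=None) -> ValidationReport:
    """Boundary, PDE-residual, convergence and symmetry checks in one report."""
    if coeffs is None:
        coeffs = solver.coefficients(cfg.config, cfg.params, cfg.sources)
    report = ValidationReport()
    res = boundary_residuals(cfg.config, cfg.params, cfg.sources, coeffs)
    report.add("boundary_potential_continuity_rel", res["potential_continuity"], 1e-8)
    report.add("boundary_normal_current_rel", res["normal_current_continuity"], 1e-6)
    report.add(
        "boundary_intracellular_current_rel",
        res["intracellular_normal_current"],
        1e-10,
    )

    probes = interior_probes(cfg.config.a, n=50, r_max=0.8)
    a = cfg.config.a
    helm = {h: helmholtz_residual(coeffs, cfg.params, probes, h) for h in (a / 50, a / 100, a / 200)}
    report.add("helmholtz_residual_rel_h_a200", helm[a / 200], 1e-3)
    lap = laplace_residuals(coeffs, cfg.config, probes, a / 200)
    report.add("laplace_residual_psi_rel_h_a200", lap["psi"], 1e-3)
    report.add("laplace_residual_bath_rel_h_a200", lap["phi_bath"], 1e-3)
    report.tables["helmholtz_residuals"] = pd.DataFrame(
        {"h_over_a": [1 / 50, 1 / 100, 1 / 200], "residual": list(helm.values())}
    )

    conv = convergence_study(cfg, [cfg.config.mu_max, cfg.config.mu_max + 4])
    report.add(
        "convergence_max_change_V", conv["max_abs_change_V"].iloc[0], 0.5e-5
    )
    report.tables["convergence"] = conv

    report.add(
        "planar_symmetry_max_Jz_rel",
        planar_symmetry(cfg.config, cfg.params, cfg.sources, coeffs),
        1e-10 if _sources_in_plane(cfg.sources) else None,
    )
    if cfg.tag == "axisymmetric":
        report.add(
            "azimuthal_variation_rel",
            azimuthal_variation(coeffs, cfg.params, cfg.config),
            1e-10,
        )
    report.add(
        "source_flux_error_rel",
        abs(source_flux(cfg.config, cfg.params, cfg.sources, coeffs) - cfg.sources.I_0)
        / cfg.sources.I_0,
        1e-3,
    )
    return report


def _sources_in_plane(sources: SourcePair) -> bool:
    """True when both electrodes lie in the z = 0 plane (mirror symmetry)."""
    return (
        abs(sources.p_plus.cartesian[2]) < 1e-15
        and abs(sources.p_minus.cartesian[2]) < 1e-15
    )


def run_scenario(cfg: ScenarioConfig) -> dict:
    """Full pipeline: coefficients, field grids, B_z and validation report.

    Returns the in-memory products; writes CSV grids and a JSON report when
    ``cfg.outdir`` is set.  Deterministic given the configuration.
    """
    cfg.sources.validate_outside(cfg.config.a)
    coeffs = solver.coefficients(cfg.config, cfg.params, cfg.sources)
    j_grid = current_fields.sample_grid(
        cfg.config, cfg.params, cfg.sources, coeffs, extent=cfg.extent, dims=cfg.dims
    )
    b_grid = biot_savart.bz_fft(j_grid)
    potential_plane = _potential_plane(cfg, coeffs)
    report = validation_report(cfg, coeffs)

    if cfg.outdir is not None:
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        j_grid.to_dataframe().to_csv(outdir / "current_density.csv", index=False)
        bz = j_grid.to_dataframe()[["x", "y", "z"]]
        bz["Bz"] = b_grid.Bz.ravel()
        bz.to_csv(outdir / "bz.csv", index=False)
        potential_plane.to_csv(outdir / "potential_plane.csv", index=False)
        report.write(outdir / "validation_report.json")
    return {
        "coeffs": coeffs,
        "current_grid": j_grid,
        "bz_grid": b_grid,
        "potential_plane": potential_plane,
        "report": report,
    }


def _potential_plane(cfg: ScenarioConfig, coeffs) -> pd.DataFrame:
    """phi_o inside / phi_e outside on the z = 0 plane (the plotted field)."""
    n = cfg.dims[0]
    ax = np.linspace(-cfg.extent / 2, cfg.extent / 2, n)
    X, Y = np.meshgrid(ax, ax, indexing="ij")
    x, y = X.ravel(), Y.ravel()
    r, th, ph = current_fields.cartesian_to_spherical_coords(x, y, np.zeros_like(x))
    inside = r < cfg.config.a
    vals = np.empty_like(r)
    _, phi_o = solver.domain_potentials(
        r[inside], th[inside], ph[inside], coeffs, cfg.params
    )
    vals[inside] = phi_o
    vals[~inside] = solver.external_potential(
        r[~inside], th[~inside], ph[~inside], coeffs, cfg.sources, cfg.params
    )
    return pd.DataFrame(
        {"x": x, "y": y, "potential": vals, "region": np.where(inside, "tissue", "bath")}
    )
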