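"""Physical and geometric inputs of the spherical bidomain forward model.

All quantities are SI internally (m, Ohm*m, A, V, T).  Configuration files
may declare a ``length_unit`` (default ``mm``, matching the scale at which
positions and radii are usually quoted for small tissue preparations);
lengths are converted on load.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "TissueParameters",
    "SphericalPoint",
    "SourcePair",
    "ModelConfig",
    "default_parameters",
    "default_sources",
    "default_config",
    "load_config",
]

_LENGTH_UNITS = {"m": 1.0, "mm": 1e-3, "cm": 1e-2, "um": 1e-6}


@dataclass(frozen=True)
class TissueParameters:
    """Bidomain tissue and bath material constants.

    Attributes
    ----------
    rho_i, rho_o : float
        Intracellular and interstitial (extracellular-within-tissue)
        resistivities, Ohm*m.
    rho_e : float
        Bath resistivity, Ohm*m.
    R_m : float
        Membrane resistance times unit area, Ohm*m^2.
    beta : float
        Membrane surface-area-to-cell-volume ratio, 1/m.
    """

    rho_i: float
    rho_o: float
    rho_e: float
    R_m: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("rho_i", "rho_o", "rho_e", "R_m", "beta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def rho_m(self) -> float:
        """Membrane resistance times unit volume, R_m / beta (Ohm*m^3)."""
        return self.R_m / self.beta

    @property
    def length_constant(self) -> float:
        """Membrane length constant lambda = sqrt(rho_m / (rho_i + rho_o)) (m)."""
        return math.sqrt(self.rho_m / (self.rho_i + self.rho_o))

    def with_rho_o(self, rho_o: float) -> "TissueParameters":
        return replace(self, rho_o=rho_o)


@dataclass(frozen=True)
class SphericalPoint:
    """Point in spherical coordinates (r [m], theta [rad], phi [rad])."""

    r: float
    theta: float
    phi: float

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError("radius must be non-negative")
        if not (0.0 <= self.theta <= math.pi):
            # tolerate rounded literals like 3.1415927 from config files
            if -1e-6 <= self.theta < 0.0 or math.pi < self.theta <= math.pi + 1e-6:
                object.__setattr__(
                    self, "theta", min(max(self.theta, 0.0), math.pi)
                )
            else:
                raise ValueError("polar angle theta must lie in [0, pi]")

    @property
    def cartesian(self) -> np.ndarray:
        st = math.sin(self.theta)
        return np.array(
            [
                self.r * st * math.cos(self.phi),
                self.r * st * math.sin(self.phi),
                self.r * math.cos(self.theta),
            ]
        )


def _as_point(p) -> SphericalPoint:
    if isinstance(p, SphericalPoint):
        return p
    r, theta, phi = p
    return SphericalPoint(float(r), float(theta), float(phi))


@dataclass(frozen=True)
class SourcePair:
    """Point current source (+I_0) and sink (-I_0) in the bath.

    The injected current magnitude ``I_0`` is in amperes; both electrodes
    must lie strictly outside the tissue sphere (checked where the tissue
    radius is known, e.g. at coefficient computation).
    """

    p_plus: SphericalPoint
    p_minus: SphericalPoint
    I_0: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "p_plus", _as_point(self.p_plus))
        object.__setattr__(self, "p_minus", _as_point(self.p_minus))
        if self.I_0 <= 0:
            raise ValueError("injected current magnitude I_0 must be positive")

    @property
    def coincident(self) -> bool:
        return bool(
            np.allclose(self.p_plus.cartesian, self.p_minus.cartesian, atol=0.0)
        )

    def validate_outside(self, a: float) -> None:
        if self.p_plus.r <= a or self.p_minus.r <= a:
            raise ValueError(
                "current source and sink must lie strictly outside the tissue "
                f"sphere: r+={self.p_plus.r}, r-={self.p_minus.r}, a={a}"
            )

    def gamma(self, theta, phi, which: str = "+"):
        """cos of the angle between a field direction and the source (+) or sink (-)."""
        p = self.p_plus if which == "+" else self.p_minus
        theta = np.asarray(theta, dtype=float)
        phi = np.asarray(phi, dtype=float)
        return np.cos(theta) * math.cos(p.theta) + np.sin(theta) * math.sin(
            p.theta
        ) * np.cos(phi - p.phi)

    def distance(self, r, theta, phi, which: str = "+"):
        """Distance from the source/sink point to field points (law of cosines)."""
        p = self.p_plus if which == "+" else self.p_minus
        r = np.asarray(r, dtype=float)
        cosg = self.gamma(theta, phi, which)
        return np.sqrt(np.maximum(r**2 + p.r**2 - 2.0 * r * p.r * cosg, 0.0))


@dataclass(frozen=True)
class ModelConfig:
    """Numerical configuration: tissue radius, truncation and guards.

    ``mu_max`` truncates the spherical-harmonic series (the default 10
    stabilizes the default-geometry potentials to five decimal places in
    volts).  ``exclusion_radius`` is the minimum distance from the singular
    source/sink points at which fields may be evaluated; it defaults to 5%
    of the tissue radius.  ``tol_real`` bounds the tolerated relative
    imaginary residue of physically real fields.
    """

    a: float
    mu_max: int = 10
    exclusion_radius: float | None = None
    tol_real: float = 1e-10

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("tissue radius a must be positive")
        if self.mu_max < 1:
            raise ValueError("series truncation mu_max must be >= 1")
        if self.exclusion_radius is None:
            object.__setattr__(self, "exclusion_radius", 0.05 * self.a)


def default_parameters(rho_o: float | None = None) -> TissueParameters:
    """Default material constants; rho_o defaults to the bath value (ratio 1)."""
    rho_e = 0.29
    return TissueParameters(
        rho_i=0.19,
        rho_o=rho_e if rho_o is None else rho_o,
        rho_e=rho_e,
        R_m=0.15,
        beta=20000.0,
    )


def default_sources() -> SourcePair:
    """Default electrode pair, 1 mA, both in the z = 0 imaging plane.

    Source at Cartesian (5, 0, 0) mm, sink at (0, -5, 0) mm: a cathode to
    the right of, and an anode directly below, the tissue sphere, with the
    bore (z) axis normal to the plane that contains both electrodes and
    the sphere center.  That plane is then a mirror plane of the fields
    (J_z = 0 on it, B_z even in z).
    """
    return SourcePair(
        p_plus=SphericalPoint(5e-3, math.pi / 2, 0.0),
        p_minus=SphericalPoint(5e-3, math.pi / 2, -math.pi / 2),
        I_0=1e-3,
    )


def default_config(mu_max: int = 10) -> ModelConfig:
    """Default numerical configuration: a = 2 mm, series truncated at mu_max."""
    return ModelConfig(a=2e-3, mu_max=mu_max)


def _read_mapping(path: Path) -> dict:
    text = path.read_text()
    suffix = path.suffix.lower()
    if suffix in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text) or {}
    if suffix == ".toml":
        import tomllib

        return tomllib.loads(text)
    if suffix == ".json":
        return json.loads(text)
    raise ValueError(f"unsupported config format: {path.suffix}")


def load_config(path) -> tuple[ModelConfig, TissueParameters, SourcePair]:
    """Read a YAML/TOML/JSON config; absent keys fall back to the defaults.

    Recognized keys: rho_i, rho_o, rho_e, R_m, beta, I0, a,
    p_plus: [r, theta, phi], p_minus: [r, theta, phi], mu_max, length_unit.
    Lengths (a, r-components of p_plus/p_minus, exclusion_radius) are in
    ``length_unit`` (default mm); angles are radians.
    """
    raw = _read_mapping(Path(path))
    unit = raw.get("length_unit", "mm")
    if unit not in _LENGTH_UNITS:
        raise ValueError(f"unknown length_unit {unit!r}; use one of {sorted(_LENGTH_UNITS)}")
    scale = _LENGTH_UNITS[unit]

    defaults_p = default_parameters()
    params = TissueParameters(
        rho_i=float(raw.get("rho_i", defaults_p.rho_i)),
        rho_o=float(raw.get("rho_o", defaults_p.rho_o)),
        rho_e=float(raw.get("rho_e", defaults_p.rho_e)),
        R_m=float(raw.get("R_m", defaults_p.R_m)),
        beta=float(raw.get("beta", defaults_p.beta)),
    )

    def point(key, default):
        if key not in raw:
            return default
        r, theta, phi = raw[key]
        return SphericalPoint(float(r) * scale, float(theta), float(phi))

    defaults_s = default_sources()
    sources = SourcePair(
        p_plus=point("p_plus", defaults_s.p_plus),
        p_minus=point("p_minus", defaults_s.p_minus),
        I_0=float(raw.get("I0", defaults_s.I_0)),
    )

    config = ModelConfig(
        a=float(raw.get("a", 2e-3 / scale)) * scale,
        mu_max=int(raw.get("mu_max", 10)),
        exclusion_radius=(
            float(raw["exclusion_radius"]) * scale if "exclusion_radius" in raw else None
        ),
    )
    return config, params, sources
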