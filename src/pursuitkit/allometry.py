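"""Mass-dependent locomotor performance for terrestrial cursorial mammals.

Two physical ingredients drive everything in this package:

1. An empirical allometric law for maximum running speed,
   ``log10(Vmax[km/h]) = a0 + a1*log10(M) + a2*log10(M)**2`` with mass M in kg.
   The default coefficients describe mammals across roughly five orders of
   magnitude of mass; the quadratic term makes the law unimodal, peaking near
   120 kg and falling off for very large animals.

2. A strength-limited minimum turn radius.  Under geometric similarity the
   characteristic length is ``L = (M/rho)**(1/3)``, available limb force
   scales as ``k*L**2`` (k in N/m^2, a material constant of muscle, bone and
   tendon), while the centripetal force needed to hold a circular path of
   radius r at speed v is ``M*v**2/r``.  Equating the two gives

       r_min(v) = M*v**2 / (k*L**2) = rho*L*v**2 / k.

Forces required for a turn scale as mass^1 while available force scales as
mass^(2/3), so heavier animals turn wider at any common speed: r_min grows as
M^(1/3).  All public interfaces are SI (m, s, kg); the speed law's native
km/h is converted internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AllometryCoefficients",
    "AnimalSpec",
    "vmax_allometric",
    "speed_factor",
    "min_turn_radius",
    "strength_constant_from_reference",
    "turn_arc_length",
    "turn_distance_differential",
    "read_species_table",
    "write_species_table",
]

KMH_TO_MS = 1.0 / 3.6

#: Default strength constant (N/m^2): force available per unit limb
#: cross-section.  Calibrated from a 30 kg cursor turning with r = 40 m
#: at 20 m/s (see :func:`strength_constant_from_reference`).
DEFAULT_STRENGTH_CONSTANT = 3100.0

#: Default body density (kg/m^3).  Not a measured quantity here: it is the
#: density that makes the (M=30 kg, v=20 m/s, r=40 m) reference triple yield
#: k ~= 3100, and close to the density of animal tissue.
DEFAULT_BODY_DENSITY = 1000.0

#: Default tangential-acceleration law a(v) = c1 * v**c2 (m/s^2 at 1 m/s,
#: dimensionless exponent), measured for a ~30 kg cursorial predator running
#: at about 90 W/kg.
DEFAULT_ACCEL_COEFFS = (47.041, -0.945)


@dataclass(frozen=True)
class AllometryCoefficients:
    """Coefficients of the quadratic log-log maximum-speed law.

    ``log10(Vmax[km/h]) = a0 + a1*log10(M[kg]) + a2*log10(M[kg])**2``
    """

    a0: float = 1.478
    a1: float = 0.2589
    a2: float = -0.0623

    def log10_vmax_kmh(self, mass_kg: np.ndarray | float) -> np.ndarray | float:
        lm = np.log10(mass_kg)
        return self.a0 + self.a1 * lm + self.a2 * lm * lm

    @property
    def vertex_log10_mass(self) -> float:
        """log10 of the mass maximizing Vmax (vertex of the quadratic)."""
        if self.a2 == 0:
            raise ValueError("linear law has no interior vertex")
        return -self.a1 / (2.0 * self.a2)


@dataclass(frozen=True)
class AnimalSpec:
    """Physical parameters of one animal.

    Parameters
    ----------
    mass : float
        Body mass in kg (> 0).
    body_density : float
        kg/m^3; with mass it fixes the characteristic length
        ``L = (M/rho)**(1/3)`` under geometric similarity.
    strength_constant : float
        k in N/m^2, capping centripetal force at ``k*L**2``.
    accel_coeffs : tuple of (float, float)
        (c1, c2) of the tangential acceleration law ``a(v) = c1*v**c2``.
    reaction_time : float
        Response latency in s (>= 0); the delay before this animal reacts
        to a manoeuvre by the other party.
    vmax_override : float or None
        Top speed in m/s; ``None`` resolves to the allometric value.
    coeffs : AllometryCoefficients
        Speed-law coefficients used when ``vmax_override`` is None.
    """

    mass: float
    body_density: float = DEFAULT_BODY_DENSITY
    strength_constant: float = DEFAULT_STRENGTH_CONSTANT
    accel_coeffs: tuple[float, float] = DEFAULT_ACCEL_COEFFS
    reaction_time: float = 0.3
    vmax_override: float | None = None
    coeffs: AllometryCoefficients = field(default_factory=AllometryCoefficients)

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise ValueError(f"mass must be > 0, got {self.mass}")
        if not self.body_density > 0:
            raise ValueError(f"body_density must be > 0, got {self.body_density}")
        if not self.strength_constant > 0:
            raise ValueError(
                f"strength_constant must be > 0, got {self.strength_constant}"
            )
        if self.reaction_time < 0:
            raise ValueError(f"reaction_time must be >= 0, got {self.reaction_time}")
        if self.vmax_override is not None and not self.vmax_override > 0:
            raise ValueError(f"vmax_override must be > 0, got {self.vmax_override}")

    @property
    def length(self) -> float:
        """Characteristic length L = (M/rho)**(1/3) in m."""
        return (self.mass / self.body_density) ** (1.0 / 3.0)

    @property
    def vmax(self) -> float:
        """Resolved top speed in m/s."""
        if self.vmax_override is not None:
            return self.vmax_override
        return vmax_allometric(self.mass, self.coeffs)


def vmax_allometric(
    mass_kg: float | np.ndarray,
    coeffs: AllometryCoefficients | None = None,
) -> float | np.ndarray:
    """Allometric maximum running speed, in m/s.

    Evaluates ``10**(a0 + a1*log10(M) + a2*log10(M)**2)`` km/h and converts
    to m/s.  Accepts scalars or arrays; mass must be strictly positive.
    """
    coeffs = coeffs or AllometryCoefficients()
    m = np.asarray(mass_kg, dtype=float)
    if np.any(m <= 0):
        raise ValueError("mass must be > 0")
    v = 10.0 ** np.asarray(coeffs.log10_vmax_kmh(m)) * KMH_TO_MS
    return float(v) if np.isscalar(mass_kg) else v


def speed_factor(
    mass_range: tuple[float, float],
    coeffs: AllometryCoefficients | None = None,
    n_grid: int = 1000,
) -> float:
    """Ratio max/min of allometric Vmax over a mass range.

    The grid is log-spaced; because the speed law is quadratic in log-mass
    its vertex is also evaluated explicitly whenever it lies inside the
    range, so an interior maximum is never missed regardless of grid
    density.  Returns 1.0 for a degenerate (lo == hi) range.
    """
    coeffs = coeffs or AllometryCoefficients()
    lo, hi = mass_range
    if not (0 < lo <= hi):
        raise ValueError(f"need 0 < lo <= hi, got {mass_range}")
    if lo == hi:
        return 1.0
    if n_grid < 2:
        raise ValueError("n_grid must be >= 2")
    masses = np.logspace(np.log10(lo), np.log10(hi), n_grid)
    if coeffs.a2 != 0:
        vertex = 10.0 ** coeffs.vertex_log10_mass
        if lo < vertex < hi:
            masses = np.append(masses, vertex)
    v = vmax_allometric(masses, coeffs)
    return float(np.max(v) / np.min(v))


def min_turn_radius(spec: AnimalSpec, v: float) -> float:
    """Strength-limited minimum turn radius (m) at speed v (m/s).

    ``r = M*v**2/(k*L**2) = rho*L*v**2/k``; zero at v = 0 and strictly
    increasing (quadratically) in speed.
    """
    if v < 0:
        raise ValueError(f"speed must be >= 0, got {v}")
    return spec.body_density * spec.length * v * v / spec.strength_constant


def strength_constant_from_reference(
    mass_kg: float, body_density: float, v: float, r: float
) -> float:
    """Back out the strength constant k (N/m^2) from one observed turn.

    Inverts the minimum-turn-radius relation: ``k = rho*L*v**2/r`` with
    ``L = (M/rho)**(1/3)``.  Exact algebraic inverse of
    :func:`min_turn_radius`.
    """
    for name, val in (("mass_kg", mass_kg), ("body_density", body_density),
                      ("v", v), ("r", r)):
        if not val > 0:
            raise ValueError(f"{name} must be > 0, got {val}")
    length = (mass_kg / body_density) ** (1.0 / 3.0)
    return body_density * length * v * v / r


def turn_arc_length(angle: float, r: float) -> float:
    """Arc length (m) of a turn of ``angle`` rad at radius ``r`` m."""
    if angle < 0 or r < 0:
        raise ValueError("angle and radius must be >= 0")
    return angle * r


def turn_distance_differential(
    pred: AnimalSpec, prey: AnimalSpec, v: float, angle: float = math.pi / 2
) -> float:
    """Extra distance (m) the predator runs during a shared turn.

    Both animals execute a turn of ``angle`` rad at the common speed ``v``
    on their own minimum radii; the result is
    ``angle * (r_pred - r_prey)``.  Positive means the predator covers more
    ground than the prey during the manoeuvre — the prey benefits from
    cornering; negative means the predator turns tighter.

    The common speed must be attainable by both parties, so ``v`` may not
    exceed either resolved top speed.
    """
    if not angle > 0:
        raise ValueError(f"angle must be > 0, got {angle}")
    for role, spec in (("predator", pred), ("prey", prey)):
        if v > spec.vmax:
            raise ValueError(
                f"speed {v:.3f} m/s exceeds the {role}'s maximum "
                f"{spec.vmax:.3f} m/s; the differential is only defined at "
                "speeds both animals can reach"
            )
    return angle * (min_turn_radius(pred, v) - min_turn_radius(prey, v))


# ---------------------------------------------------------------------------
# species table I/O

_SPECIES_COLUMNS = ["predator_name", "predator_mass_kg", "prey_mass_kg"]


def read_species_table(path: str | Path) -> pd.DataFrame:
    """Read a predator-prey mass-pair table (CSV, one row per pairing)."""
    df = pd.read_csv(path)
    missing = [c for c in _SPECIES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"species table missing columns: {missing}")
    return df[_SPECIES_COLUMNS + [c for c in df.columns if c not in _SPECIES_COLUMNS]]


def write_species_table(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in _SPECIES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"species table missing columns: {missing}")
    df.to_csv(path, index=False)
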