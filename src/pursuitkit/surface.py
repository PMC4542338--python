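"""Predator/prey performance-ratio surface over body-mass grids.

For every (predator mass, prey mass) pair the surface holds two
dimensionless ratios:

* ``vratio = Vmax_pred / Vmax_prey`` — relative top speed (> 1: the
  predator outruns the prey),
* ``tratio = Tmin_prey / Tmin_pred`` — relative agility, each party's
  minimum turn radius evaluated at its *own* allometric top speed
  (> 1: the predator turns tighter than the prey).

Because ``Tmin = rho*L*Vmax**2/k = (M/rho)**(1/3)*rho*Vmax**2/k``, the
strength constant and density cancel from ``tratio`` whenever both animals
share them: the agility ratio is a pure consequence of the speed allometry
and geometric similarity.  Species mass pairs are placed on the surface by
direct evaluation, and flagged as inside the predator-advantage region when
``tratio >= 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .allometry import (
    AllometryCoefficients,
    AnimalSpec,
    min_turn_radius,
    vmax_allometric,
)

__all__ = ["MassRatioSurface", "build_surface", "place_species"]


@dataclass(frozen=True)
class MassRatioSurface:
    """Gridded speed and turn-radius ratios over predator x prey masses.

    ``vratio`` and ``tratio`` are indexed [i, j] = (predator mass i,
    prey mass j).
    """

    pred_mass: np.ndarray
    prey_mass: np.ndarray
    vratio: np.ndarray
    tratio: np.ndarray
    coeffs: AllometryCoefficients

    def __post_init__(self) -> None:
        np_, nq = self.pred_mass.size, self.prey_mass.size
        if self.vratio.shape != (np_, nq) or self.tratio.shape != (np_, nq):
            raise ValueError("ratio grid shapes do not match the mass axes")
        if np.any(self.pred_mass <= 0) or np.any(self.prey_mass <= 0):
            raise ValueError("mass grids must be strictly positive")

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (predator, prey) grid cell."""
        pm, qm = np.meshgrid(self.pred_mass, self.prey_mass, indexing="ij")
        return pd.DataFrame(
            {
                "pred_mass_kg": pm.ravel(),
                "prey_mass_kg": qm.ravel(),
                "vratio": self.vratio.ravel(),
                "tratio": self.tratio.ravel(),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _tmin(mass: np.ndarray | float, coeffs: AllometryCoefficients,
          body_density: float, strength_constant: float,
          at_speed: float | None = None) -> np.ndarray | float:
    """Minimum turn radius at the animal's own allometric Vmax (or a
    common speed for sensitivity checks)."""
    v = vmax_allometric(mass, coeffs) if at_speed is None else at_speed
    m = np.asarray(mass, dtype=float)
    length = (m / body_density) ** (1.0 / 3.0)
    return body_density * length * np.asarray(v) ** 2 / strength_constant


def build_surface(
    mass_range: tuple[float, float] = (0.05, 5000.0),
    n: int = 60,
    coeffs: AllometryCoefficients | None = None,
    body_density: float = 1000.0,
    strength_constant: float = 3100.0,
    common_speed: float | None = None,
) -> MassRatioSurface:
    """Build the performance surface over a log-spaced mass grid.

    ``common_speed`` switches the turn-radius ratio from the default
    own-Vmax evaluation to a shared fixed speed (a sensitivity mode in
    which ``tratio`` reduces to the pure mass^(1/3) ratio).
    """
    coeffs = coeffs or AllometryCoefficients()
    lo, hi = mass_range
    if not (0 < lo < hi):
        raise ValueError(f"need 0 < lo < hi, got {mass_range}")
    if n < 2:
        raise ValueError("n must be >= 2 per axis")
    masses = np.logspace(np.log10(lo), np.log10(hi), n)
    vmax = vmax_allometric(masses, coeffs)
    tmin = _tmin(masses, coeffs, body_density, strength_constant, common_speed)
    vratio = vmax[:, None] / vmax[None, :]
    tratio = tmin[None, :] / tmin[:, None]  # prey over predator
    return MassRatioSurface(
        pred_mass=masses, prey_mass=masses.copy(),
        vratio=vratio, tratio=tratio, coeffs=coeffs,
    )


def place_species(
    surface: MassRatioSurface,
    pairs: pd.DataFrame,
    body_density: float = 1000.0,
    strength_constant: float = 3100.0,
) -> pd.DataFrame:
    """Place predator-prey mass pairs on the performance surface.

    ``pairs`` follows the species-table schema (``predator_name,
    predator_mass_kg, prey_mass_kg``).  Ratios are evaluated directly from
    the allometric laws (no grid interpolation).  Rows with masses outside
    the surface's range are skipped with a warning.  Adds ``vratio``,
    ``tratio`` and ``predator_advantage`` (tratio >= 1) columns.
    """
    import warnings

    lo = min(surface.pred_mass.min(), surface.prey_mass.min())
    hi = max(surface.pred_mass.max(), surface.prey_mass.max())
    rows = []
    for _, row in pairs.iterrows():
        mp, mq = float(row["predator_mass_kg"]), float(row["prey_mass_kg"])
        if not (lo <= mp <= hi and lo <= mq <= hi):
            warnings.warn(
                f"row {row.get('predator_name', '?')}: mass pair ({mp}, {mq}) kg "
                f"outside surface range [{lo}, {hi}] — skipped", stacklevel=2,
            )
            continue
        vr = vmax_allometric(mp, surface.coeffs) / vmax_allometric(mq, surface.coeffs)
        tr = float(
            _tmin(mq, surface.coeffs, body_density, strength_constant)
            / _tmin(mp, surface.coeffs, body_density, strength_constant)
        )
        out = dict(row)
        out.update(vratio=vr, tratio=tr, predator_advantage=tr >= 1.0)
        rows.append(out)
    return pd.DataFrame(rows)
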