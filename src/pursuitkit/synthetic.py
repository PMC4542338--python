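"""Synthetic inputs with known ground truth.

Three generators cover everything the pipeline consumes:

* collar accelerometer traces — a 1 g gravity baseline split between heave
  and sway by a slowly random-walking collar angle, a bounding-gait lateral
  sinusoid, Gaussian-bump cornering episodes of known peak time, and white
  noise;
* predator-prey species mass tables with a configurable log-normal
  prey/predator mass-ratio distribution;
* batteries of chase scenarios on parameter grids (reaction time, turn
  trigger distance, party speeds).

Every generator is a pure function of (recipe, seed): identical inputs
give bit-identical outputs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .allometry import AnimalSpec
from .pursuit import ChaseConfig, PreyTurn
from .turns import AccelTrace

__all__ = [
    "TraceRecipe",
    "SpeciesTableRecipe",
    "make_trace",
    "make_species_table",
    "make_scenario_battery",
    "random_turn_schedule",
]


@dataclass(frozen=True)
class TraceRecipe:
    """Recipe for one synthetic accelerometer trace.

    ``turn_schedule`` is a tuple of (peak time s, peak departure g,
    half-width s) triples; the half-width is the Gaussian sigma of the
    cornering bump.  Gait defaults (3 Hz, 0.5 g lateral amplitude) are
    plausible for a galloping cursor.  ``seed`` is mandatory: traces are
    reproducible by construction.
    """

    duration: float = 20.0
    sampling_rate: float = 30.0
    gait_frequency: float = 3.0
    gait_amplitude: float = 0.5
    turn_schedule: tuple[tuple[float, float, float], ...] = (
        (4.0, 0.3, 0.4),
        (8.0, 0.3, 0.4),
        (12.0, 0.3, 0.4),
        (16.0, 0.3, 0.4),
    )
    noise_sigma: float = 0.05
    collar_walk_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration > 0 or not self.sampling_rate > 0:
            raise ValueError("duration and sampling_rate must be > 0")
        if self.gait_frequency < 0 or self.gait_amplitude < 0:
            raise ValueError("gait parameters must be >= 0")
        if self.noise_sigma < 0 or self.collar_walk_sigma < 0:
            raise ValueError("noise parameters must be >= 0")
        for t, amp, hw in self.turn_schedule:
            if not (0 <= t <= self.duration):
                raise ValueError(f"turn at t={t}s outside the {self.duration}s trace")
            if amp < 0 or not hw > 0:
                raise ValueError("turn amplitude must be >= 0 and half-width > 0")
        times = sorted(t for t, _, _ in self.turn_schedule)
        widths = {t: hw for t, _, hw in self.turn_schedule}
        for t1, t2 in zip(times, times[1:]):
            if t2 - t1 < 3.0 * (widths[t1] + widths[t2]):
                raise ValueError(
                    f"turn bumps at {t1}s and {t2}s overlap: ground truth "
                    "would be ambiguous"
                )


def make_trace(recipe: TraceRecipe) -> AccelTrace:
    """Generate a collar trace with ground-truth turn annotations.

    The static lateral magnitude is ``1 + sum of Gaussian bumps``; it is
    projected onto heave/sway through a collar angle performing a slow
    Gaussian random walk (the axes are interchangeable under collar
    rotation, and detection must not care).  The gait sinusoid rides on
    the lateral axes along the instantaneous collar direction; surge
    carries an independent gait component plus noise.
    """
    rng = np.random.default_rng(recipe.seed)
    n = int(round(recipe.duration * recipe.sampling_rate))
    t = np.arange(n) / recipe.sampling_rate

    magnitude = np.ones(n)
    truth = []
    for tc, amp, hw in recipe.turn_schedule:
        magnitude += amp * np.exp(-0.5 * ((t - tc) / hw) ** 2)
        truth.append(tc)

    # slowly rotating collar: random-walk angle, radians
    angle = np.cumsum(rng.normal(0.0, recipe.collar_walk_sigma, n))
    angle += rng.uniform(0.0, 2.0 * math.pi)

    gait = recipe.gait_amplitude * np.sin(2.0 * math.pi * recipe.gait_frequency * t)
    heave = magnitude * np.cos(angle) + gait * np.cos(angle)
    sway = magnitude * np.sin(angle) + gait * np.sin(angle)
    heave = heave + rng.normal(0.0, recipe.noise_sigma, n)
    sway = sway + rng.normal(0.0, recipe.noise_sigma, n)
    surge = 0.3 * np.sin(2.0 * math.pi * recipe.gait_frequency * t + 1.0) + rng.normal(
        0.0, recipe.noise_sigma, n
    )
    return AccelTrace(
        surge=surge,
        heave=heave,
        sway=sway,
        sampling_rate=recipe.sampling_rate,
        truth_turns=np.asarray(sorted(truth)),
    )


def random_turn_schedule(
    n_turns: int,
    duration: float,
    rng: np.random.Generator,
    amplitude: float = 0.3,
    half_width: float = 0.4,
    min_spacing: float | None = None,
    edge_margin: float = 2.0,
) -> tuple[tuple[float, float, float], ...]:
    """Draw non-overlapping random turn times for a :class:`TraceRecipe`."""
    if min_spacing is None:
        min_spacing = 6.0 * half_width + 0.1
    lo, hi = edge_margin, duration - edge_margin
    if hi - lo < (n_turns - 1) * min_spacing:
        raise ValueError("duration too short for the requested turn count")
    for _ in range(1000):
        times = np.sort(rng.uniform(lo, hi, n_turns))
        if n_turns < 2 or np.min(np.diff(times)) >= min_spacing:
            return tuple((float(tc), amplitude, half_width) for tc in times)
    raise RuntimeError("could not place non-overlapping turns")


@dataclass(frozen=True)
class SpeciesTableRecipe:
    """Recipe for a synthetic predator-prey mass-pair table.

    Predator masses are log-uniform over ``predator_mass_range``; each
    prey mass is the predator mass times a log-normal ratio with the given
    median and log-space sigma (sigma 0 gives a degenerate, fixed ratio).
    Stands in for a carnivore-diet database of mean predator and prey
    masses.
    """

    n_predators: int = 54
    predator_mass_range: tuple[float, float] = (1.0, 300.0)
    ratio_median: float = 1.0
    ratio_sigma_log: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_predators < 1:
            raise ValueError("n_predators must be >= 1")
        lo, hi = self.predator_mass_range
        if not (0 < lo <= hi):
            raise ValueError("predator mass range must satisfy 0 < lo <= hi")
        if not self.ratio_median > 0 or self.ratio_sigma_log < 0:
            raise ValueError("ratio_median must be > 0 and ratio_sigma_log >= 0")


def make_species_table(recipe: SpeciesTableRecipe) -> pd.DataFrame:
    """Generate a species mass-pair table in the standard schema."""
    rng = np.random.default_rng(recipe.seed)
    lo, hi = recipe.predator_mass_range
    pred = 10.0 ** rng.uniform(np.log10(lo), np.log10(hi), recipe.n_predators)
    ratio = recipe.ratio_median * np.exp(
        rng.normal(0.0, recipe.ratio_sigma_log, recipe.n_predators)
    )
    return pd.DataFrame(
        {
            "predator_name": [f"predator_{i:03d}" for i in range(recipe.n_predators)],
            "predator_mass_kg": pred,
            "prey_mass_kg": pred * ratio,
        }
    )


def make_scenario_battery(
    t_react_grid: tuple[float, ...] = (0.3,),
    trigger_grid: tuple[float, ...] = (10.0,),
    speed_grid: tuple[tuple[float, float], ...] = ((20.0, 15.0),),
    mass: float = 30.0,
    turn_angle: float = math.pi / 2,
    initial_separation: float = 30.0,
    timestep: float = 0.01,
    max_duration: float = 15.0,
    escape_factor: float = 1e9,
) -> list[ChaseConfig]:
    """Cartesian product of chase configurations over parameter grids.

    Each config pairs equal-mass predator and prey running at fixed
    (overridden) speeds, with a single prey turn of ``turn_angle`` at the
    given trigger distance — the canonical single-turn gambit.  Varying
    one grid at a time reproduces the classic sensitivity panels:
    trigger distance, predator speed, and predator reaction time.
    """
    if not (t_react_grid and trigger_grid and speed_grid):
        raise ValueError("all parameter grids must be non-empty")
    configs = []
    for t_react, trigger, (v_pred, v_prey) in itertools.product(
        t_react_grid, trigger_grid, speed_grid
    ):
        pred = AnimalSpec(mass=mass, reaction_time=t_react, vmax_override=v_pred)
        prey = AnimalSpec(mass=mass, reaction_time=0.0, vmax_override=v_prey)
        configs.append(
            ChaseConfig(
                predator=pred,
                prey=prey,
                initial_separation=max(initial_separation, 1.5 * trigger),
                timestep=timestep,
                max_duration=max_duration,
                prey_turn_policy=(
                    PreyTurn(trigger_distance=trigger, angle=turn_angle),
                ),
                constant_speed=True,
                escape_factor=escape_factor,
            )
        )
    return configs
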