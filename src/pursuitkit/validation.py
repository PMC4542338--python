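"""Reusable model-validation batteries.

These routines bundle the package's standard self-checks — the
overshoot-sensitivity grid for the chase simulator and the recall/precision
benchmark for the turn detector — so that tests, scripts and notebooks all
run exactly the same protocol.
"""

from __future__ import annotations

import itertools
from dataclasses import replace

import numpy as np
import pandas as pd

from .pursuit import simulate_chase
from .synthetic import TraceRecipe, make_scenario_battery, make_trace, random_turn_schedule
from .turns import detect_turns

__all__ = [
    "overshoot_sensitivity_grid",
    "check_monotone",
    "detection_benchmark",
    "timestep_convergence",
]

#: Default 3x3x3 sensitivity grid: predator reaction time (s), prey turn
#: trigger distance (m) and predator speed (m/s, prey fixed at 15).  Chosen
#: so every cell yields a complete, classified predator response.
DEFAULT_T_REACT_GRID = (0.3, 0.6, 0.9)
DEFAULT_TRIGGER_GRID = (6.0, 10.0, 14.0)
DEFAULT_SPEED_GRID = ((18.0, 15.0), (19.0, 15.0), (20.0, 15.0))


def overshoot_sensitivity_grid(
    t_react_grid: tuple[float, ...] = DEFAULT_T_REACT_GRID,
    trigger_grid: tuple[float, ...] = DEFAULT_TRIGGER_GRID,
    speed_grid: tuple[tuple[float, float], ...] = DEFAULT_SPEED_GRID,
) -> pd.DataFrame:
    """Overshoot magnitude over a scenario grid.

    Runs the single-90°-turn gambit for every grid combination and records
    the predator's path excess (its response-window path minus the prey's
    turn path, m; positive = overshoot).  The model predicts the excess to
    grow with reaction time and predator speed and to shrink with trigger
    distance.
    """
    rows = []
    for t_react, trigger, (v_pred, v_prey) in itertools.product(
        t_react_grid, trigger_grid, speed_grid
    ):
        cfg = make_scenario_battery(
            t_react_grid=(t_react,),
            trigger_grid=(trigger,),
            speed_grid=((v_pred, v_prey),),
        )[0]
        result = simulate_chase(cfg)
        events = result.predator_events
        rows.append(
            {
                "t_react_s": t_react,
                "trigger_m": trigger,
                "v_pred": v_pred,
                "v_prey": v_prey,
                "path_excess_m": events[0].path_excess if events else np.nan,
                "classification": events[0].classification if events else None,
                "outcome": result.outcome,
            }
        )
    return pd.DataFrame(rows)


def check_monotone(grid: pd.DataFrame) -> dict[str, bool]:
    """Check the three predicted monotonicities on a sensitivity grid.

    Returns {axis: True/False} for overshoot increasing in reaction time,
    increasing in predator speed, and decreasing in trigger distance,
    holding the other two axes fixed.
    """
    def _axis(col: str, increasing: bool) -> bool:
        others = [c for c in ("t_react_s", "trigger_m", "v_pred") if c != col]
        for _, grp in grid.groupby(others):
            vals = grp.sort_values(col)["path_excess_m"].to_numpy()
            diffs = np.diff(vals)
            if np.any(diffs <= 0 if increasing else diffs >= 0):
                return False
        return True

    return {
        "t_react": _axis("t_react_s", increasing=True),
        "v_pred": _axis("v_pred", increasing=True),
        "trigger_distance": _axis("trigger_m", increasing=False),
    }


def detection_benchmark(
    n_traces: int = 100,
    seed: int = 0,
    n_turns: int = 4,
    match_tolerance: float = 0.5,
    recipe: TraceRecipe | None = None,
) -> dict[str, float]:
    """Recall and precision of the turn detector on synthetic traces.

    Each trace draws ``n_turns`` non-overlapping cornering episodes at
    random times (everything else from the default recipe), runs the
    default detector, and matches detections to ground-truth peak times
    within ``match_tolerance`` seconds (one-to-one, greedy in time).
    """
    base = recipe or TraceRecipe()
    hits = misses = false_alarms = 0
    for i in range(n_traces):
        trace_seed = seed * 100_003 + i
        rng = np.random.default_rng(trace_seed)
        schedule = random_turn_schedule(n_turns, base.duration, rng)
        trace = make_trace(replace(base, turn_schedule=schedule, seed=trace_seed))
        detected = detect_turns(trace)
        truth = list(trace.truth_turns)
        matched: set[int] = set()
        for det in detected:
            candidates = [
                j for j, tt in enumerate(truth)
                if abs(det.peak - tt) <= match_tolerance and j not in matched
            ]
            if candidates:
                matched.add(min(candidates, key=lambda j: abs(det.peak - truth[j])))
                hits += 1
            else:
                false_alarms += 1
        misses += len(truth) - len(matched)
    recall = hits / (hits + misses) if hits + misses else 1.0
    precision = hits / (hits + false_alarms) if hits + false_alarms else 1.0
    return {
        "recall": recall,
        "precision": precision,
        "n_traces": n_traces,
        "n_truth": hits + misses,
    }


def timestep_convergence(dt: float = 0.01) -> dict[str, float]:
    """Relative change in final separation when the timestep halves.

    Uses the canonical single-turn scenario (20 vs 15 m/s, 0.3 s reaction,
    90° turn triggered at 10 m).
    """
    cfg = make_scenario_battery(timestep=dt)[0]
    coarse = simulate_chase(cfg)
    fine = simulate_chase(replace(cfg, timestep=dt / 2))
    d0, d1 = coarse.distance[-1], fine.distance[-1]
    return {
        "final_distance_coarse": float(d0),
        "final_distance_fine": float(d1),
        "relative_change": float(abs(d0 - d1) / abs(d0)),
    }
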