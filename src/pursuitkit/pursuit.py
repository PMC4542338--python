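"""Planar predator-prey chase simulation for cursorial animals.

The chase is modelled in two stages on a flat, featureless plane:

* **Stage 1 — the rush.**  The predator accelerates from concealment toward
  a stationary prey following a speed-dependent tangential acceleration law
  ``a(v) = c1*v**c2``.  Once the predator comes within the prey's reaction
  distance the prey flees directly away (any other heading closes the gap
  faster when the predator is still distant).

* **Stage 2 — turning.**  As the gap closes the prey's only remaining
  option is to turn.  It does so on its own strength-limited minimum radius
  at its current speed.  The predator, after its reaction time, first turns
  toward the prey on *its* minimum radius until its velocity vector points
  at the prey, then reverts to pure pursuit (always heading at the prey's
  current position).

Because the predator is faster, its minimum turn radius at speed is larger
(r grows with v^2 and with mass^(1/3)), so a well-timed prey turn makes the
predator *overshoot* — carry past the corner and lose ground — while a
premature turn lets the predator *cut the corner* and gain.  Each predator
response is classified by comparing the path length it ran during its
response window against the path the prey ran during its turn.

Integration is fixed-step explicit Euler (default dt = 0.01 s) and fully
deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .allometry import AnimalSpec, min_turn_radius

__all__ = [
    "KinematicState",
    "StageOneGeometry",
    "PreyTurn",
    "ChaseConfig",
    "SimTurnEvent",
    "ChaseResult",
    "EnergeticsParams",
    "accel_from_speed",
    "heading_after_reaction",
    "stage1_rush",
    "simulate_chase",
    "predator_response",
    "classify_turn",
    "cumulative_energy",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_turn_events_csv",
]

#: Below this speed the power-law acceleration (which diverges at v = 0 for
#: negative exponents) is frozen at its v_floor value.
V_FLOOR = 0.1

#: Turn radii below this are treated as "instantaneous heading change".
_R_FLOOR = 1e-9


def wrap_angle(a: float) -> float:
    """Wrap an angle to (-pi, pi]."""
    a = (a + math.pi) % (2.0 * math.pi) - math.pi
    return math.pi if a == -math.pi else a


@dataclass
class KinematicState:
    """Position (m), speed (m/s) and heading (rad, CCW from +x) of one party."""

    x: float
    y: float
    v: float
    heading: float

    def __post_init__(self) -> None:
        if self.v < 0:
            raise ValueError(f"speed must be >= 0, got {self.v}")
        self.heading = wrap_angle(self.heading)


@dataclass(frozen=True)
class StageOneGeometry:
    """Geometry of the prey's first evasive move, seen from the predator.

    ``D`` is the predator-prey distance at the end of the predator's
    reaction time, ``theta`` the prey's escape angle relative to the
    predator's approach line, and ``s_prey`` the distance the prey covered
    during that reaction time.  ``s`` (initial concealment distance) and
    ``x`` (prey reaction distance) document the wider stage-1 setup.
    """

    D: float
    theta: float
    s_prey: float
    s: float = 0.0
    x: float = 0.0

    def __post_init__(self) -> None:
        for name in ("D", "s_prey", "s", "x"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def heading_after_reaction(geom: StageOneGeometry) -> float:
    """Bearing change (rad) of the prey seen at the predator.

    Planar sine-rule geometry for the triangle (predator, prey start, prey
    after moving ``s_prey`` at angle ``theta``) gives

        sin(phi) = (s_prey / D) * sin(theta).

    Zero when the prey flees straight away (theta = 0) or has not moved.
    """
    if geom.D <= 0:
        raise ValueError("D must be > 0")
    arg = (geom.s_prey / geom.D) * math.sin(geom.theta)
    if abs(arg) > 1.0:
        raise ValueError(
            f"inconsistent geometry: |s_prey/D * sin(theta)| = {abs(arg):.4f} > 1 "
            f"(s_prey={geom.s_prey}, D={geom.D}, theta={geom.theta})"
        )
    return math.asin(arg)


def accel_from_speed(spec: AnimalSpec, v: float) -> float:
    """Tangential acceleration (m/s^2) available at speed v (m/s).

    Evaluates ``c1 * v**c2`` with the power law frozen below
    ``V_FLOOR`` = 0.1 m/s (it diverges at v = 0 for c2 < 0) and clamped to
    zero at and above the animal's resolved top speed.
    """
    if v < 0:
        raise ValueError(f"speed must be >= 0, got {v}")
    if v >= spec.vmax:
        return 0.0
    c1, c2 = spec.accel_coeffs
    return c1 * max(v, V_FLOOR) ** c2


@dataclass(frozen=True)
class PreyTurn:
    """One entry of the prey's turn policy.

    The turn of ``angle`` rad (``direction`` "left" = CCW or "right" = CW)
    starts when the predator-prey distance first drops to
    ``trigger_distance`` — or at ``trigger_time`` seconds if that is given
    instead.
    """

    trigger_distance: float | None = None
    angle: float = math.pi / 2
    direction: str = "left"
    trigger_time: float | None = None

    def __post_init__(self) -> None:
        if (self.trigger_distance is None) == (self.trigger_time is None):
            raise ValueError("give exactly one of trigger_distance / trigger_time")
        if self.direction not in ("left", "right"):
            raise ValueError(f"direction must be 'left' or 'right', got {self.direction!r}")
        if not self.angle > 0:
            raise ValueError(f"angle must be > 0, got {self.angle}")

    @property
    def sign(self) -> int:
        return 1 if self.direction == "left" else -1


@dataclass(frozen=True)
class ChaseConfig:
    """Full definition of one chase scenario.

    With ``constant_speed`` (the default) both parties run at their
    resolved top speeds from t = 0, collinear and ``initial_separation``
    apart — the canonical stage-2 setup.  With ``constant_speed=False`` the
    predator accelerates from rest toward a prey that stays put until the
    gap drops to ``prey_reaction_distance``, then flees directly away,
    itself accelerating.
    """

    predator: AnimalSpec
    prey: AnimalSpec
    initial_separation: float = 30.0
    prey_reaction_distance: float | None = None
    timestep: float = 0.01
    capture_radius: float = 0.2
    max_duration: float = 30.0
    prey_turn_policy: tuple[PreyTurn, ...] = ()
    constant_speed: bool = True
    escape_factor: float = 2.0
    energy_budget: float | None = None
    energetics: "EnergeticsParams | None" = None

    def __post_init__(self) -> None:
        if not self.timestep > 0:
            raise ValueError(f"timestep must be > 0, got {self.timestep}")
        if self.capture_radius < 0:
            raise ValueError("capture_radius must be >= 0")
        if not self.initial_separation > 0:
            raise ValueError("initial_separation must be > 0")
        if not self.max_duration > 0:
            raise ValueError("max_duration must be > 0")
        if not self.escape_factor > 1:
            raise ValueError("escape_factor must be > 1")
        for turn in self.prey_turn_policy:
            if (turn.trigger_distance is not None
                    and turn.trigger_distance <= self.capture_radius):
                raise ValueError(
                    f"trigger_distance {turn.trigger_distance} must exceed "
                    f"capture_radius {self.capture_radius}"
                )

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        def _spec(s: AnimalSpec) -> dict:
            return {
                "mass": s.mass,
                "body_density": s.body_density,
                "strength_constant": s.strength_constant,
                "accel_coeffs": list(s.accel_coeffs),
                "reaction_time": s.reaction_time,
                "vmax_override": s.vmax_override,
            }

        return {
            "predator": _spec(self.predator),
            "prey": _spec(self.prey),
            "initial_separation": self.initial_separation,
            "prey_reaction_distance": self.prey_reaction_distance,
            "timestep": self.timestep,
            "capture_radius": self.capture_radius,
            "max_duration": self.max_duration,
            "prey_turn_policy": [
                {
                    "trigger_distance": t.trigger_distance,
                    "angle": t.angle,
                    "direction": t.direction,
                    "trigger_time": t.trigger_time,
                }
                for t in self.prey_turn_policy
            ],
            "constant_speed": self.constant_speed,
            "escape_factor": self.escape_factor,
            "energy_budget": self.energy_budget,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChaseConfig":
        def _spec(sd: dict) -> AnimalSpec:
            sd = dict(sd)
            if "accel_coeffs" in sd:
                sd["accel_coeffs"] = tuple(sd["accel_coeffs"])
            return AnimalSpec(**sd)

        d = dict(d)
        d["predator"] = _spec(d["predator"])
        d["prey"] = _spec(d["prey"])
        d["prey_turn_policy"] = tuple(
            PreyTurn(**t) for t in d.get("prey_turn_policy", ())
        )
        return cls(**d)


@dataclass
class SimTurnEvent:
    """One turn during a chase, by either party.

    Prey events describe the commanded arc.  Predator events describe the
    response window — from the prey's turn onset, through the reaction
    delay and the minimum-radius realignment — and carry a classification:

    * ``corner_cut`` — the predator's response path was shorter than the
      prey's turn path (inside line; gap closes faster),
    * ``overshoot`` — longer (carried past the corner; gap opens),
    * ``matched`` — equal within one integration step of path.

    ``path_excess`` is the signed difference predator-minus-prey in metres;
    ``delta_d`` the change in separation over the window.
    """

    party: str
    start: float
    end: float
    angle: float
    radius: float
    arc_length: float
    classification: str | None = None
    path_excess: float | None = None
    delta_d: float | None = None


@dataclass
class ChaseResult:
    """Sampled trajectories, separation series and events of one chase."""

    time: np.ndarray
    pred_xy: np.ndarray
    pred_v: np.ndarray
    pred_heading: np.ndarray
    prey_xy: np.ndarray
    prey_v: np.ndarray
    prey_heading: np.ndarray
    distance: np.ndarray
    turn_events: list[SimTurnEvent]
    outcome: str
    config: ChaseConfig
    pred_energy: np.ndarray | None = None
    prey_energy: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.time,
                "pred_x": self.pred_xy[:, 0],
                "pred_y": self.pred_xy[:, 1],
                "pred_v": self.pred_v,
                "prey_x": self.prey_xy[:, 0],
                "prey_y": self.prey_xy[:, 1],
                "prey_v": self.prey_v,
                "distance_m": self.distance,
            }
        )

    @property
    def predator_events(self) -> list[SimTurnEvent]:
        return [e for e in self.turn_events if e.party == "predator"]

    @property
    def prey_events(self) -> list[SimTurnEvent]:
        return [e for e in self.turn_events if e.party == "prey"]


@dataclass(frozen=True)
class EnergeticsParams:
    """Mass-specific locomotion cost model.

    Straight-line power is ``intercept + slope*v`` (J/kg/s with slope in
    J/kg per metre — the classic linear cost-of-transport law).  Turning
    adds a surcharge proportional to the centripetal-work proxy
    ``v**2/r * v = v**2 * |omega|`` per unit time.  The surcharge
    coefficient is dimensionless and qualitative: it orders corner-cutting
    versus overshooting chases but is not calibrated to any species.
    """

    slope: float = 4.0
    intercept: float = 2.0
    turn_surcharge: float = 1.0

    def __post_init__(self) -> None:
        if self.slope < 0 or self.intercept < 0 or self.turn_surcharge < 0:
            raise ValueError("energetics parameters must be >= 0")


# ---------------------------------------------------------------------------
# simulation internals


class _Party:
    """Mutable per-party integration state."""

    __slots__ = ("spec", "x", "y", "v", "heading", "path", "omega")

    def __init__(self, spec: AnimalSpec, x: float, y: float, v: float, heading: float):
        self.spec = spec
        self.x = x
        self.y = y
        self.v = v
        self.heading = heading
        self.path = 0.0  # cumulative path length, m
        self.omega = 0.0  # heading rate last step, rad/s

    def advance(self, dt: float, dh: float = 0.0) -> None:
        """Advance one step, turning by ``dh`` along the way.

        The position update uses the midpoint heading, which integrates a
        constant-rate turn (a circular arc) with second-order accuracy;
        the heading update is applied afterwards.
        """
        mid = self.heading + 0.5 * dh
        self.x += self.v * math.cos(mid) * dt
        self.y += self.v * math.sin(mid) * dt
        self.path += self.v * dt
        self.heading = wrap_angle(self.heading + dh)
        self.omega = dh / dt

    def accelerate(self, dt: float) -> None:
        a = accel_from_speed(self.spec, self.v)
        self.v = min(self.v + a * dt, self.spec.vmax)


def _classify(path_excess: float, tol: float) -> str:
    if path_excess > tol:
        return "overshoot"
    if path_excess < -tol:
        return "corner_cut"
    return "matched"


def classify_turn(
    pred_path_length: float, prey_path_length: float, tol: float
) -> str:
    """Classify one predator response from path lengths.

    ``pred_path_length`` is the distance the predator covered from the
    prey's turn onset to the end of its own realignment turn;
    ``prey_path_length`` the distance the prey covered during its turn arc.
    A shorter predator path means it took the inside line (``corner_cut``);
    a longer one means it carried past the corner (``overshoot``);
    agreement within ``tol`` metres is ``matched``.
    """
    if pred_path_length < 0 or prey_path_length < 0 or tol < 0:
        raise ValueError("path lengths and tolerance must be >= 0")
    return _classify(pred_path_length - prey_path_length, tol)


def simulate_chase(config: ChaseConfig) -> ChaseResult:
    """Run one chase to capture, escape or timeout.

    Fixed-step synchronous Euler integration.  The prey executes its turn
    policy; each prey turn triggers, after the predator's reaction time, a
    minimum-radius realignment by the predator followed by pure pursuit.
    Escape is declared when the separation exceeds ``escape_factor`` times
    its value at the most recent prey-turn onset (or the initial
    separation before any turn) — but never while the predator is still
    mid-response — or when the optional predator energy budget is spent.
    """
    dt = config.timestep
    spec_pred, spec_prey = config.predator, config.prey

    if config.constant_speed:
        pred = _Party(spec_pred, -config.initial_separation, 0.0, spec_pred.vmax, 0.0)
        prey = _Party(spec_prey, 0.0, 0.0, spec_prey.vmax, 0.0)
        prey_mode = "straight"
    else:
        pred = _Party(spec_pred, -config.initial_separation, 0.0, 0.0, 0.0)
        prey = _Party(spec_prey, 0.0, 0.0, 0.0, 0.0)
        prey_mode = "wait"

    pending = sorted(
        config.prey_turn_policy,
        key=lambda t: (-(t.trigger_distance or math.inf), t.trigger_time or 0.0),
    )
    pending = list(pending)

    # prey turning state
    prey_turn: PreyTurn | None = None
    prey_remaining = 0.0
    prey_event: SimTurnEvent | None = None

    # predator response state
    pred_mode = "pursue"  # pursue | locked | realign
    response_at = math.inf
    response_sign = 0
    pred_event: SimTurnEvent | None = None
    pred_event_path0 = 0.0
    pred_event_d0 = 0.0
    pred_event_angle = 0.0
    # (pred_path_at_realign_end, prey_turn_path_length) pairs awaiting both ends
    open_pair: dict = {}

    energetics = config.energetics or EnergeticsParams()
    e_pred = 0.0

    times, pxy, pv, ph, qxy, qv, qh, dist = [], [], [], [], [], [], [], []
    events: list[SimTurnEvent] = []
    tol = (spec_pred.vmax + spec_prey.vmax) * dt

    n_steps = int(round(config.max_duration / dt))
    d_ref = config.initial_separation
    outcome = "timeout"
    t = 0.0

    def _record() -> None:
        times.append(t)
        pxy.append((pred.x, pred.y))
        pv.append(pred.v)
        ph.append(pred.heading)
        qxy.append((prey.x, prey.y))
        qv.append(prey.v)
        qh.append(prey.heading)
        dist.append(math.hypot(prey.x - pred.x, prey.y - pred.y))

    def _finish_pair() -> None:
        """Classify once both the prey turn and predator realignment ended."""
        if "pred_len" in open_pair and "prey_len" in open_pair:
            ev = open_pair["event"]
            ev.path_excess = open_pair["pred_len"] - open_pair["prey_len"]
            ev.classification = _classify(ev.path_excess, tol)
            open_pair.clear()

    for _ in range(n_steps + 1):
        _record()
        d = dist[-1]

        if d <= config.capture_radius:
            outcome = "capture"
            break
        if (
            pred_mode == "pursue"
            and not open_pair
            and d > config.escape_factor * d_ref
        ):
            outcome = "escape"
            break
        if config.energy_budget is not None and e_pred > config.energy_budget:
            outcome = "escape"
            break

        bearing = math.atan2(prey.y - pred.y, prey.x - pred.x)

        # ---- prey decision ------------------------------------------------
        if prey_mode == "wait":
            if (config.prey_reaction_distance is None
                    or d <= config.prey_reaction_distance):
                prey_mode = "straight"
                prey.heading = bearing  # flee directly away, along the approach line
        if prey_mode == "straight" and pending and prey.v > 0:
            nxt = pending[0]
            triggered = (
                nxt.trigger_distance is not None and d <= nxt.trigger_distance
            ) or (nxt.trigger_time is not None and t >= nxt.trigger_time)
            if triggered:
                # a new prey turn interrupts any unfinished predator
                # response: close and classify the old event as-is
                if pred_event is not None:
                    pred_event.end = t
                    pred_event.angle = response_sign * pred_event_angle
                    pred_event.arc_length = pred_event_angle * pred_event.radius
                    pred_event.delta_d = d - pred_event_d0
                    events.append(pred_event)
                    open_pair["pred_len"] = pred.path - pred_event_path0
                    open_pair.setdefault("prey_len", 0.0)
                    _finish_pair()
                    pred_event = None
                open_pair.clear()

                prey_turn = pending.pop(0)
                prey_remaining = prey_turn.angle
                prey_mode = "turn"
                r0 = min_turn_radius(spec_prey, prey.v)
                prey_event = SimTurnEvent(
                    party="prey", start=t, end=math.nan,
                    angle=prey_turn.sign * prey_turn.angle,
                    radius=r0, arc_length=0.0,
                )
                # predator response is scheduled off the turn onset
                pred_mode = "locked"
                response_at = t + spec_pred.reaction_time
                response_sign = prey_turn.sign
                d_ref = d
                pred_event_path0 = pred.path
                pred_event_d0 = d
                pred_event_angle = 0.0
                pred_event = SimTurnEvent(
                    party="predator", start=t, end=math.nan,
                    angle=0.0, radius=min_turn_radius(spec_pred, pred.v),
                    arc_length=0.0,
                )
                open_pair["event"] = pred_event

        prey_dh = 0.0
        if prey_mode == "turn":
            r = min_turn_radius(spec_prey, prey.v)
            max_dh = prey.v * dt / r if r > _R_FLOOR else prey_remaining
            prey_dh = prey_turn.sign * min(max_dh, prey_remaining)
            prey_remaining -= abs(prey_dh)
            if prey_remaining <= 1e-12:
                prey_mode = "straight"
                prey_event.end = t + dt
                prey_event.arc_length = abs(prey_event.angle) * prey_event.radius
                events.append(prey_event)
                if open_pair:
                    open_pair["prey_len"] = prey_event.arc_length
                    _finish_pair()
                prey_event = None

        # ---- predator decision --------------------------------------------
        pred_dh = 0.0
        if pred_mode == "locked" and t >= response_at:
            err0 = wrap_angle(bearing - pred.heading)
            # already aimed at (or past) the prey on the turn side: skip the arc
            if err0 == 0.0 or (err0 > 0) != (response_sign > 0):
                pred_mode = "pursue"
                _close_pred = True
            else:
                pred_mode = "realign"
                _close_pred = False
            if _close_pred and pred_event is not None:
                pred_event.end = t
                pred_event.angle = response_sign * pred_event_angle
                pred_event.arc_length = pred_event_angle * pred_event.radius
                pred_event.delta_d = d - pred_event_d0
                events.append(pred_event)
                open_pair["pred_len"] = pred.path - pred_event_path0
                _finish_pair()
                pred_event = None

        if pred_mode == "realign":
            err = wrap_angle(bearing - pred.heading)
            r = min_turn_radius(spec_pred, pred.v)
            max_dh = pred.v * dt / r if r > _R_FLOOR else abs(err)
            done = abs(err) <= max_dh or (err > 0) != (response_sign > 0)
            # never change heading faster than the minimum radius allows
            pred_dh = max(-max_dh, min(max_dh, err)) if done \
                else response_sign * max_dh
            pred_event_angle += abs(pred_dh)
            if done:
                # velocity vector now points at (or has swept past) the
                # prey: realignment over, revert to pure pursuit
                pred_mode = "pursue"
                if pred_event is not None:
                    pred_event.end = t + dt
                    pred_event.angle = response_sign * pred_event_angle
                    pred_event.arc_length = pred_event_angle * pred_event.radius
                    pred_event.delta_d = d - pred_event_d0
                    events.append(pred_event)
                    open_pair["pred_len"] = pred.path - pred_event_path0 + pred.v * dt
                    _finish_pair()
                    pred_event = None
        elif pred_mode == "pursue":
            err = wrap_angle(bearing - pred.heading)
            r = min_turn_radius(spec_pred, pred.v)
            max_dh = pred.v * dt / r if r > _R_FLOOR else abs(err)
            pred_dh = max(-max_dh, min(max_dh, err))

        # ---- synchronous state advance ------------------------------------
        if not config.constant_speed:
            if prey_mode != "wait":
                prey.accelerate(dt)
            pred.accelerate(dt)
        prey.advance(dt, prey_dh)
        pred.advance(dt, pred_dh)
        if config.energy_budget is not None:
            e_pred += (
                energetics.intercept + energetics.slope * pred.v
            ) * dt + energetics.turn_surcharge * pred.v**2 * abs(pred.omega) * dt
        t += dt

        if not all(map(math.isfinite, (pred.x, pred.y, prey.x, prey.y))):
            raise FloatingPointError(
                f"non-finite state at t={t:.3f}s: pred=({pred.x}, {pred.y}) "
                f"prey=({prey.x}, {prey.y})"
            )

    # close any dangling events at termination
    if prey_event is not None:
        prey_event.end = t
        prey_event.arc_length = (abs(prey_event.angle) - prey_remaining) * prey_event.radius
        events.append(prey_event)
    if pred_event is not None:
        # response still in progress at termination: classify from the
        # partial window (the chase was decided mid-manoeuvre)
        pred_event.end = t
        pred_event.angle = response_sign * pred_event_angle
        pred_event.arc_length = pred_event_angle * pred_event.radius
        pred_event.delta_d = dist[-1] - pred_event_d0
        events.append(pred_event)
        open_pair["pred_len"] = pred.path - pred_event_path0
        open_pair.setdefault(
            "prey_len",
            (abs(prey_event.angle) - prey_remaining) * prey_event.radius
            if prey_event is not None else 0.0,
        )
        _finish_pair()

    events.sort(key=lambda e: (e.start, e.party))
    return ChaseResult(
        time=np.asarray(times),
        pred_xy=np.asarray(pxy),
        pred_v=np.asarray(pv),
        pred_heading=np.asarray(ph),
        prey_xy=np.asarray(qxy),
        prey_v=np.asarray(qv),
        prey_heading=np.asarray(qh),
        distance=np.asarray(dist),
        turn_events=events,
        outcome=outcome,
        config=config,
    )


def stage1_rush(config: ChaseConfig) -> ChaseResult:
    """Simulate the opening rush only: no prey turns, no predator response.

    The predator accelerates from rest toward the prey; the prey stays put
    until the separation drops to the reaction distance, then flees
    straight away.  A configuration whose reaction distance is not below
    the initial separation degenerates to an immediate flight (the stage-2
    handoff) — allowed, with a warning.
    """
    import warnings

    if (config.prey_reaction_distance is not None
            and config.prey_reaction_distance >= config.initial_separation):
        warnings.warn(
            "prey reaction distance >= initial separation: the prey flees "
            "immediately (stage-2 handoff)", stacklevel=2,
        )
    cfg = replace(config, prey_turn_policy=(), constant_speed=False)
    return simulate_chase(cfg)


def predator_response(
    state_pred: KinematicState,
    prey_track: tuple[np.ndarray, np.ndarray],
    t_react: float,
    spec: AnimalSpec,
    turn_sign: int | None = None,
    dt: float = 0.01,
) -> pd.DataFrame:
    """Integrate the predator's delayed response against a fixed prey track.

    The prey's positions are given as ``(times, xy)`` with ``xy`` of shape
    (n, 2); the prey's manoeuvre is taken to begin at ``times[0]``.  For
    ``t < times[0] + t_react`` the predator holds its heading; it then
    turns on its minimum radius toward the prey (side chosen from the
    bearing error at response time unless ``turn_sign`` forces it) until
    its velocity vector points at the prey, after which it heads at the
    prey's current position each step (pure pursuit).

    Returns a frame ``t_s, x, y, v, heading, mode``.
    """
    times, xy = np.asarray(prey_track[0], float), np.asarray(prey_track[1], float)
    if times.ndim != 1 or xy.shape != (times.size, 2):
        raise ValueError("prey_track must be (times[n], xy[n, 2])")
    if t_react < 0:
        raise ValueError("t_react must be >= 0")

    p = _Party(spec, state_pred.x, state_pred.y, state_pred.v, state_pred.heading)
    mode = "locked"
    sign = 0
    t0 = float(times[0])
    t_resp = t0 + t_react
    rows = []
    for t in np.arange(t0, float(times[-1]) + dt / 2, dt):
        prey_x = float(np.interp(t, times, xy[:, 0]))
        prey_y = float(np.interp(t, times, xy[:, 1]))
        bearing = math.atan2(prey_y - p.y, prey_x - p.x)
        err = wrap_angle(bearing - p.heading)
        dh = 0.0
        if mode == "locked" and t >= t_resp:
            if err == 0.0:
                mode = "pursue"
            else:
                sign = turn_sign if turn_sign is not None else (1 if err > 0 else -1)
                mode = "realign"
        if mode == "realign":
            r = min_turn_radius(spec, p.v)
            max_dh = p.v * dt / r if r > _R_FLOOR else abs(err)
            if abs(err) <= max_dh or (err > 0) != (sign > 0):
                dh = max(-max_dh, min(max_dh, err))
                mode = "pursue"
            else:
                dh = sign * max_dh
        elif mode == "pursue":
            r = min_turn_radius(spec, p.v)
            max_dh = p.v * dt / r if r > _R_FLOOR else abs(err)
            dh = max(-max_dh, min(max_dh, err))
        rows.append((t, p.x, p.y, p.v, p.heading, mode))
        p.advance(dt, dh)
    return pd.DataFrame(rows, columns=["t_s", "x", "y", "v", "heading", "mode"])


def cumulative_energy(
    result: ChaseResult,
    pred_params: EnergeticsParams | None = None,
    prey_params: EnergeticsParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mass-specific cumulative energy (J/kg) for both parties over the chase.

    Each step accrues straight-line cost ``(intercept + slope*v)*dt``; while
    a party is turning it additionally accrues
    ``surcharge * v**2 * |omega| * dt`` (the centripetal-work proxy
    ``(v**2/r)*v`` with ``r = v/|omega|``).  Both series are attached to
    ``result`` and returned; they are non-decreasing by construction.
    """
    pred_params = pred_params or EnergeticsParams()
    prey_params = prey_params or EnergeticsParams()

    def _series(v: np.ndarray, heading: np.ndarray, t: np.ndarray,
                p: EnergeticsParams) -> np.ndarray:
        dt = np.diff(t)
        omega = np.abs(np.diff(np.unwrap(heading))) / np.where(dt > 0, dt, 1.0)
        vmid = v[:-1]
        de = (p.intercept + p.slope * vmid) * dt + p.turn_surcharge * vmid**2 * omega * dt
        return np.concatenate([[0.0], np.cumsum(de)])

    e_pred = _series(result.pred_v, result.pred_heading, result.time, pred_params)
    e_prey = _series(result.prey_v, result.prey_heading, result.time, prey_params)
    result.pred_energy = e_pred
    result.prey_energy = e_prey
    return e_pred, e_prey


def energy_in_window(
    result: ChaseResult,
    t0: float,
    t1: float,
    party: str = "predator",
    params: EnergeticsParams | None = None,
) -> float:
    """Energy (J/kg) one party accrues between two chase times.

    Useful for comparing turn-response costs across scenarios that share
    the same prey path: the window is typically one predator response
    event (prey-turn onset to realignment end).
    """
    if t1 < t0:
        raise ValueError("need t1 >= t0")
    if result.pred_energy is None:
        cumulative_energy(result, params, params)
    series = result.pred_energy if party == "predator" else result.prey_energy
    e0, e1 = np.interp([t0, t1], result.time, series)
    return float(e1 - e0)


# ---------------------------------------------------------------------------
# trajectory / event I/O

_TRAJ_COLUMNS = ["t_s", "pred_x", "pred_y", "pred_v",
                 "prey_x", "prey_y", "prey_v", "distance_m"]


def write_trajectory_csv(result: ChaseResult, path: str | Path) -> None:
    result.to_frame().to_csv(path, index=False)


def read_trajectory_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory file missing columns: {missing}")
    return df


def write_turn_events_csv(events: Sequence[SimTurnEvent], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "party": e.party,
                "start_s": e.start,
                "end_s": e.end,
                "angle_rad": e.angle,
                "radius_m": e.radius,
                "arc_length_m": e.arc_length,
                "classification": e.classification or "",
                "path_excess_m": e.path_excess,
                "delta_d_m": e.delta_d,
            }
            for e in events
        ]
    ).to_csv(path, index=False)
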