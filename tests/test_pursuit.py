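"""Chase simulator: acceleration law, stage geometry, pursuit dynamics,
turn classification and energetics."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pursuitkit import (
    AnimalSpec,
    ChaseConfig,
    EnergeticsParams,
    KinematicState,
    PreyTurn,
    StageOneGeometry,
    accel_from_speed,
    classify_turn,
    cumulative_energy,
    heading_after_reaction,
    predator_response,
    simulate_chase,
    stage1_rush,
)
from pursuitkit.pursuit import (
    energy_in_window,
    read_trajectory_csv,
    wrap_angle,
    write_trajectory_csv,
)
from pursuitkit.synthetic import make_scenario_battery


class TestAccelFromSpeed:
    def test_power_law_instance_at_unit_speed(self):
        # the printed coefficients give exactly c1 at v = 1
        spec = AnimalSpec(mass=30.0, vmax_override=29.0)
        assert accel_from_speed(spec, 1.0) == pytest.approx(47.041, rel=1e-12)

    def test_power_law_at_4(self):
        # frozen from a by-hand evaluation of 47.041 * 4**(-0.945)
        spec = AnimalSpec(mass=30.0, vmax_override=29.0)
        assert accel_from_speed(spec, 4.0) == pytest.approx(12.69199, rel=1e-5)

    def test_zero_at_and_above_vmax(self):
        spec = AnimalSpec(mass=30.0, vmax_override=20.0)
        assert accel_from_speed(spec, 20.0) == 0.0
        assert accel_from_speed(spec, 25.0) == 0.0

    def test_low_speed_floor(self):
        spec = AnimalSpec(mass=30.0, vmax_override=20.0)
        assert accel_from_speed(spec, 0.0) == accel_from_speed(spec, 0.05)
        assert accel_from_speed(spec, 0.0) == accel_from_speed(spec, 0.1)


class TestHeadingAfterReaction:
    def test_straight_flight_no_bearing_change(self):
        assert heading_after_reaction(StageOneGeometry(D=30.0, theta=0.0, s_prey=5.0)) == 0.0

    def test_perpendicular_escape(self):
        # s_prey=3, D=30, 90°: sin(phi) = 0.1 -> 5.739°
        phi = heading_after_reaction(StageOneGeometry(D=30.0, theta=math.pi / 2, s_prey=3.0))
        assert math.degrees(phi) == pytest.approx(5.7392, abs=1e-3)

    def test_isoceles_limit(self):
        phi = heading_after_reaction(StageOneGeometry(D=10.0, theta=math.pi / 2, s_prey=10.0))
        assert phi == pytest.approx(math.pi / 2)

    def test_inconsistent_geometry_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            heading_after_reaction(StageOneGeometry(D=2.0, theta=math.pi / 2, s_prey=5.0))


@given(st.floats(-50.0, 50.0))
@settings(derandomize=True, max_examples=100)
def test_wrap_angle_range(a):
    w = wrap_angle(a)
    assert -math.pi < w <= math.pi
    assert math.isclose(math.sin(w), math.sin(a), abs_tol=1e-12)


def _straight_config(v_pred=20.0, v_prey=15.0, sep=30.0, **kw):
    pred = AnimalSpec(mass=30.0, reaction_time=0.3, vmax_override=v_pred)
    prey = AnimalSpec(mass=30.0, reaction_time=0.0, vmax_override=v_prey)
    return ChaseConfig(predator=pred, prey=prey, initial_separation=sep, **kw)


class TestStage1Rush:
    def test_stationary_prey_is_caught(self):
        cfg = _straight_config(constant_speed=False, prey_reaction_distance=0.0,
                               max_duration=20.0)
        res = stage1_rush(cfg)
        assert res.outcome == "capture"
        # the gap never opens while the prey stays put
        assert np.all(np.diff(res.distance) <= 1e-12)

    def test_predator_speed_reaches_top(self):
        cfg = _straight_config(constant_speed=False, prey_reaction_distance=0.0,
                               sep=100.0, max_duration=20.0)
        res = stage1_rush(cfg)
        assert np.all(np.diff(res.pred_v) >= -1e-12)
        assert res.pred_v.max() == pytest.approx(20.0, rel=1e-6)

    def test_fleeing_prey_linear_closure_at_top_speed(self):
        # both at constant top speed: D(t) drops linearly at v_pred - v_prey
        cfg = _straight_config(sep=50.0, max_duration=8.0)
        res = simulate_chase(cfg)
        slopes = np.diff(res.distance) / np.diff(res.time)
        assert np.allclose(slopes, -(20.0 - 15.0), atol=1e-9)

    def test_capture_time_matches_closed_form(self):
        cfg = _straight_config(sep=50.0, max_duration=15.0)
        res = simulate_chase(cfg)
        assert res.outcome == "capture"
        t_expected = (50.0 - cfg.capture_radius) / 5.0
        assert res.time[-1] == pytest.approx(t_expected, abs=0.05)

    @pytest.mark.parametrize("v_pred", [16.0, 18.0, 20.0])
    def test_gap_closure_scales_with_speed_surplus(self, v_pred):
        # time to close a fixed gap goes as 1/(v_pred - v_prey)
        cfg = _straight_config(v_pred=v_pred, sep=30.0, max_duration=40.0)
        res = simulate_chase(cfg)
        assert res.outcome == "capture"
        assert res.time[-1] * (v_pred - 15.0) == pytest.approx(
            30.0 - cfg.capture_radius, abs=0.1 * (v_pred - 15.0)
        )

    def test_handoff_warning_when_reaction_exceeds_separation(self):
        cfg = _straight_config(constant_speed=False, prey_reaction_distance=60.0,
                               sep=30.0, max_duration=1.0)
        with pytest.warns(UserWarning, match="stage-2"):
            stage1_rush(cfg)


class TestSimulateChase:
    def test_well_timed_turn_causes_transient_overshoot(self, single_turn_scenario):
        # a 90° turn at 10 m makes the gap rise before renewed closure
        res = simulate_chase(single_turn_scenario)
        i = np.searchsorted(res.time, res.prey_events[0].start)
        d_at_turn = res.distance[i]
        assert res.distance[i:].max() > d_at_turn + 1.0
        assert res.predator_events[0].classification == "overshoot"

    def test_premature_turn_is_corner_cut(self):
        # turning while the predator is still far lets it cut the corner
        cfg = make_scenario_battery(trigger_grid=(25.0,), initial_separation=40.0)[0]
        res = simulate_chase(cfg)
        ev = res.predator_events[0]
        assert ev.classification == "corner_cut"
        # no transient rise in separation
        i = np.searchsorted(res.time, res.prey_events[0].start)
        j = np.searchsorted(res.time, ev.end)
        assert res.distance[i:j + 1].max() <= res.distance[i] + 0.05
        # the gap shrinks faster than the straight-line counterfactual
        no_turn = simulate_chase(replace(cfg, prey_turn_policy=()))
        k = min(j, len(no_turn.distance) - 1)
        assert res.distance[k] < no_turn.distance[k]

    def test_overshoot_grows_with_reaction_time(self):
        excess = []
        for t_react in (0.5, 2.0):
            cfg = make_scenario_battery(t_react_grid=(t_react,))[0]
            res = simulate_chase(cfg)
            excess.append(res.predator_events[0].path_excess)
        assert excess[1] > excess[0] > 0

    def test_distance_series_physical(self, single_turn_scenario):
        res = simulate_chase(single_turn_scenario)
        dt = single_turn_scenario.timestep
        v_sum = single_turn_scenario.predator.vmax + single_turn_scenario.prey.vmax
        assert np.all(res.distance >= 0)
        assert np.all(np.abs(np.diff(res.distance)) <= v_sum * dt + 1e-9)

    def test_turn_event_arc_geometry(self, single_turn_scenario):
        for ev in simulate_chase(single_turn_scenario).turn_events:
            assert ev.end > ev.start
            assert ev.arc_length == pytest.approx(abs(ev.angle) * ev.radius, abs=1e-9)

    def test_equal_parties_zero_reaction_never_overshoot(self):
        spec = AnimalSpec(mass=30.0, reaction_time=0.0, vmax_override=15.0)
        cfg = ChaseConfig(
            predator=spec, prey=spec, initial_separation=12.0,
            prey_turn_policy=(PreyTurn(trigger_distance=11.0),),
            escape_factor=1e9, max_duration=10.0,
        )
        res = simulate_chase(cfg)
        assert all(e.classification != "overshoot" for e in res.predator_events)

    def test_alternating_multi_turn_policy(self):
        cfg = make_scenario_battery()[0]
        cfg = replace(
            cfg,
            prey_turn_policy=(
                PreyTurn(trigger_time=2.0, direction="left"),
                PreyTurn(trigger_time=6.0, direction="right"),
            ),
            max_duration=10.0,
        )
        res = simulate_chase(cfg)
        prey_ev = res.prey_events
        assert len(prey_ev) == 2
        assert prey_ev[0].angle > 0 > prey_ev[1].angle

    def test_timestep_convergence(self, single_turn_scenario):
        coarse = simulate_chase(single_turn_scenario)
        fine = simulate_chase(replace(single_turn_scenario, timestep=0.005))
        rel = abs(coarse.distance[-1] - fine.distance[-1]) / coarse.distance[-1]
        assert rel < 0.01

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="trigger_distance"):
            _straight_config(prey_turn_policy=(PreyTurn(trigger_distance=0.1),))
        with pytest.raises(ValueError, match="timestep"):
            _straight_config(timestep=0.0)


class TestClassifyTurn:
    def test_rules(self):
        assert classify_turn(30.0, 40.0, 0.5) == "corner_cut"
        assert classify_turn(50.0, 40.0, 0.5) == "overshoot"
        assert classify_turn(40.2, 40.0, 0.5) == "matched"

    def test_refuses_negative_window(self):
        with pytest.raises(ValueError):
            classify_turn(-1.0, 10.0, 0.5)


class TestPredatorResponse:
    def test_prey_dead_ahead_keeps_heading(self):
        spec = AnimalSpec(mass=30.0, vmax_override=20.0)
        t = np.arange(0.0, 2.0, 0.01)
        track = np.column_stack([30.0 + 15.0 * t, np.zeros_like(t)])
        out = predator_response(
            KinematicState(x=0.0, y=0.0, v=20.0, heading=0.0), (t, track), 0.3, spec
        )
        assert np.allclose(out["heading"], 0.0)

    def test_zero_radius_zero_reaction_shadows_prey(self):
        # the k->infinity limit degenerates to an exact pursuit curve; for a
        # prey moving straight ahead the predator shadows its track
        spec = AnimalSpec(mass=30.0, strength_constant=1e18, vmax_override=20.0)
        t = np.arange(0.0, 3.0, 0.01)
        track = np.column_stack([20.0 + 15.0 * t, np.zeros_like(t)])
        out = predator_response(
            KinematicState(x=0.0, y=0.0, v=20.0, heading=0.0), (t, track), 0.0, spec
        )
        assert np.allclose(out["y"], 0.0, atol=1e-9)

    def test_realign_turn_rate_is_v_over_r(self):
        # circular-motion oracle: during minimum-radius realignment the
        # heading rate magnitude equals v/r
        spec = AnimalSpec(mass=30.0, reaction_time=0.3, vmax_override=20.0)
        from pursuitkit import min_turn_radius

        r = min_turn_radius(spec, 20.0)
        t = np.arange(0.0, 4.0, 0.01)
        track = np.column_stack([20.0 * np.ones_like(t), 5.0 + 15.0 * t])
        out = predator_response(
            KinematicState(x=0.0, y=0.0, v=20.0, heading=0.0), (t, track), 0.3, spec
        )
        realign = out[out["mode"] == "realign"]
        omega = np.diff(realign["heading"]) / np.diff(realign["t_s"])
        assert np.allclose(np.abs(omega), 20.0 / r, rtol=1e-6)


class TestEnergetics:
    def test_equal_straight_chases_equal_totals(self):
        spec = AnimalSpec(mass=30.0, vmax_override=15.0)
        cfg = ChaseConfig(predator=spec, prey=spec, initial_separation=20.0,
                          max_duration=5.0, escape_factor=1e9)
        res = simulate_chase(cfg)
        params = EnergeticsParams(turn_surcharge=0.0)
        ep, eq = cumulative_energy(res, params, params)
        assert ep[-1] == pytest.approx(eq[-1], rel=1e-9)
        assert np.all(np.diff(ep) >= 0) and np.all(np.diff(eq) >= 0)

    def test_linearity_in_duration(self):
        cfg = _straight_config(v_pred=16.0, sep=200.0, max_duration=4.0,
                               escape_factor=1e9)
        short = simulate_chase(cfg)
        long = simulate_chase(replace(cfg, max_duration=8.0))
        es, _ = cumulative_energy(short)
        el, _ = cumulative_energy(long)
        assert el[-1] == pytest.approx(2.0 * es[-1], rel=1e-3)

    def test_overshoot_costs_predator_more_than_corner_cut(self):
        # same prey path, different reaction times: the overshooting
        # predator spends more over its response window
        configs = make_scenario_battery(t_react_grid=(0.3, 2.0), trigger_grid=(15.0,))
        energies = {}
        for cfg in configs:
            res = simulate_chase(cfg)
            ev = res.predator_events[0]
            energies[ev.classification] = energy_in_window(res, ev.start, ev.end)
        assert set(energies) == {"corner_cut", "overshoot"}
        assert energies["overshoot"] > energies["corner_cut"]


def test_config_and_trajectory_roundtrip(tmp_path, single_turn_scenario):
    import yaml

    d = single_turn_scenario.to_dict()
    text = yaml.safe_dump(d)
    back = ChaseConfig.from_dict(yaml.safe_load(text))
    assert back == single_turn_scenario

    res = simulate_chase(single_turn_scenario)
    path = tmp_path / "traj.csv"
    write_trajectory_csv(res, path)
    df = read_trajectory_csv(path)
    assert len(df) == len(res.time)
    assert df["distance_m"].iloc[0] == pytest.approx(res.distance[0])
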