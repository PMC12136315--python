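"""Speed-loop plant discretisation, PID laws and step metrics."""

import math

import numpy as np
import pytest

from pumptwin.motor_control import (
    BPNetwork,
    LoadSchedule,
    PIDState,
    PlantModel,
    SimulationTrace,
    bp_pid_step,
    default_bp_network,
    default_load_schedule,
    default_pid_gains,
    default_plant,
    pid_step,
    plant_step,
    run_experiment,
    step_metrics,
)


def test_plant_equilibrium_at_rest():
    model = PlantModel()
    assert plant_step(model, 0.0, 0.0, 0.0) == 0.0


def test_plant_single_step_closed_form():
    """One step with sample_time == time_constant reaches 1 - e^-1."""
    model = PlantModel(gain=1.0, time_constant=0.05, sample_time=0.0099)
    # use exact formula at arbitrary ratio instead: a = exp(-Ts/T)
    a = math.exp(-0.0099 / 0.05)
    assert plant_step(model, 0.0, 1.0, 0.0) == pytest.approx(1.0 - a, abs=1e-15)


def test_plant_discretisation_matches_continuous_response():
    """The ZOH discretisation equals 1 - e^(-t/T) at every sample to 1e-9."""
    model = PlantModel(gain=1.0, time_constant=0.05, sample_time=0.001)
    y = 0.0
    for k in range(1, 501):
        y = plant_step(model, y, 1.0, 0.0)
        t = k * model.sample_time
        assert y == pytest.approx(1.0 - math.exp(-t / model.time_constant), abs=1e-9)


def test_plant_converges_to_static_gain():
    model = PlantModel(gain=100.0, time_constant=0.05, sample_time=0.001)
    y = 0.0
    for _ in range(350):  # 7 time constants
        y = plant_step(model, y, 2.0, 0.0)
    assert y == pytest.approx(200.0, rel=1e-3)


def test_plant_rejects_coarse_sampling():
    with pytest.raises(ValueError):
        PlantModel(time_constant=0.01, sample_time=0.01)


def test_pid_zero_gains_keep_output():
    state = PIDState(kp=0, ki=0, kd=0, u=1.5)
    assert pid_step(state, 100.0, 0.0) == 1.5


def test_pid_first_step_proportional_increment():
    state = PIDState(kp=1.0, ki=0.0, kd=0.0, u_min=-100, u_max=100)
    assert pid_step(state, 5.0, 0.0) == pytest.approx(5.0)


def test_pid_output_clamped():
    state = PIDState(kp=10.0, ki=0.0, kd=0.0, u_min=0.0, u_max=2.0)
    assert pid_step(state, 1000.0, 0.0) == 2.0


def test_p_only_loop_reaches_loop_gain_steady_state():
    """Pure-P incremental loop settles at kp*G/(1+kp*G) of the setpoint."""
    model = PlantModel(gain=100.0, time_constant=0.05, sample_time=0.001)
    kp = 0.05
    loads = LoadSchedule(steps=((0.0, 0.0),))
    trace = run_experiment(
        model, "pid", 1000.0, loads, 1.0, gains=(kp, 0.0, 0.0),
        u_min=-1e9, u_max=1e9,  # unclamped: the closed form assumes no saturation
    )
    expected = kp * model.gain / (1 + kp * model.gain) * 1000.0
    assert trace.speed[-1] == pytest.approx(expected, rel=0.005)


def test_integral_action_removes_steady_state_error():
    model = default_plant()
    loads = LoadSchedule(steps=((0.0, 1.0),))
    trace = run_experiment(model, "pid", 1000.0, loads, 0.5)  # 10 time constants
    assert abs(trace.speed[-1] - 1000.0) / 1000.0 < 0.001


def test_bp_pid_no_learning_degenerates_to_fixed_pid():
    """With a zero learning rate the adaptive loop is bit-identical to a
    fixed-gain PID at the network's initial gains."""
    model = default_plant()
    loads = LoadSchedule(steps=((0.0, 1.0),))
    net = BPNetwork(learning_rate=0.0, seed=0)
    tr_adaptive = run_experiment(model, "bp_pid", 1000.0, loads, 0.3, network=net)
    assert np.unique(tr_adaptive.kp).size == 1
    gains = (tr_adaptive.kp[0], tr_adaptive.ki[0], tr_adaptive.kd[0])
    tr_fixed = run_experiment(model, "pid", 1000.0, loads, 0.3, gains=gains)
    assert np.array_equal(tr_adaptive.speed, tr_fixed.speed)
    assert np.array_equal(tr_adaptive.control, tr_fixed.control)


def test_bp_zero_output_weights_emit_half_ceilings():
    net = BPNetwork(seed=1, kp_max=2.0, ki_max=0.5, kd_max=0.1)
    net.w_ho[:] = 0.0
    _, _, _, gains = net.forward(1000.0, 0.0, 1000.0)
    assert gains == pytest.approx([1.0, 0.25, 0.05])


def test_bp_gains_respect_ceilings_throughout_default_run():
    model = default_plant()
    trace = run_experiment(model, "bp_pid", 1000.0, default_load_schedule(), 1.0, seed=0)
    net = default_bp_network()
    assert np.all(trace.kp >= 0) and np.all(trace.kp <= net.ceilings[0])
    assert np.all(trace.ki >= 0) and np.all(trace.ki <= net.ceilings[1])
    assert np.all(trace.kd >= 0) and np.all(trace.kd <= net.ceilings[2])


def test_default_comparison_adaptive_beats_fixed():
    """On the shipped load-step scenario the adaptive controller has no
    larger overshoot and no slower disturbance recovery than the fixed
    tuning (the packaged stand-in for the bench waveform comparison)."""
    model = default_plant()
    loads = default_load_schedule()
    tr_pid = run_experiment(model, "pid", 1000.0, loads, 1.0)
    tr_bp = run_experiment(model, "bp_pid", 1000.0, loads, 1.0, seed=0)
    m_pid = step_metrics(tr_pid, 1000.0, disturbance_time=0.5)
    m_bp = step_metrics(tr_bp, 1000.0, disturbance_time=0.5)
    assert m_bp.overshoot <= m_pid.overshoot
    assert m_bp.disturbance_recovery_time <= m_pid.disturbance_recovery_time


def test_shortened_scenario_supported():
    """0.1 s duration with the load stepping at 5 ms runs and stays finite."""
    model = default_plant()
    loads = LoadSchedule(steps=((0.0, 1.0), (0.005, 1.5)))
    trace = run_experiment(model, "bp_pid", 1000.0, loads, 0.1, seed=0)
    assert np.all(np.isfinite(trace.speed))
    assert len(trace.time) == 100


def test_zero_gain_pid_speed_stays_at_load_offset():
    model = default_plant()
    loads = LoadSchedule(steps=((0.0, 0.0),))
    trace = run_experiment(model, "pid", 1000.0, loads, 0.1, gains=(0.0, 0.0, 0.0))
    assert np.all(trace.speed == 0.0)


def test_run_experiment_deterministic_under_seed():
    model = default_plant()
    loads = LoadSchedule(steps=((0.0, 1.0),))
    t1 = run_experiment(model, "bp_pid", 1000.0, loads, 0.3, seed=5)
    t2 = run_experiment(model, "bp_pid", 1000.0, loads, 0.3, seed=5)
    assert np.array_equal(t1.speed, t2.speed)
    assert np.array_equal(t1.kp, t2.kp)


def test_load_schedule_validation():
    with pytest.raises(ValueError):
        LoadSchedule(steps=((0.1, 1.0),))  # must start at 0
    with pytest.raises(ValueError):
        LoadSchedule(steps=((0.0, 1.0), (0.0, 1.5)))  # strictly increasing


def _synthetic_trace(speeds, dt=0.001):
    n = len(speeds)
    t = (np.arange(n) + 1) * dt
    z = np.zeros(n)
    return SimulationTrace(
        time=t, setpoint=np.full(n, 1.0), speed=np.asarray(speeds, dtype=float),
        control=z, load=z, kp=z, ki=z, kd=z,
    )


def test_metrics_monotone_convergence_has_zero_overshoot():
    speeds = 1.0 - np.exp(-np.linspace(0, 10, 1000))
    m = step_metrics(_synthetic_trace(speeds), 1.0)
    assert m.overshoot == 0.0


def test_metrics_peak_20_percent():
    speeds = np.concatenate([np.linspace(0, 1.2, 50), np.full(200, 1.0)])
    m = step_metrics(_synthetic_trace(speeds), 1.0)
    assert m.overshoot == pytest.approx(20.0, abs=1e-9)


def test_metrics_settling_matches_first_order_closed_form():
    """An analytic first-order trace settles in -T*ln(0.02), within one sample."""
    dt, T = 0.001, 0.05
    t = (np.arange(1, 1001)) * dt
    speeds = 1.0 - np.exp(-t / T)
    m = step_metrics(_synthetic_trace(speeds, dt), 1.0)
    assert m.overshoot == 0.0
    assert m.settling_time == pytest.approx(-T * math.log(0.02), abs=dt + 1e-12)


def test_metrics_never_settles_reports_infinity():
    speeds = np.tile([0.0, 2.0], 100)  # oscillates forever
    m = step_metrics(_synthetic_trace(speeds), 1.0)
    assert math.isinf(m.settling_time)
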