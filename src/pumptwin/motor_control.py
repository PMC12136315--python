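"""Discrete-time brushless-DC-motor speed loop with fixed and adaptive PID.

The motor's speed-vs-voltage behaviour is approximated by a first-order
lag y_dot = (gain*u - load_gain*load - y)/T, discretised exactly under a
zero-order hold:

    y[k+1] = a*y[k] + (1 - a)*(gain*u[k] - load_gain*load[k]),
    a = exp(-Ts/T).

Two speed controllers are provided:

* a fixed-gain incremental (velocity-form) PID,
  du = kp*(e - e1) + ki*e + kd*(e - 2*e1 + e2), with output clamping;
* a BP-PID controller in which a small 4-input perceptron (setpoint,
  measurement, error, bias -> tanh hidden layer -> sigmoid outputs
  scaled by per-gain ceilings) emits kp/ki/kd at every step and is
  trained online by gradient descent with momentum, using the sign of
  the plant Jacobian dy/du as a surrogate for its value.

``run_experiment`` drives either controller through a load-step scenario
(e.g. 1 N.m stepping to 1.5 N.m mid-run) and ``step_metrics`` extracts
overshoot, 2%-band settling time, disturbance recovery time and
steady-state error from the resulting trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PlantModel",
    "LoadSchedule",
    "PIDState",
    "BPNetwork",
    "SimulationTrace",
    "StepResponseMetrics",
    "AdaptationDivergedError",
    "plant_step",
    "pid_step",
    "bp_pid_step",
    "run_experiment",
    "step_metrics",
    "default_plant",
    "default_pid_gains",
    "default_bp_network",
    "default_load_schedule",
]


class AdaptationDivergedError(RuntimeError):
    """Raised when online gain adaptation produces non-finite weights."""


@dataclass(frozen=True)
class PlantModel:
    """First-order speed-vs-voltage lag with additive load disturbance."""

    gain: float = 100.0  # rpm per volt
    time_constant: float = 0.05  # s
    sample_time: float = 0.001  # s
    load_gain: float = 800.0  # rpm drop per N.m of load torque (open loop, steady state)

    def __post_init__(self) -> None:
        if self.time_constant <= 0 or self.sample_time <= 0:
            raise ValueError("time_constant and sample_time must be > 0")
        if self.sample_time >= self.time_constant / 5:
            raise ValueError(
                "sample_time must be < time_constant/5 for a meaningful discretisation"
            )

    @property
    def decay(self) -> float:
        return math.exp(-self.sample_time / self.time_constant)


@dataclass(frozen=True)
class LoadSchedule:
    """Piecewise-constant load torque: ordered (time_s, torque_Nm) steps."""

    steps: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        times = [t for t, _ in self.steps]
        if not times or times[0] != 0.0:
            raise ValueError("load schedule must start at t=0")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("load schedule times must be strictly increasing")

    def torque_at(self, t: float) -> float:
        torque = self.steps[0][1]
        for ts, tq in self.steps:
            if t >= ts:
                torque = tq
            else:
                break
        return torque


@dataclass
class PIDState:
    """Incremental-PID state: gains, error history and clamped output."""

    kp: float
    ki: float
    kd: float
    e_prev: float = 0.0
    e_prev2: float = 0.0
    u: float = 0.0
    u_min: float = 0.0
    u_max: float = 24.0

    def __post_init__(self) -> None:
        if self.u_min >= self.u_max:
            raise ValueError("u_min must be < u_max")


def plant_step(model: PlantModel, state_speed: float, u: float, load: float) -> float:
    """One exact zero-order-hold step of the first-order speed lag."""
    a = model.decay
    forced = model.gain * u - model.load_gain * load
    return a * state_speed + (1.0 - a) * forced


def pid_step(state: PIDState, setpoint: float, measurement: float) -> float:
    """Incremental PID update; mutates state, returns the clamped output."""
    e = setpoint - measurement
    du = (
        state.kp * (e - state.e_prev)
        + state.ki * e
        + state.kd * (e - 2.0 * state.e_prev + state.e_prev2)
    )
    state.u = min(max(state.u + du, state.u_min), state.u_max)
    state.e_prev2 = state.e_prev
    state.e_prev = e
    return state.u


class BPNetwork:
    """3-layer perceptron emitting live PID gains (the BP-PID scheme).

    Inputs are [setpoint, measurement, error, 1], normalised by a fixed
    scale so the tanh hidden layer is not saturated by rpm-magnitude
    signals.  Outputs pass through a sigmoid and are scaled by per-gain
    ceilings, so the emitted gains always lie in [0, ceiling].  Online
    training minimises the squared tracking error, propagating through
    the incremental-PID law and a sign-of-Jacobian surrogate for the
    plant sensitivity dy/du.
    """

    def __init__(
        self,
        hidden_size: int = 5,
        learning_rate: float = 0.3,
        momentum: float = 0.05,
        kp_max: float = 1.0,
        ki_max: float = 0.2,
        kd_max: float = 0.0,  # differential ceiling 0: derivative action disabled
        input_scale: float = 1000.0,
        seed: int | None = 0,
    ) -> None:
        if hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")
        self.input_size = 4
        self.hidden_size = hidden_size
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.ceilings = np.array([kp_max, ki_max, kd_max], dtype=float)
        self.input_scale = input_scale
        rng = np.random.default_rng(seed)
        self.w_ih = rng.uniform(-0.5, 0.5, size=(hidden_size, self.input_size))
        self.w_ho = rng.uniform(-0.5, 0.5, size=(3, hidden_size))
        self._dw_ih = np.zeros_like(self.w_ih)
        self._dw_ho = np.zeros_like(self.w_ho)
        self._frozen: tuple | None = None

    def forward(self, setpoint: float, measurement: float, error: float):
        # with the learning rate at zero the controller is static: the gain
        # schedule freezes at its first evaluation, so the loop degenerates
        # exactly to a fixed-gain PID with those gains
        if self.learning_rate == 0.0 and self._frozen is not None:
            return self._frozen
        x = np.array(
            [setpoint / self.input_scale, measurement / self.input_scale,
             error / self.input_scale, 1.0]
        )
        h = np.tanh(self.w_ih @ x)
        o = 1.0 / (1.0 + np.exp(-(self.w_ho @ h)))  # in (0,1)
        gains = self.ceilings * o
        if self.learning_rate == 0.0:
            self._frozen = (x, h, o, gains)
        return x, h, o, gains

    def backward(
        self,
        x: np.ndarray,
        h: np.ndarray,
        o: np.ndarray,
        error: float,
        e_prev: float,
        e_prev2: float,
        jacobian_sign: float,
    ) -> None:
        """One gradient-descent-with-momentum step on the squared error."""
        s = self.input_scale
        # sensitivity of the PID increment to each gain (normalised errors)
        du_dk = np.array(
            [(error - e_prev) / s, error / s,
             (error - 2.0 * e_prev + e_prev2) / s]
        )
        delta_o = (error / s) * jacobian_sign * du_dk * self.ceilings * o * (1.0 - o)
        delta_h = (self.w_ho.T @ delta_o) * (1.0 - h**2)
        self._dw_ho = self.learning_rate * np.outer(delta_o, h) + self.momentum * self._dw_ho
        self._dw_ih = self.learning_rate * np.outer(delta_h, x) + self.momentum * self._dw_ih
        self.w_ho += self._dw_ho
        self.w_ih += self._dw_ih
        if not (np.all(np.isfinite(self.w_ho)) and np.all(np.isfinite(self.w_ih))):
            raise AdaptationDivergedError("BP-PID weight update produced non-finite values")


def bp_pid_step(
    net: BPNetwork,
    state: PIDState,
    setpoint: float,
    measurement: float,
    jacobian_sign: float = 1.0,
    *,
    learn: bool = True,
) -> tuple[float, float, float, float]:
    """One adaptive step: emit gains, apply the PID law, update weights.

    Returns (u, kp, ki, kd).
    """
    e = setpoint - measurement
    x, h, o, gains = net.forward(setpoint, measurement, e)
    state.kp, state.ki, state.kd = float(gains[0]), float(gains[1]), float(gains[2])
    e_prev, e_prev2 = state.e_prev, state.e_prev2
    u = pid_step(state, setpoint, measurement)
    if learn and net.learning_rate != 0.0:
        net.backward(x, h, o, e, e_prev, e_prev2, jacobian_sign)
    return u, state.kp, state.ki, state.kd


@dataclass(frozen=True)
class SimulationTrace:
    """Equal-length time series from one speed-loop experiment."""

    time: np.ndarray
    setpoint: np.ndarray
    speed: np.ndarray
    control: np.ndarray
    load: np.ndarray
    kp: np.ndarray
    ki: np.ndarray
    kd: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("setpoint", "speed", "control", "load", "kp", "ki", "kd"):
            if len(getattr(self, name)) != n:
                raise ValueError("trace series must have equal lengths")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("trace time must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "setpoint_rpm": self.setpoint,
                "speed_rpm": self.speed,
                "u_V": self.control,
                "load_Nm": self.load,
                "kp": self.kp,
                "ki": self.ki,
                "kd": self.kd,
            }
        )


@dataclass(frozen=True)
class StepResponseMetrics:
    overshoot: float  # percent of setpoint
    settling_time: float  # s; inf if the 2% band is never held
    disturbance_recovery_time: float  # s; inf / nan if not applicable
    steady_state_error: float  # rpm


def default_plant() -> PlantModel:
    return PlantModel()


def default_pid_gains() -> tuple[float, float, float]:
    """Fixed-gain tuning of the shipped comparison scenario (kp, ki, kd)."""
    return (0.02, 0.03, 0.0)


def default_bp_network(seed: int = 0) -> BPNetwork:
    return BPNetwork(seed=seed)


def default_load_schedule() -> LoadSchedule:
    """1 N.m from start, stepping to 1.5 N.m at 0.5 s."""
    return LoadSchedule(steps=((0.0, 1.0), (0.5, 1.5)))


def run_experiment(
    model: PlantModel,
    controller: Literal["pid", "bp_pid"],
    setpoint: float,
    loads: LoadSchedule,
    duration: float,
    *,
    gains: tuple[float, float, float] | None = None,
    network: BPNetwork | None = None,
    seed: int = 0,
    u_min: float = 0.0,
    u_max: float = 24.0,
) -> SimulationTrace:
    """Simulate the closed speed loop through a load schedule.

    Deterministic given the seed (which initialises the BP network when
    one is not supplied).  The fixed-gain branch uses ``gains`` or the
    shipped default tuning.
    """
    if duration < loads.steps[-1][0]:
        raise ValueError("duration must cover the load schedule")
    n = int(round(duration / model.sample_time))
    if controller == "pid":
        kp, ki, kd = gains if gains is not None else default_pid_gains()
        state = PIDState(kp=kp, ki=ki, kd=kd, u_min=u_min, u_max=u_max)
        net = None
    elif controller == "bp_pid":
        net = network if network is not None else default_bp_network(seed=seed)
        state = PIDState(kp=0.0, ki=0.0, kd=0.0, u_min=u_min, u_max=u_max)
    else:
        raise ValueError(f"unknown controller {controller!r}")

    t = np.arange(n) * model.sample_time
    speed = np.empty(n)
    control = np.empty(n)
    load = np.empty(n)
    kp_s = np.empty(n)
    ki_s = np.empty(n)
    kd_s = np.empty(n)

    y = 0.0  # current speed y_k
    y_prev = 0.0  # y_{k-1}
    u_prev = 0.0  # u_{k-1}
    u_prev2 = 0.0  # u_{k-2}
    for k in range(n):
        lk = loads.torque_at(t[k])
        if net is None:
            u = pid_step(state, setpoint, y)
        else:
            # sign of dy/du estimated from the last two samples, eps-guarded
            du_obs = u_prev - u_prev2
            dy_obs = y - y_prev
            if abs(du_obs) > 1e-9 and abs(dy_obs) > 1e-9:
                jac = math.copysign(1.0, dy_obs / du_obs)
            else:
                jac = 1.0
            u, _, _, _ = bp_pid_step(net, state, setpoint, y, jacobian_sign=jac)
        y_prev = y
        u_prev2 = u_prev
        u_prev = u
        y = plant_step(model, y, u, lk)
        speed[k] = y
        control[k] = u
        load[k] = lk
        kp_s[k] = state.kp
        ki_s[k] = state.ki
        kd_s[k] = state.kd

    return SimulationTrace(
        time=t + model.sample_time,
        setpoint=np.full(n, float(setpoint)),
        speed=speed,
        control=control,
        load=load,
        kp=kp_s,
        ki=ki_s,
        kd=kd_s,
    )


def step_metrics(
    trace: SimulationTrace,
    setpoint: float,
    disturbance_time: float | None = None,
    band: float = 0.02,
) -> StepResponseMetrics:
    """Overshoot, 2%-band settling, disturbance recovery and final error.

    Settling is measured on the segment before ``disturbance_time`` (or
    the whole trace when no disturbance is given): the first time the
    speed enters the +/-band of the setpoint and stays there.  Recovery
    is the time from the disturbance until the speed re-enters the band
    and stays until the end of the trace.  Times that never occur are
    reported as +inf.
    """
    if len(trace.time) == 0:
        raise ValueError("empty trace")
    speed = trace.speed
    time = trace.time
    overshoot = max(0.0, float(np.max(speed)) - setpoint) / setpoint * 100.0
    tol = band * abs(setpoint)

    def first_hold(idx: np.ndarray) -> float:
        """Earliest time from which |speed-setpoint| <= tol holds to the end of idx."""
        inside = np.abs(speed[idx] - setpoint) <= tol
        if not inside[-1]:
            return math.inf
        # last index where the trace is outside the band
        outside = np.nonzero(~inside)[0]
        k = 0 if len(outside) == 0 else outside[-1] + 1
        return float(time[idx][k])

    if disturbance_time is None:
        pre = np.arange(len(time))
        settling = first_hold(pre)
        recovery = math.inf
    else:
        pre = np.nonzero(time < disturbance_time)[0]
        post = np.nonzero(time >= disturbance_time)[0]
        settling = first_hold(pre) if len(pre) else math.inf
        recovery = (first_hold(post) - disturbance_time) if len(post) else math.inf

    tail = speed[-max(1, len(speed) // 20):]
    sse = float(abs(setpoint - np.mean(tail)))
    return StepResponseMetrics(
        overshoot=overshoot,
        settling_time=settling,
        disturbance_recovery_time=recovery,
        steady_state_error=sse,
    )
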