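"""Closed-loop stochastic simulation of the tightrope balancer.

The equation of motion

    J q̈ = T_g(q) − T_s(q, q̇) − T_int(q_δ, q̇_δ) + w_n

is integrated with the forward Euler method at a fixed step (1 ms by
default): the velocity update uses the acceleration at the current step
and the position update uses the pre-update velocity.  ``T_int`` is the
intermittent control torque, a function of the state delayed by δ; the
delay is realized by reading the recorded state exactly round(δ/dt)
samples back (the initial state is returned while the buffer fills, so
both controllers start in the off-phase).  ``w_n`` is a zero-mean white
Gaussian torque disturbance, one independent sample per axis per step.

The whole closed loop — switching cones, PD laws, gravity, stiffness and
the smoothing filter — is positively homogeneous of degree 1: scaling the
realized noise sequence by c > 0 scales every continuous signal by exactly
c and leaves the on/off switching pattern unchanged.  All dimensionless
statistics reported by :mod:`tightrope.metrics` (duty cycles, pulse rates,
correlations, range ratios, spectral peak location) are therefore
invariant to the noise amplitude, which the model does not pin down.

The per-step arithmetic lives in :func:`_core_loop`, compiled with numba;
its uncompiled ``py_func`` is the pure-Python reference used in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from numba import njit

from .control import ComsParams, CopsParams, filter_discretization
from .mechanics import (
    G_GRAVITY,
    AnkleImpedance,
    BalancePole,
    BodyAnthropometry,
    InertiaTensor,
    SwayState,
    TorquePair,
    global_inertia,
)

#: default white torque-noise SD per axis per Euler step, N m.  Calibrated so
#: that the antero-posterior CoP range (±2σ) of the default configuration is
#: ≈ ±16 mm, a typical quiet-standing value; every dimensionless statistic is
#: invariant to this choice (see module docstring).
DEFAULT_NOISE_SD = 17.63

TRAJECTORY_COLUMNS = [
    "t", "q_ap", "q_ml", "qd_ap", "qd_ml",
    "T_ap", "T_s", "G_ap", "G_ml", "T_ml",
    "gamma", "dx_p", "on_ap", "on_ml", "y_cop", "y_com",
]


@dataclass(frozen=True)
class SimConfig:
    """Everything needed to reproduce one run."""

    dt: float = 0.001  # s
    duration: float = 240.0  # s
    seed: int = 1
    noise_sd: float = DEFAULT_NOISE_SD  # N m per axis per step
    initial_state: SwayState = field(default_factory=SwayState)
    body: BodyAnthropometry = field(default_factory=BodyAnthropometry)
    pole: BalancePole = field(default_factory=BalancePole)
    ankle: AnkleImpedance = field(default_factory=AnkleImpedance)
    cops: CopsParams = field(default_factory=CopsParams)
    coms: ComsParams = field(default_factory=ComsParams)
    warmup_discard: float = 10.0  # s excluded from statistics
    fall_threshold: float = 0.26  # rad, ≈ 15 deg
    coms_include_tilt_term: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not self.duration > self.warmup_discard >= 0:
            raise ValueError("need duration > warmup_discard >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=int(seed))


class DelayBuffer:
    """Ring buffer returning the state exactly round(delta/dt) steps back;
    yields the initial state until filled."""

    def __init__(self, delta: float, dt: float, initial: SwayState):
        self.lag = int(round(delta / dt))
        self._store = [initial] * max(self.lag, 1)
        self._i = 0

    def push_and_read(self, state: SwayState) -> SwayState:
        """Append the current state, return the state ``lag`` steps earlier."""
        if self.lag == 0:
            return state
        delayed = self._store[self._i]
        self._store[self._i] = state
        self._i = (self._i + 1) % self.lag
        return delayed


@dataclass
class Trajectory:
    """Uniform-grid record of one run (arrays of length n_steps+1, possibly
    truncated if the state became non-finite)."""

    config: SimConfig
    t: np.ndarray
    q_ap: np.ndarray
    q_ml: np.ndarray
    qd_ap: np.ndarray
    qd_ml: np.ndarray
    T_ap: np.ndarray
    T_s: np.ndarray
    G_ap: np.ndarray
    G_ml: np.ndarray
    T_ml: np.ndarray
    gamma: np.ndarray
    dx_p: np.ndarray
    on_ap: np.ndarray
    on_ml: np.ndarray
    y_cop: np.ndarray
    y_com: np.ndarray
    aborted: bool = False  # state became non-finite before the horizon

    @property
    def dt(self) -> float:
        return self.config.dt

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({c: getattr(self, c) for c in TRAJECTORY_COLUMNS})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# single-step dynamics (reference implementation, used per-step and in tests)


def step(
    state: SwayState,
    t_int: TorquePair,
    noise: TorquePair,
    J: InertiaTensor,
    body: BodyAnthropometry,
    pole: BalancePole,
    ankle: AnkleImpedance,
    dt: float,
) -> SwayState:
    """One forward-Euler step of J q̈ = T_g − T_s − T_int + w_n.

    ``t_int`` bundles the already-evaluated intermittent torques (COPS
    ankle torque and COMS pole torque).  The full 2×2 inertia solve is
    used, retaining the off-diagonal coupling J_xy.
    """
    c_ap = (body.m_b + pole.m_p) * G_GRAVITY * body.h_com
    c_ml = body.m_b * G_GRAVITY * body.h_com
    rhs = np.array(
        [
            c_ap * state.q_ap
            - (ankle.K_a * state.q_ap + ankle.B_a * state.qd_ap)
            - t_int.t_ap
            + noise.t_ap,
            c_ml * state.q_ml - t_int.t_ml + noise.t_ml,
        ]
    )
    qdd = J.inverse() @ rhs
    return SwayState(
        q_ap=state.q_ap + state.qd_ap * dt,
        q_ml=state.q_ml + state.qd_ml * dt,
        qd_ap=state.qd_ap + qdd[0] * dt,
        qd_ml=state.qd_ml + qdd[1] * dt,
    )


# ---------------------------------------------------------------------------
# compiled closed loop


@njit(cache=True)
def _core_loop(
    n, dt, lag,
    ji11, ji12, ji21, ji22,
    c_gap, c_gml, Ka, Ba,
    P_ap, D_ap, alpha_ap,
    P_ml, D_ml, alpha_ml,
    a11, a12, a21, a22, b1, b2,
    mp_g, h_com, include_tilt,
    noise_ap, noise_ml,
    q_ap, q_ml, qd_ap, qd_ml,
    T_ap, T_ml_arr, gamma, dx_p, on_ap, on_ml,
):  # pragma: no cover - exercised through simulate()
    """Advance the closed loop n steps, writing into preallocated arrays
    (index 0 holds the initial state).  Returns the number of completed
    steps (< n only if the state became non-finite)."""
    x1 = 0.0
    x2 = 0.0
    for i in range(n):
        j = i - lag
        if j < 0:
            j = 0
            if lag > 0:
                # buffer not yet filled: delayed state is the initial state
                dq_ap, dqd_ap = q_ap[0], qd_ap[0]
                dq_ml, dqd_ml = q_ml[0], qd_ml[0]
            else:
                dq_ap, dqd_ap = q_ap[i], qd_ap[i]
                dq_ml, dqd_ml = q_ml[i], qd_ml[i]
        else:
            dq_ap, dqd_ap = q_ap[j], qd_ap[j]
            dq_ml, dqd_ml = q_ml[j], qd_ml[j]

        # sagittal controller (COPS): PD ankle torque in the unsafe cone
        if dq_ap * (dqd_ap + alpha_ap * dq_ap) > 0.0:
            t_ap = P_ap * dq_ap + D_ap * dqd_ap
            on_ap[i] = True
        else:
            t_ap = 0.0
            on_ap[i] = False
        T_ap[i] = t_ap

        # coronal controller (COMS): commanded pole shift, then smoothing
        if dq_ml * (dqd_ml + alpha_ml * dq_ml) > 0.0:
            g = -(P_ml * dq_ml + D_ml * dqd_ml)
            on_ml[i] = True
        else:
            g = 0.0
            on_ml[i] = False
        gamma[i] = g
        dx_p[i] = x1  # filter output as of this sample
        lever = x1
        if include_tilt:
            lever += h_com * q_ml[i]
        t_ml = -mp_g * lever
        T_ml_arr[i] = t_ml

        # equation of motion, full 2x2 inertia solve
        rhs_ap = c_gap * q_ap[i] - (Ka * q_ap[i] + Ba * qd_ap[i]) - t_ap + noise_ap[i]
        rhs_ml = c_gml * q_ml[i] - t_ml + noise_ml[i]
        qdd_ap = ji11 * rhs_ap + ji12 * rhs_ml
        qdd_ml = ji21 * rhs_ap + ji22 * rhs_ml

        q_ap[i + 1] = q_ap[i] + qd_ap[i] * dt
        q_ml[i + 1] = q_ml[i] + qd_ml[i] * dt
        qd_ap[i + 1] = qd_ap[i] + qdd_ap * dt
        qd_ml[i + 1] = qd_ml[i] + qdd_ml * dt

        # advance the smoothing filter (zero-order hold on gamma)
        x1_new = a11 * x1 + a12 * x2 + b1 * g
        x2 = a21 * x1 + a22 * x2 + b2 * g
        x1 = x1_new

        if not (
            np.isfinite(q_ap[i + 1])
            and np.isfinite(q_ml[i + 1])
            and np.isfinite(qd_ap[i + 1])
            and np.isfinite(qd_ml[i + 1])
        ):
            return i + 1

    # controller outputs at the final sample, for a complete record
    i = n
    j = i - lag if i - lag >= 0 else 0
    if lag > 0 and i - lag < 0:
        dq_ap, dqd_ap, dq_ml, dqd_ml = q_ap[0], qd_ap[0], q_ml[0], qd_ml[0]
    else:
        dq_ap, dqd_ap, dq_ml, dqd_ml = q_ap[j], qd_ap[j], q_ml[j], qd_ml[j]
    if dq_ap * (dqd_ap + alpha_ap * dq_ap) > 0.0:
        T_ap[i] = P_ap * dq_ap + D_ap * dqd_ap
        on_ap[i] = True
    else:
        T_ap[i] = 0.0
        on_ap[i] = False
    if dq_ml * (dqd_ml + alpha_ml * dq_ml) > 0.0:
        gamma[i] = -(P_ml * dq_ml + D_ml * dqd_ml)
        on_ml[i] = True
    else:
        gamma[i] = 0.0
        on_ml[i] = False
    dx_p[i] = x1
    lever = x1
    if include_tilt:
        lever += h_com * q_ml[i]
    T_ml_arr[i] = -mp_g * lever
    return n


def draw_noise(config: SimConfig, n: int) -> np.ndarray:
    """The realized (n, 2) white Gaussian torque-noise sequence of a run."""
    rng = np.random.default_rng(config.seed)
    return rng.normal(0.0, config.noise_sd, size=(n, 2))


def simulate(
    config: SimConfig,
    noise: Optional[np.ndarray] = None,
    use_numba: bool = True,
) -> Trajectory:
    """Run the full closed loop; deterministic given (config, seed).

    ``noise`` overrides the seeded noise sequence (shape (n, 2)); this is
    how the homogeneity property is exercised.  ``use_numba=False`` runs
    the identical arithmetic through the uncompiled loop.
    """
    n = int(round(config.duration / config.dt))
    lag = int(round(config.cops.delta / config.dt))
    lag_ml = int(round(config.coms.delta / config.dt))
    if lag != lag_ml:
        raise ValueError("the two controllers must share the feedback delay grid")

    J = global_inertia(config.body, config.pole)
    Ji = J.inverse()
    Ad, Bd = filter_discretization(config.coms, config.dt)
    if noise is None:
        noise = draw_noise(config, n)
    noise = np.asarray(noise, dtype=np.float64)
    if noise.shape != (n, 2):
        raise ValueError(f"noise must have shape {(n, 2)}")

    q_ap = np.empty(n + 1)
    q_ml = np.empty(n + 1)
    qd_ap = np.empty(n + 1)
    qd_ml = np.empty(n + 1)
    T_ap = np.empty(n + 1)
    T_ml = np.empty(n + 1)
    gamma = np.empty(n + 1)
    dx_p = np.empty(n + 1)
    on_ap = np.zeros(n + 1, dtype=np.bool_)
    on_ml = np.zeros(n + 1, dtype=np.bool_)
    s0 = config.initial_state
    q_ap[0], q_ml[0], qd_ap[0], qd_ml[0] = s0.q_ap, s0.q_ml, s0.qd_ap, s0.qd_ml

    loop = _core_loop if use_numba else _core_loop.py_func
    body, pole, ankle = config.body, config.pole, config.ankle
    done = loop(
        n, config.dt, lag,
        Ji[0, 0], Ji[0, 1], Ji[1, 0], Ji[1, 1],
        (body.m_b + pole.m_p) * G_GRAVITY * body.h_com,
        body.m_b * G_GRAVITY * body.h_com,
        ankle.K_a, ankle.B_a,
        config.cops.P_ap, config.cops.D_ap, config.cops.alpha,
        config.coms.P_ml, config.coms.D_ml, config.coms.alpha,
        Ad[0, 0], Ad[0, 1], Ad[1, 0], Ad[1, 1], Bd[0], Bd[1],
        pole.m_p * G_GRAVITY, body.h_com, config.coms_include_tilt_term,
        np.ascontiguousarray(noise[:, 0]), np.ascontiguousarray(noise[:, 1]),
        q_ap, q_ml, qd_ap, qd_ml,
        T_ap, T_ml, gamma, dx_p, on_ap, on_ml,
    )
    aborted = done < n
    m = done + 1  # samples actually recorded

    sl = slice(0, m)
    t = np.arange(m) * config.dt
    T_s = ankle.K_a * q_ap[sl] + ankle.B_a * qd_ap[sl]
    G_ap = (body.m_b + pole.m_p) * G_GRAVITY * body.h_com * q_ap[sl]
    G_ml = body.m_b * G_GRAVITY * body.h_com * q_ml[sl]
    weight = (body.m_b + pole.m_p) * G_GRAVITY
    return Trajectory(
        config=config,
        t=t,
        q_ap=q_ap[sl], q_ml=q_ml[sl], qd_ap=qd_ap[sl], qd_ml=qd_ml[sl],
        T_ap=T_ap[sl], T_s=T_s, G_ap=G_ap, G_ml=G_ml, T_ml=T_ml[sl],
        gamma=gamma[sl], dx_p=dx_p[sl],
        on_ap=on_ap[sl], on_ml=on_ml[sl],
        y_cop=(T_s + T_ap[sl]) / weight,
        y_com=body.h_com * q_ap[sl],
        aborted=aborted,
    )


def cop_com_positions(traj: Trajectory):
    """Antero-posterior CoP and CoM excursions, m.

    The CoP is proportional to the combined stabilizing torque,
    y_cop = (T_s + T_ap)/((m_b+m_p) g), and the CoM projection to the
    gravity torque, y_com = h_com q_ap.
    """
    body, pole = traj.config.body, traj.config.pole
    weight = (body.m_b + pole.m_p) * G_GRAVITY
    return (traj.T_s + traj.T_ap) / weight, body.h_com * traj.q_ap
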