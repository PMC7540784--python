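"""Closed-loop integration: oracles, homogeneity, determinism."""

import dataclasses

import numpy as np
import pytest
from scipy.linalg import expm

from tightrope import (
    G_GRAVITY,
    AnkleImpedance,
    BalancePole,
    BodyAnthropometry,
    ComsParams,
    CopsParams,
    DelayBuffer,
    SimConfig,
    SwayState,
    TorquePair,
    cop_com_positions,
    draw_noise,
    falling_time_constant,
    global_inertia,
    simulate,
    step,
)

NO_CONTROL = dict(
    cops=CopsParams(P_ap=0.0, D_ap=0.0),
    coms=ComsParams(P_ml=0.0, D_ml=0.0),
    noise_sd=0.0,
)


def test_equilibrium_is_a_fixed_point():
    cfg = SimConfig(duration=2.0, warmup_discard=0.0, noise_sd=0.0)
    traj = simulate(cfg)
    assert len(traj.t) == int(round(cfg.duration / cfg.dt)) + 1
    for col in ("q_ap", "q_ml", "qd_ap", "qd_ml", "T_ap", "T_ml", "dx_p", "y_cop"):
        assert np.all(getattr(traj, col) == 0.0), col


def test_uncontrolled_divergence_follows_cosh_oracle():
    """Without pole, stiffness, noise or control, the coronal tilt follows
    the closed-form saddle solution q0 cosh(t/tau) with tau = sqrt(J/(m g h))."""
    body = BodyAnthropometry()
    cfg = SimConfig(
        duration=0.5,
        warmup_discard=0.0,
        pole=BalancePole(0.0, 0.0),
        ankle=AnkleImpedance(K_a=0.0, B_a=0.0),
        initial_state=SwayState(q_ml=0.01),
        **NO_CONTROL,
    )
    traj = simulate(cfg)
    tau = falling_time_constant(
        body.I_yy + body.h_com**2 * body.m_b, body.m_b, body
    )
    assert tau == pytest.approx(0.3477, abs=5e-4)
    expected = 0.01 * np.cosh(traj.t / tau)
    # forward Euler is first order: relative error ~ t dt / (2 tau^2),
    # about 0.2% at t = 0.5 s
    np.testing.assert_allclose(traj.q_ml, expected, rtol=3e-3)


def test_offphase_orbit_matches_matrix_exponential():
    """The noise-free off-phase dynamics is linear; forward Euler at 1 ms must
    track the exact 2x2 matrix-exponential solution to < 1e-4 rad over 0.3 s."""
    cfg = SimConfig(
        duration=0.3,
        warmup_discard=0.0,
        initial_state=SwayState(q_ap=0.01, q_ml=0.005, qd_ap=0.0, qd_ml=0.0),
        **NO_CONTROL,
    )
    traj = simulate(cfg)

    body, pole, ankle = cfg.body, cfg.pole, cfg.ankle
    Ji = global_inertia(body, pole).inverse()
    c_ap = (body.m_b + pole.m_p) * G_GRAVITY * body.h_com
    c_ml = body.m_b * G_GRAVITY * body.h_com
    # with gamma = 0 the pole channel contributes its tilt gravity only
    k_ml = c_ml + pole.m_p * G_GRAVITY * body.h_com
    K = np.array([[c_ap - ankle.K_a, 0.0], [0.0, k_ml]])
    B = np.array([[ankle.B_a, 0.0], [0.0, 0.0]])
    A = np.zeros((4, 4))
    A[0:2, 2:4] = np.eye(2)
    A[2:4, 0:2] = Ji @ K
    A[2:4, 2:4] = -Ji @ B
    x0 = np.array([0.01, 0.005, 0.0, 0.0])
    exact = np.stack([expm(A * t) @ x0 for t in traj.t])
    assert np.max(np.abs(traj.q_ap - exact[:, 0])) < 1e-4
    assert np.max(np.abs(traj.q_ml - exact[:, 1])) < 1e-4


def test_positive_homogeneity_is_exact():
    """Doubling the realized noise doubles every continuous signal
    sample-for-sample (bit-exact) and leaves the switching pattern unchanged."""
    cfg = SimConfig(duration=20.0, warmup_discard=0.0, seed=11)
    noise = draw_noise(cfg, int(round(cfg.duration / cfg.dt)))
    tr1 = simulate(cfg, noise=noise)
    tr2 = simulate(cfg, noise=2.0 * noise)
    for col in ("q_ap", "q_ml", "qd_ap", "qd_ml", "T_ap", "T_ml",
                "gamma", "dx_p", "y_cop", "y_com"):
        assert np.array_equal(getattr(tr2, col), 2.0 * getattr(tr1, col)), col
    assert np.array_equal(tr1.on_ap, tr2.on_ap)
    assert np.array_equal(tr1.on_ml, tr2.on_ml)


def test_determinism_same_seed_bit_identical():
    cfg = SimConfig(duration=10.0, warmup_discard=0.0, seed=5)
    tr1, tr2 = simulate(cfg), simulate(cfg)
    for col in ("q_ap", "q_ml", "qd_ap", "qd_ml", "T_ap", "on_ap"):
        assert np.array_equal(getattr(tr1, col), getattr(tr2, col))
    tr3 = simulate(cfg.with_seed(6))
    assert not np.array_equal(tr1.q_ap, tr3.q_ap)


def test_compiled_and_python_loops_agree():
    cfg = SimConfig(duration=3.0, warmup_discard=0.0, seed=3)
    fast = simulate(cfg, use_numba=True)
    slow = simulate(cfg, use_numba=False)
    for col in ("q_ap", "q_ml", "qd_ap", "qd_ml", "T_ap", "T_ml", "dx_p"):
        assert np.array_equal(getattr(fast, col), getattr(slow, col)), col


def test_stiffness_sign_conventions():
    """Overcritical ankle stiffness (K_a > m g h) makes the uncontrolled
    sagittal plane oscillate boundedly; undercritical stiffness diverges."""
    base = dict(
        duration=5.0,
        warmup_discard=0.0,
        initial_state=SwayState(q_ap=0.01),
        **NO_CONTROL,
    )
    over = simulate(SimConfig(ankle=AnkleImpedance(K_a=1200.0, B_a=20.0), **base))
    assert np.max(np.abs(over.q_ap)) < 0.05
    under = simulate(SimConfig(ankle=AnkleImpedance(K_a=495.87, B_a=20.0), **base))
    assert np.max(np.abs(under.q_ap)) > 0.26


def test_cop_position_examples():
    body, pole = BodyAnthropometry(), BalancePole()
    cfg = SimConfig(duration=1.0, warmup_discard=0.0, noise_sd=0.0)
    traj = simulate(cfg)
    y_cop, y_com = cop_com_positions(traj)
    assert np.all(y_cop == 0.0)
    # scale check at the published operating point
    weight = (body.m_b + pole.m_p) * G_GRAVITY
    assert 8.9 / weight == pytest.approx(0.00997, abs=5e-5)
    assert body.h_com * 0.0161 == pytest.approx(0.0160, abs=1e-4)


def test_step_matches_manual_solve():
    body, pole, ankle = BodyAnthropometry(), BalancePole(), AnkleImpedance()
    J = global_inertia(body, pole)
    s = SwayState(q_ap=0.01, q_ml=-0.004, qd_ap=0.02, qd_ml=0.01)
    t_int = TorquePair(t_ap=3.0, t_ml=-1.0)
    noise = TorquePair(t_ap=0.5, t_ml=-0.2)
    out = step(s, t_int, noise, J, body, pole, ankle, dt=0.001)
    rhs = np.array([
        (body.m_b + pole.m_p) * G_GRAVITY * body.h_com * s.q_ap
        - (ankle.K_a * s.q_ap + ankle.B_a * s.qd_ap) - 3.0 + 0.5,
        body.m_b * G_GRAVITY * body.h_com * s.q_ml - (-1.0) + (-0.2),
    ])
    qdd = np.linalg.solve(J.as_matrix(), rhs)
    assert out.q_ap == pytest.approx(s.q_ap + s.qd_ap * 0.001, rel=1e-14)
    assert out.qd_ap == pytest.approx(s.qd_ap + qdd[0] * 0.001, rel=1e-12)
    assert out.qd_ml == pytest.approx(s.qd_ml + qdd[1] * 0.001, rel=1e-12)


def test_delay_buffer_returns_lagged_state():
    init = SwayState()
    buf = DelayBuffer(delta=0.003, dt=0.001, initial=init)
    states = [SwayState(q_ap=0.01 * i) for i in range(1, 8)]
    out = [buf.push_and_read(s) for s in states]
    assert out[0] is init and out[1] is init and out[2] is init
    assert out[3] is states[0]  # exactly 3 steps back
    assert out[6] is states[3]


def test_weak_coupling_between_planes(table_runs):
    """The inertia off-diagonal is tiny, so the two sway angles stay nearly
    uncorrelated over a full run."""
    from tightrope import pearson_correlation

    rs = []
    for traj in table_runs:
        i0 = int(round(traj.config.warmup_discard / traj.dt))
        rs.append(pearson_correlation(traj.q_ap[i0:], traj.q_ml[i0:]))
    assert abs(np.mean(rs)) < 0.2
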