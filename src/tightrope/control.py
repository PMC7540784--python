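"""Intermittent delayed feedback controllers.

Two independent controllers stabilize the two sway planes:

* **COPS** (centre-of-pressure strategy, sagittal plane): an intermittent
  ankle torque, a PD law on the delayed state, active only while the
  delayed state sits in the *unsafe* region of the phase plane.
* **COMS** (centre-of-mass strategy, coronal plane): an intermittent
  commanded lateral pole shift gamma = −(P q + D q̇), smoothed by a
  second-order low-pass filter into the actual shift Δx_p, which produces
  a stabilizing gravity torque through the displaced pole CoM.

The phase plane of each plane is split by the vertical axis q = 0 and the
line q̇ = −α q into *unsafe* regions (first and third quadrants plus the
triangular slice between that line and the q axis), where the uncontrolled
saddle dynamics diverges, and complementary *safe* regions where the
stable manifold carries the state back toward equilibrium.  The controller
switches on only in the unsafe regions — a minimum-intervention policy
that exploits this dynamic affordance of the saddle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.linalg import expm

from .mechanics import G_GRAVITY, BalancePole, BodyAnthropometry

SAFE = "safe"
UNSAFE = "unsafe"


@dataclass(frozen=True)
class PhasePoint:
    """A (possibly delayed) point in one plane's phase plane."""

    q: float  # rad
    qd: float  # rad s^-1


@dataclass(frozen=True)
class CopsParams:
    """Sagittal (ankle torque) controller parameters."""

    P_ap: float = 578.52  # N m rad^-1
    D_ap: float = 20.0  # N m s rad^-1
    alpha: float = 0.4  # s^-1, slope of the safe/unsafe boundary line
    delta: float = 0.2  # s, feedback delay

    def __post_init__(self) -> None:
        if self.delta < 0 or self.alpha < 0:
            raise ValueError("alpha and delta must be non-negative")


@dataclass(frozen=True)
class ComsParams:
    """Coronal (pole shift) controller parameters.

    ``omega_f`` is the low-pass filter cut-off in Hz; ``xi`` its damping
    ratio.  The filter emulates the smoothing of the discontinuous pole
    command by the arm motor system.
    """

    P_ml: float = 9.0  # m rad^-1
    D_ml: float = 8.0  # m s rad^-1
    alpha: float = 0.4  # s^-1
    delta: float = 0.2  # s
    omega_f: float = 2.0  # Hz
    xi: float = 0.7

    def __post_init__(self) -> None:
        if self.omega_f <= 0 or self.xi <= 0:
            raise ValueError("filter frequency and damping must be positive")
        if self.delta < 0 or self.alpha < 0:
            raise ValueError("alpha and delta must be non-negative")


@dataclass(frozen=True)
class FilterState:
    """Internal state of the pole-shift smoothing filter."""

    x1: float = 0.0  # filter output (pole shift), m
    x2: float = 0.0  # output rate, m s^-1


@dataclass(frozen=True)
class ControlSignals:
    """All controller outputs at one instant."""

    t_ap: float  # COPS ankle torque, N m
    gamma: float  # commanded pole shift before smoothing, m
    dx_p: float  # smoothed pole shift, m
    t_ml: float  # COMS gravity torque, N m
    on_ap: bool
    on_ml: bool


# ---------------------------------------------------------------------------
# switching geometry


def classify_region(p: PhasePoint, alpha: float) -> str:
    """Label a phase point safe/unsafe.

    Unsafe iff q·(q̇ + αq) > 0: the first and third quadrants plus the
    slice between the line q̇ = −αq and the q axis.  Boundary points are
    safe, so control stays off on ties (minimum intervention).
    """
    return UNSAFE if p.q * (p.qd + alpha * p.q) > 0 else SAFE


# ---------------------------------------------------------------------------
# control laws


def cops_torque(delayed: PhasePoint, params: CopsParams) -> Tuple[float, bool]:
    """Intermittent ankle PD torque on the delayed sagittal state.

    Returns ``(torque, on_flag)``; the torque opposes gravity through the
    minus sign of the equation of motion, so the gains are positive.
    """
    if classify_region(delayed, params.alpha) == UNSAFE:
        return params.P_ap * delayed.q + params.D_ap * delayed.qd, True
    return 0.0, False


def coms_gamma(delayed: PhasePoint, params: ComsParams) -> Tuple[float, bool]:
    """Commanded pole shift: γ = −(P q + D q̇) in the unsafe region (pole
    CoM displaced opposite to the body disequilibrium), γ = 0 in the safe
    region (the two CoMs kept aligned)."""
    if classify_region(delayed, params.alpha) == UNSAFE:
        return -(params.P_ml * delayed.q + params.D_ml * delayed.qd), True
    return 0.0, False


# ---------------------------------------------------------------------------
# pole-shift smoothing filter


def filter_discretization(params: ComsParams, dt: float) -> Tuple[np.ndarray, np.ndarray]:
    """Exact zero-order-hold discretization of the second-order low-pass
    F(s) = 1/((s/ω)² + 2ξ(s/ω) + 1), ω = 2π·omega_f rad/s.

    Returns ``(Ad, Bd)`` for x[k+1] = Ad x[k] + Bd γ[k].  The ZOH map is
    unconditionally stable and has DC gain exactly 1.
    """
    w = 2.0 * math.pi * params.omega_f
    A = np.array([[0.0, 1.0], [-w * w, -2.0 * params.xi * w]])
    B = np.array([0.0, w * w])
    # augmented-matrix trick: expm([[A, B], [0, 0]] dt) holds Ad and Bd
    M = np.zeros((3, 3))
    M[:2, :2] = A
    M[:2, 2] = B
    Md = expm(M * dt)
    return Md[:2, :2].copy(), Md[:2, 2].copy()


def filter_step(
    fs: FilterState, gamma: float, dt: float, params: ComsParams
) -> Tuple[FilterState, float]:
    """Advance the smoothing filter one step; returns the new state and the
    smoothed shift dx_p (the filter output at the *new* state)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    Ad, Bd = filter_discretization(params, dt)
    x = Ad @ np.array([fs.x1, fs.x2]) + Bd * gamma
    new = FilterState(x1=float(x[0]), x2=float(x[1]))
    return new, new.x1


def coms_torque(
    dx_p: float, q_ml: float, pole: BalancePole, body: BodyAnthropometry,
    include_tilt_term: bool = True,
) -> float:
    """Gravity torque produced by the displaced pole CoM.

    T_ml = −m_p g (h_com q_ml + Δx_p): the pole CoM sits at lateral offset
    h_com q_ml + Δx_p from the wire, so its whole gravity acts through this
    channel (the body-only coronal gravity term carries just m_b).  With
    ``include_tilt_term=False`` only the shift part −m_p g Δx_p is applied.
    """
    lever = dx_p + (body.h_com * q_ml if include_tilt_term else 0.0)
    return -pole.m_p * G_GRAVITY * lever
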