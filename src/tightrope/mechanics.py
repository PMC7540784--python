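"""Rigid-body mechanics of a tandem-stance tightrope walker.

The body is a single inverted pendulum pivoting on the wire with two
degrees of freedom: sagittal tilt ``q_ap`` (rotation about the
medio-lateral x-axis) and coronal tilt ``q_ml`` (rotation about the
along-wire y-axis).  A rigid balance pole of length ``l_p`` and mass
``m_p`` is held at the height of the body centre of mass, parallel to
the x-axis.  All quantities here are pure functions of the physical
parameters: inertias referred to the wire (parallel-axis theorem),
linearized gravity and ankle-impedance torques, and the falling time
constant of the uncontrolled pendulum.

Sign conventions: ``q_ap > 0`` is a forward lean, ``q_ml > 0`` a lean
toward the positive x side; torques are positive in the direction that
increases the corresponding angle.  Angles are radians throughout; the
reporting layer converts to degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: standard gravity, m s^-2
G_GRAVITY = 9.81


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class BodyAnthropometry:
    """Anthropometric parameters of the standing body.

    ``I_xx, I_xy, I_yy`` are the components of the CoM-referenced inertia
    tensor restricted to the two sway axes (the tensor is symmetric, so
    only the upper triangle is stored).
    """

    m_b: float = 78.0  # body mass, kg
    h_com: float = 0.997  # CoM height above the wire, m
    I_xx: float = 13.496  # kg m^2
    I_xy: float = 0.0344  # kg m^2
    I_yy: float = 14.690  # kg m^2

    def __post_init__(self) -> None:
        if self.m_b <= 0 or self.h_com <= 0:
            raise ValueError("body mass and CoM height must be positive")
        if self.I_xx <= 0 or self.I_yy <= 0:
            raise ValueError("diagonal inertia components must be positive")
        if self.I_xx * self.I_yy - self.I_xy**2 <= 0:
            raise ValueError("body inertia tensor must be positive definite")


@dataclass(frozen=True)
class BalancePole:
    """Rigid, straight balance pole. Zero length/mass means no pole."""

    l_p: float = 12.0  # length, m
    m_p: float = 13.0  # mass, kg

    def __post_init__(self) -> None:
        if self.l_p < 0 or self.m_p < 0:
            raise ValueError("pole length and mass must be non-negative")

    def scaled(self, fraction: float) -> "BalancePole":
        """Shorter and proportionally lighter pole (length and mass × fraction)."""
        return BalancePole(l_p=fraction * self.l_p, m_p=fraction * self.m_p)


@dataclass(frozen=True)
class AnkleImpedance:
    """Passive visco-elastic ankle parameters (sagittal plane only)."""

    K_a: float = 495.87  # stiffness, N m rad^-1
    B_a: float = 20.0  # viscosity, N m s rad^-1

    def __post_init__(self) -> None:
        if self.K_a < 0 or self.B_a < 0:
            raise ValueError("ankle impedance parameters must be non-negative")


@dataclass(frozen=True)
class InertiaTensor:
    """Global (body + pole) inertia tensor referred to the wire, kg m^2."""

    J_xx: float
    J_xy: float
    J_yx: float
    J_yy: float

    def __post_init__(self) -> None:
        if self.J_xy != self.J_yx:
            raise ValueError("inertia tensor must be symmetric")
        if self.J_xx <= 0 or self.J_yy <= 0 or self.determinant <= 0:
            raise ValueError("inertia tensor must be positive definite")

    @property
    def determinant(self) -> float:
        return self.J_xx * self.J_yy - self.J_xy * self.J_yx

    def as_matrix(self) -> np.ndarray:
        return np.array([[self.J_xx, self.J_xy], [self.J_yx, self.J_yy]])

    def inverse(self) -> np.ndarray:
        det = self.determinant
        if det == 0:
            raise np.linalg.LinAlgError("singular inertia tensor")
        return (
            np.array([[self.J_yy, -self.J_xy], [-self.J_yx, self.J_xx]]) / det
        )


@dataclass(frozen=True)
class SwayState:
    """Instantaneous sway state (angles rad, angular velocities rad/s)."""

    q_ap: float = 0.0
    q_ml: float = 0.0
    qd_ap: float = 0.0
    qd_ml: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.q_ap, self.q_ml, self.qd_ap, self.qd_ml):
            if not np.isfinite(v):
                raise ValueError("sway state must be finite")


@dataclass(frozen=True)
class TorquePair:
    """Torque about the x-axis (t_ap) and the y-axis (t_ml), N m."""

    t_ap: float = 0.0
    t_ml: float = 0.0


# ---------------------------------------------------------------------------
# operations


def pole_moment_of_inertia(pole: BalancePole) -> float:
    """Moment of inertia of a uniform slender rod about a transverse axis
    through its CoM: (1/12) m l², kg m^2.  The longitudinal-axis inertia
    of the pole is neglected."""
    return pole.m_p * pole.l_p**2 / 12.0


def global_inertia(body: BodyAnthropometry, pole: BalancePole) -> InertiaTensor:
    """Wire-referenced inertia tensor of body plus pole.

    The parallel-axis theorem lifts the CoM-referenced body tensor to the
    wire; the pole (held at CoM height, parallel to x) contributes only to
    the yy component.
    """
    h2 = body.h_com**2
    J_xx = body.I_xx + h2 * body.m_b
    J_yy = body.I_yy + h2 * body.m_b + pole_moment_of_inertia(pole) + h2 * pole.m_p
    return InertiaTensor(J_xx=J_xx, J_xy=body.I_xy, J_yx=body.I_xy, J_yy=J_yy)


def falling_time_constant(
    J_axis: float, m_total: float, body: BodyAnthropometry
) -> float:
    """e-folding time sqrt(J/(m g h)) of the uncontrolled inverted pendulum.

    A larger pole inertia slows the gravitational divergence, which is the
    mechanical rationale for carrying a long, heavy pole.
    """
    if J_axis <= 0 or m_total <= 0:
        raise ValueError("inertia and mass must be positive")
    return float(np.sqrt(J_axis / (m_total * G_GRAVITY * body.h_com)))


def gravity_torque(
    state: SwayState, body: BodyAnthropometry, pole: BalancePole
) -> TorquePair:
    """Linearized gravity toppling torque about the wire.

    The full body+pole weight acts in the sagittal plane; in the coronal
    plane only the body weight is assigned here — the pole's gravity acts
    through the pole-shift control channel (see :func:`tightrope.control.coms_torque`).
    """
    g_ap = (body.m_b + pole.m_p) * G_GRAVITY * body.h_com * state.q_ap
    g_ml = body.m_b * G_GRAVITY * body.h_com * state.q_ml
    return TorquePair(t_ap=g_ap, t_ml=g_ml)


def stiffness_torque(state: SwayState, ankle: AnkleImpedance) -> TorquePair:
    """Passive ankle visco-elastic torque; sagittal plane only, since ankle
    muscles cannot act medio-laterally in tandem stance on a wire."""
    return TorquePair(t_ap=ankle.K_a * state.q_ap + ankle.B_a * state.qd_ap, t_ml=0.0)


def stiffness_condition_holds(
    ankle: AnkleImpedance, body: BodyAnthropometry, pole: BalancePole
) -> bool:
    """True iff the passive ankle stiffness is strictly below the growth
    rate of the gravity toppling torque, K_a < (m_b+m_p) g h_com — i.e.
    passive stiffness alone cannot stabilize the sagittal plane and active
    control is required."""
    return ankle.K_a < (body.m_b + pole.m_p) * G_GRAVITY * body.h_com
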