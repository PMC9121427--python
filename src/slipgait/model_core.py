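"""Core types and dynamics of the bipedal SLIP model with passive swing legs.

The model is a point-mass body on two massless linear-spring legs. Each leg
is attached to the body through a frictionless hip joint carrying a torsional
spring of infinitesimal stiffness that drives the swing leg toward its
neutral leg swing angle (NLSA) ``phi`` with angular frequency ``omega``.
All quantities are normalized by body mass ``m``, uncompressed leg length
``lo`` and gravity ``g`` (speeds in sqrt(g*lo), times in sqrt(lo/g),
stiffness in m*g/lo).

Conventions
-----------
* Leg angles ``alpha`` are measured from the downward vertical through the
  COM, positive counterclockwise; with forward motion along +x, a foot
  placed ahead of the COM has ``alpha > 0``.
* The foot of leg *i* sits at ``(x + l*sin(alpha_i), y - l*cos(alpha_i))``.
* In stance the foot anchor is stationary (holonomic constraint
  ``x_c,i - x - y*tan(alpha_i) = 0``) and the leg length is
  ``y / cos(alpha_i)``; in swing the leg keeps its rest length ``lo = 1``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Side",
    "Mode",
    "GaitLabel",
    "ModelParams",
    "HybridState",
    "EventTimes",
    "NetForce",
    "DegenerateGeometryError",
    "FallError",
    "leg_length",
    "net_force",
    "swing_leg_accel",
    "stance_leg_accel",
    "touchdown_reset",
    "total_energy",
]


class DegenerateGeometryError(ValueError):
    """Stance geometry left the admissible region (|alpha| >= pi/2 or y <= 0)."""


class FallError(RuntimeError):
    """The body reached the ground (y -> 0); the simulation must terminate."""


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"

    @property
    def other(self) -> "Side":
        return Side.RIGHT if self is Side.LEFT else Side.LEFT


class Mode(str, enum.Enum):
    SWING = "swing"
    STANCE = "stance"


class GaitLabel(str, enum.Enum):
    WALKING = "walking"
    HOPPING = "hopping"
    SKIPPING = "skipping"
    SYMMETRIC_RUNNING = "symmetric_running"
    ASYMMETRIC_RUNNING = "asymmetric_running"
    DEGENERATE = "degenerate"


@dataclass(frozen=True)
class ModelParams:
    """Dimensionless parameter vector (m, lo, g, k, omega, phi_l, phi_r).

    ``m``, ``lo`` and ``g`` are the normalization scales and must equal 1;
    they are kept as explicit fields so that configurations document the
    convention.  ``k`` is the linear leg-spring stiffness [m*g/lo], ``omega``
    the swing-leg oscillation frequency [sqrt(g/lo)] and ``phi_l``/``phi_r``
    the neutral leg swing angles [rad, from vertical, CCW positive].
    """

    k: float = 20.0
    omega: float = 6.5
    phi_l: float = 0.0
    phi_r: float = 0.0
    m: float = 1.0
    lo: float = 1.0
    g: float = 1.0

    def __post_init__(self) -> None:
        if not (self.m > 0 and self.lo > 0 and self.g > 0):
            raise ValueError("m, lo, g must be positive")
        if not (self.k > 0):
            raise ValueError("leg stiffness k must be positive")
        if not (self.omega > 0):
            raise ValueError("swing frequency omega must be positive")

    @property
    def normalized(self) -> bool:
        return self.m == 1.0 and self.lo == 1.0 and self.g == 1.0

    def require_normalized(self) -> None:
        if not self.normalized:
            raise ValueError(
                "dynamics are implemented in normalized units; m, lo, g must be 1"
            )

    def phi(self, leg: Side) -> float:
        return self.phi_l if leg is Side.LEFT else self.phi_r

    def with_phis(self, phi_l: float, phi_r: float) -> "ModelParams":
        return replace(self, phi_l=phi_l, phi_r=phi_r)

    def to_dict(self) -> dict:
        return {
            "m": self.m, "lo": self.lo, "g": self.g, "k": self.k,
            "omega": self.omega, "phi_l": self.phi_l, "phi_r": self.phi_r,
        }


@dataclass
class HybridState:
    """Continuous states plus per-leg contact mode and foot anchors.

    ``xc_l``/``xc_r`` (stationary foot anchor x-positions) are only
    meaningful while the corresponding leg is in stance; they are NaN in
    swing.
    """

    x: float = 0.0
    y: float = 1.0
    alpha_l: float = 0.0
    alpha_r: float = 0.0
    xdot: float = 0.0
    ydot: float = 0.0
    alphadot_l: float = 0.0
    alphadot_r: float = 0.0
    mode_l: Mode = Mode.SWING
    mode_r: Mode = Mode.SWING
    xc_l: float = math.nan
    xc_r: float = math.nan

    # -- accessors ---------------------------------------------------------
    def alpha(self, leg: Side) -> float:
        return self.alpha_l if leg is Side.LEFT else self.alpha_r

    def alphadot(self, leg: Side) -> float:
        return self.alphadot_l if leg is Side.LEFT else self.alphadot_r

    def mode(self, leg: Side) -> Mode:
        return self.mode_l if leg is Side.LEFT else self.mode_r

    def xc(self, leg: Side) -> float:
        return self.xc_l if leg is Side.LEFT else self.xc_r

    def q(self) -> np.ndarray:
        return np.array([self.x, self.y, self.alpha_l, self.alpha_r])

    def qdot(self) -> np.ndarray:
        return np.array([self.xdot, self.ydot, self.alphadot_l, self.alphadot_r])

    def as_array(self) -> np.ndarray:
        """Continuous state vector [x, y, al, ar, xdot, ydot, aldot, ardot]."""
        return np.concatenate([self.q(), self.qdot()])

    def copy(self) -> "HybridState":
        return replace(self)

    def constraint_residual(self, leg: Side) -> float:
        """Eq.-3 residual x_c,i - x - y*tan(alpha_i) for a stance leg."""
        if self.mode(leg) is not Mode.STANCE:
            raise ValueError(f"{leg.value} leg is not in stance")
        return self.xc(leg) - self.x - self.y * math.tan(self.alpha(leg))


@dataclass
class EventTimes:
    """Touchdown/liftoff times per leg and the stride time T [sqrt(lo/g)].

    Times are measured from the stride-anchoring apex; all four event times
    lie in (0, T) and per leg the touchdown precedes the liftoff in the
    stride's cyclic ordering.
    """

    t_ltd: float
    t_llo: float
    t_rtd: float
    t_rlo: float
    T: float

    def td(self, leg: Side) -> float:
        return self.t_ltd if leg is Side.LEFT else self.t_rtd

    def lo(self, leg: Side) -> float:
        return self.t_llo if leg is Side.LEFT else self.t_rlo

    def as_array(self) -> np.ndarray:
        return np.array([self.t_ltd, self.t_llo, self.t_rtd, self.t_rlo, self.T])

    def stance_duration(self, leg: Side) -> float:
        """Per-leg stance duration, cyclically wrapped into [0, T)."""
        d = self.lo(leg) - self.td(leg)
        return d if d >= 0 else d + self.T

    def stance_intervals(self, leg: Side) -> list[tuple[float, float]]:
        """Within-stride intervals during which the leg is on the ground."""
        td, lo = self.td(leg), self.lo(leg)
        if td <= lo:
            return [(td, lo)]
        return [(0.0, lo), (td, self.T)]

    def aerial_intervals(self) -> list[tuple[float, float]]:
        """Maximal intervals with neither leg in contact (cyclic, merged)."""
        edges = sorted(
            self.stance_intervals(Side.LEFT) + self.stance_intervals(Side.RIGHT)
        )
        gaps: list[tuple[float, float]] = []
        cursor = 0.0
        for a, b in edges:
            if a > cursor:
                gaps.append((cursor, a))
            cursor = max(cursor, b)
        if cursor < self.T:
            gaps.append((cursor, self.T))
        # merge across the cyclic seam at t=0/T
        if len(gaps) >= 2 and gaps[0][0] == 0.0 and gaps[-1][1] == self.T:
            a = gaps.pop()
            b = gaps.pop(0)
            gaps.append((a[0], self.T + b[1]))  # duration spans the seam
        return gaps

    def validate(self, tol: float = 0.0) -> bool:
        ts = [self.t_ltd, self.t_llo, self.t_rtd, self.t_rlo]
        return all(-tol < t < self.T + tol for t in ts) and self.T > 0


@dataclass(frozen=True)
class NetForce:
    """Net horizontal/vertical force on the body from the legs [m*g]."""

    Fx: float
    Fy: float


# ---------------------------------------------------------------------------
# Continuous / discrete dynamics
# ---------------------------------------------------------------------------

def leg_length(state: HybridState, leg: Side) -> float:
    """Instantaneous leg length [lo]: rest length in swing, y/cos(alpha) in stance."""
    if state.mode(leg) is Mode.SWING:
        return 1.0
    a = state.alpha(leg)
    if state.y <= 0.0 or abs(a) >= math.pi / 2:
        raise DegenerateGeometryError(
            f"degenerate stance geometry: y={state.y}, alpha={a}"
        )
    return state.y / math.cos(a)


def net_force(state: HybridState, p: ModelParams) -> NetForce:
    """Net spring force on the body: sum over stance legs of k*(lo - l_i)
    directed from the foot anchor toward the COM. Swing legs are massless
    with infinitesimal torsional stiffness and contribute nothing."""
    p.require_normalized()
    Fx = 0.0
    Fy = 0.0
    for leg in Side:
        if state.mode(leg) is Mode.STANCE:
            a = state.alpha(leg)
            l = leg_length(state, leg)
            if l <= 0.0:
                raise DegenerateGeometryError(f"non-positive leg length {l}")
            f = p.k * (1.0 - l)
            Fx += f * (-math.sin(a))
            Fy += f * math.cos(a)
    return NetForce(Fx, Fy)


def body_accel(state: HybridState, p: ModelParams) -> tuple[float, float]:
    """COM acceleration (xddot, yddot) from the net leg force and gravity."""
    F = net_force(state, p)
    return F.Fx / p.m, F.Fy / p.m - p.g


def swing_leg_accel(
    state: HybridState,
    body_acc: tuple[float, float],
    leg: Side,
    p: ModelParams,
) -> float:
    """Angular acceleration of a swing leg [g/lo].

    Combines the pendulum coupling to the accelerating body,
    -(1/lo)*[xddot*cos(alpha) + (g + yddot)*sin(alpha)], with the torsional
    restoring term -omega^2*(alpha - phi). In ballistic flight the coupling
    vanishes exactly and the leg oscillates harmonically about phi at
    angular frequency omega.
    """
    p.require_normalized()
    ax, ay = body_acc
    a = state.alpha(leg)
    return -(ax * math.cos(a) + (1.0 + ay) * math.sin(a)) - p.omega**2 * (
        a - p.phi(leg)
    )


def stance_leg_accel(
    state: HybridState,
    body_acc: tuple[float, float],
    leg: Side,
) -> float:
    """Angular acceleration of a stance leg [g/lo].

    Obtained by differentiating the holonomic foot-anchor constraint
    x_c - x - y*tan(alpha) = 0 twice in time:

        alphaddot = -2*alphadot^2*tan(a) - 2*alphadot*ydot/y
                    - (xddot + yddot*tan(a)) * cos(a)^2 / y
    """
    a = state.alpha(leg)
    if state.y <= 0.0:
        raise FallError("stance with y <= 0: body reached the ground")
    if abs(a) >= math.pi / 2:
        raise DegenerateGeometryError(f"stance leg angle |{a}| >= pi/2")
    w = state.alphadot(leg)
    ax, ay = body_acc
    ta = math.tan(a)
    ca2 = math.cos(a) ** 2
    return -2.0 * w * w * ta - 2.0 * w * state.ydot / state.y - (
        ax + ay * ta
    ) * ca2 / state.y


def constrained_alphadot(y: float, alpha: float, xdot: float, ydot: float) -> float:
    """The unique stance-compatible leg angular velocity.

    Differentiating Eq. 3 once with a stationary anchor gives
    0 = -xdot - ydot*tan(a) - y*alphadot/cos(a)^2, hence
    alphadot = -(xdot + ydot*tan(a)) * cos(a)^2 / y.
    """
    ta = math.tan(alpha)
    return -(xdot + ydot * ta) * math.cos(alpha) ** 2 / y


def touchdown_reset(state_minus: HybridState, leg: Side) -> HybridState:
    """Discrete touchdown map: COM state unchanged (massless legs); the
    touching leg's angular velocity is replaced by the unique value that
    keeps the new foot anchor stationary; the anchor is placed by Eq. 3 and
    the mode switches to stance."""
    a = state_minus.alpha(leg)
    if abs(a) >= math.pi / 2:
        raise DegenerateGeometryError(f"touchdown with |alpha| >= pi/2 ({a})")
    s = state_minus.copy()
    w_plus = constrained_alphadot(s.y, a, s.xdot, s.ydot)
    xc = s.x + s.y * math.tan(a)
    if leg is Side.LEFT:
        s.alphadot_l = w_plus
        s.xc_l = xc
        s.mode_l = Mode.STANCE
    else:
        s.alphadot_r = w_plus
        s.xc_r = xc
        s.mode_r = Mode.STANCE
    return s


def liftoff_reset(state_minus: HybridState, leg: Side) -> HybridState:
    """Liftoff map: the leg returns to rest length; velocities continuous."""
    s = state_minus.copy()
    if leg is Side.LEFT:
        s.mode_l = Mode.SWING
        s.xc_l = math.nan
    else:
        s.mode_r = Mode.SWING
        s.xc_r = math.nan
    return s


def total_energy(state: HybridState, p: ModelParams) -> float:
    """Total mechanical energy [m*g*lo]: kinetic + gravitational + elastic.

    At a flight apex (ydot = 0, both legs swinging) this reduces to
    E = xdot^2/2 + y, the expression used to parameterize gait branches.
    """
    p.require_normalized()
    E = 0.5 * (state.xdot**2 + state.ydot**2) + state.y
    for leg in Side:
        if state.mode(leg) is Mode.STANCE:
            E += 0.5 * p.k * (1.0 - leg_length(state, leg)) ** 2
    return E
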