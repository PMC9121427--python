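"""Event-driven stride simulation: the apex-to-apex Poincaré return map.

A stride is anchored at an apex of the COM height (``ydot = 0`` crossing
from above).  For aerial gaits the anchor lies in the flight phase; walking
has no flight phase, so its anchor falls in single stance (double-support
anchors are rejected).  The stride chains integration phases across
touchdown/liftoff events until each leg has touched down and lifted off
once, then stops at the next apex.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from . import _dynamics as dyn
from .model_core import (
    EventTimes,
    HybridState,
    Mode,
    ModelParams,
    Side,
    total_energy,
)

__all__ = [
    "SectionMode",
    "StrideTrajectory",
    "integrate_phase",
    "simulate_stride",
    "poincare_map",
    "state_from_reduced",
    "reduced_from_state",
    "IntegratorOptions",
]

_STATUS_NAMES = {
    dyn.STATUS_OK: "periodic-candidate",
    dyn.STATUS_FELL: "fell",
    dyn.STATUS_PREMATURE: "premature-touchdown",
    dyn.STATUS_OVERFLOW: "event-overflow",
    dyn.STATUS_UNDERFLOW: "numerical-failure",
    dyn.STATUS_TIME_CAP: "time-cap",
    dyn.STATUS_DEGENERATE: "degenerate",
    dyn.STATUS_EVENT: "event",
}

_EVENT_NAMES = {
    dyn.EV_TD_L: "touchdown-left",
    dyn.EV_LO_L: "liftoff-left",
    dyn.EV_TD_R: "touchdown-right",
    dyn.EV_LO_R: "liftoff-right",
    dyn.EV_APEX: "apex",
    dyn.EV_FALL: "fall",
}


@dataclass(frozen=True)
class IntegratorOptions:
    """Tolerances and guards for the hybrid integrator.

    Defaults are tight (rtol 1e-9 / atol 1e-11) because branch geometry
    near bifurcations is sensitive; the event time cap and step storage
    bound guard against chatter.

    ``premature_tol`` is the anterior angular-velocity threshold [rad per
    sqrt(lo/g)] above which a touchdown counts as premature (the leg still
    rotating forward at contact, producing a large velocity reset).  It
    sits well above integration jitter yet far below genuine anterior
    swing rates (~1), so near-synchronized touchdowns with vanishing leg
    rotation are not misflagged.
    """

    rtol: float = 1e-9
    atol: float = 1e-11
    t_cap: float = 20.0
    max_events: int = 8
    premature_tol: float = 0.02
    max_steps: int = 60000


DEFAULT_OPTIONS = IntegratorOptions()


class SectionMode(enum.IntEnum):
    """Contact configuration at the Poincaré anchor."""

    FLIGHT = 0
    STANCE_L = 1
    STANCE_R = 2


@dataclass
class StrideTrajectory:
    """Dense output of one stride plus realized event times and status."""

    t: np.ndarray                 # (n,) sample times, event points duplicated
    states: np.ndarray            # (n, 8) continuous states
    derivs: np.ndarray            # (n, 8) time derivatives at the samples
    modes: np.ndarray             # (n, 2) contact flags (0 swing / 1 stance)
    status: str
    params: ModelParams
    event_log: list[tuple[float, str]] = field(default_factory=list)
    event_times: EventTimes | None = None
    max_swing_amp: float = 0.0
    end_state: HybridState | None = None
    # prescribed-schedule diagnostics
    td_w_minus: np.ndarray | None = None   # pre-reset angular velocity per leg
    min_clearance: float = math.nan        # min swing foot height over the stride
    max_swing_excursion: float = math.nan  # max |alpha - phi| while swinging
    ev_states: np.ndarray | None = None    # (4, 8) states just before each event

    @property
    def T(self) -> float:
        return float(self.t[-1]) if len(self.t) else math.nan

    @property
    def completed(self) -> bool:
        return self.status == "periodic-candidate"

    def sample(self, times: np.ndarray) -> np.ndarray:
        """Cubic-Hermite interpolation of the stored steps at ``times``."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        out = np.empty((len(times), 8))
        idx = np.searchsorted(self.t, times, side="right") - 1
        idx = np.clip(idx, 0, len(self.t) - 2)
        for j, (tq, i) in enumerate(zip(times, idx)):
            # skip zero-length (event) segments
            while i > 0 and self.t[i + 1] == self.t[i]:
                i -= 1
            while i < len(self.t) - 2 and self.t[i + 1] == self.t[i]:
                i += 1
            h = self.t[i + 1] - self.t[i]
            if h <= 0:
                out[j] = self.states[i]
                continue
            s = (tq - self.t[i]) / h
            h00 = (2 * s - 3) * s * s + 1
            h10 = ((s - 2) * s + 1) * s
            h01 = (3 - 2 * s) * s * s
            h11 = (s - 1) * s * s
            out[j] = (
                h00 * self.states[i]
                + h10 * h * self.derivs[i]
                + h01 * self.states[i + 1]
                + h11 * h * self.derivs[i + 1]
            )
        return out

    def energies(self) -> np.ndarray:
        """Total mechanical energy at every stored sample (conservation audit)."""
        p = self.params
        E = 0.5 * (self.states[:, 4] ** 2 + self.states[:, 5] ** 2) + self.states[:, 1]
        for leg in (0, 1):
            stance = self.modes[:, leg] == 1
            l = self.states[stance, 1] / np.cos(self.states[stance, 2 + leg])
            E[stance] += 0.5 * p.k * (1.0 - l) ** 2
        return E

    def to_frame(self):
        """Tabular export (pandas DataFrame) with the documented columns."""
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.t,
                "x": self.states[:, 0],
                "y": self.states[:, 1],
                "alpha_l": self.states[:, 2],
                "alpha_r": self.states[:, 3],
                "xdot": self.states[:, 4],
                "ydot": self.states[:, 5],
                "alphadot_l": self.states[:, 6],
                "alphadot_r": self.states[:, 7],
                "mode_l": self.modes[:, 0],
                "mode_r": self.modes[:, 1],
            }
        )


def _state_to_core(state: HybridState):
    y = state.as_array()
    ml = 1 if state.mode_l is Mode.STANCE else 0
    mr = 1 if state.mode_r is Mode.STANCE else 0
    xcl = state.xc_l
    xcr = state.xc_r
    if ml and math.isnan(xcl):
        xcl = state.x + state.y * math.tan(state.alpha_l)
    if mr and math.isnan(xcr):
        xcr = state.x + state.y * math.tan(state.alpha_r)
    return y, ml, mr, xcl, xcr


def _core_to_state(yv, ml, mr, xcl, xcr) -> HybridState:
    return HybridState(
        x=yv[0], y=yv[1], alpha_l=yv[2], alpha_r=yv[3],
        xdot=yv[4], ydot=yv[5], alphadot_l=yv[6], alphadot_r=yv[7],
        mode_l=Mode.STANCE if ml else Mode.SWING,
        mode_r=Mode.STANCE if mr else Mode.SWING,
        xc_l=xcl if ml else math.nan,
        xc_r=xcr if mr else math.nan,
    )


def _run_core(
    state: HybridState,
    p: ModelParams,
    opts: IntegratorOptions,
    *,
    events_before_stop: int,
    stop_on_any_event: bool,
    store: bool,
    t_cap: float | None = None,
    sequence: np.ndarray | None = None,
) -> StrideTrajectory:
    p.require_normalized()
    y0, ml, mr, xcl, xcr = _state_to_core(state)
    seq = (
        np.empty(0, dtype=np.int64)
        if sequence is None
        else np.asarray(sequence, dtype=np.int64)
    )
    (
        status, t_end, y_end, ml_e, mr_e, xcl_e, xcr_e,
        ev, n_ev, max_amp, n_rec, t_h, y_h, f_h, m_h, evt, evc,
    ) = dyn._sim_core(
        y0, ml, mr, xcl, xcr,
        p.k, p.omega, p.phi_l, p.phi_r,
        opts.rtol, opts.atol,
        opts.t_cap if t_cap is None else t_cap,
        events_before_stop, stop_on_any_event,
        opts.max_events, opts.premature_tol,
        store, opts.max_steps, seq,
    )
    event_times = None
    if not np.any(np.isnan(ev)):
        event_times = EventTimes(
            t_ltd=float(ev[0]), t_llo=float(ev[1]),
            t_rtd=float(ev[2]), t_rlo=float(ev[3]), T=float(t_end),
        )
    end_state = _core_to_state(y_end, ml_e, mr_e, xcl_e, xcr_e)
    log = [(float(te), _EVENT_NAMES[int(c)]) for te, c in zip(evt, evc)]
    if not store:
        t_h = np.array([0.0, t_end])
        y_h = np.vstack([y0, y_end])
        f_h = np.zeros((2, 8))
        m_h = np.array([[ml, mr], [ml_e, mr_e]])
    return StrideTrajectory(
        t=np.asarray(t_h), states=np.asarray(y_h), derivs=np.asarray(f_h),
        modes=np.asarray(m_h), status=_STATUS_NAMES[int(status)], params=p,
        event_log=log, event_times=event_times,
        max_swing_amp=float(max_amp), end_state=end_state,
    )


def integrate_phase(
    state: HybridState,
    p: ModelParams,
    t_max: float = 10.0,
    opts: IntegratorOptions = DEFAULT_OPTIONS,
) -> tuple[StrideTrajectory, str]:
    """Adaptive integration until the first touchdown/liftoff/apex/failure
    event; the returned segment ends at the located event with the discrete
    reset already applied.  Returns (segment, event name)."""
    traj = _run_core(
        state, p, opts,
        events_before_stop=0, stop_on_any_event=True, store=True, t_cap=t_max,
    )
    if traj.status == "event":
        name = traj.event_log[-1][1] if traj.event_log else "apex"
    else:
        name = traj.status
    return traj, name


def simulate_stride(
    apex_state: HybridState,
    p: ModelParams,
    opts: IntegratorOptions = DEFAULT_OPTIONS,
    *,
    store: bool = False,
    events_required: int = 4,
    sequence: np.ndarray | None = None,
) -> StrideTrajectory:
    """Simulate one stride from an apex anchor to the next apex.

    The anchor must satisfy ``ydot = 0`` with at most one leg in stance;
    footfall order is not prescribed — events are collected as they occur.
    An explicit ``sequence`` of event channels switches on guided shooting
    (used by root solves to stay on a fixed event ordering).
    """
    if abs(apex_state.ydot) > 1e-8:
        raise ValueError(f"apex anchor requires ydot=0, got {apex_state.ydot}")
    if apex_state.mode_l is Mode.STANCE and apex_state.mode_r is Mode.STANCE:
        raise ValueError("double-support apex anchors are rejected")
    return _run_core(
        apex_state, p, opts,
        events_before_stop=events_required, stop_on_any_event=False, store=store,
        sequence=sequence,
    )


def simulate_prescribed(
    state: HybridState,
    p: ModelParams,
    sequence: np.ndarray,
    times: np.ndarray,
    opts: IntegratorOptions = DEFAULT_OPTIONS,
    *,
    store: bool = False,
) -> StrideTrajectory:
    """Integrate one stride with a prescribed event schedule.

    ``sequence`` lists the four touchdown/liftoff channels in order and
    ``times`` their times plus the stride time T.  Transitions are applied
    at the scheduled instants; the foot-height conditions at those instants
    are *not* enforced here — they are residuals of the gait boundary value
    problem.  Swing-foot ground crossings between scheduled events are
    ignored (massless-leg template convention); the minimum swing-foot
    clearance is recorded as a diagnostic.
    """
    p.require_normalized()
    y0, ml, mr, xcl, xcr = _state_to_core(state)
    seq = np.asarray(sequence, dtype=np.int64)
    times = np.asarray(times, dtype=float)
    (
        status, y_end, ev_states, td_w_minus, min_clear, max_amp, max_exc,
        n_rec, t_h, y_h, f_h, m_h,
    ) = dyn._sim_fixed_times(
        y0, ml, mr, xcl, xcr,
        p.k, p.omega, p.phi_l, p.phi_r,
        opts.rtol, opts.atol, seq, times,
        store, opts.max_steps,
    )
    slots = {int(c): float(times[i]) for i, c in enumerate(seq)}
    event_times = None
    if len(slots) == 4:
        event_times = EventTimes(
            t_ltd=slots[dyn.EV_TD_L], t_llo=slots[dyn.EV_LO_L],
            t_rtd=slots[dyn.EV_TD_R], t_rlo=slots[dyn.EV_LO_R],
            T=float(times[4]),
        )
    # a completed prescribed stride returns to the anchor's contact pattern
    end_state = _core_to_state(
        y_end, ml, mr,
        y_end[0] + y_end[1] * math.tan(y_end[2]) if ml else math.nan,
        y_end[0] + y_end[1] * math.tan(y_end[3]) if mr else math.nan,
    )
    if not store:
        t_h = np.array([0.0, times[4]])
        y_h = np.vstack([y0, y_end])
        f_h = np.zeros((2, 8))
        m_h = np.array([[ml, mr], [ml, mr]])
    log = [(float(times[i]), _EVENT_NAMES[int(c)]) for i, c in enumerate(seq)]
    return StrideTrajectory(
        t=np.asarray(t_h), states=np.asarray(y_h), derivs=np.asarray(f_h),
        modes=np.asarray(m_h), status=_STATUS_NAMES[int(status)], params=p,
        event_log=log, event_times=event_times,
        max_swing_amp=float(max_amp), end_state=end_state,
        td_w_minus=np.asarray(td_w_minus),
        min_clearance=float(min_clear),
        max_swing_excursion=float(max_exc),
        ev_states=np.asarray(ev_states),
    )


def sequence_from_event_times(et: EventTimes) -> np.ndarray:
    """Event-channel ordering realized by a stride (touchdowns first on ties),
    suitable as the guided-shooting sequence for nearby candidates."""
    items = [
        (et.t_ltd, 0, dyn.EV_TD_L),
        (et.t_rtd, 0, dyn.EV_TD_R),
        (et.t_llo, 1, dyn.EV_LO_L),
        (et.t_rlo, 1, dyn.EV_LO_R),
    ]
    items.sort()
    return np.array([c for _, _, c in items], dtype=np.int64)


# ---------------------------------------------------------------------------
# Reduced coordinates on the Poincaré section
# ---------------------------------------------------------------------------
# The section is ydot = 0 (apex); translation invariance fixes x = 0.  The
# reduced state is s = [y, xdot, alpha_l, alphadot_l, alpha_r, alphadot_r].
# For a stance anchor the stance leg's angular velocity is not free: it is
# pinned by the holonomic constraint, but it is kept in s for uniformity.


def state_from_reduced(
    s: np.ndarray, smode: SectionMode = SectionMode.FLIGHT
) -> HybridState:
    y, vx, al, wl, ar, wr = (float(v) for v in s)
    st = HybridState(
        x=0.0, y=y, alpha_l=al, alpha_r=ar,
        xdot=vx, ydot=0.0, alphadot_l=wl, alphadot_r=wr,
    )
    if smode == SectionMode.STANCE_L:
        st.mode_l = Mode.STANCE
        st.alphadot_l = -vx * math.cos(al) ** 2 / y
        st.xc_l = y * math.tan(al)
    elif smode == SectionMode.STANCE_R:
        st.mode_r = Mode.STANCE
        st.alphadot_r = -vx * math.cos(ar) ** 2 / y
        st.xc_r = y * math.tan(ar)
    return st


def reduced_from_state(state: HybridState) -> tuple[np.ndarray, SectionMode]:
    s = np.array(
        [
            state.y, state.xdot,
            state.alpha_l, state.alphadot_l,
            state.alpha_r, state.alphadot_r,
        ]
    )
    if state.mode_l is Mode.STANCE:
        smode = SectionMode.STANCE_L
    elif state.mode_r is Mode.STANCE:
        smode = SectionMode.STANCE_R
    else:
        smode = SectionMode.FLIGHT
    return s, smode


def poincare_map(
    s: np.ndarray,
    p: ModelParams,
    smode: SectionMode = SectionMode.FLIGHT,
    opts: IntegratorOptions = DEFAULT_OPTIONS,
    sequence: np.ndarray | None = None,
) -> tuple[np.ndarray, SectionMode, StrideTrajectory]:
    """Stride-to-stride return map in reduced apex coordinates.

    Returns (s_next, end section mode, the underlying trajectory); fixed
    points of this map are periodic gaits.  On failure the returned reduced
    state is the terminal state (status in the trajectory).
    """
    st = state_from_reduced(s, smode)
    traj = _run_core(
        st, p, opts, events_before_stop=4, stop_on_any_event=False, store=False,
        sequence=sequence,
    )
    s_next, smode_next = reduced_from_state(traj.end_state)
    return s_next, smode_next, traj


def apex_energy(s: np.ndarray, smode: SectionMode, p: ModelParams) -> float:
    """Total energy of a reduced anchor point."""
    return total_energy(state_from_reduced(s, smode), p)
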