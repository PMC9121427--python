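"""Periodic-gait search and classification.

A gait is a fixed point of the apex-to-apex return map.  With parameters
fixed the model is conservative, so periodic solutions form one-dimensional
families parameterized by total energy; a stand-alone search therefore
closes the spare degree of freedom with an anchor (total energy, apex
forward speed, or a pseudo-arclength plane supplied by the continuation).

Two formulations are provided in reduced apex coordinates
``s = [y, xdot, alpha_l, alphadot_l, alpha_r, alphadot_r]`` (x = 0, ydot = 0
on the section).  ``find_gait`` shoots on the free event-detecting return
map (event times realized by detection) — convenient for flight-dominated
seeds.  ``refine_gait`` solves the prescribed-schedule boundary value
problem with the event times as unknowns (the 13-variable / 12-constraint
formulation with the translation pair removed); it is the workhorse behind
continuation and supports every gait, including walking, whose strides
involve swing-foot scuffing that free event detection cannot cross.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as _dc_replace
from dataclasses import replace as _opts_replace

import numpy as np
from scipy.optimize import least_squares

from . import _dynamics as dyn
from .hybrid_sim import (
    DEFAULT_OPTIONS,
    IntegratorOptions,
    SectionMode,
    StrideTrajectory,
    apex_energy,
    poincare_map,
    sequence_from_event_times,
    simulate_prescribed,
    simulate_stride,
    state_from_reduced,
)
from .model_core import EventTimes, GaitLabel, ModelParams, Side

__all__ = [
    "PeriodicSolution",
    "Chart",
    "GaitSearchError",
    "periodicity_residual",
    "find_gait",
    "refine_gait",
    "resolve_gait",
    "classify_gait",
    "gait_metrics",
    "swap_legs",
    "mirror_solution",
    "bvp_vector",
    "times_from_sequence",
]

PENALTY = 10.0


class GaitSearchError(RuntimeError):
    """The root solve did not converge to a valid periodic solution."""


@dataclass
class PeriodicSolution:
    """A fixed point of the return map with its gait metadata."""

    s: np.ndarray
    smode: SectionMode
    params: ModelParams
    event_times: EventTimes
    energy: float
    label: GaitLabel
    stride_length: float
    avg_speed: float
    duty_factor: float
    residual_norm: float
    max_swing_amp: float = 0.0
    floquet: np.ndarray | None = None
    sync: bool = False
    sequence: np.ndarray | None = None   # solved event-channel ordering
    min_clearance: float = math.nan      # min swing-foot height (diagnostic)
    max_swing_excursion: float = math.nan  # max |alpha - phi| while swinging
    td_w_minus: np.ndarray | None = None  # pre-reset leg rate at touchdown

    @property
    def T(self) -> float:
        return self.event_times.T

    @property
    def apex_speed(self) -> float:
        """Forward speed at the anchoring apex [sqrt(g*lo)]."""
        return float(self.s[1])

    def to_record(self) -> dict:
        rec = {
            "y0": float(self.s[0]), "xdot0": float(self.s[1]),
            "alpha_l0": float(self.s[2]), "alphadot_l0": float(self.s[3]),
            "alpha_r0": float(self.s[4]), "alphadot_r0": float(self.s[5]),
            "section": self.smode.name.lower(),
            "energy": self.energy,
            "t_ltd": self.event_times.t_ltd, "t_llo": self.event_times.t_llo,
            "t_rtd": self.event_times.t_rtd, "t_rlo": self.event_times.t_rlo,
            "T": self.T,
            "label": self.label.value,
            "stride_length": self.stride_length,
            "avg_speed": self.avg_speed,
            "duty_factor": self.duty_factor,
            "residual_norm": self.residual_norm,
            "max_swing_amp": self.max_swing_amp,
            "min_clearance": self.min_clearance,
            "max_swing_excursion": self.max_swing_excursion,
            "sequence": None if self.sequence is None else [int(c) for c in self.sequence],
            "params": self.params.to_dict(),
        }
        if self.floquet is not None:
            rec["floquet_re"] = [float(v.real) for v in self.floquet]
            rec["floquet_im"] = [float(v.imag) for v in self.floquet]
        return rec

    @classmethod
    def from_record(cls, rec: dict) -> "PeriodicSolution":
        p = ModelParams(**rec["params"])
        fl = None
        if "floquet_re" in rec:
            fl = np.array(rec["floquet_re"]) + 1j * np.array(rec["floquet_im"])
        return cls(
            s=np.array([rec["y0"], rec["xdot0"], rec["alpha_l0"],
                        rec["alphadot_l0"], rec["alpha_r0"], rec["alphadot_r0"]]),
            smode=SectionMode[rec["section"].upper()],
            params=p,
            event_times=EventTimes(rec["t_ltd"], rec["t_llo"], rec["t_rtd"],
                                   rec["t_rlo"], rec["T"]),
            energy=rec["energy"],
            label=GaitLabel(rec["label"]),
            stride_length=rec["stride_length"],
            avg_speed=rec["avg_speed"],
            duty_factor=rec["duty_factor"],
            residual_norm=rec["residual_norm"],
            max_swing_amp=rec.get("max_swing_amp", 0.0),
            min_clearance=rec.get("min_clearance", math.nan),
            max_swing_excursion=rec.get("max_swing_excursion", math.nan),
            sequence=None if rec.get("sequence") is None else np.array(rec["sequence"], dtype=np.int64),
            floquet=fl,
        )


class Chart:
    """Packing of the reduced apex state into free solver variables.

    ``smode`` selects the anchor's contact configuration: for a stance
    anchor the stance leg's angular velocity is pinned by the holonomic
    constraint and removed from the unknowns.  ``sync=True`` restricts to
    the leg-synchronized subspace (alpha_l = alpha_r), used to continue
    hopping branches robustly.
    """

    def __init__(self, smode: SectionMode = SectionMode.FLIGHT, sync: bool = False):
        if sync and smode != SectionMode.FLIGHT:
            raise ValueError("synchronized subspace requires a flight anchor")
        self.smode = smode
        self.sync = sync
        if sync:
            self.n = 4
        elif smode == SectionMode.FLIGHT:
            self.n = 6
        else:
            self.n = 5

    def pack(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        if self.sync:
            return np.array([s[0], s[1], 0.5 * (s[2] + s[4]), 0.5 * (s[3] + s[5])])
        if self.smode == SectionMode.STANCE_L:
            return s[[0, 1, 2, 4, 5]]
        if self.smode == SectionMode.STANCE_R:
            return s[[0, 1, 2, 3, 4]]
        return s.copy()

    def unpack(self, u: np.ndarray) -> np.ndarray:
        if self.sync:
            y, vx, a, w = u
            return np.array([y, vx, a, w, a, w])
        if self.smode == SectionMode.STANCE_L:
            y, vx, al, ar, wr = u
            wl = -vx * math.cos(al) ** 2 / y
            return np.array([y, vx, al, wl, ar, wr])
        if self.smode == SectionMode.STANCE_R:
            y, vx, al, wl, ar = u
            wr = -vx * math.cos(ar) ** 2 / y
            return np.array([y, vx, al, wl, ar, wr])
        return np.asarray(u, dtype=float).copy()

    def pack_residual(self, r: np.ndarray) -> np.ndarray:
        if self.sync:
            return np.array(
                [r[0], r[1], 0.5 * (r[2] + r[4]), 0.5 * (r[3] + r[5])]
            )
        if self.smode == SectionMode.STANCE_L:
            return r[[0, 1, 2, 4, 5]]
        if self.smode == SectionMode.STANCE_R:
            return r[[0, 1, 2, 3, 4]]
        return np.asarray(r)

    # --- boundary-value (prescribed schedule) packing ---------------------
    @property
    def n_times(self) -> int:
        return 3 if self.sync else 5

    @property
    def n_events(self) -> int:
        return 2 if self.sync else 4

    def pack_times(self, times5: np.ndarray) -> np.ndarray:
        if self.sync:
            return np.array([times5[0], times5[2], times5[4]])
        return np.asarray(times5, dtype=float).copy()

    def unpack_times(self, ut: np.ndarray) -> np.ndarray:
        if self.sync:
            td, lo, T = ut
            return np.array([td, td, lo, lo, T])
        return np.asarray(ut, dtype=float).copy()

    def pack_events(self, g4: np.ndarray) -> np.ndarray:
        if self.sync:
            return np.array([g4[0], g4[2]])
        return np.asarray(g4)


def _map_residual(
    u: np.ndarray,
    chart: Chart,
    p: ModelParams,
    opts: IntegratorOptions,
    sequence: np.ndarray | None = None,
) -> tuple[np.ndarray, StrideTrajectory | None]:
    s = chart.unpack(u)
    if s[0] <= 0.05:
        return np.full(chart.n, PENALTY), None
    s1, smode1, traj = poincare_map(s, p, chart.smode, opts, sequence=sequence)
    if traj.status != "periodic-candidate" or smode1 != chart.smode:
        return np.full(chart.n, PENALTY), traj
    return chart.pack_residual(s1 - s), traj


def periodicity_residual(
    s: np.ndarray,
    times: EventTimes,
    p: ModelParams,
    smode: SectionMode = SectionMode.FLIGHT,
    opts: IntegratorOptions = DEFAULT_OPTIONS,
) -> np.ndarray:
    """The 12-component boundary-value residual of the gait root problem.

    Components: positional periodicity of (x modulo the forward translation,
    y, alpha_l, alpha_r), velocity periodicity of (xdot, ydot, alphadot_l,
    alphadot_r) evaluated at the candidate stride time, and the four
    touchdown/liftoff leg-length conditions y(t) - lo*cos(alpha_i(t)) = 0
    evaluated at the candidate event times.  A failed stride yields a
    large-penalty residual.
    """
    st0 = state_from_reduced(np.asarray(s, dtype=float), smode)
    traj = simulate_stride(st0, p, opts, store=True)
    if traj.status != "periodic-candidate":
        return np.full(12, PENALTY)
    q0 = st0.as_array()
    qT = traj.sample(np.array([times.T]))[0]
    stride_len = float(traj.states[-1, 0] - traj.states[0, 0])
    r = np.empty(12)
    r[0] = qT[0] - q0[0] - stride_len
    r[1:4] = qT[1:4] - q0[1:4]
    r[4:8] = qT[4:8] - q0[4:8]
    ev = [
        (times.t_ltd, 2), (times.t_llo, 2),
        (times.t_rtd, 3), (times.t_rlo, 3),
    ]
    for j, (te, ai) in enumerate(ev):
        ye = traj.sample(np.array([te]))[0]
        r[8 + j] = ye[1] - math.cos(ye[ai])
    return r


def _build_solution(
    s: np.ndarray,
    chart: Chart,
    p: ModelParams,
    opts: IntegratorOptions,
    residual_norm: float,
    tol_t_rel: float = 1e-3,
) -> PeriodicSolution:
    st = state_from_reduced(s, chart.smode)
    traj = simulate_stride(st, p, opts, store=False)
    if traj.status != "periodic-candidate" or traj.event_times is None:
        raise GaitSearchError(f"stride failed while building solution: {traj.status}")
    et = traj.event_times
    stride_length = float(traj.end_state.x - st.x)
    T = et.T
    duty = 0.5 * (
        et.stance_duration(Side.LEFT) + et.stance_duration(Side.RIGHT)
    ) / T
    label = classify_gait(et, tol_t_rel * T)
    return PeriodicSolution(
        s=np.asarray(s, dtype=float).copy(),
        smode=chart.smode,
        params=p,
        event_times=et,
        energy=apex_energy(s, chart.smode, p),
        label=label,
        stride_length=stride_length,
        avg_speed=stride_length / T,
        duty_factor=duty,
        residual_norm=residual_norm,
        max_swing_amp=traj.max_swing_amp,
        sync=chart.sync,
    )


def find_gait(
    seed: np.ndarray,
    p: ModelParams,
    anchor: tuple[str, object] | None = ("energy", None),
    smode: SectionMode = SectionMode.FLIGHT,
    sync: bool = False,
    opts: IntegratorOptions = DEFAULT_OPTIONS,
    tol: float = 1e-8,
    max_nfev: int = 400,
    sequence: np.ndarray | None = None,
) -> PeriodicSolution:
    """Solve the periodic-gait root problem from a seed apex state.

    Parameters
    ----------
    seed : reduced apex state [y, xdot, alpha_l, alphadot_l, alpha_r, alphadot_r]
    anchor : closes the spare (energy) direction of the 1-D solution family:
        ("energy", E) fixes total energy (E=None anchors at the seed's energy),
        ("speed", v) fixes apex forward speed,
        ("plane", (u_ref, tau)) fixes the pseudo-arclength plane
        dot(u - u_ref, tau) = 0, and None leaves the family direction free.
    sync : restrict to the leg-synchronized (hopping) subspace.
    sequence : optional guided-shooting event ordering used while the
        corrector iterates (the converged orbit is always re-validated
        with free event detection).
    """
    chart = Chart(smode, sync)
    seed = np.asarray(seed, dtype=float)
    u0 = chart.pack(seed)

    if anchor is not None and anchor[0] == "energy" and anchor[1] is None:
        anchor = ("energy", apex_energy(seed, smode, p))

    # The premature-touchdown guard is suspended while the corrector
    # iterates (transient candidates may graze it); the converged orbit is
    # re-simulated and validated against the real criterion below.
    search_opts = _opts_replace(opts, premature_tol=math.inf)

    def fun(u):
        r, _ = _map_residual(u, chart, p, search_opts, sequence=sequence)
        if anchor is None:
            return r
        kind, val = anchor
        if kind == "energy":
            extra = apex_energy(chart.unpack(u), chart.smode, p) - val
        elif kind == "speed":
            extra = u[1] - val
        elif kind == "plane":
            u_ref, tau = val
            extra = float(np.dot(u - u_ref, tau))
        else:
            raise ValueError(f"unknown anchor kind {kind!r}")
        return np.append(r, extra)

    res = least_squares(
        fun, u0, method="lm", diff_step=1e-6,
        ftol=1e-15, xtol=1e-14, gtol=1e-15, max_nfev=max_nfev,
    )
    r_per, traj = _map_residual(res.x, chart, p, opts)
    rnorm = float(np.linalg.norm(r_per))
    if rnorm > tol:
        raise GaitSearchError(
            f"gait search did not converge: periodicity residual {rnorm:.3e}"
            + (f" (stride status {traj.status})" if traj is not None else "")
        )
    return _build_solution(chart.unpack(res.x), chart, p, opts, rnorm)


def classify_gait(et: EventTimes, tol_t: float | None = None) -> GaitLabel:
    """Label a periodic solution from its realized event times.

    Simultaneity is tested before strict ordering: synchronized legs give
    hopping; otherwise, absence of any aerial phase gives walking, a
    double-stance overlap with an aerial phase gives skipping, and two
    aerial phases are symmetric or asymmetric running depending on whether
    their durations differ by more than ``tol_t`` (default ``1e-3 * T``).
    """
    T = et.T
    if tol_t is None:
        tol_t = 1e-3 * T
    if not et.validate(tol=tol_t):
        return GaitLabel.DEGENERATE
    if abs(et.t_ltd - et.t_rtd) < tol_t and abs(et.t_llo - et.t_rlo) < tol_t:
        return GaitLabel.HOPPING
    aerial = et.aerial_intervals()
    durations = [b - a for a, b in aerial if b - a > tol_t]
    if not durations:
        return GaitLabel.WALKING
    if len(durations) == 1:
        return GaitLabel.SKIPPING
    if len(durations) == 2:
        if abs(durations[0] - durations[1]) < tol_t:
            return GaitLabel.SYMMETRIC_RUNNING
        return GaitLabel.ASYMMETRIC_RUNNING
    return GaitLabel.DEGENERATE


def gait_metrics(sol: PeriodicSolution) -> dict:
    """Duty factor, stride time, stride length and average speed."""
    return {
        "duty_factor": sol.duty_factor,
        "stride_time": sol.T,
        "stride_length": sol.stride_length,
        "average_speed": sol.avg_speed,
    }


def mirror_solution(sol: PeriodicSolution) -> PeriodicSolution:
    """Spatial mirror (x -> -x): reverses forward speed and leg angles and
    negates both neutral angles; at phi_l = phi_r = 0 this maps solutions
    of the nominal model onto forward-moving counterparts."""
    s = sol.s
    s_m = np.array([s[0], -s[1], -s[2], -s[3], -s[4], -s[5]])
    return _dc_replace(
        sol,
        s=s_m,
        params=sol.params.with_phis(-sol.params.phi_l, -sol.params.phi_r),
        stride_length=-sol.stride_length,
        avg_speed=-sol.avg_speed,
    )


def swap_legs(sol: PeriodicSolution) -> PeriodicSolution:
    """Left/right exchange of a solution (valid model trajectory whenever the
    swapped parameters are used; for phi_l = phi_r this maps solutions to
    solutions of the same model)."""
    s = sol.s
    s_swapped = np.array([s[0], s[1], s[4], s[5], s[2], s[3]])
    smode = {
        SectionMode.FLIGHT: SectionMode.FLIGHT,
        SectionMode.STANCE_L: SectionMode.STANCE_R,
        SectionMode.STANCE_R: SectionMode.STANCE_L,
    }[sol.smode]
    et = sol.event_times
    seq_swapped = None
    if sol.sequence is not None:
        remap = {
            dyn.EV_TD_L: dyn.EV_TD_R, dyn.EV_TD_R: dyn.EV_TD_L,
            dyn.EV_LO_L: dyn.EV_LO_R, dyn.EV_LO_R: dyn.EV_LO_L,
        }
        seq_swapped = np.array([remap[int(c)] for c in sol.sequence],
                               dtype=np.int64)
    return _dc_replace(
        sol,
        s=s_swapped,
        smode=smode,
        params=sol.params.with_phis(sol.params.phi_r, sol.params.phi_l),
        event_times=EventTimes(et.t_rtd, et.t_rlo, et.t_ltd, et.t_llo, et.T),
        sequence=seq_swapped,
    )


# ---------------------------------------------------------------------------
# Boundary-value (prescribed event schedule) formulation
# ---------------------------------------------------------------------------
# Unknowns: reduced apex state (chart variables) plus the event times and
# the stride time.  Residuals: state periodicity on the chart, the apex
# closure ydot(T) = 0, and the foot-height conditions
# y(t_i^j) - lo*cos(alpha_i(t_i^j)) = 0 at the scheduled events.  This is
# the 13-variable / 12-constraint root problem with the translation pair
# (x, its periodicity) removed and one anchor closing the energy direction.

_CH_ANGLE = {dyn.EV_TD_L: 2, dyn.EV_LO_L: 2, dyn.EV_TD_R: 3, dyn.EV_LO_R: 3}


def times_from_sequence(et: EventTimes, seq: np.ndarray) -> np.ndarray:
    """Schedule vector [t1..t4, T] ordered as the given channel sequence."""
    by_ch = {
        dyn.EV_TD_L: et.t_ltd, dyn.EV_LO_L: et.t_llo,
        dyn.EV_TD_R: et.t_rtd, dyn.EV_LO_R: et.t_rlo,
    }
    return np.array([by_ch[int(c)] for c in seq] + [et.T])


def _bvp_penalty(chart: "Chart") -> np.ndarray:
    return np.full(chart.n + 1 + chart.n_events, PENALTY)


def _bvp_residual(
    u: np.ndarray,
    chart: "Chart",
    seq: np.ndarray,
    p: ModelParams,
    opts: IntegratorOptions,
) -> tuple[np.ndarray, StrideTrajectory | None]:
    n = chart.n
    s = chart.unpack(u[:n])
    times = chart.unpack_times(u[n:])
    if s[0] <= 0.05 or times[4] <= 1e-3 or times[4] > opts.t_cap:
        return _bvp_penalty(chart), None
    prev = 0.0
    for tv in times:
        if tv < prev - 1e-9:
            return _bvp_penalty(chart), None
        prev = max(prev, tv)
    times = np.maximum.accumulate(np.maximum(times, 0.0))
    st = state_from_reduced(s, chart.smode)
    traj = simulate_prescribed(st, p, seq, times, opts)
    if traj.status != "periodic-candidate":
        return _bvp_penalty(chart), traj
    e = traj.end_state
    s_end = np.array(
        [e.y, e.xdot, e.alpha_l, e.alphadot_l, e.alpha_r, e.alphadot_r]
    )
    # periodicity measured relative to the state scale: the integrator's
    # relative accuracy sets an absolute error floor proportional to the
    # state magnitude (fast gaits have apex speeds up to ~30)
    r_state = chart.pack_residual(s_end - s) / (
        1.0 + np.abs(chart.pack_residual(s))
    )
    g = np.empty(4)
    for k_, ch in enumerate(seq):
        ye = traj.ev_states[k_]
        g[k_] = ye[1] - math.cos(ye[_CH_ANGLE[int(ch)]])
    res = np.concatenate([r_state, [e.ydot], chart.pack_events(g)])
    return res, traj


def _build_solution_bvp(
    u: np.ndarray,
    chart: "Chart",
    seq: np.ndarray,
    p: ModelParams,
    opts: IntegratorOptions,
    residual_norm: float,
    tol_t_rel: float = 1e-3,
) -> PeriodicSolution:
    s = chart.unpack(u[: chart.n])
    times = chart.unpack_times(u[chart.n:])
    st = state_from_reduced(s, chart.smode)
    traj = simulate_prescribed(st, p, seq, times, opts)
    if traj.status != "periodic-candidate":
        raise GaitSearchError(f"prescribed stride failed: {traj.status}")
    # anterior rotation at a solved touchdown (premature contact) is
    # recorded in td_w_minus; callers decide whether it terminates a search
    wtd = traj.td_w_minus
    et = traj.event_times
    T = et.T
    duty = 0.5 * (
        et.stance_duration(Side.LEFT) + et.stance_duration(Side.RIGHT)
    ) / T
    stride_length = float(traj.end_state.x)
    return PeriodicSolution(
        s=np.asarray(s, dtype=float).copy(),
        smode=chart.smode,
        params=p,
        event_times=et,
        energy=apex_energy(s, chart.smode, p),
        label=classify_gait(et, tol_t_rel * T),
        stride_length=stride_length,
        avg_speed=stride_length / T,
        duty_factor=duty,
        residual_norm=residual_norm,
        max_swing_amp=traj.max_swing_amp,
        sync=chart.sync,
        sequence=np.asarray(seq, dtype=np.int64).copy(),
        min_clearance=traj.min_clearance,
        max_swing_excursion=traj.max_swing_excursion,
        td_w_minus=np.asarray(wtd),
    )


def refine_gait(
    seed_s: np.ndarray,
    seed_times: np.ndarray,
    seq: np.ndarray,
    p: ModelParams,
    anchor: tuple[str, object] | None = ("energy", None),
    smode: SectionMode = SectionMode.FLIGHT,
    sync: bool = False,
    opts: IntegratorOptions = DEFAULT_OPTIONS,
    tol: float = 1e-8,
    max_nfev: int = 600,
) -> PeriodicSolution:
    """Solve the prescribed-schedule boundary value problem from a seed.

    ``seed_s`` is the reduced apex state, ``seed_times`` the schedule
    [t1..t4, T] ordered as ``seq``.  The anchor semantics match
    :func:`find_gait`; for ("plane", (u_ref, tau)) the plane lives in the
    extended unknown space (chart variables + packed times).
    """
    chart = Chart(smode, sync)
    seed_s = np.asarray(seed_s, dtype=float)
    u0 = np.concatenate([chart.pack(seed_s), chart.pack_times(seed_times)])

    if anchor is not None and anchor[0] == "energy" and anchor[1] is None:
        anchor = ("energy", apex_energy(seed_s, smode, p))

    def fun(u):
        r, _ = _bvp_residual(u, chart, seq, p, opts)
        if anchor is None:
            return r
        kind, val = anchor
        if kind == "energy":
            extra = apex_energy(chart.unpack(u[: chart.n]), chart.smode, p) - val
        elif kind == "speed":
            extra = u[1] - val
        elif kind == "plane":
            u_ref, tau = val
            extra = float(np.dot(u - u_ref, tau))
        else:
            raise ValueError(f"unknown anchor kind {kind!r}")
        return np.append(r, extra)

    res = least_squares(
        fun, u0, method="lm", diff_step=1e-7,
        ftol=1e-15, xtol=1e-14, gtol=1e-15, max_nfev=max_nfev,
    )
    r_per, _traj = _bvp_residual(res.x, chart, seq, p, opts)
    rnorm = float(np.linalg.norm(r_per))
    if tol < rnorm < 1e-3:
        # LM occasionally stalls just short of convergence; one warm
        # restart recovers the remaining digits
        res = least_squares(
            fun, res.x, method="lm", diff_step=1e-8,
            ftol=1e-15, xtol=1e-15, gtol=1e-15, max_nfev=max_nfev,
        )
        r_per, _traj = _bvp_residual(res.x, chart, seq, p, opts)
        rnorm = float(np.linalg.norm(r_per))
    if rnorm > tol:
        raise GaitSearchError(
            f"BVP gait search did not converge: residual {rnorm:.3e}"
        )
    return _build_solution_bvp(res.x, chart, seq, p, opts, rnorm)


def resolve_gait(
    sol: PeriodicSolution,
    p: ModelParams | None = None,
    anchor: tuple[str, object] | None = ("energy", None),
    opts: IntegratorOptions = DEFAULT_OPTIONS,
    tol: float = 1e-8,
) -> PeriodicSolution:
    """Re-solve a periodic solution (possibly under new parameters).

    The seed's realized event ordering becomes the prescribed schedule;
    used for idempotent refinement and for transporting solutions across
    parameter changes.
    """
    if p is None:
        p = sol.params
    seq = (
        sol.sequence
        if sol.sequence is not None
        else sequence_from_event_times(sol.event_times)
    )
    times = times_from_sequence(sol.event_times, seq)
    return refine_gait(
        sol.s, times, seq, p, anchor=anchor, smode=sol.smode, sync=sol.sync,
        opts=opts, tol=tol,
    )


def bvp_vector(sol: PeriodicSolution) -> tuple[np.ndarray, "Chart", np.ndarray]:
    """Extended unknown vector (chart vars + packed times), its chart and
    sequence — the coordinates used by pseudo-arclength continuation."""
    chart = Chart(sol.smode, sol.sync)
    seq = (
        sol.sequence
        if sol.sequence is not None
        else sequence_from_event_times(sol.event_times)
    )
    times = times_from_sequence(sol.event_times, seq)
    u = np.concatenate([chart.pack(sol.s), chart.pack_times(times)])
    return u, chart, seq
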