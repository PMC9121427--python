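"""Branch continuation, bifurcation detection and NLSA parameter sweeps.

Periodic gaits form one-dimensional families (branches) as total energy
varies.  This module traces them with a pseudo-arclength predictor–
corrector in the extended boundary-value unknown space (reduced apex state
+ event schedule), detects and refines

* timing degeneracies, where two scheduled events become simultaneous
  (walking <-> symmetric running, skipping <-> asymmetrical running) —
  the continuation crosses them by flipping the prescribed event order;
* bifurcations, where a nontrivial Floquet multiplier of the return map
  crosses +1 (hop <-> skip: the leg-synchronized subspace loses
  transversal stability and leg motions desynchronize);

and provides the coupled / uncoupled neutral-leg-swing-angle sweeps built
on top of solution transport in parameter space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _dynamics as dyn
from .gait_search import (
    Chart,
    GaitSearchError,
    PeriodicSolution,
    _bvp_residual,
    bvp_vector,
    classify_gait,
    find_gait,
    refine_gait,
    resolve_gait,
    swap_legs,
    times_from_sequence,
)
from .hybrid_sim import (
    DEFAULT_OPTIONS,
    IntegratorOptions,
    SectionMode,
    poincare_map,
    simulate_prescribed,
    simulate_stride,
    state_from_reduced,
)
from .model_core import GaitLabel, ModelParams

__all__ = [
    "ContinuationOptions",
    "TransitionPoint",
    "Branch",
    "monodromy",
    "floquet_multipliers",
    "continue_branch",
    "trace_branch",
    "detect_bifurcation",
    "branch_switch",
    "locate_timing_degeneracy",
    "timing_gap",
    "continue_transition",
    "solve_transition_at",
    "transport_solution",
    "phi_existence_boundary",
    "continue_in_phi",
    "seed_vertical_hop",
    "seed_forward_hopping",
    "seed_symmetric_running",
    "sweep_coupled",
    "sweep_uncoupled",
]


@dataclass(frozen=True)
class ContinuationOptions:
    """Step control and termination rules for branch tracing."""

    ds0: float = 0.02          # initial arclength step
    ds_min: float = 1e-5
    ds_max: float = 0.35
    grow: float = 1.3
    max_points: int = 500
    speed_cap: float = 30.0    # |apex forward speed| beyond which tracing stops
    swing_amp_cap: float = math.inf  # rad; optional stop (amplitudes are
    # always recorded per solution so results can be filtered for the
    # biologically plausible range, e.g. 1.7 rad)
    tol: float = 1e-8
    min_T: float = 0.02
    # anterior leg rotation at a solved touchdown above this rate is a
    # premature contact; tracing stops there only if stop_on_premature is
    # set (solutions carry the diagnostic either way)
    premature_w: float = 0.02
    stop_on_premature: bool = False


DEFAULT_CONTINUATION = ContinuationOptions()


@dataclass
class TransitionPoint:
    """A refined special point on a branch."""

    solution: PeriodicSolution
    kind: str            # "timing-degeneracy" | "bifurcation" | "branch-end"
    detail: str = ""     # e.g. "skip<->asymmetric_run", termination reason
    critical_multiplier: complex | None = None
    eigenvector: np.ndarray | None = None

    @property
    def speed(self) -> float:
        return abs(self.solution.apex_speed)


@dataclass
class Branch:
    """An ordered one-parameter family of periodic solutions."""

    solutions: list[PeriodicSolution] = field(default_factory=list)
    transitions: list[TransitionPoint] = field(default_factory=list)
    termination: str = ""
    closed: bool = False
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.solutions)

    @property
    def speeds(self) -> np.ndarray:
        return np.array([s.apex_speed for s in self.solutions])

    @property
    def energies(self) -> np.ndarray:
        return np.array([s.energy for s in self.solutions])

    def labels(self) -> list[GaitLabel]:
        return [s.label for s in self.solutions]

    def max_speed(self) -> float:
        return float(np.max(np.abs(self.speeds))) if self.solutions else math.nan


# ---------------------------------------------------------------------------
# Floquet analysis
# ---------------------------------------------------------------------------

def _free_map_valid(sol: PeriodicSolution, opts: IntegratorOptions) -> bool:
    """Whether free event detection reproduces the solved stride (no
    scuffing ambiguity) so the plain return map can be differentiated."""
    try:
        traj = simulate_stride(state_from_reduced(sol.s, sol.smode), sol.params, opts)
    except ValueError:
        return False
    if traj.status != "periodic-candidate" or traj.event_times is None:
        return False
    a = traj.event_times.as_array()
    b = sol.event_times.as_array()
    return bool(np.max(np.abs(a - b)) < 1e-5 * max(1.0, b[-1]))


def _resolved_map(
    s: np.ndarray,
    p: ModelParams,
    seq: np.ndarray,
    times_guess: np.ndarray,
    smode: SectionMode,
    opts: IntegratorOptions,
) -> tuple[np.ndarray, np.ndarray]:
    """Return map with the event schedule re-solved for the given apex state.

    Newton-solves the five timing unknowns against the four foot-height
    conditions and the apex closure, keeping the prescribed ordering; this
    is the differentiable stride-to-stride map consistent with the
    boundary-value formulation.
    """
    from scipy.optimize import least_squares

    st = state_from_reduced(s, smode)
    ang = [2 if int(c) in (dyn.EV_TD_L, dyn.EV_LO_L) else 3 for c in seq]

    def fun(t5):
        tt = np.maximum.accumulate(np.maximum(t5, 0.0))
        traj = simulate_prescribed(st, p, seq, tt, opts)
        if traj.status != "periodic-candidate":
            return np.full(5, 10.0)
        g = [
            traj.ev_states[k][1] - math.cos(traj.ev_states[k][ang[k]])
            for k in range(4)
        ]
        return np.array(g + [traj.end_state.ydot])

    res = least_squares(
        fun, times_guess, method="lm", diff_step=1e-7,
        ftol=1e-14, xtol=1e-13, max_nfev=200,
    )
    tt = np.maximum.accumulate(np.maximum(res.x, 0.0))
    traj = simulate_prescribed(st, p, seq, tt, opts)
    e = traj.end_state
    s_end = np.array([e.y, e.xdot, e.alpha_l, e.alphadot_l, e.alpha_r, e.alphadot_r])
    return s_end, tt


def monodromy(
    sol: PeriodicSolution,
    h: float = 1e-6,
    opts: IntegratorOptions = DEFAULT_OPTIONS,
    force_resolved: bool = False,
) -> np.ndarray:
    """Finite-difference Jacobian of the return map at a fixed point.

    Computed in the full 6-dimensional reduced apex coordinates for flight
    anchors (so leg-desynchronization directions are visible even for
    synchronized solutions); for stance anchors the pinned leg rate is
    excluded (5x5).  Uses the free event-detecting map when it reproduces
    the solution's stride; otherwise differentiates the schedule-resolving
    map of the boundary-value formulation.
    """
    chart = Chart(sol.smode, sync=False)
    n = chart.n
    u0 = chart.pack(sol.s)
    use_free = (not force_resolved) and _free_map_valid(sol, opts)
    seq = sol.sequence
    if seq is None:
        from .hybrid_sim import sequence_from_event_times

        seq = sequence_from_event_times(sol.event_times)
    times = times_from_sequence(sol.event_times, seq)

    def themap(u):
        s = chart.unpack(u)
        if use_free:
            s1, smode1, traj = poincare_map(s, sol.params, sol.smode, opts)
            if traj.status != "periodic-candidate" or smode1 != sol.smode:
                raise GaitSearchError(f"map evaluation failed: {traj.status}")
            return chart.pack(s1)
        s1, _ = _resolved_map(s, sol.params, seq, times, sol.smode, opts)
        return chart.pack(s1)

    M = np.empty((n, n))
    for i in range(n):
        e = np.zeros(n)
        e[i] = h
        try:
            fp = themap(u0 + e)
            fm = themap(u0 - e)
            M[:, i] = (fp - fm) / (2 * h)
        except GaitSearchError:
            # fall back to one-sided difference if a perturbation fails
            f0 = themap(u0)
            try:
                fp = themap(u0 + e)
                M[:, i] = (fp - f0) / h
            except GaitSearchError:
                fm = themap(u0 - e)
                M[:, i] = (f0 - fm) / h
    return M


def floquet_multipliers(
    sol: PeriodicSolution,
    h: float = 1e-6,
    opts: IntegratorOptions = DEFAULT_OPTIONS,
) -> np.ndarray:
    """Eigenvalues of the linearized return map (Floquet multipliers)."""
    return np.linalg.eigvals(monodromy(sol, h=h, opts=opts))


def _antisym_block(M: np.ndarray) -> np.ndarray:
    """2x2 leg-desynchronization block of a monodromy matrix evaluated at a
    leg-synchronized fixed point, in coordinates
    (alpha_l - alpha_r, alphadot_l - alphadot_r) / 2."""
    # s = [y, vx, al, wl, ar, wr]; antisymmetric directions
    v1 = np.array([0.0, 0.0, 1.0, 0.0, -1.0, 0.0]) / 2.0
    v2 = np.array([0.0, 0.0, 0.0, 1.0, 0.0, -1.0]) / 2.0
    P = np.vstack([v1 * 2, v2 * 2])  # project
    B = np.empty((2, 2))
    for j, v in enumerate((v1, v2)):
        w = M @ v
        B[:, j] = P @ w
    return B


def _antisym_block_direct(
    sol: PeriodicSolution,
    h: float = 1e-6,
    opts: IntegratorOptions = DEFAULT_OPTIONS,
) -> np.ndarray:
    """Leg-desynchronization block by differentiating the free return map
    along the two antisymmetric directions only (4 strides instead of a
    full monodromy; valid on flight-anchored synchronized branches)."""
    s0 = sol.s
    p = sol.params
    dirs = (
        np.array([0.0, 0.0, 1.0, 0.0, -1.0, 0.0]),
        np.array([0.0, 0.0, 0.0, 1.0, 0.0, -1.0]),
    )
    proj = np.vstack([d / 2.0 for d in dirs])
    B = np.empty((2, 2))
    for j, d in enumerate(dirs):
        sp, smp, tp_ = poincare_map(s0 + h * d / 2.0, p, sol.smode, opts)
        sm, smm, tm_ = poincare_map(s0 - h * d / 2.0, p, sol.smode, opts)
        if (
            tp_.status != "periodic-candidate"
            or tm_.status != "periodic-candidate"
        ):
            raise GaitSearchError("antisymmetric perturbation stride failed")
        B[:, j] = proj @ ((sp - sm) / h)
    return B


# ---------------------------------------------------------------------------
# Pseudo-arclength continuation
# ---------------------------------------------------------------------------

def _fd_jacobian(fun, u, f0=None, h=1e-7):
    if f0 is None:
        f0 = fun(u)
    J = np.empty((len(f0), len(u)))
    for i in range(len(u)):
        e = np.zeros(len(u))
        e[i] = h * max(1.0, abs(u[i]))
        J[:, i] = (fun(u + e) - f0) / e[i]
    return J


def _branch_tangent(
    u: np.ndarray,
    chart: Chart,
    seq: np.ndarray,
    p: ModelParams,
    opts: IntegratorOptions,
) -> np.ndarray:
    """Unit tangent of the solution manifold: right null vector of the
    boundary-value Jacobian."""

    def fun(v):
        r, _ = _bvp_residual(v, chart, seq, p, opts)
        return r

    J = _fd_jacobian(fun, u)
    _, _, Vt = np.linalg.svd(J)
    tau = Vt[-1]
    return tau / np.linalg.norm(tau)


def timing_gap(sol: PeriodicSolution) -> float:
    """Signed separation between the later touchdown and the earlier leg's
    liftoff: negative in overlapping-stance patterns (walking, skipping),
    positive when the stances are disjoint (running gaits); zero at the
    walk<->run and skip<->asymmetrical-run degeneracies."""
    et = sol.event_times
    if et.t_ltd <= et.t_rtd:
        return et.t_rtd - et.t_llo
    return et.t_ltd - et.t_rlo


def _flip_permutation(seq: np.ndarray, i: int) -> np.ndarray:
    new = seq.copy()
    new[i], new[i + 1] = new[i + 1], new[i]
    return new


def _permute_times_block(u: np.ndarray, chart: Chart, i: int) -> np.ndarray:
    """Swap scheduled times i and i+1 inside the packed unknown vector."""
    v = u.copy()
    n = chart.n
    v[n + i], v[n + i + 1] = v[n + i + 1], v[n + i]
    return v


def _correct(
    u_pred: np.ndarray,
    tau: np.ndarray,
    seq: np.ndarray,
    p: ModelParams,
    smode: SectionMode,
    sync: bool,
    opts: IntegratorOptions,
    tol: float,
) -> PeriodicSolution:
    chart = Chart(smode, sync)
    s_seed = chart.unpack(u_pred[: chart.n])
    times_seed = chart.unpack_times(u_pred[chart.n:])
    return refine_gait(
        s_seed, times_seed, seq, p,
        anchor=("plane", (u_pred, tau)),
        smode=smode, sync=sync, opts=opts, tol=tol,
    )


def continue_branch(
    start: PeriodicSolution,
    direction: int = +1,
    copts: ContinuationOptions = DEFAULT_CONTINUATION,
    opts: IntegratorOptions = DEFAULT_OPTIONS,
    detect_degeneracies: bool = True,
) -> Branch:
    """Trace the one-dimensional solution family through ``start``.

    The predictor steps along the manifold tangent; the corrector re-solves
    the boundary value problem on the pseudo-arclength plane.  Timing
    degeneracies are crossed by flipping the two adjacent scheduled events
    (the refined crossing point is recorded as a transition); tracing stops
    at premature touchdown, falls, the swing-amplitude cap, the speed cap,
    corrector breakdown, point budget, or on closing a loop.
    """
    p = start.params
    smode, sync = start.smode, start.sync
    u, chart, seq = bvp_vector(start)
    tau = _branch_tangent(u, chart, seq, p, opts)
    tau = tau * float(direction)

    branch = Branch(
        solutions=[start],
        provenance={"params": p.to_dict(), "direction": direction},
    )
    us = [u.copy()]
    seqs = [seq.copy()]
    ds = copts.ds0
    prev_label = start.label

    while len(branch.solutions) < copts.max_points:
        u_pred = u + ds * tau
        try:
            sol_new = _correct(u_pred, tau, seq, p, smode, sync, opts, copts.tol)
        except GaitSearchError as err:
            if ds > copts.ds_min:
                ds = max(ds * 0.25, copts.ds_min)
                continue
            # attempt a sequence flip across a timing degeneracy
            flipped = _attempt_flip(
                u, tau, seq, p, smode, sync, opts, copts
            )
            if flipped is not None:
                seq_new, u_new_coords, tau_new, sol_new, tp = flipped
                if tp is not None:
                    branch.transitions.append(tp)
                seq = seq_new
                u = u_new_coords
                tau = tau_new
                branch.solutions.append(sol_new)
                us.append(u.copy())
                seqs.append(seq.copy())
                prev_label = sol_new.label
                ds = copts.ds0
                continue
            branch.termination = getattr(err, "reason", "") or "no-convergence"
            break

        u_new, _, _ = bvp_vector(sol_new)

        # termination rules
        if copts.stop_on_premature and sol_new.td_w_minus is not None and (
            np.nanmax(sol_new.td_w_minus) > copts.premature_w
        ):
            branch.solutions.append(sol_new)
            branch.termination = "premature-touchdown"
            break
        if abs(sol_new.apex_speed) > copts.speed_cap:
            branch.solutions.append(sol_new)
            branch.termination = "speed-cap"
            break
        if sol_new.max_swing_amp > copts.swing_amp_cap:
            branch.solutions.append(sol_new)
            branch.termination = "swing-amplitude"
            break
        if sol_new.T < copts.min_T:
            branch.solutions.append(sol_new)
            branch.termination = "stride-collapse"
            break
        # loop closure
        travelled = len(branch.solutions) > 12
        if travelled and np.linalg.norm(u_new - us[0]) < 1.5 * ds:
            branch.solutions.append(sol_new)
            branch.closed = True
            branch.termination = "closed-loop"
            break

        if detect_degeneracies and sol_new.label != prev_label:
            tp = _refine_label_change(
                branch.solutions[-1], sol_new, seq, p, smode, sync, opts, copts
            )
            if tp is not None:
                branch.transitions.append(tp)
        prev_label = sol_new.label

        tau_new = u_new - u
        nrm = np.linalg.norm(tau_new)
        if nrm > 0:
            tau = tau_new / nrm
        u = u_new
        branch.solutions.append(sol_new)
        us.append(u.copy())
        seqs.append(seq.copy())
        ds = min(ds * copts.grow, copts.ds_max)
    else:
        branch.termination = "point-budget"

    if not branch.termination:
        branch.termination = "point-budget"
    branch.provenance["u_vectors"] = us
    branch.provenance["sequences"] = seqs
    return branch


def _attempt_flip(u, tau, seq, p, smode, sync, opts, copts):
    """Cross a timing degeneracy by swapping the two nearest scheduled
    events; returns (new seq, new u, new tau, first solution beyond, the
    refined transition point) or None."""
    chart = Chart(smode, sync)
    if sync:
        return None
    times = chart.unpack_times(u[chart.n:])
    gaps = np.diff(times[:4])
    i = int(np.argmin(gaps))
    if gaps[i] > 0.05:
        return None
    seq_new = _flip_permutation(seq, i)
    u_al = _permute_times_block(u, chart, i)
    tau_al = _permute_times_block(tau, chart, i)
    for ds_try in (copts.ds0, 4 * copts.ds0, 0.25 * copts.ds0):
        u_pred = u_al + ds_try * tau_al
        try:
            sol_new = _correct(
                u_pred, tau_al, seq_new, p, smode, sync, opts, copts.tol
            )
        except GaitSearchError:
            continue
        # refine the degeneracy point itself (events i, i+1 simultaneous)
        tp = None
        try:
            tp_sol = _refine_simultaneity(u, seq, i, p, smode, sync, opts)
            tp = TransitionPoint(
                solution=tp_sol,
                kind="timing-degeneracy",
                detail=_degeneracy_detail(tp_sol),
            )
        except GaitSearchError:
            pass
        u_new, _, _ = bvp_vector(sol_new)
        tau_new = u_new - u_al
        tau_new /= np.linalg.norm(tau_new)
        return seq_new, u_new, tau_new, sol_new, tp
    return None


def _degeneracy_detail(sol: PeriodicSolution) -> str:
    et = sol.event_times
    aerial = et.aerial_intervals()
    if not aerial:
        return "walk<->run"
    return "skip<->asymmetric_run" if sol.label in (
        GaitLabel.SKIPPING, GaitLabel.ASYMMETRIC_RUNNING, GaitLabel.DEGENERATE
    ) else "walk<->run"


def _refine_simultaneity(u, seq, i, p, smode, sync, opts, tol_gap=1e-9):
    """Solve the boundary value problem with t_{i+1} = t_i imposed by
    construction (two scheduled events exactly simultaneous): the
    timing-degeneracy point itself.  Removing the duplicated time from the
    unknowns avoids the ordering-guard cliff at the degeneracy."""
    from scipy.optimize import least_squares

    chart = Chart(smode, sync)
    if sync:
        raise GaitSearchError("simultaneity refinement needs a full chart")
    n = chart.n
    keep = [j for j in range(5) if j != i + 1]

    def to_full_u(w):
        tt = np.empty(5)
        tt[keep] = w[n : n + 4]
        tt[i + 1] = tt[i]
        return np.concatenate([w[:n], tt])

    w0 = np.concatenate([u[:n], u[n:][keep]])

    def fun(w):
        r, _ = _bvp_residual(to_full_u(w), chart, seq, p, opts)
        return r

    res = least_squares(
        fun, w0, method="lm", diff_step=1e-7,
        ftol=1e-15, xtol=1e-14, max_nfev=400,
    )
    r_fin = fun(res.x)
    if np.linalg.norm(r_fin) > 1e-7:
        raise GaitSearchError("simultaneity refinement failed")
    from .gait_search import _build_solution_bvp

    return _build_solution_bvp(
        to_full_u(res.x), chart, seq, p, opts, float(np.linalg.norm(r_fin))
    )


def _refine_label_change(sol_a, sol_b, seq, p, smode, sync, opts, copts):
    """Refine a gait-label change between consecutive branch points when it
    corresponds to a timing simultaneity (gap sign change)."""
    ga, gb = timing_gap(sol_a), timing_gap(sol_b)
    if not (np.isfinite(ga) and np.isfinite(gb)) or ga * gb > 0:
        return None
    u_a, chart, _ = bvp_vector(sol_a)
    times = times_from_sequence(sol_a.event_times, seq)
    order = np.argsort(times[:4], kind="stable")
    # locate adjacent pair with the sign-changing gap
    i = int(np.argmin(np.diff(np.sort(times[:4]))))
    try:
        tp_sol = _refine_simultaneity(u_a, seq, i, p, smode, sync, opts)
    except GaitSearchError:
        return None
    return TransitionPoint(
        solution=tp_sol, kind="timing-degeneracy", detail=_degeneracy_detail(tp_sol)
    )


def trace_branch(
    start: PeriodicSolution,
    copts: ContinuationOptions = DEFAULT_CONTINUATION,
    opts: IntegratorOptions = DEFAULT_OPTIONS,
) -> Branch:
    """Continue in both directions from a start point and merge."""
    fwd = continue_branch(start, +1, copts, opts)
    bwd = continue_branch(start, -1, copts, opts)
    sols = list(reversed(bwd.solutions[1:])) + fwd.solutions
    br = Branch(
        solutions=sols,
        transitions=bwd.transitions + fwd.transitions,
        termination=f"bwd:{bwd.termination};fwd:{fwd.termination}",
        closed=fwd.closed or bwd.closed,
        provenance={"params": start.params.to_dict()},
    )
    return br


# ---------------------------------------------------------------------------
# Bifurcation detection and branch switching
# ---------------------------------------------------------------------------

def detect_bifurcation(
    branch: Branch,
    opts: IntegratorOptions = DEFAULT_OPTIONS,
    refine: bool = True,
    stride: int = 1,
) -> list[TransitionPoint]:
    """Locate +1 crossings of a nontrivial Floquet multiplier along a
    leg-synchronized (hopping) branch: sign changes of det(B - I) where B
    is the leg-desynchronization block of the monodromy.  Refined by
    bisection in arclength; each point carries the critical eigenvector.
    ``stride`` subsamples the branch for the scan (crossings are still
    bracketed between the sampled points)."""
    sols = branch.solutions[:: max(1, stride)]
    if branch.solutions and sols[-1] is not branch.solutions[-1]:
        sols.append(branch.solutions[-1])
    if len(sols) < 2:
        return []
    dets = []
    for sol in sols:
        try:
            B = _antisym_block(monodromy(sol, opts=opts))
            dets.append(float(np.linalg.det(B - np.eye(2))))
        except GaitSearchError:
            dets.append(np.nan)
    out: list[TransitionPoint] = []
    for k in range(len(sols) - 1):
        da, db = dets[k], dets[k + 1]
        if not (np.isfinite(da) and np.isfinite(db)) or da * db >= 0:
            continue
        sol_a, sol_b = sols[k], sols[k + 1]
        if refine:
            sol_c = _bisect_bifurcation(sol_a, sol_b, da, db, opts)
        else:
            sol_c = sol_a if abs(da) < abs(db) else sol_b
        B = _antisym_block(monodromy(sol_c, opts=opts))
        lam, vecs = np.linalg.eig(B)
        j = int(np.argmin(np.abs(lam - 1.0)))
        v2 = np.real(vecs[:, j])
        eigvec = np.zeros(6)
        eigvec[2], eigvec[3] = v2[0], v2[1]
        eigvec[4], eigvec[5] = -v2[0], -v2[1]
        if any(
            abs(t.solution.energy - sol_c.energy) < 1e-3
            and abs(t.speed - abs(sol_c.apex_speed)) < 1e-3
            for t in out
        ):
            continue
        out.append(
            TransitionPoint(
                solution=sol_c,
                kind="bifurcation",
                detail="hop<->skip",
                critical_multiplier=complex(lam[j]),
                eigenvector=eigvec / np.linalg.norm(eigvec),
            )
        )
    return out


def _bisect_bifurcation(sol_a, sol_b, da, db, opts, n_iter=30, tol=1e-3):
    """Secant/bisection refinement of det(B - I) = 0 between two branch
    points, re-solving on the chord with a pseudo-arclength plane."""
    u_a, chart, seq = bvp_vector(sol_a)
    u_b, _, _ = bvp_vector(sol_b)
    chord = u_b - u_a
    nrm = np.linalg.norm(chord)
    if nrm == 0:
        return sol_a
    tau = chord / nrm
    lo, hi = 0.0, 1.0
    flo, fhi = da, db
    sol_best = sol_a if abs(da) < abs(db) else sol_b
    for _ in range(n_iter):
        lam = lo - flo * (hi - lo) / (fhi - flo)
        lam = min(max(lam, lo + 0.05 * (hi - lo)), hi - 0.05 * (hi - lo))
        u_pred = u_a + lam * chord
        try:
            sol_m = _correct(
                u_pred, tau, seq, sol_a.params, sol_a.smode, sol_a.sync,
                opts, 1e-8,
            )
            Bm = _antisym_block(monodromy(sol_m, opts=opts))
            fm = float(np.linalg.det(Bm - np.eye(2)))
        except GaitSearchError:
            hi = lam
            continue
        sol_best = sol_m
        if abs(fm) < 1e-10 or hi - lo < 1e-10:
            return sol_m
        lam_crit = np.linalg.eigvals(Bm)
        if abs(lam_crit[np.argmin(np.abs(lam_crit - 1))] - 1.0) < tol:
            return sol_m
        if fm * flo < 0:
            hi, fhi = lam, fm
        else:
            lo, flo = lam, fm
    return sol_best


def branch_switch(
    tp: TransitionPoint,
    delta: float = 5e-3,
    opts: IntegratorOptions = DEFAULT_OPTIONS,
    tol: float = 1e-8,
) -> PeriodicSolution:
    """Seed and converge a solution on the branch emanating from a
    bifurcation point, displacing along the critical eigenvector (both
    signs tried, escalating the displacement on reconvergence to the old
    branch)."""
    sol0 = tp.solution
    if tp.eigenvector is None:
        raise ValueError("transition point carries no critical eigenvector")
    v = tp.eigenvector
    # full (non-sync) chart embedding of the bifurcation point
    full = replace(sol0, sync=False)
    seq0 = (
        sol0.sequence
        if sol0.sequence is not None and not sol0.sync
        else np.array(
            [dyn.EV_TD_R, dyn.EV_TD_L, dyn.EV_LO_R, dyn.EV_LO_L], dtype=np.int64
        )
    )
    chart = Chart(sol0.smode, sync=False)
    times0 = times_from_sequence(sol0.event_times, seq0)
    u0 = np.concatenate([chart.pack(sol0.s), chart.pack_times(times0)])
    v_ext = np.concatenate([v, np.zeros(5)])

    last_err: Exception | None = None
    for scale in (1.0, 3.0, 10.0, 30.0):
        for sign in (+1.0, -1.0):
            d = sign * scale * delta
            u_pred = u0 + d * v_ext
            try:
                sol_new = _correct(
                    u_pred, v_ext, seq0, sol0.params, sol0.smode, False,
                    opts, tol,
                )
            except GaitSearchError as err:
                last_err = err
                continue
            if np.linalg.norm(sol_new.s - sol0.s) > 0.2 * abs(d):
                return sol_new
    raise GaitSearchError(
        f"branch switch failed to leave the original branch ({last_err})"
    )


def locate_timing_degeneracy(
    branch: Branch,
    opts: IntegratorOptions = DEFAULT_OPTIONS,
    end_gap_tol: float = 1e-3,
) -> list[TransitionPoint]:
    """All refined timing-degeneracy points of a branch: those recorded
    during tracing, sign changes of the timing gap between consecutive
    stored solutions, and branch endpoints where the gap has shrunk to
    (near) zero — e.g. the walk<->run point, which terminates the
    flight-anchored running branch because the anchoring aerial phase
    itself vanishes there."""
    found = [t for t in branch.transitions if t.kind == "timing-degeneracy"]
    for sol_end in (branch.solutions[0], branch.solutions[-1]):
        g = timing_gap(sol_end)
        if not np.isfinite(g) or abs(g) > end_gap_tol or sol_end.sync:
            continue
        seq = sol_end.sequence
        if seq is None:
            continue
        u_e, chart, _ = bvp_vector(sol_end)
        times = times_from_sequence(sol_end.event_times, seq)
        i = int(np.argmin(np.diff(times[:4])))
        try:
            tp_sol = _refine_simultaneity(
                u_e, seq, i, sol_end.params, sol_end.smode, sol_end.sync, opts
            )
        except GaitSearchError:
            tp_sol = sol_end
        found.append(
            TransitionPoint(
                solution=tp_sol,
                kind="timing-degeneracy",
                detail=_degeneracy_detail(tp_sol),
            )
        )
    sols = branch.solutions
    for k in range(len(sols) - 1):
        ga, gb = timing_gap(sols[k]), timing_gap(sols[k + 1])
        if ga * gb >= 0 or not (np.isfinite(ga) and np.isfinite(gb)):
            continue
        sol_a = sols[k]
        if any(
            abs(t.solution.energy - sol_a.energy) < 1e-6 for t in found
        ):
            continue
        seq = sol_a.sequence
        if seq is None:
            continue
        u_a, chart, _ = bvp_vector(sol_a)
        times = times_from_sequence(sol_a.event_times, seq)
        i = int(np.argmin(np.diff(times[:4])))
        try:
            tp_sol = _refine_simultaneity(
                u_a, seq, i, sol_a.params, sol_a.smode, sol_a.sync, opts
            )
        except GaitSearchError:
            continue
        found.append(
            TransitionPoint(
                solution=tp_sol,
                kind="timing-degeneracy",
                detail=_degeneracy_detail(tp_sol),
            )
        )
    found.sort(key=lambda t: t.speed)
    unique: list[TransitionPoint] = []
    for t in found:
        if any(
            abs(t.speed - u.speed) < 1e-4 and abs(t.solution.energy - u.solution.energy) < 1e-4
            for u in unique
        ):
            continue
        unique.append(t)
    return unique


# ---------------------------------------------------------------------------
# Existence boundaries in NLSA space
# ---------------------------------------------------------------------------

def continue_in_phi(
    sol: PeriodicSolution,
    vary: str = "coupled",
    anchor: tuple[str, float | None] = ("speed", None),
    phi_range: tuple[float, float] = (-2.0, 2.0),
    copts: ContinuationOptions = DEFAULT_CONTINUATION,
    opts: IntegratorOptions = DEFAULT_OPTIONS,
    min_speed: float = 0.05,
) -> list[tuple[float, PeriodicSolution]]:
    """Pseudo-arclength continuation of a gait in the NLSA direction.

    Fixing the anchor (apex speed by default) slices the two-parameter
    solution surface into a curve over (state, phi); tracing it passes
    through folds in phi, so the extremal phi reached is the slice's
    existence boundary (typically terminated by premature touchdown for
    posterior NLSA, or corrector breakdown).  Returns sampled (phi,
    solution) pairs from both directions.
    """
    from scipy.optimize import least_squares

    p0 = sol.params
    chart = Chart(sol.smode, sol.sync)
    u0, _, seq = bvp_vector(sol)
    phi0 = p0.phi_l
    if anchor[0] == "speed":
        anchor = ("speed", sol.apex_speed if anchor[1] is None else anchor[1])

    def params_at(phi: float) -> ModelParams:
        if vary == "coupled":
            return p0.with_phis(phi, phi)
        if vary == "left":
            return p0.with_phis(phi, p0.phi_r)
        raise ValueError(f"unknown vary mode {vary!r}")

    def fun_plain(w):
        p = params_at(w[-1])
        r, _ = _bvp_residual(w[:-1], chart, seq, p, opts)
        if anchor[0] == "speed":
            extra = w[1] - anchor[1]
        else:
            extra = apex_energy_of(chart, w[: chart.n], p) - anchor[1]
        return np.append(r, extra)

    def apex_energy_of(ch, uu, p):
        from .hybrid_sim import apex_energy

        return apex_energy(ch.unpack(uu), ch.smode, p)

    def solve_on_plane(w_pred, tau_v):
        def fun(w):
            return np.append(fun_plain(w), float(np.dot(w - w_pred, tau_v)))

        res = least_squares(
            fun, w_pred, method="lm", diff_step=1e-7,
            ftol=1e-15, xtol=1e-14, max_nfev=300,
        )
        r = fun_plain(res.x)
        if np.linalg.norm(r) > 1e-7:
            raise GaitSearchError("phi-continuation corrector failed")
        p = params_at(res.x[-1])
        sol_new = _build_solution_bvp_public(
            res.x[:-1], chart, seq, p, opts, float(np.linalg.norm(r))
        )
        return res.x, sol_new

    v = np.append(u0, phi0)
    J = _fd_jacobian(fun_plain, v)
    _, _, Vt = np.linalg.svd(J)
    tau = Vt[-1]
    tau /= np.linalg.norm(tau)

    out: list[tuple[float, PeriodicSolution]] = [(phi0, sol)]
    for direction in (+1.0, -1.0):
        v_cur = v.copy()
        tau_cur = tau * direction
        ds = copts.ds0
        for _ in range(copts.max_points):
            v_pred = v_cur + ds * tau_cur
            try:
                v_new, sol_new = solve_on_plane(v_pred, tau_cur)
            except GaitSearchError:
                if ds > copts.ds_min:
                    ds = max(0.25 * ds, copts.ds_min)
                    continue
                break
            out.append((float(v_new[-1]), sol_new))
            step = v_new - v_cur
            nrm = np.linalg.norm(step)
            if nrm > 0:
                tau_cur = step / nrm
            v_cur = v_new
            ds = min(ds * copts.grow, copts.ds_max)
            if not (phi_range[0] <= v_new[-1] <= phi_range[1]):
                break
            if abs(sol_new.apex_speed) < min_speed:
                break
            if abs(sol_new.apex_speed) > copts.speed_cap:
                break
    return out

def phi_existence_boundary(
    rep: PeriodicSolution,
    phi_target: float,
    vary: str = "coupled",
    label: GaitLabel | None = None,
    step0: float = 0.1,
    resolution: float = 0.02,
    copts: ContinuationOptions | None = None,
    opts: IntegratorOptions = DEFAULT_OPTIONS,
) -> tuple[float, PeriodicSolution]:
    """March a gait family's NLSA toward ``phi_target`` until solutions
    disappear; returns (last phi with a solution, that solution).

    At each failed step the probe re-anchors: the local branch is traced
    coarsely and transport is retried from several representatives (the
    family may survive only in a shifted speed window).  The step is then
    bisected down to ``resolution``.
    """
    if copts is None:
        copts = ContinuationOptions(
            ds0=0.05, ds_max=0.6, grow=1.6, max_points=60, speed_cap=14.0
        )
    p0 = rep.params
    phi_cur = p0.phi_l
    cur = rep
    direction = 1.0 if phi_target > phi_cur else -1.0
    step = step0
    reps: list[PeriodicSolution] = [rep]

    def params_at(phi: float) -> ModelParams:
        if vary == "coupled":
            return p0.with_phis(phi, phi)
        return p0.with_phis(phi, p0.phi_r)

    def try_phi(phi: float) -> PeriodicSolution | None:
        for r in reps:
            try:
                sol = transport_solution(r, params_at(phi), opts, max_substeps=16)
            except GaitSearchError:
                continue
            if label is not None and sol.label != label:
                continue
            return sol
        return None

    def refresh_reps(sol: PeriodicSolution) -> None:
        reps.clear()
        reps.append(sol)
        try:
            br = trace_branch(sol, copts, opts)
        except GaitSearchError:
            return
        ns = len(br.solutions)
        if ns > 3:
            for frac in (0.25, 0.5, 0.75):
                cand = br.solutions[int(frac * (ns - 1))]
                if label is None or cand.label == label:
                    reps.append(cand)

    while direction * (phi_target - phi_cur) > 1e-12:
        step = min(step, direction * (phi_target - phi_cur))
        phi_try = phi_cur + direction * step
        sol = try_phi(phi_try)
        if sol is None and len(reps) == 1:
            refresh_reps(cur)
            sol = try_phi(phi_try)
        if sol is None:
            if step <= resolution:
                break
            step *= 0.5
            continue
        cur = sol
        phi_cur = phi_try
        reps[0] = sol
        step = min(step * 2.0, step0)
    return phi_cur, cur


# ---------------------------------------------------------------------------
# Continuation of transition points across NLSA values
# ---------------------------------------------------------------------------

def continue_transition(
    tp: TransitionPoint,
    vary: str = "coupled",
    phi_range: tuple[float, float] = (-1.0, 1.0),
    copts: ContinuationOptions = DEFAULT_CONTINUATION,
    opts: IntegratorOptions = DEFAULT_OPTIONS,
) -> list[tuple[float, PeriodicSolution]]:
    """Trace a timing-degeneracy point through parameter space.

    The degeneracy (two scheduled events simultaneous) plus the gait
    boundary value problem defines a one-dimensional curve in (solution,
    phi) space; tracing it yields the transition speed as a function of the
    neutral leg swing angle directly (``vary="coupled"`` moves
    phi_l = phi_r together, ``vary="left"`` moves phi_l at fixed phi_r).
    Returns the sampled (phi, transition solution) pairs, ordered along the
    curve (phi may fold back).
    """
    sol0 = tp.solution
    p0 = sol0.params
    if sol0.sync or sol0.sequence is None:
        raise ValueError("transition continuation needs a full-chart solution")
    chart = Chart(sol0.smode, sync=False)
    seq = sol0.sequence
    times0 = times_from_sequence(sol0.event_times, seq)
    i_pair = int(np.argmin(np.diff(times0[:4])))
    phi0 = p0.phi_l if vary in ("coupled", "left") else p0.phi_r

    # simultaneity imposed by construction: the duplicated event time is
    # removed from the unknowns (no gap residual, no ordering cliff)
    n = chart.n
    keep = [j for j in range(5) if j != i_pair + 1]

    def to_full_u(w):
        tt = np.empty(5)
        tt[keep] = w[n : n + 4]
        tt[i_pair + 1] = tt[i_pair]
        return np.concatenate([w[:n], tt])

    u_full0 = np.concatenate([chart.pack(sol0.s), chart.pack_times(times0)])
    v = np.concatenate([u_full0[:n], u_full0[n:][keep], [phi0]])

    def params_at(phi: float) -> ModelParams:
        if vary == "coupled":
            return p0.with_phis(phi, phi)
        if vary == "left":
            return p0.with_phis(phi, p0.phi_r)
        raise ValueError(f"unknown vary mode {vary!r}")

    def fun_plain(w):
        p = params_at(w[-1])
        r, _ = _bvp_residual(to_full_u(w[:-1]), chart, seq, p, opts)
        return r

    def solve_on_plane(w_pred, tau_v):
        from scipy.optimize import least_squares

        def fun(w):
            return np.append(fun_plain(w), float(np.dot(w - w_pred, tau_v)))

        res = least_squares(
            fun, w_pred, method="lm", diff_step=1e-7,
            ftol=1e-15, xtol=1e-14, max_nfev=400,
        )
        r = fun_plain(res.x)
        if np.linalg.norm(r) > 1e-7:
            raise GaitSearchError(
                f"transition-curve corrector failed ({np.linalg.norm(r):.2e})"
            )
        p = params_at(res.x[-1])
        sol = _build_solution_bvp_public(
            to_full_u(res.x[:-1]), chart, seq, p, opts, float(np.linalg.norm(r))
        )
        return res.x, sol

    J = _fd_jacobian(fun_plain, v)
    _, _, Vt = np.linalg.svd(J)
    tau = Vt[-1]
    tau /= np.linalg.norm(tau)

    out: list[tuple[float, PeriodicSolution]] = [(phi0, sol0)]
    for direction in (+1.0, -1.0):
        v_cur = v.copy()
        tau_cur = tau * direction
        ds = copts.ds0
        for _ in range(copts.max_points):
            v_pred = v_cur + ds * tau_cur
            try:
                v_new, sol_new = solve_on_plane(v_pred, tau_cur)
            except GaitSearchError:
                if ds > copts.ds_min:
                    ds = max(0.25 * ds, copts.ds_min)
                    continue
                break
            phi_new = float(v_new[-1])
            out.append((phi_new, sol_new))
            step = v_new - v_cur
            nrm = np.linalg.norm(step)
            if nrm > 0:
                tau_cur = step / nrm
            v_cur = v_new
            ds = min(ds * copts.grow, copts.ds_max)
            if not (phi_range[0] <= phi_new <= phi_range[1]):
                break
            if abs(sol_new.apex_speed) > copts.speed_cap:
                break
            if abs(sol_new.apex_speed) < 1e-3:
                break
    return out


def _build_solution_bvp_public(u, chart, seq, p, opts, rnorm):
    from .gait_search import _build_solution_bvp

    return _build_solution_bvp(u, chart, seq, p, opts, rnorm)


def solve_transition_at(
    tp_near: TransitionPoint,
    p: ModelParams,
    opts: IntegratorOptions = DEFAULT_OPTIONS,
    tol: float = 1e-7,
) -> TransitionPoint:
    """Re-solve a timing-degeneracy point at exactly the given parameters,
    seeding from a nearby transition (e.g. a sample of a transition curve).
    At fixed parameters the degeneracy is an isolated solution: the
    simultaneity constraint absorbs the energy direction."""
    from scipy.optimize import least_squares

    sol0 = tp_near.solution
    chart = Chart(sol0.smode, sync=False)
    seq = sol0.sequence
    times0 = times_from_sequence(sol0.event_times, seq)
    i_pair = int(np.argmin(np.diff(times0[:4])))
    n = chart.n
    keep = [j for j in range(5) if j != i_pair + 1]

    def to_full_u(w):
        tt = np.empty(5)
        tt[keep] = w[n : n + 4]
        tt[i_pair + 1] = tt[i_pair]
        return np.concatenate([w[:n], tt])

    u_full0 = np.concatenate([chart.pack(sol0.s), chart.pack_times(times0)])
    w0 = np.concatenate([u_full0[:n], u_full0[n:][keep]])

    def fun(w):
        r, _ = _bvp_residual(to_full_u(w), chart, seq, p, opts)
        return r

    res = least_squares(
        fun, w0, method="lm", diff_step=1e-7,
        ftol=1e-15, xtol=1e-14, max_nfev=400,
    )
    rn = float(np.linalg.norm(fun(res.x)))
    if rn > tol:
        raise GaitSearchError(f"transition re-solve failed (residual {rn:.2e})")
    sol = _build_solution_bvp_public(
        to_full_u(res.x), chart, seq, p, opts, rn
    )
    return TransitionPoint(
        solution=sol, kind="timing-degeneracy", detail=tp_near.detail
    )


# ---------------------------------------------------------------------------
# Seeds for the nominal gait structure
# ---------------------------------------------------------------------------

def seed_vertical_hop(
    p: ModelParams,
    apex_height: float = 1.2,
    opts: IntegratorOptions = DEFAULT_OPTIONS,
) -> PeriodicSolution:
    """The zero-forward-speed vertical hop (legs at rest angle zero): the
    easiest first periodic motion, exact for phi_l = phi_r = 0."""
    if p.phi_l != 0.0 or p.phi_r != 0.0:
        raise ValueError("the exact vertical hop requires phi_l = phi_r = 0")
    t_td = math.sqrt(2.0 * (apex_height - 1.0))
    # analytic double-stance bounce of the 1-D oscillator ydd = 2k(1-y) - 1
    om_s = math.sqrt(2.0 * p.k)
    y_eq = 1.0 - 1.0 / (2.0 * p.k)
    amp = math.hypot(1.0 - y_eq, t_td / om_s)
    phase = math.acos(min(1.0, (1.0 - y_eq) / amp))
    d_stance = 2.0 * (math.pi - phase) / om_s
    T = 2.0 * t_td + d_stance
    seq = np.array([dyn.EV_TD_L, dyn.EV_TD_R, dyn.EV_LO_L, dyn.EV_LO_R],
                   dtype=np.int64)
    times = np.array([t_td, t_td, t_td + d_stance, t_td + d_stance, T])
    return refine_gait(
        np.array([apex_height, 0, 0, 0, 0, 0.0]), times, seq, p,
        anchor=("energy", apex_height), sync=True, opts=opts,
    )


def seed_forward_hopping(
    p: ModelParams,
    speed: float = 0.5,
    opts: IntegratorOptions = DEFAULT_OPTIONS,
) -> PeriodicSolution:
    """A forward hopping solution near the nominal parameters, found by the
    free-map shooting from the known structure of slow hops (legs crossing
    vertical at the apex)."""
    seeds = [
        np.array([1.04, speed, 0.0, 0.65 + 0.8 * speed, 0.0, 0.65 + 0.8 * speed]),
        np.array([1.08, speed, 0.0, 1.3 * speed, 0.0, 1.3 * speed]),
        np.array([1.2, speed, 0.0, 0.5, 0.0, 0.5]),
    ]
    last: Exception | None = None
    for s0 in seeds:
        try:
            sol = find_gait(s0, p, anchor=("speed", speed), sync=True, opts=opts)
            if sol.label == GaitLabel.HOPPING:
                return resolve_gait(sol, anchor=("speed", speed), opts=opts)
        except GaitSearchError as err:
            last = err
    raise GaitSearchError(f"no forward hopping found at speed {speed} ({last})")


def seed_symmetric_running(
    p: ModelParams,
    speed: float = 2.0,
    opts: IntegratorOptions = DEFAULT_OPTIONS,
) -> PeriodicSolution:
    """Construct and converge a symmetric running solution.

    The massless swing legs leave the COM dynamics identical to the classic
    body-only SLIP, so a symmetric single-stance step (touchdown/liftoff
    mirror states) is found first by two nested scalar root solves; the
    swing-leg phases are then attached analytically (flight-phase leg
    motion is exact simple-harmonic about phi) and the full boundary value
    problem polishes the assembled seed.
    """
    from scipy.optimize import brentq

    from .model_core import HybridState, Side, touchdown_reset
    from .hybrid_sim import _run_core

    sopts = replace(opts, premature_tol=math.inf)
    om = p.omega

    def stance_exit(a_td, y0):
        ca = math.cos(a_td)
        if y0 <= ca + 1e-9:
            return None
        t_f = math.sqrt(2.0 * (y0 - ca))
        st = HybridState(
            x=0.0, y=ca, alpha_l=0.6, alpha_r=a_td,
            xdot=speed, ydot=-t_f, alphadot_l=0.0, alphadot_r=0.0,
        )
        st = touchdown_reset(st, Side.RIGHT)
        tr = _run_core(
            st, p, sopts, events_before_stop=1, stop_on_any_event=True,
            store=False, sequence=np.array([dyn.EV_LO_R], dtype=np.int64),
        )
        if tr.status != "event":
            return None
        e = tr.end_state
        return dict(t_f=t_f, d=tr.T, vy_lo=e.ydot, w_lo=e.alphadot_r)

    def sym_y0(a_td):
        ca = math.cos(a_td)

        def f(y0):
            r = stance_exit(a_td, y0)
            return np.nan if r is None else r["vy_lo"] - math.sqrt(2 * (y0 - ca))

        ys = np.linspace(ca + 2e-4, ca + 0.6, 60)
        vv = np.array([f(y) for y in ys])
        ok = np.isfinite(vv)
        yy, v = ys[ok], vv[ok]
        iz = np.where(np.diff(np.sign(v)))[0]
        if len(iz) == 0:
            return None
        return brentq(f, yy[iz[0]], yy[iz[0] + 1], xtol=1e-13)

    def timing_defect(a_td):
        y0 = sym_y0(a_td)
        if y0 is None:
            return np.nan, None
        r = stance_exit(a_td, y0)
        T = 2.0 * (r["t_f"] + r["d"] + r["vy_lo"])
        A = math.hypot(a_td - p.phi_r, r["w_lo"] / om)
        if A < abs(a_td - p.phi_r):
            return np.nan, None
        psi = math.atan2(-(a_td - p.phi_r) / A, r["w_lo"] / (om * A))
        chi = math.pi - math.asin(min(1.0, (a_td - p.phi_r) / A))
        arrive = ((chi - psi) % (2.0 * math.pi)) / om
        return (T - r["d"]) - arrive, (y0, r, T)

    grid = np.linspace(0.05, 0.65, 31)
    vals = np.array([timing_defect(a)[0] for a in grid])
    ok = np.isfinite(vals)
    gg, v = grid[ok], vals[ok]
    iz = np.where(np.diff(np.sign(v)))[0]
    if len(iz) == 0:
        raise GaitSearchError(
            f"no symmetric-step construction at speed {speed}"
        )
    a_td = brentq(lambda a: timing_defect(a)[0], gg[iz[0]], gg[iz[0] + 1],
                  xtol=1e-10)
    _, info = timing_defect(a_td)
    y0, r, T = info
    t_f, d_st = r["t_f"], r["d"]
    A = math.hypot(a_td - p.phi_r, r["w_lo"] / om)
    w_arr = -om * math.sqrt(max(A * A - (a_td - p.phi_r) ** 2, 0.0))

    def sho_back(a, w, dt, phi):
        c, s = math.cos(om * dt), math.sin(om * dt)
        return phi + (a - phi) * c - (w / om) * s, om * (a - phi) * s + w * c

    Th = T / 2.0
    ar0, wr0 = sho_back(a_td, w_arr, t_f, p.phi_r)
    al0, wl0 = sho_back(a_td, w_arr, Th + t_f, p.phi_l)
    s_seed = np.array([y0, speed, al0, wl0, ar0, wr0])
    seq = np.array([dyn.EV_TD_R, dyn.EV_LO_R, dyn.EV_TD_L, dyn.EV_LO_L],
                   dtype=np.int64)
    times = np.array([t_f, t_f + d_st, Th + t_f, Th + t_f + d_st, T])
    return refine_gait(s_seed, times, seq, p, anchor=("speed", speed), opts=opts)


# ---------------------------------------------------------------------------
# Parameter transport and NLSA sweeps
# ---------------------------------------------------------------------------

def transport_solution(
    sol: PeriodicSolution,
    p_target: ModelParams,
    opts: IntegratorOptions = DEFAULT_OPTIONS,
    max_substeps: int = 64,
    anchor_kind: str = "speed",
) -> PeriodicSolution:
    """Continue a periodic solution across a change of model parameters.

    The parameter ray from the solution's parameters to ``p_target`` is
    traversed by pseudo-arclength continuation in (solution, ray fraction)
    space, which tracks the *same* solution through folds and near
    coexisting fixed points; on breakdown, the probe re-anchors along the
    local energy family and retries (the admissible window of the anchored
    quantity may shift with the parameters).
    """
    from dataclasses import replace as _rp
    from scipy.optimize import least_squares

    p0 = sol.params
    if (
        p0.k == p_target.k and p0.omega == p_target.omega
        and p0.phi_l == p_target.phi_l and p0.phi_r == p_target.phi_r
    ):
        return sol

    def params_at(lam_v: float) -> ModelParams:
        return _rp(
            p0,
            k=p0.k + lam_v * (p_target.k - p0.k),
            omega=p0.omega + lam_v * (p_target.omega - p0.omega),
            phi_l=p0.phi_l + lam_v * (p_target.phi_l - p0.phi_l),
            phi_r=p0.phi_r + lam_v * (p_target.phi_r - p0.phi_r),
        )

    def ray_leg(cur: PeriodicSolution, lam0: float) -> PeriodicSolution | None:
        """Arclength continuation along the ray from lam0 to 1; returns the
        solution at the target or None."""
        chart = Chart(cur.smode, cur.sync)
        u0, _, seq = bvp_vector(cur)
        anchor_val = cur.apex_speed if anchor_kind == "speed" else cur.energy

        def fun_plain(w):
            lam_v = float(w[-1])
            if not (-0.5 <= lam_v <= 1.5):
                return np.full(chart.n + 2 + chart.n_events, 10.0)
            try:
                p = params_at(lam_v)
            except ValueError:
                return np.full(chart.n + 2 + chart.n_events, 10.0)
            r, _ = _bvp_residual(w[:-1], chart, seq, p, opts)
            if anchor_kind == "speed":
                extra = w[1] - anchor_val
            else:
                from .hybrid_sim import apex_energy

                extra = (
                    apex_energy(chart.unpack(w[: chart.n]), chart.smode, p)
                    - anchor_val
                )
            return np.append(r, extra)

        def solve(w_pred, tau_v):
            def fun(w):
                return np.append(fun_plain(w), float(np.dot(w - w_pred, tau_v)))

            res = least_squares(
                fun, w_pred, method="lm", diff_step=1e-7,
                ftol=1e-15, xtol=1e-14, max_nfev=300,
            )
            if np.linalg.norm(fun_plain(res.x)) > 1e-7:
                raise GaitSearchError("transport corrector failed")
            return res.x

        v = np.append(u0, lam0)
        J = _fd_jacobian(fun_plain, v)
        _, _, Vt = np.linalg.svd(J)
        tau = Vt[-1]
        tau /= np.linalg.norm(tau)
        if tau[-1] < 0:
            tau = -tau
        if tau[-1] < 1e-6:
            return None
        # cap steps so each advances lambda by a bounded amount
        ds = min(0.2, 0.25 / max(tau[-1], 1e-3) / max_substeps * 4)
        ds = max(ds, 1e-4)
        v_cur = v
        for _ in range(8 * max_substeps):
            if v_cur[-1] >= 1.0 - 1e-12:
                break
            v_pred = v_cur + ds * tau
            if v_pred[-1] > 1.0:
                # land exactly on the target parameters
                e_lam = np.zeros_like(v_pred)
                e_lam[-1] = 1.0
                v_pred[-1] = 1.0
                try:
                    v_new = solve(v_pred, e_lam)
                except GaitSearchError:
                    ds *= 0.25
                    if ds < 1e-6:
                        return None
                    continue
            else:
                try:
                    v_new = solve(v_pred, tau)
                except GaitSearchError:
                    ds *= 0.25
                    if ds < 1e-6:
                        return None
                    continue
            step = v_new - v_cur
            nrm = np.linalg.norm(step)
            if nrm > 0:
                tau = step / nrm
            if tau[-1] < -0.5:
                return None  # folded back in the ray parameter
            v_cur = v_new
            ds = min(ds * 1.5, 0.25)
        if v_cur[-1] < 1.0 - 1e-9:
            return None
        p_fin = params_at(1.0)
        chart_f = Chart(cur.smode, cur.sync)
        return _build_solution_bvp_public(
            v_cur[:-1], chart_f, seq, p_fin, opts, 0.0,
        )

    cur = sol
    lam = 0.0
    for refresh in range(4):
        out = ray_leg(cur, lam)
        if out is not None:
            # rebuild with an exact residual check
            return resolve_gait(
                out, p_target,
                anchor=(anchor_kind, None) if anchor_kind == "energy" else (
                    "speed", out.apex_speed),
                opts=opts,
            )
        if refresh == 3:
            break
        # re-anchor along the energy family at the current parameters
        br = trace_branch(
            cur,
            ContinuationOptions(
                ds0=0.05, ds_max=0.5, grow=1.5, max_points=60, speed_cap=31.0
            ),
            opts,
        )
        ns = len(br.solutions)
        moved = False
        for frac in (0.25, 0.4, 0.6, 0.75, 0.1, 0.9):
            rep = br.solutions[int(frac * (ns - 1))]
            if abs(rep.apex_speed - cur.apex_speed) < 1e-9:
                continue
            cur = rep
            moved = True
            break
        if not moved:
            break
    raise GaitSearchError("parameter transport failed along the ray")



def _structure_at(
    p: ModelParams,
    hop_rep: PeriodicSolution,
    copts: ContinuationOptions,
    opts: IntegratorOptions,
) -> dict:
    """Asymmetric-continuum structure at fixed parameters: hopping branch,
    hop<->skip bifurcations, skipping/asymmetric-running continuations and
    their timing degeneracies."""
    out: dict = {"params": p, "hopping": None, "bifurcations": [],
                 "skip_branches": [], "skip_ar_points": []}
    hop_branch = trace_branch(hop_rep, copts, opts)
    out["hopping"] = hop_branch
    bifs = detect_bifurcation(hop_branch, opts)
    out["bifurcations"] = bifs
    for tp in bifs:
        try:
            skip0 = branch_switch(tp, opts=opts)
        except GaitSearchError:
            continue
        skip_branch = trace_branch(skip0, copts, opts)
        out["skip_branches"].append(skip_branch)
        out["skip_ar_points"].extend(locate_timing_degeneracy(skip_branch, opts))
    return out


def sweep_coupled(
    phis: list[float],
    p_base: ModelParams,
    copts: ContinuationOptions = DEFAULT_CONTINUATION,
    opts: IntegratorOptions = DEFAULT_OPTIONS,
    with_symmetric: bool = True,
) -> dict:
    """Gait structure across coupled NLSA values (phi_l = phi_r = phi).

    Per phi: the hopping branch with its hop<->skip bifurcations and the
    skipping / asymmetrical-running continuum, plus (optionally) the
    symmetric walking/running branch with its walk<->run degeneracy.
    Failures at individual phi values are recorded and the sweep continues.
    """
    results: dict = {}
    hop_rep = seed_forward_hopping(p_base.with_phis(0.0, 0.0), 0.5, opts)
    sym_rep = (
        seed_symmetric_running(p_base.with_phis(0.0, 0.0), 2.0, opts)
        if with_symmetric
        else None
    )
    for phi in phis:
        p = p_base.with_phis(phi, phi)
        entry: dict = {"phi": phi, "error": None}
        try:
            hop_here = transport_solution(hop_rep, p, opts)
            entry.update(_structure_at(p, hop_here, copts, opts))
        except GaitSearchError as err:
            entry["error"] = f"hopping: {err}"
        if sym_rep is not None:
            try:
                sym_here = transport_solution(sym_rep, p, opts)
                sym_branch = trace_branch(sym_here, copts, opts)
                entry["symmetric"] = sym_branch
                entry["walk_run_points"] = [
                    t
                    for t in locate_timing_degeneracy(sym_branch, opts)
                    if t.detail == "walk<->run"
                ]
            except GaitSearchError as err:
                entry["symmetric"] = None
                entry["sym_error"] = str(err)
        results[phi] = entry
    return results


def sweep_uncoupled(
    phi_ls: list[float],
    phi_rs: list[float],
    p_base: ModelParams,
    copts: ContinuationOptions = DEFAULT_CONTINUATION,
    opts: IntegratorOptions = DEFAULT_OPTIONS,
    skip_rep: PeriodicSolution | None = None,
) -> dict:
    """Skipping / asymmetrical-running structure across uncoupled NLSA
    combinations (phi_l varied at fixed phi_r): per configuration, the
    (possibly closed-loop) skipping/AR continuum and its skip<->AR
    transition points."""
    results: dict = {}
    for phi_r in phi_rs:
        # representative skipping solution at the coupled base point
        p_diag = p_base.with_phis(phi_r, phi_r)
        if skip_rep is None:
            hop0 = seed_forward_hopping(p_base.with_phis(0.0, 0.0), 0.5, opts)
            hop_d = transport_solution(hop0, p_diag, opts)
            st = _structure_at(p_diag, hop_d, copts, opts)
            reps = [
                b.solutions[len(b.solutions) // 2] for b in st["skip_branches"]
            ]
            if not reps:
                results[(phi_r,)] = {"error": "no skipping at coupled base"}
                continue
            rep0 = reps[0]
        else:
            rep0 = transport_solution(skip_rep, p_diag, opts)
        for phi_l in phi_ls:
            p = p_base.with_phis(phi_l, phi_r)
            key = (phi_l, phi_r)
            try:
                rep = transport_solution(rep0, p, opts)
            except GaitSearchError as err:
                results[key] = {"error": f"transport: {err}"}
                continue
            br = trace_branch(rep, copts, opts)
            results[key] = {
                "branch": br,
                "skip_ar_points": locate_timing_degeneracy(br, opts),
            }
    return results
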