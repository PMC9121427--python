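"""Reference study computations on the nominal model (k=20, omega=6.5).

High-level recipes that assemble the package's machinery into the standard
analyses: the nominal gait structure (both continua with their transition
points), the coupled and uncoupled neutral-leg-swing-angle sweeps, and the
existence boundaries of the gait families.  Problem sizes (branch point
budgets, slice speed grids, sweep resolutions) are chosen so the full
study runs in minutes on one core; they are documented here and in the
methods note.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np

from .continuation import (
    ContinuationOptions,
    TransitionPoint,
    branch_switch,
    continue_branch,
    continue_in_phi,
    continue_transition,
    detect_bifurcation,
    locate_timing_degeneracy,
    seed_forward_hopping,
    seed_symmetric_running,
    solve_transition_at,
    trace_branch,
    transport_solution,
)
from .gait_search import GaitSearchError, mirror_solution, resolve_gait, swap_legs
from .hybrid_sim import DEFAULT_OPTIONS, IntegratorOptions
from .model_core import GaitLabel, ModelParams

__all__ = [
    "symmetric_study",
    "asymmetric_study",
    "hopping_upper_boundary",
    "skipping_lower_boundary",
    "running_lower_boundary",
    "coupled_lower_transition_speeds",
    "uncoupled_transition_catalogue",
    "loop_vanishing_angle",
]

NOMINAL = ModelParams()
SWING_EXCURSION_CAP = 1.7  # rad; biologically unrealistic beyond


def _copts(**kw) -> ContinuationOptions:
    base = dict(ds0=0.05, ds_max=1.0, grow=1.5, max_points=400, speed_cap=30.5)
    base.update(kw)
    return ContinuationOptions(**base)


def symmetric_study(opts: IntegratorOptions = DEFAULT_OPTIONS) -> dict:
    """The nominal walking/running continuum.

    Continues the symmetric branch from a constructed running gait at apex
    speed 2 down to the walk<->run timing degeneracy (where the anchoring
    aerial phase vanishes) and up to the branch's high-speed end.
    """
    run = seed_symmetric_running(NOMINAL, 2.0, opts)
    down = continue_branch(run, +1, _copts(ds_max=0.35, max_points=150), opts)
    up = continue_branch(run, -1, _copts(max_points=250), opts)
    if down.speeds[-1] > down.speeds[0]:
        down, up = up, down
    tps = locate_timing_degeneracy(down, opts)
    walk_run = [t for t in tps if t.detail == "walk<->run"]
    return {
        "seed": run,
        "branch_down": down,
        "branch_up": up,
        "walk_run_point": walk_run[0] if walk_run else None,
        "walk_run_speed": walk_run[0].speed if walk_run else math.nan,
        "max_speed": max(down.max_speed(), up.max_speed()),
    }


def asymmetric_study(opts: IntegratorOptions = DEFAULT_OPTIONS) -> dict:
    """The nominal hopping/skipping/asymmetrical-running continuum.

    Traces the hopping branch in the leg-synchronized subspace from near
    zero speed to its high-speed fold, detects the hop<->skip
    (Floquet multiplier +1) bifurcations, switches onto the
    desynchronized continuum and refines its skip<->AR timing
    degeneracies.
    """
    hop = seed_forward_hopping(NOMINAL, 0.5, opts)
    hop_branch = trace_branch(hop, _copts(), opts)
    bifs = detect_bifurcation(hop_branch, opts, stride=3)
    bifs.sort(key=lambda t: t.speed)
    skip_branches = []
    skip_ar = []
    if bifs:
        skip0 = branch_switch(bifs[0], opts=opts)
        if skip0.apex_speed < 0:
            skip0 = resolve_gait(
                mirror_solution(skip0), anchor=("speed", -skip0.apex_speed),
                opts=opts,
            )
        skbr = trace_branch(skip0, _copts(max_points=250), opts)
        skip_branches.append(skbr)
        skip_ar = locate_timing_degeneracy(skbr, opts)
    speeds = [t.speed for t in skip_ar if t.detail == "skip<->asymmetric_run"]
    max_speed = max(
        [hop_branch.max_speed()] + [b.max_speed() for b in skip_branches]
    )
    return {
        "hopping": hop_branch,
        "bifurcations": bifs,
        "skip_branches": skip_branches,
        "skip_ar_points": skip_ar,
        "skip_ar_lower": min(speeds) if speeds else math.nan,
        "skip_ar_upper": max(speeds) if speeds else math.nan,
        "max_speed": max_speed,
    }


def _rep_near_speed(branch, v, label=None, tol=1.0):
    cands = [
        s for s in branch.solutions
        if abs(abs(s.apex_speed) - v) < tol
        and (label is None or s.label == label)
    ]
    if not cands:
        return None
    return min(cands, key=lambda s: abs(abs(s.apex_speed) - v))


def _slice_curve(rep, opts, phi_range=(-1.5, 3.0)):
    return continue_in_phi(
        rep, vary="coupled",
        copts=_copts(ds0=0.05, ds_max=0.4, grow=1.4, max_points=400,
                     speed_cap=32.0),
        opts=opts, phi_range=phi_range,
    )


def hopping_upper_boundary(
    asym: dict,
    opts: IntegratorOptions = DEFAULT_OPTIONS,
    speeds=(0.5, 1.0, 2.0, 4.0),
    exc_cap: float = SWING_EXCURSION_CAP,
) -> float:
    """Largest coupled NLSA admitting hopping with realistic swing motion.

    Fixed-speed slices of the hopping family are continued in phi; along
    each slice the swing excursion about the neutral angle grows with phi,
    and the boundary is where it exceeds ``exc_cap`` (the model itself
    admits periodic hops with arbitrarily wild swings beyond).  The
    boundary over the family is the maximum over the sampled speeds.
    """
    best = -math.inf
    for v in speeds:
        rep = _rep_near_speed(asym["hopping"], v)
        if rep is None:
            continue
        curve = _slice_curve(rep, opts)
        pts = sorted(
            (phi, s.max_swing_excursion)
            for phi, s in curve if s.apex_speed > 0.05 and phi > 0
        )
        for (f1, e1), (f2, e2) in zip(pts[:-1], pts[1:]):
            if (e1 - exc_cap) * (e2 - exc_cap) < 0:
                best = max(best, f1 + (exc_cap - e1) * (f2 - f1) / (e2 - e1))
                break
    return best


def skipping_lower_boundary(
    asym: dict,
    opts: IntegratorOptions = DEFAULT_OPTIONS,
    speeds=(6.5, 7.2, 28.3, 29.0),
) -> float:
    """Most negative coupled NLSA reached by the skipping family
    (fold envelope of fixed-speed slices; the deepest reach occurs on the
    high-speed skipping segment)."""
    best = math.inf
    for v in speeds:
        rep = None
        for br in asym["skip_branches"]:
            rep = _rep_near_speed(br, v, label=GaitLabel.SKIPPING, tol=0.5)
            if rep is not None:
                break
        if rep is None:
            continue
        curve = _slice_curve(rep, opts, phi_range=(-1.2, 1.2))
        phis = [
            phi for phi, s in curve
            if s.apex_speed > 0.05 and s.label == GaitLabel.SKIPPING
        ]
        if phis:
            best = min(best, min(phis))
    return best


def running_lower_boundary(
    sym: dict,
    opts: IntegratorOptions = DEFAULT_OPTIONS,
    speeds=(6.0, 10.0, 14.0, 18.0, 22.0, 26.0),
) -> float:
    """Coupled NLSA at which the symmetric running branch vanishes: the
    fold envelope of fixed-speed slices (the branch shrinks to a shrinking
    speed window before disappearing)."""
    best = math.inf
    for v in speeds:
        rep = _rep_near_speed(sym["branch_up"], v, tol=0.6)
        if rep is None:
            rep = _rep_near_speed(sym["branch_down"], v, tol=0.6)
        if rep is None:
            continue
        curve = _slice_curve(rep, opts, phi_range=(-1.2, 1.2))
        phis = [
            phi for phi, s in curve
            if s.apex_speed > 0.05 and s.label == GaitLabel.SYMMETRIC_RUNNING
        ]
        if phis:
            best = min(best, min(phis))
    return best


def coupled_lower_transition_speeds(
    asym: dict,
    phis=(-0.4, -0.2, 0.0, 0.2, 0.4),
    opts: IntegratorOptions = DEFAULT_OPTIONS,
) -> dict:
    """Lower-speed skip<->AR transition speed as a function of coupled
    NLSA, read off the continued transition curve."""
    tps = [
        t for t in asym["skip_ar_points"]
        if t.detail == "skip<->asymmetric_run"
    ]
    tp_low = min(tps, key=lambda t: t.speed)
    curve = continue_transition(
        tp_low, vary="coupled", phi_range=(min(phis) - 0.05, max(phis) + 0.05),
        copts=_copts(ds0=0.05, ds_max=0.5, max_points=150),
        opts=opts,
    )
    ph = np.array([c[0] for c in curve])
    sp = np.array([abs(c[1].apex_speed) for c in curve])
    out = {}
    for target in phis:
        i = int(np.argmin(np.abs(ph - target)))
        if abs(ph[i] - target) < 0.05:
            out[target] = float(sp[i])
    return {"per_phi": out, "curve": curve, "tp_low": tp_low}


def _curve_grid_speeds(curve, grid):
    """Speeds of all curve crossings of each grid phi value."""
    out = {g: [] for g in grid}
    for (p1, s1), (p2, s2) in zip(curve[:-1], curve[1:]):
        f1, f2 = p1, p2
        v1, v2 = abs(s1.apex_speed), abs(s2.apex_speed)
        for g in grid:
            lo, hi = min(f1, f2), max(f1, f2)
            if lo <= g <= hi and hi > lo:
                lam = (g - f1) / (f2 - f1)
                out[g].append(v1 + lam * (v2 - v1))
            elif abs(f1 - g) < 1e-9:
                out[g].append(v1)
    return out


def uncoupled_transition_catalogue(
    coupled: dict,
    phi_rs=(-0.2, 0.0, 0.2),
    phi_l_range=(-0.06, 0.14),
    grid_step: float = 0.02,
    opts: IntegratorOptions = DEFAULT_OPTIONS,
) -> dict:
    """Skip<->AR transition points across uncoupled NLSA combinations.

    For each fixed right NLSA, the nominal transition is re-solved at the
    coupled point and its curve is continued in phi_l; transition points
    are catalogued on a phi_l grid at the printed two-decimal resolution.
    Also derives the configuration of minimum transition speed and the
    transition speed 0.08 rad of phi_l above it.
    """
    curve_c = coupled["curve"]
    ph_c = np.array([c[0] for c in curve_c])
    copts = _copts(ds0=0.05, ds_max=0.5, max_points=250, speed_cap=30.5)
    grid = np.round(
        np.arange(phi_l_range[0], phi_l_range[1] + grid_step / 2, grid_step), 6
    )
    catalogue: dict = {}
    curves: dict = {}
    for phi_r in phi_rs:
        i = int(np.argmin(np.abs(ph_c - phi_r)))
        try:
            tp = solve_transition_at(
                TransitionPoint(solution=curve_c[i][1], kind="timing-degeneracy",
                                detail="skip<->asymmetric_run"),
                NOMINAL.with_phis(phi_r, phi_r), opts,
            )
        except GaitSearchError:
            continue
        curve = continue_transition(
            tp, vary="left", phi_range=(phi_r - 0.45, phi_r + 0.45),
            copts=copts, opts=opts,
        )
        curves[phi_r] = curve
        # the diagonal (phi_l = phi_r) is the coupled model, where the
        # uncoupled transition curve degenerates into the symmetric
        # structure; only genuinely uncoupled grid entries are catalogued
        off_diag = [g for g in grid if abs(g - phi_r) > grid_step / 2]
        catalogue[phi_r] = _curve_grid_speeds(curve, off_diag)
    all_speeds = [
        v
        for per in catalogue.values()
        for vs in per.values()
        for v in vs
    ]
    # minimum-speed configuration and the +0.08 rad phi_l comparison
    t10 = math.nan
    best = None
    for phi_r, curve in curves.items():
        for phi_l, sol in curve:
            v = abs(sol.apex_speed)
            if best is None or v < best[2]:
                best = (phi_l, phi_r, v)
    if best is not None:
        phi_l0, phi_r0, _v0 = best
        cands = [
            abs(sol.apex_speed)
            for phi_l, sol in curves[phi_r0]
            if abs(phi_l - (phi_l0 + 0.08)) < 0.01
        ]
        if cands:
            t10 = float(min(cands))
    return {
        "catalogue": catalogue,
        "curves": curves,
        "max_speed": max(all_speeds) if all_speeds else math.nan,
        "min_speed": min(all_speeds) if all_speeds else math.nan,
        "min_config": best,
        "speed_after_offset": t10,
    }


def loop_vanishing_angle(
    asym: dict,
    opts: IntegratorOptions = DEFAULT_OPTIONS,
    slice_speeds=(3.0, 8.0, 12.0, 17.0, 22.0, 27.0),
) -> float:
    """Most negative uncoupled left NLSA (phi_r = 0) with solutions on the
    closed skipping/asymmetrical-running loop: the loop shrinks as phi_l
    decreases and the fold envelope of fixed-speed slices locates where it
    contracts to a point."""
    reps = [
        s for b in asym["skip_branches"] for s in b.solutions
        if s.label in (GaitLabel.SKIPPING, GaitLabel.ASYMMETRIC_RUNNING)
        and abs(s.event_times.t_ltd - s.event_times.t_rtd) / s.T > 0.08
    ]
    if not reps:
        return math.nan
    rep = reps[len(reps) // 3]
    seed = None
    for cand in (swap_legs(rep), rep):
        try:
            seed = transport_solution(
                cand, NOMINAL.with_phis(-0.03, 0.0), opts
            )
            break
        except GaitSearchError:
            continue
    if seed is None:
        return math.nan
    loop = trace_branch(
        seed, _copts(ds0=0.05, ds_max=0.5, grow=1.4, max_points=300,
                     speed_cap=31.0), opts,
    )
    best = math.inf
    for v in slice_speeds:
        rep_v = _rep_near_speed(loop, v, tol=1.0)
        if rep_v is None:
            continue
        curve = continue_in_phi(
            rep_v, vary="left",
            copts=_copts(ds0=0.05, ds_max=0.4, grow=1.4, max_points=300,
                         speed_cap=31.0),
            opts=opts, phi_range=(-0.4, 0.1),
        )
        phis = [phi for phi, s in curve if abs(s.apex_speed) > 0.05]
        if phis:
            best = min(best, min(phis))
    return best
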