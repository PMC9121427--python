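"""Parameter identification by fitting periodic gaits to kinematic data.

Given a one-stride kinematic trajectory (COM position and leg angles with
velocities, anchored at a height apex), the fit jointly adjusts the
periodic solution (its reduced apex state and event schedule) and the free
model parameters — swing frequency ``omega`` and the neutral leg swing
angles by default — to minimize the integrated squared deviation of
positions and velocities over the stride.  Periodicity and the foot-height
event conditions enter as strongly weighted residuals of the same
least-squares problem, so the optimum is a periodic gait of the model that
tracks the data (the boundary-value constraints are satisfied to high
accuracy at convergence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from . import _dynamics as dyn
from .gait_search import (
    Chart,
    GaitSearchError,
    PeriodicSolution,
    _build_solution_bvp,
    _bvp_residual,
    bvp_vector,
    times_from_sequence,
)
from .hybrid_sim import (
    DEFAULT_OPTIONS,
    IntegratorOptions,
    SectionMode,
    simulate_prescribed,
    state_from_reduced,
)
from .model_core import ModelParams

__all__ = [
    "KinematicTrajectory",
    "FitResult",
    "trajectory_cost",
    "fit_parameters",
    "r_squared",
    "estimate_event_times",
]

CHANNELS = ("x", "y", "alpha_l", "alpha_r")
VEL_CHANNELS = ("xdot", "ydot", "alphadot_l", "alphadot_r")
PENALTY_COST = 1e6


@dataclass
class KinematicTrajectory:
    """One stride of kinematics: sample times, positions and velocities.

    Times are dimensionless (sqrt(lo/g)); the stride starts at a height
    apex.  ``provenance`` records whether the samples are synthetic or
    external, and ``meta`` carries free-form header metadata (frame rate,
    noise level, seed, source parameters).
    """

    t: np.ndarray
    q: np.ndarray          # (n, 4): x, y, alpha_l, alpha_r
    qdot: np.ndarray       # (n, 4): velocities
    frame_rate: float = math.nan
    provenance: str = "external"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        self.qdot = np.asarray(self.qdot, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if self.q.shape != (len(self.t), 4) or self.qdot.shape != self.q.shape:
            raise ValueError("q and qdot must be (n, 4) arrays")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def aligned(self) -> "KinematicTrajectory":
        """Time origin at the first sample; x origin at the first x sample
        (the cost is invariant to the data's x origin after this)."""
        q = self.q.copy()
        q[:, 0] -= q[0, 0]
        return replace(self, t=self.t - self.t[0], q=q)


@dataclass
class FitResult:
    params: ModelParams
    solution: PeriodicSolution
    cost: float
    r2: dict[str, float]
    free: tuple[str, ...]
    n_iterations: int = 0

    def to_record(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "free": list(self.free),
            "cost": self.cost,
            "r2": self.r2,
            "solution": self.solution.to_record(),
        }


def _model_samples(
    sol_u: np.ndarray,
    chart: Chart,
    seq: np.ndarray,
    p: ModelParams,
    t_data: np.ndarray,
    opts: IntegratorOptions,
) -> tuple[np.ndarray, float] | None:
    """Sample the prescribed-schedule stride at the (time-normalized) data
    grid; returns ((n, 8) states, model stride time) or None on failure."""
    s = chart.unpack(sol_u[: chart.n])
    times = chart.unpack_times(sol_u[chart.n:])
    if times[4] <= 1e-3 or s[0] <= 0.05:
        return None
    prev = 0.0
    for tv in times:
        if tv < prev - 1e-9:
            return None
        prev = max(prev, tv)
    times = np.maximum.accumulate(np.maximum(times, 0.0))
    st = state_from_reduced(s, chart.smode)
    traj = simulate_prescribed(st, p, seq, times, opts, store=True)
    if traj.status != "periodic-candidate":
        return None
    T = times[4]
    scale = T / t_data[-1] if t_data[-1] > 0 else 1.0
    samples = traj.sample(np.clip(t_data * scale, 0.0, T))
    return samples, T


def trajectory_cost(
    sol: PeriodicSolution,
    traj: KinematicTrajectory,
    opts: IntegratorOptions = DEFAULT_OPTIONS,
) -> float:
    """Integrated squared deviation of positions and velocities over the
    stride (trapezoidal quadrature on the empirical sample grid, the data's
    resolution being the limiting factor).  Simulation failure yields a
    large penalty value."""
    traj = traj.aligned()
    u, chart, seq = bvp_vector(sol)
    out = _model_samples(u, chart, seq, sol.params, traj.t, opts)
    if out is None:
        return PENALTY_COST
    samples, _T = out
    dq = samples[:, :4] - traj.q
    dqd = samples[:, 4:] - traj.qdot
    integrand = np.sum(dq**2, axis=1) + np.sum(dqd**2, axis=1)
    return float(np.trapezoid(integrand, traj.t))


def r_squared(
    sol: PeriodicSolution,
    traj: KinematicTrajectory,
    channel: str,
    opts: IntegratorOptions = DEFAULT_OPTIONS,
) -> float:
    """Coefficient of determination of one position channel."""
    if channel not in CHANNELS:
        raise ValueError(f"channel must be one of {CHANNELS}")
    traj = traj.aligned()
    u, chart, seq = bvp_vector(sol)
    out = _model_samples(u, chart, seq, sol.params, traj.t, opts)
    if out is None:
        return -math.inf
    samples, _ = out
    j = CHANNELS.index(channel)
    data = traj.q[:, j]
    ss_tot = float(np.sum((data - data.mean()) ** 2))
    if ss_tot == 0.0:
        raise ZeroDivisionError(f"channel {channel} has zero variance")
    ss_res = float(np.sum((samples[:, j] - data) ** 2))
    return 1.0 - ss_res / ss_tot


def estimate_event_times(traj: KinematicTrajectory, height_tol: float = 0.02):
    """Rough touchdown/liftoff estimates from the kinematics: per leg, the
    longest interval over which the foot height y - cos(alpha) stays below
    ``height_tol`` is taken as stance.  Used only to seed the fit."""
    t = traj.t
    out = {}
    for leg, j in (("l", 2), ("r", 3)):
        h = traj.q[:, 1] - np.cos(traj.q[:, j])
        below = h < height_tol
        best = None
        i = 0
        n = len(t)
        while i < n:
            if below[i]:
                k = i
                while k + 1 < n and below[k + 1]:
                    k += 1
                if best is None or (t[k] - t[i]) > (t[best[1]] - t[best[0]]):
                    best = (i, k)
                i = k + 1
            else:
                i += 1
        if best is None:
            return None
        out[f"t_{leg}td"] = float(t[best[0]])
        out[f"t_{leg}lo"] = float(t[best[1]])
    return out


_FREE_DEFAULT = ("omega", "phi_l", "phi_r")


def fit_parameters(
    traj: KinematicTrajectory,
    free: tuple[str, ...] = _FREE_DEFAULT,
    init: ModelParams | None = None,
    seed: PeriodicSolution | None = None,
    opts: IntegratorOptions = DEFAULT_OPTIONS,
    periodicity_weight: float = 30.0,
    max_nfev: int = 300,
) -> FitResult:
    """Fit the free model parameters and the periodic solution to a stride.

    The joint unknowns are the reduced apex state, the event schedule and
    the free parameters; residuals combine the (heavily weighted) gait
    boundary-value conditions with the quadrature-weighted deviations of
    all position and velocity channels on the empirical grid.  Leg
    stiffness ``k`` stays fixed unless listed in ``free``.
    """
    for name in free:
        if name not in ("omega", "phi_l", "phi_r", "k"):
            raise ValueError(f"unknown free parameter {name!r}")
    traj = traj.aligned()
    p0 = init if init is not None else ModelParams()

    if seed is None:
        ev = estimate_event_times(traj)
        if ev is None:
            raise GaitSearchError(
                "could not estimate stance intervals from the kinematics"
            )
        T = traj.duration
        items = sorted(
            [
                (ev["t_ltd"], 0, dyn.EV_TD_L),
                (ev["t_llo"], 1, dyn.EV_LO_L),
                (ev["t_rtd"], 0, dyn.EV_TD_R),
                (ev["t_rlo"], 1, dyn.EV_LO_R),
            ]
        )
        seq = np.array([c for _, _, c in items], dtype=np.int64)
        times0 = np.array([tv for tv, _, _ in items] + [T])
        s0 = np.array(
            [
                traj.q[0, 1], traj.qdot[0, 0],
                traj.q[0, 2], traj.qdot[0, 2],
                traj.q[0, 3], traj.qdot[0, 3],
            ]
        )
        chart = Chart(SectionMode.FLIGHT, sync=False)
        u0 = np.concatenate([chart.pack(s0), chart.pack_times(times0)])
    else:
        u0, chart, seq = bvp_vector(seed)
        p0 = seed.params if init is None else init

    theta0 = np.array([getattr(p0, name) for name in free])
    wq = np.sqrt(np.gradient(traj.t))

    def with_params(theta: np.ndarray) -> ModelParams:
        kw = dict(zip(free, theta))
        return replace(p0, **kw)

    def fun(z):
        u = z[: len(u0)]
        p = with_params(z[len(u0):])
        try:
            p.__post_init__()
        except ValueError:
            return np.full(chart.n + 1 + chart.n_events + 8 * len(traj.t), 1e3)
        r_bvp, _ = _bvp_residual(u, chart, seq, p, opts)
        out = _model_samples(u, chart, seq, p, traj.t, opts)
        if out is None:
            data_res = np.full(8 * len(traj.t), 1e3)
        else:
            samples, _T = out
            dq = (samples[:, :4] - traj.q) * wq[:, None]
            dqd = (samples[:, 4:] - traj.qdot) * wq[:, None]
            data_res = np.concatenate([dq.ravel(), dqd.ravel()])
        return np.concatenate([periodicity_weight * r_bvp, data_res])

    z0 = np.concatenate([u0, theta0])
    res = least_squares(
        fun, z0, method="trf", diff_step=1e-6,
        ftol=1e-12, xtol=1e-12, max_nfev=max_nfev,
    )
    u_fit = res.x[: len(u0)]
    p_fit = with_params(res.x[len(u0):])
    r_bvp, _ = _bvp_residual(u_fit, chart, seq, p_fit, opts)
    rnorm = float(np.linalg.norm(r_bvp))
    if rnorm > 1e-8:
        # noisy data pulls the soft-constrained optimum slightly off the
        # periodic manifold; project back by re-solving the exact gait at
        # the fitted parameters (anchored at the fitted apex speed)
        from .gait_search import refine_gait

        s_fit = chart.unpack(u_fit[: chart.n])
        times_fit = chart.unpack_times(u_fit[chart.n:])
        sol = refine_gait(
            s_fit, times_fit, seq, p_fit,
            anchor=("speed", float(s_fit[1])),
            smode=chart.smode, opts=opts,
        )
        rnorm = sol.residual_norm
    else:
        sol = _build_solution_bvp(u_fit, chart, seq, p_fit, opts, rnorm)
    cost = trajectory_cost(sol, traj, opts)
    r2 = {ch: r_squared(sol, traj, ch, opts) for ch in CHANNELS}
    return FitResult(
        params=p_fit, solution=sol, cost=cost, r2=r2, free=tuple(free),
        n_iterations=int(res.nfev),
    )
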