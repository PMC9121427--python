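"""Synthetic kinematics generation, file I/O and configuration.

The fixture generator emulates pose-track kinematics of a periodic gait:
it finds a periodic solution at the requested parameters, samples one
stride at a fixed frame rate and adds independent Gaussian noise per
channel.  The default frame rate mirrors 500 fps video of a small bipedal
hopper: with a leg length of ~0.065 m the time unit sqrt(lo/g) is
~0.081 s, i.e. about 40 frames per dimensionless time unit.

All text formats are plain: CSV with '#'-prefixed key=value header lines
for trajectories, JSON for solution/branch archives, and flat key=value
files for configuration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .continuation import Branch, TransitionPoint, transport_solution
from .fitting import KinematicTrajectory
from .gait_search import GaitSearchError, PeriodicSolution, resolve_gait
from .hybrid_sim import (
    DEFAULT_OPTIONS,
    IntegratorOptions,
    simulate_prescribed,
    state_from_reduced,
)
from .model_core import GaitLabel, ModelParams

__all__ = [
    "FixtureSpec",
    "generate_fixture",
    "trial_like_skipping",
    "write_trajectory",
    "read_trajectory",
    "write_branch",
    "read_branch",
    "write_solution",
    "read_solution",
    "load_config",
    "DEFAULT_FRAME_RATE",
]

# ~500 fps rescaled by sqrt(lo/g) for lo ≈ 0.065 m
DEFAULT_FRAME_RATE = 40.0

CONFIG_KEYS = {
    "k": float, "omega": float, "phi_l": float, "phi_r": float,
    "rtol": float, "atol": float, "premature_tol": float,
    "seed": int, "frame_rate": float, "noise_sigma": float,
    "speed": float, "energy": float,
}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic kinematic stride."""

    params: ModelParams = field(default_factory=ModelParams)
    speed: float = 2.0                    # apex forward speed anchor
    frame_rate: float = DEFAULT_FRAME_RATE
    noise_sigma: float = 0.0              # per-channel Gaussian std [lo / rad]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame rate must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be nonnegative")


def trial_like_skipping(
    params: ModelParams,
    speed: float,
    opts: IntegratorOptions = DEFAULT_OPTIONS,
) -> PeriodicSolution:
    """A skipping solution at (possibly off-nominal) parameters, obtained by
    transporting a nominal skipping gait across (k, omega, phi_l, phi_r)."""
    from .continuation import (
        ContinuationOptions,
        detect_bifurcation,
        branch_switch,
        seed_forward_hopping,
        trace_branch,
    )

    p_nom = ModelParams()
    hop = seed_forward_hopping(p_nom, 0.5, opts)
    copts = ContinuationOptions(ds0=0.05, ds_max=1.0, grow=1.5,
                                max_points=150, speed_cap=10.0)
    br = trace_branch(hop, copts, opts)
    bifs = detect_bifurcation(br, opts, stride=3)
    if not bifs:
        raise GaitSearchError("no hop<->skip bifurcation found for the fixture")
    skip0 = branch_switch(bifs[0], opts=opts)
    # a strongly staggered skipping representative transports much more
    # robustly than the near-synchronized solutions at the bifurcation
    skip_br = trace_branch(skip0, ContinuationOptions(
        ds0=0.05, ds_max=0.5, grow=1.4, max_points=60, speed_cap=9.0), opts)
    staggered = [
        s for s in skip_br.solutions
        if s.label == GaitLabel.SKIPPING and abs(s.apex_speed) < 9.0
    ]
    if staggered:
        skip0 = max(
            staggered,
            key=lambda s: abs(s.event_times.t_ltd - s.event_times.t_rtd) / s.T,
        )

    from dataclasses import replace as _rp
    from .gait_search import mirror_solution, swap_legs

    if skip0.apex_speed < 0:
        # the branch switch may land on the backward-moving mirror image
        skip0 = resolve_gait(
            mirror_solution(skip0),
            anchor=("speed", -skip0.apex_speed), opts=opts,
        )

    # staged parameter transport: along the coupled diagonal (and omega/k)
    # first, then open the left/right offset; finally trace the branch at
    # the target parameters to reach the requested speed (fixed-speed
    # anchoring cannot pass the folds of the energy family)
    mid_phi = 0.5 * (params.phi_l + params.phi_r)
    p_mid = _rp(params, phi_l=mid_phi, phi_r=mid_phi)
    last_err: Exception | None = None
    for cand in (skip0, swap_legs(skip0)):
        try:
            cur = transport_solution(cand, p_mid, opts)
            cur = transport_solution(cur, params, opts)
            br = trace_branch(cur, ContinuationOptions(
                ds0=0.05, ds_max=0.5, grow=1.4, max_points=300,
                speed_cap=31.0), opts)
            best = min(br.solutions, key=lambda s: abs(s.apex_speed - speed))
            sol = resolve_gait(best, anchor=("speed", speed), opts=opts)
            return sol
        except GaitSearchError as err:
            last_err = err
    raise GaitSearchError(f"no skipping gait at the requested speed ({last_err})")


def generate_fixture(
    spec: FixtureSpec,
    solution: PeriodicSolution | None = None,
    opts: IntegratorOptions = DEFAULT_OPTIONS,
) -> KinematicTrajectory:
    """Synthesize one noisy stride of kinematics from a periodic gait.

    If no solution is supplied, a skipping gait is found at the spec's
    parameters and speed.  Sampling is uniform at the frame rate from the
    anchoring apex over one stride; independent Gaussian noise of the
    spec's standard deviation is added to every position and velocity
    channel (velocity noise scaled by the frame rate as finite-differenced
    position noise would be).  Deterministic given the seed.
    """
    if solution is None:
        solution = trial_like_skipping(spec.params, spec.speed, opts)
    from .gait_search import bvp_vector, times_from_sequence

    seq = solution.sequence
    times = times_from_sequence(solution.event_times, seq)
    st = state_from_reduced(solution.s, solution.smode)
    traj = simulate_prescribed(st, solution.params, seq, times, opts, store=True)
    if traj.status != "periodic-candidate":
        raise GaitSearchError(f"fixture stride failed: {traj.status}")
    T = solution.T
    n = max(int(math.floor(T * spec.frame_rate)) + 1, 8)
    ts = np.linspace(0.0, T, n)
    samples = traj.sample(ts)
    rng = np.random.default_rng(spec.seed)
    q = samples[:, :4].copy()
    qd = samples[:, 4:].copy()
    if spec.noise_sigma > 0:
        q += rng.normal(0.0, spec.noise_sigma, q.shape)
        qd += rng.normal(0.0, spec.noise_sigma * spec.frame_rate / 2.0, qd.shape)
    return KinematicTrajectory(
        t=ts, q=q, qdot=qd,
        frame_rate=spec.frame_rate,
        provenance="synthetic",
        meta={
            "seed": spec.seed,
            "noise_sigma": spec.noise_sigma,
            "label": solution.label.value,
            **{f"source_{k}": v for k, v in solution.params.to_dict().items()},
            "source_speed": solution.apex_speed,
        },
    )


# ---------------------------------------------------------------------------
# Trajectory CSV dialect
# ---------------------------------------------------------------------------

_TRAJ_COLUMNS = [
    "t", "x", "y", "alpha_l", "alpha_r",
    "xdot", "ydot", "alphadot_l", "alphadot_r",
]


def write_trajectory(traj: KinematicTrajectory, path: str | Path) -> None:
    """Comma-separated samples with '#' key=value metadata header lines."""
    path = Path(path)
    header = {
        "format": "slipgait-kinematics-v1",
        "frame_rate": traj.frame_rate,
        "provenance": traj.provenance,
        "units": "normalized m=lo=g=1",
        **traj.meta,
    }
    with open(path, "w") as fh:
        for k, v in header.items():
            fh.write(f"# {k}={v}\n")
        fh.write(",".join(_TRAJ_COLUMNS) + "\n")
        data = np.column_stack([traj.t, traj.q, traj.qdot])
        for row in data:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


def _parse_header(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" not in body:
                raise ValueError(f"{path}:{ln}: malformed header line {body!r}")
            k, v = body.split("=", 1)
            meta[k.strip()] = v.strip()
    return meta


def read_trajectory(path: str | Path) -> KinematicTrajectory:
    path = Path(path)
    meta = _parse_header(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in _TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    fr = float(meta.get("frame_rate", "nan"))
    return KinematicTrajectory(
        t=df["t"].to_numpy(),
        q=df[["x", "y", "alpha_l", "alpha_r"]].to_numpy(),
        qdot=df[["xdot", "ydot", "alphadot_l", "alphadot_r"]].to_numpy(),
        frame_rate=fr,
        provenance=meta.get("provenance", "external"),
        meta={k: v for k, v in meta.items()
              if k not in ("format", "frame_rate", "provenance", "units")},
    )


# ---------------------------------------------------------------------------
# Solution / branch archives
# ---------------------------------------------------------------------------

def write_solution(sol: PeriodicSolution, path: str | Path) -> None:
    Path(path).write_text(json.dumps(sol.to_record(), indent=1))


def read_solution(path: str | Path) -> PeriodicSolution:
    return PeriodicSolution.from_record(json.loads(Path(path).read_text()))


def write_branch(branch: Branch, path: str | Path, csv_path: str | Path | None = None) -> None:
    """JSON archive (solutions + transition points); optionally also a flat
    CSV with one row per solution."""
    rec = {
        "termination": branch.termination,
        "closed": branch.closed,
        "provenance": {
            k: v for k, v in branch.provenance.items()
            if k not in ("u_vectors", "sequences")
            and isinstance(v, (str, int, float, dict, bool, type(None)))
        },
        "solutions": [s.to_record() for s in branch.solutions],
        "transitions": [
            {
                "kind": t.kind,
                "detail": t.detail,
                "critical_multiplier": (
                    None if t.critical_multiplier is None
                    else [t.critical_multiplier.real, t.critical_multiplier.imag]
                ),
                "solution": t.solution.to_record(),
            }
            for t in branch.transitions
        ],
    }
    Path(path).write_text(json.dumps(rec))
    if csv_path is not None:
        rows = []
        for s in branch.solutions:
            r = s.to_record()
            pr = r.pop("params")
            r.pop("sequence", None)
            r.pop("floquet_re", None)
            r.pop("floquet_im", None)
            r.update({f"param_{k}": v for k, v in pr.items()})
            rows.append(r)
        pd.DataFrame(rows).to_csv(csv_path, index=False)


def read_branch(path: str | Path) -> Branch:
    rec = json.loads(Path(path).read_text())
    branch = Branch(
        solutions=[PeriodicSolution.from_record(r) for r in rec["solutions"]],
        termination=rec.get("termination", ""),
        closed=rec.get("closed", False),
        provenance=rec.get("provenance", {}),
    )
    for t in rec.get("transitions", []):
        cm = t.get("critical_multiplier")
        branch.transitions.append(
            TransitionPoint(
                solution=PeriodicSolution.from_record(t["solution"]),
                kind=t["kind"],
                detail=t.get("detail", ""),
                critical_multiplier=None if cm is None else complex(cm[0], cm[1]),
            )
        )
    return branch


# ---------------------------------------------------------------------------
# Flat key=value configuration
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Parse a flat key=value configuration file ('#' comments allowed)."""
    out: dict = {}
    path = Path(path)
    for ln, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{ln}: expected key=value, got {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        if key not in CONFIG_KEYS:
            raise ValueError(
                f"{path}:{ln}: unknown key {key!r}; valid keys: "
                + ", ".join(sorted(CONFIG_KEYS))
            )
        out[key] = CONFIG_KEYS[key](val)
    return out


def params_from_config(cfg: dict) -> ModelParams:
    kw = {k: cfg[k] for k in ("k", "omega", "phi_l", "phi_r") if k in cfg}
    return ModelParams(**kw)


def options_from_config(cfg: dict) -> IntegratorOptions:
    from dataclasses import replace as _rp

    kw = {k: cfg[k] for k in ("rtol", "atol", "premature_tol") if k in cfg}
    return _rp(DEFAULT_OPTIONS, **kw)
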