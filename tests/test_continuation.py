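"""Floquet analysis, branch tracing and transition machinery."""

import numpy as np
import pytest

from slipgait.continuation import (
    ContinuationOptions,
    branch_switch,
    continue_branch,
    detect_bifurcation,
    floquet_multipliers,
    locate_timing_degeneracy,
    monodromy,
    timing_gap,
    trace_branch,
    transport_solution,
)
from slipgait.gait_search import resolve_gait, swap_legs
from slipgait.model_core import GaitLabel, ModelParams


class TestMonodromy:
    def test_one_unit_multiplier_at_conservative_fixed_point(self, forward_hop):
        lam = floquet_multipliers(forward_hop)
        unit = np.abs(lam - 1.0)
        assert np.min(unit) < 1e-4
        # exactly one within the tolerance (phase/energy direction)
        assert np.sum(unit < 1e-4) == 1

    def test_step_size_robustness(self, forward_hop):
        l1 = np.sort_complex(np.linalg.eigvals(monodromy(forward_hop, h=1e-5)))
        l2 = np.sort_complex(np.linalg.eigvals(monodromy(forward_hop, h=1e-6)))
        assert np.max(np.abs(l1 - l2)) < 1e-3

    def test_spectrum_invariant_under_leg_swap(self, forward_hop):
        swapped = resolve_gait(
            swap_legs(forward_hop), anchor=("speed", forward_hop.apex_speed)
        )
        l1 = np.sort(np.abs(floquet_multipliers(forward_hop)))
        l2 = np.sort(np.abs(floquet_multipliers(swapped)))
        assert np.max(np.abs(l1 - l2)) < 1e-4


@pytest.fixture(scope="module")
def short_hop_branch(forward_hop):
    copts = ContinuationOptions(
        ds0=0.05, ds_max=0.6, grow=1.5, max_points=60, speed_cap=6.5
    )
    return trace_branch(forward_hop, copts)


class TestContinuation:
    def test_branch_has_bounded_steps_and_one_label(self, short_hop_branch):
        br = short_hop_branch
        assert len(br) > 10
        assert set(br.labels()) == {GaitLabel.HOPPING}
        E = br.energies
        assert np.max(np.abs(np.diff(E))) < 5.0

    def test_retraceability(self, short_hop_branch, forward_hop):
        # re-solving from a mid-branch solution recovers it
        mid = short_hop_branch.solutions[len(short_hop_branch) // 2]
        again = resolve_gait(mid, anchor=("energy", mid.energy))
        assert np.allclose(again.s, mid.s, atol=1e-6)

    def test_hop_skip_bifurcation_and_switch(self, short_hop_branch):
        tps = detect_bifurcation(short_hop_branch, stride=2)
        assert len(tps) >= 1, "at least one hop<->skip bifurcation"
        tp = tps[0]
        assert abs(tp.critical_multiplier - 1.0) < 1e-3
        assert tp.eigenvector is not None
        new = branch_switch(tp)
        assert new.label != GaitLabel.HOPPING
        # desynchronized legs: staggered touchdowns
        et = new.event_times
        assert abs(et.t_ltd - et.t_rtd) > 1e-4

    def test_no_crossing_gives_empty_list(self, forward_hop):
        copts = ContinuationOptions(
            ds0=0.02, ds_max=0.1, max_points=8, speed_cap=2.0
        )
        br = continue_branch(forward_hop, +1, copts)
        tps = detect_bifurcation(br, stride=1)
        assert tps == [] or all(t.speed > 5.0 for t in tps)


class TestTimingDegeneracy:
    def test_gap_sign_distinguishes_patterns(self, forward_hop, symmetric_run):
        # hopping: simultaneous (gap ~ -stance duration); running: positive
        assert timing_gap(symmetric_run) > 0

    def test_walk_run_point_on_symmetric_branch(self, sym_study):
        tp = sym_study["walk_run_point"]
        assert tp is not None
        # at the degeneracy one leg's touchdown coincides with the other's
        # liftoff
        et = tp.solution.event_times
        assert abs(timing_gap(tp.solution)) < 1e-7
        assert min(abs(et.t_ltd - et.t_rlo), abs(et.t_rtd - et.t_llo)) < 1e-6


class TestTransport:
    def test_transport_roundtrip(self, forward_hop):
        # a small parameter excursion and back recovers the same solution
        p = ModelParams()
        there = transport_solution(forward_hop, p.with_phis(0.05, 0.05))
        assert there.params.phi_l == pytest.approx(0.05)
        back = transport_solution(there, p.with_phis(0.0, 0.0))
        assert np.allclose(back.s, forward_hop.s, atol=1e-6)

    def test_nominal_structure_mirror_symmetry(self, forward_hop):
        # with phi_l = phi_r = 0 the structure is symmetric under mirroring
        from slipgait.gait_search import mirror_solution

        mirrored = resolve_gait(
            mirror_solution(forward_hop),
            anchor=("speed", -forward_hop.apex_speed),
        )
        assert mirrored.s[0] == pytest.approx(forward_hop.s[0], abs=1e-8)
        assert mirrored.T == pytest.approx(forward_hop.T, abs=1e-8)


class TestSweeps:
    def test_coupled_sweep_smoke(self):
        """One-entry coupled sweep reproduces the nominal asymmetric
        structure (hopping branch with at least one hop<->skip
        bifurcation)."""
        from slipgait.continuation import sweep_coupled

        res = sweep_coupled(
            [0.0], ModelParams(),
            copts=ContinuationOptions(
                ds0=0.05, ds_max=0.8, grow=1.5, max_points=40, speed_cap=7.0
            ),
            with_symmetric=False,
        )
        entry = res[0.0]
        assert entry["error"] is None
        assert entry["hopping"] is not None and len(entry["hopping"]) > 10
        assert len(entry["bifurcations"]) >= 1
        assert all(
            s.label is GaitLabel.HOPPING for s in entry["hopping"].solutions
        )
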