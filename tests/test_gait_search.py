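"""Gait finding, classification and metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from slipgait.gait_search import (
    GaitSearchError,
    classify_gait,
    find_gait,
    gait_metrics,
    mirror_solution,
    periodicity_residual,
    resolve_gait,
    swap_legs,
    times_from_sequence,
)
from slipgait.hybrid_sim import SectionMode
from slipgait.model_core import EventTimes, GaitLabel, ModelParams


class TestClassifyGait:
    def test_hopping_synchronized(self):
        et = EventTimes(0.3, 0.6, 0.3, 0.6, 1.0)
        assert classify_gait(et) is GaitLabel.HOPPING

    def test_skipping_overlapping(self):
        et = EventTimes(0.4, 0.7, 0.2, 0.5, 1.0)
        assert classify_gait(et) is GaitLabel.SKIPPING

    def test_symmetric_running_equal_aerial_phases(self):
        et = EventTimes(0.6, 0.8, 0.1, 0.3, 1.0)
        assert classify_gait(et) is GaitLabel.SYMMETRIC_RUNNING

    def test_asymmetric_running_unequal_aerial_phases(self):
        et = EventTimes(0.55, 0.8, 0.1, 0.3, 1.0)
        assert classify_gait(et) is GaitLabel.ASYMMETRIC_RUNNING

    def test_walking_no_aerial_phase(self):
        # left in stance across the anchor: llo before ltd, full coverage
        et = EventTimes(0.6, 0.35, 0.25, 0.95, 1.0)
        assert classify_gait(et) is GaitLabel.WALKING

    def test_simultaneity_tested_before_ordering(self):
        # near-synchronized within tolerance stays hopping
        et = EventTimes(0.3000001, 0.6, 0.3, 0.6000001, 1.0)
        assert classify_gait(et, tol_t=1e-3) is GaitLabel.HOPPING

    def test_invalid_times_degenerate(self):
        et = EventTimes(-0.1, 0.6, 0.3, 0.6, 1.0)
        assert classify_gait(et) is GaitLabel.DEGENERATE

    @given(
        td=st.floats(0.05, 0.9),
        dur=st.floats(0.05, 0.5),
        shift=st.floats(0.0, 0.95),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_two_leg_patterns_always_labelled(self, td, dur, shift):
        T = 1.0
        lo = min(td + dur, 0.99)
        ltd = (td + shift) % T
        llo = (lo + shift) % T
        et = EventTimes(ltd, llo, td, lo, T)
        label = classify_gait(et)
        assert isinstance(label, GaitLabel)
        if abs(ltd - td) < 1e-4 and abs(llo - lo) < 1e-4:
            assert label is GaitLabel.HOPPING


class TestFindGait:
    def test_vertical_hop_energy_anchor(self, vertical_hop):
        assert vertical_hop.label is GaitLabel.HOPPING
        assert vertical_hop.residual_norm < 1e-8
        assert vertical_hop.energy == pytest.approx(1.2, abs=1e-9)
        assert vertical_hop.avg_speed == pytest.approx(0.0, abs=1e-8)

    def test_resolve_is_idempotent(self, forward_hop):
        again = resolve_gait(forward_hop, anchor=("speed", forward_hop.apex_speed))
        assert np.allclose(again.s, forward_hop.s, atol=1e-7)
        assert again.T == pytest.approx(forward_hop.T, abs=1e-7)

    def test_speed_anchor_respected(self, forward_hop):
        assert forward_hop.apex_speed == pytest.approx(0.5, abs=1e-10)

    def test_unconverged_seed_raises(self, nominal):
        with pytest.raises(GaitSearchError):
            find_gait(
                np.array([0.4, 8.0, 1.2, -9.0, -1.2, 9.0]), nominal,
                anchor=("speed", 8.0), max_nfev=40,
            )

    def test_symmetric_running_half_stride_offsets(self, symmetric_run):
        # symmetric gaits: leg event times offset by exactly T/2
        et = symmetric_run.event_times
        assert abs(et.t_ltd - et.t_rtd) == pytest.approx(et.T / 2, abs=1e-6)
        assert abs(et.t_llo - et.t_rlo) == pytest.approx(et.T / 2, abs=1e-6)
        assert symmetric_run.label is GaitLabel.SYMMETRIC_RUNNING


class TestPeriodicityResidual:
    def test_zero_at_solved_gait(self, nominal, vertical_hop):
        r = periodicity_residual(
            vertical_hop.s, vertical_hop.event_times, nominal
        )
        assert np.linalg.norm(r) < 1e-6

    def test_grows_smoothly_off_the_fixed_point(self, nominal, vertical_hop):
        et = vertical_hop.event_times
        r0 = np.linalg.norm(
            periodicity_residual(vertical_hop.s, et, nominal)
        )
        s_off = vertical_hop.s + np.array([1e-3, 0, 0, 0, 0, 0])
        r1 = np.linalg.norm(periodicity_residual(s_off, et, nominal))
        assert r0 < r1 < 1.0


class TestMetricsAndSymmetry:
    def test_duty_factor_definition(self, forward_hop):
        et = forward_hop.event_times
        expected = 0.5 * (
            (et.t_llo - et.t_ltd) + (et.t_rlo - et.t_rtd)
        ) / et.T
        m = gait_metrics(forward_hop)
        assert m["duty_factor"] == pytest.approx(expected, rel=1e-12)

    def test_average_speed_identity(self, forward_hop):
        m = gait_metrics(forward_hop)
        assert m["average_speed"] == pytest.approx(
            m["stride_length"] / m["stride_time"], rel=1e-12
        )

    def test_leg_swap_is_solution_for_equal_phis(self, forward_hop):
        swapped = swap_legs(forward_hop)
        sol = resolve_gait(swapped, anchor=("speed", swapped.apex_speed))
        assert np.allclose(sol.s, swapped.s, atol=1e-6)

    def test_mirror_is_backward_solution(self, forward_hop):
        mirrored = mirror_solution(forward_hop)
        sol = resolve_gait(mirrored, anchor=("speed", mirrored.apex_speed))
        assert sol.apex_speed == pytest.approx(-forward_hop.apex_speed, abs=1e-9)

    def test_aerial_phase_presence_by_label(self, forward_hop, symmetric_run):
        for sol in (forward_hop, symmetric_run):
            assert len(sol.event_times.aerial_intervals()) >= 1
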