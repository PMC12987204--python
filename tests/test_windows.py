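"""Window stacks, postprandial AUC and pre/post contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

import chronomeal as cm
from chronomeal.windows import (
    extract_stack,
    merge_stacks,
    postprandial_auc,
    postprandial_vs_mean,
    prepost_contrast,
    stack_aucs,
)
from conftest import make_event


class TestExtractStack:
    def test_single_anchor_constant_glucose(self, flat_trace):
        stacks = extract_stack(
            [make_event("2024-03-04 10:00")], glucose=flat_trace,
            pre_minutes=0, post_minutes=120,
        )
        st = stacks["glucose"]
        np.testing.assert_array_equal(st.mean_curve, np.full(25, 100.0))
        assert np.isnan(st.sem_curve).all()  # single window: SEM undefined

    def test_two_identical_windows_zero_sem(self, flat_trace):
        stacks = extract_stack(
            [make_event("2024-03-04 08:00"), make_event("2024-03-04 12:00")],
            glucose=flat_trace, pre_minutes=0, post_minutes=120,
        )
        np.testing.assert_array_equal(stacks["glucose"].sem_curve, np.zeros(25))

    def test_partial_window_padded_missing(self, flat_trace):
        stacks = extract_stack(
            [make_event("2024-03-04 23:00")], glucose=flat_trace,
            pre_minutes=0, post_minutes=120,
        )
        row = stacks["glucose"].rows[0]
        assert np.isfinite(row[:12]).all() and np.isnan(row[13:]).all()

    def test_empty_anchor_list_rejected(self, flat_trace):
        with pytest.raises(cm.ContractError):
            extract_stack([], glucose=flat_trace)

    def test_breakfast_stack_peaks_near_generator_lag(self, default_cohort):
        params, bundle = default_cohort
        stacks = []
        for trace in bundle.glucose:
            epoched = cm.to_epochs(trace, 300)
            evs = [
                e for e in bundle.events
                if e.participant_id == trace.participant_id
                and e.meal_type == "breakfast"
            ]
            if evs:
                stacks.append(
                    extract_stack(evs, glucose=epoched, pre_minutes=0,
                                  post_minutes=120)["glucose"]
                )
        merged = merge_stacks(stacks)
        apex = merged.offsets[np.nanargmax(merged.mean_curve)]
        assert apex == pytest.approx(
            params.excursion_lag_mean_min["breakfast"], abs=10
        )

    def test_time_shift_equivariance(self, flat_trace):
        values = flat_trace.values + np.arange(288) * 0.1
        trace = cm.GlucoseTrace("P01", flat_trace.times, values, 300)
        shifted = cm.GlucoseTrace(
            "P01", flat_trace.times + pd.Timedelta(days=3), values, 300
        )
        ev = make_event("2024-03-04 10:00")
        ev_shift = make_event("2024-03-07 10:00")
        a = extract_stack([ev], glucose=trace)["glucose"]
        b = extract_stack([ev_shift], glucose=shifted)["glucose"]
        np.testing.assert_array_equal(a.rows, b.rows)


class TestAUC:
    grid = np.arange(0, 125, 5.0)

    def test_constant_100_rectangle(self):
        assert postprandial_auc(self.grid, np.full(25, 100.0)) == 12000.0

    def test_linear_ramp_trapezoid(self):
        assert postprandial_auc(self.grid, np.linspace(90, 110, 25)) == 12000.0

    def test_triangle_against_quadrature_oracle(self):
        # piecewise linear 100 -> 140 at 60 min -> 100 at 120 min
        tri = lambda t: 100 + 40 * (1 - abs(t - 60) / 60)
        expected, _ = quad(tri, 0, 120, points=[60])
        values = np.array([tri(t) for t in self.grid])
        assert postprandial_auc(self.grid, values) == pytest.approx(expected)

    def test_interior_gap_bridged_linearly(self):
        values = np.linspace(90, 110, 25)
        gappy = values.copy()
        gappy[7:10] = np.nan
        assert postprandial_auc(self.grid, gappy) == pytest.approx(12000.0)

    def test_fewer_than_two_points_undefined(self):
        v = np.full(25, np.nan)
        v[3] = 100.0
        assert np.isnan(postprandial_auc(self.grid, v))

    def test_auc_of_mean_equals_mean_of_aucs_when_complete(self, flat_trace):
        values = flat_trace.values + np.sin(np.arange(288) / 7.0)
        trace = cm.GlucoseTrace("P01", flat_trace.times, values, 300)
        evs = [make_event(f"2024-03-04 {h:02d}:00") for h in (8, 10, 12)]
        st = extract_stack(evs, glucose=trace, pre_minutes=0, post_minutes=120)["glucose"]
        assert postprandial_auc(st.offsets, st.mean_curve) == pytest.approx(
            stack_aucs(st).mean()
        )


class TestPostprandialVsMean:
    def test_constant_trace_pair_equal(self, flat_trace):
        post, overall = postprandial_vs_mean(
            [make_event("2024-03-04 10:00")], flat_trace
        )
        assert post == overall == 100.0

    def test_single_event_participant(self, flat_trace):
        values = flat_trace.values.copy()
        values[120:144] += 30  # elevated 10:00-12:00
        trace = cm.GlucoseTrace("P01", flat_trace.times, values, 300)
        post, overall = postprandial_vs_mean([make_event("2024-03-04 10:00")], trace)
        assert post > overall

    def test_postbreakfast_exceeds_mean_for_most_participants(self, default_cohort):
        _, bundle = default_cohort
        wins = 0
        for trace in bundle.glucose:
            epoched = cm.to_epochs(trace, 300)
            evs = [
                e for e in bundle.events
                if e.participant_id == trace.participant_id
                and e.meal_type == "breakfast"
            ]
            post, overall = postprandial_vs_mean(evs, epoched)
            wins += post > overall
        assert wins >= 18


class TestPrePost:
    def test_constant_signal_equal_means(self, flat_trace):
        st = extract_stack(
            [make_event("2024-03-04 12:00")], glucose=flat_trace,
            anchor_kind="glucose_peak", pre_minutes=60, post_minutes=120,
        )["glucose"]
        (c,) = prepost_contrast(st)
        assert c.pre_mean == c.post_mean == 100.0

    def test_dinner_dst_rises_and_mi_falls(self, default_cohort):
        """After the dinner glucose peak DST climbs (sleep anticipation) while
        movement intensity falls (sleep onset) for most participants."""
        _, bundle = default_cohort
        dst_up = mi_down = n = 0
        for trace in bundle.glucose:
            pid = trace.participant_id
            acm = next(a for a in bundle.acm if a.participant_id == pid)
            epoched = cm.to_epochs(trace, 300)
            evs = [e for e in bundle.events
                   if e.participant_id == pid and e.meal_type == "dinner"]
            if not evs:
                continue
            peaks = cm.detect_peaks(epoched)
            linked = [lm for lm in cm.link_meals_to_peaks(evs, peaks) if lm.linked]
            if not linked:
                continue
            st = extract_stack(
                [lm.peak for lm in linked], acm=acm, anchor_kind="glucose_peak",
                pre_minutes=60, post_minutes=120,
            )
            for c in prepost_contrast(st["dst"]):
                dst_up += c.post_mean > c.pre_mean
            for c in prepost_contrast(st["mi"]):
                mi_down += c.post_mean < c.pre_mean
            n += 1
        assert n >= 15
        assert dst_up / n > 0.7
        assert mi_down / n > 0.7
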