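"""Meal-peak assignment rules and the accuracy statistic."""

import itertools

import numpy as np
import pandas as pd
import pytest

import chronomeal as cm
from chronomeal.linkage import lag_summary, link_meals_to_peaks, peak_related_accuracy
from conftest import make_event


def peak_at(ts, value=140.0, amplitude=40.0):
    t = pd.Timestamp(ts)
    return cm.PeakCall(
        nadir_time=t - pd.Timedelta(minutes=30),
        nadir_value=value - amplitude,
        peak_time=t,
        peak_value=value,
    )


class TestLinking:
    def test_nearest_subsequent_peak(self):
        ev = make_event("2024-03-04 13:00")
        out = link_meals_to_peaks([ev], [peak_at("2024-03-04 13:45"),
                                         peak_at("2024-03-04 15:30")])
        assert out[0].linked and out[0].lag_minutes == 45

    def test_beyond_two_hours_unlinked_but_lag_kept(self):
        ev = make_event("2024-03-04 13:00")
        out = link_meals_to_peaks([ev], [peak_at("2024-03-04 15:30")])
        assert not out[0].linked
        assert out[0].lag_minutes == 150  # kept for the distance distribution

    def test_peak_before_event_is_never_a_candidate(self):
        ev = make_event("2024-03-04 13:00")
        out = link_meals_to_peaks([ev], [peak_at("2024-03-04 12:30")])
        assert not out[0].linked and out[0].lag_minutes is None

    def test_one_peak_one_meal_earliest_priority(self):
        evs = [make_event("2024-03-04 13:00"), make_event("2024-03-04 13:20")]
        out = link_meals_to_peaks(evs, [peak_at("2024-03-04 13:50")])
        assert out[0].linked and not out[1].linked

    @pytest.mark.parametrize("seed", [17, 18, 19])
    def test_exclusive_assignment_bounded_by_brute_force(self, seed):
        """Linked count never exceeds the maximum feasible one-to-one matching."""
        rng = np.random.default_rng(seed)
        base = pd.Timestamp("2024-03-04 08:00")
        events = [make_event(base + pd.Timedelta(minutes=int(m)))
                  for m in np.sort(rng.choice(720, 6, replace=False))]
        peaks = [peak_at(base + pd.Timedelta(minutes=int(m)))
                 for m in np.sort(rng.choice(720, 5, replace=False))]
        linked = link_meals_to_peaks(events, peaks)
        n_linked = sum(lm.linked for lm in linked)

        def feasible(ev, pk):
            lag = (pk.peak_time - ev.timestamp).total_seconds() / 60
            return 0 <= lag <= 120

        best = 0
        for k in range(min(len(events), len(peaks)), 0, -1):
            for ev_subset in itertools.combinations(range(len(events)), k):
                for pk_perm in itertools.permutations(range(len(peaks)), k):
                    if all(feasible(events[e], peaks[p])
                           for e, p in zip(ev_subset, pk_perm)):
                        best = max(best, k)
            if best == k:
                break
        assert n_linked <= best
        # every event whose own nearest-after peak is within the window and
        # unclaimed must be linked, so a feasible pair implies >= 1 link
        if best > 0:
            assert n_linked >= 1

    def test_accuracy_monotone_in_max_lag(self):
        rng = np.random.default_rng(23)
        base = pd.Timestamp("2024-03-04 06:00")
        events = [make_event(base + pd.Timedelta(minutes=int(m)))
                  for m in np.sort(rng.choice(1440, 30, replace=False))]
        peaks = [peak_at(base + pd.Timedelta(minutes=int(m)))
                 for m in np.sort(rng.choice(1440, 25, replace=False))]
        prev = -1.0
        for max_lag in (0, 15, 30, 60, 120, 240):
            linked = link_meals_to_peaks(events, peaks, max_lag_minutes=max_lag)
            acc = peak_related_accuracy(linked).raw_fractions["overall"]
            assert acc >= prev
            prev = acc

    def test_no_peaks_zero_accuracy_everywhere(self):
        evs = [make_event(f"2024-03-04 {h:02d}:00", meal_type=m)
               for h, m in [(9, "breakfast"), (14, "lunch"), (21, "dinner")]]
        table = peak_related_accuracy(link_meals_to_peaks(evs, []))
        assert (table.table.accuracy_percent == 0).all()

    def test_peak_right_after_every_event_gives_full_accuracy(self):
        evs = [make_event(f"2024-03-04 {h:02d}:00") for h in range(8, 20, 3)]
        peaks = [peak_at(e.timestamp + pd.Timedelta(minutes=1)) for e in evs]
        table = peak_related_accuracy(link_meals_to_peaks(evs, peaks))
        assert (table.table.accuracy_percent == 100.0).all()


class TestAccuracyTable:
    def _fixture(self, spec):
        """spec: {meal_type: (n_linked, n_total)} built 3 h apart."""
        base = pd.Timestamp("2024-01-01 00:00")
        events, peaks = [], []
        i = 0
        for meal, (n_linked, n_total) in spec.items():
            for j in range(n_total):
                t = base + pd.Timedelta(hours=3 * i)
                events.append(make_event(t, meal_type=meal))
                if j < n_linked:
                    peaks.append(peak_at(t + pd.Timedelta(minutes=45)))
                i += 1
        return link_meals_to_peaks(events, peaks)

    @pytest.mark.parametrize(
        "meal,counts,expected",
        [
            ("breakfast", (102, 110), 92.7),
            ("lunch", (108, 125), 86.4),
            ("dinner", (98, 123), 79.7),
        ],
    )
    def test_printed_per_meal_counts(self, meal, counts, expected):
        table = peak_related_accuracy(self._fixture({meal: counts}))
        assert table.accuracy(meal) == expected

    def test_totals_add_up(self):
        table = peak_related_accuracy(
            self._fixture({"breakfast": (2, 3), "lunch": (1, 2)})
        ).table
        overall = table[table.meal_type == "overall"]
        per_type = table[table.meal_type != "overall"]
        assert overall.n_total.iloc[0] == per_type.n_total.sum()
        assert overall.n_linked.iloc[0] == per_type.n_linked.sum()

    def test_empty_rejected(self):
        with pytest.raises(cm.ContractError):
            peak_related_accuracy([])


class TestLagSummary:
    def _linked(self, lags, meal="breakfast"):
        base = pd.Timestamp("2024-03-04 09:00")
        out = []
        for i, lag in enumerate(lags):
            ev = make_event(base + pd.Timedelta(hours=3 * i), meal_type=meal)
            out.append(
                cm.LinkedMeal(
                    event=ev,
                    peak=peak_at(ev.timestamp + pd.Timedelta(minutes=lag)),
                    lag_minutes=float(lag),
                    linked=True,
                )
            )
        return out

    def test_mean_and_sem(self):
        df = lag_summary(self._linked([40, 42, 44])).set_index("meal_type")
        assert df.loc["breakfast", "mean_lag_min"] == 42
        assert df.loc["breakfast", "sem_lag_min"] == pytest.approx(1.1547, abs=1e-3)

    def test_single_lag_sem_absent(self):
        df = lag_summary(self._linked([50])).set_index("meal_type")
        assert df.loc["breakfast", "mean_lag_min"] == 50
        assert np.isnan(df.loc["breakfast", "sem_lag_min"])

    def test_type_without_linked_events_omitted(self):
        df = lag_summary(self._linked([40, 50], meal="dinner"))
        assert list(df.meal_type) == ["dinner"]


def test_breakfast_lag_recovered_from_cohort(default_cohort):
    """Linked breakfast lags recover the generator's mean lag within 5 min."""
    params, bundle = default_cohort
    all_linked = []
    for trace in bundle.glucose:
        epoched = cm.to_epochs(trace, 300)
        ke = [e for e in bundle.events if e.participant_id == trace.participant_id]
        peaks = cm.detect_peaks(epoched)
        all_linked.extend(cm.link_meals_to_peaks(ke, peaks))
    df = lag_summary(all_linked).set_index("meal_type")
    assert df.loc["breakfast", "mean_lag_min"] == pytest.approx(
        params.excursion_lag_mean_min["breakfast"], abs=5.0
    )
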