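"""Transition-probability estimators: worked example, orderings, oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fragmetrics import (
    StateSeries,
    UndefinedMetricError,
    WindowAnnotation,
    bayes_tp,
    extract_bouts,
    ml_tp,
    rad,
    windowed_tp,
)

state_vectors = st.lists(st.booleans(), min_size=2, max_size=120).map(
    lambda bits: np.array(bits, dtype=bool)
)
mixed_vectors = state_vectors.filter(lambda arr: 0 < arr.sum() < arr.size)


def pair_scan_tp(states: np.ndarray, active: bool) -> tuple[int, int]:
    """s=1 oracle: scan consecutive epoch pairs directly.

    Returns (count of transitions out of the state, count of pairs starting
    in the state).
    """
    leaving = opportunities = 0
    for t in range(states.size - 1):
        if states[t] == active:
            opportunities += 1
            if states[t + 1] != active:
                leaving += 1
    return leaving, opportunities


class TestWorkedExample:
    """The 15-epoch sequence with r=(2,1,2,2), a=(3,1,3,1)."""

    @pytest.mark.parametrize("fn, direction, kwargs, num, den, value", [
        (rad, "ra", {}, 4, 7, 0.57),
        (ml_tp, "ra", {"s": 1}, 3, 6, 0.50),
        (bayes_tp, "ra", {"lambda_": 0.5}, 3.5, 6.5, 0.54),
        (rad, "ar", {}, 4, 8, 0.50),
        (ml_tp, "ar", {"s": 1}, 4, 8, 0.50),
        (bayes_tp, "ar", {"lambda_": 0.5}, 4.5, 8.5, 0.53),
    ])
    def test_numerators_denominators_estimates(self, worked_bouts, fn,
                                               direction, kwargs, num, den,
                                               value):
        est = fn(worked_bouts, direction, **kwargs)
        assert est.numerator == num
        assert est.denominator == den
        assert est.value == pytest.approx(value, abs=5e-3)

    def test_memory_two_rest_transition(self, worked_bouts):
        est = ml_tp(worked_bouts, "ra", s=2)
        assert (est.numerator, est.denominator) == (2.0, 2.0)
        assert est.value == 1.0

    def test_s_out_of_range_rejected(self, worked_bouts):
        with pytest.raises(ValueError, match="out of range"):
            ml_tp(worked_bouts, "ra", s=3)   # longest rest bout is 2
        with pytest.raises(ValueError, match="out of range"):
            ml_tp(worked_bouts, "ar", s=0)


class TestEdgeCases:
    def test_fully_censored_rest_bout(self):
        # a single rest run ending the record: RAD=1/L but ML counts no
        # transition in L-1 opportunities
        b = extract_bouts(StateSeries.from_symbols(["a"] + ["r"] * 5))
        assert rad(b, "ra").value == pytest.approx(1 / 5)
        est = ml_tp(b, "ra", 1)
        assert (est.numerator, est.denominator) == (0.0, 4.0)
        assert est.value == 0.0

    def test_all_rest_series(self):
        b = extract_bouts(StateSeries.from_symbols(["r"] * 6))
        lam = 0.5
        est = bayes_tp(b, "ra", lam)
        # one fully censored rest bout: lambda / ((T_r - 1) + lambda)
        assert est.value == pytest.approx(lam / (5 + lam))
        assert bayes_tp(b, "ar", lam).value == 1.0   # state never observed
        with pytest.raises(UndefinedMetricError):
            rad(b, "ar")
        with pytest.raises(UndefinedMetricError):
            ml_tp(b, "ra", s=6)  # single bout, fully censored

    def test_bad_lambda_rejected(self, worked_bouts):
        for lam in (0.0, -0.5, float("nan")):
            with pytest.raises(ValueError):
                bayes_tp(worked_bouts, "ra", lam)

    def test_bad_direction_rejected(self, worked_bouts):
        with pytest.raises(ValueError, match="direction"):
            ml_tp(worked_bouts, "xy", 1)


class TestProperties:
    @staticmethod
    def _ml_or_none(b, direction):
        try:
            return ml_tp(b, direction, 1)
        except UndefinedMetricError:
            return None

    @given(mixed_vectors)
    @settings(max_examples=150, deadline=None)
    def test_rad_ml_orderings(self, states):
        # the RAD heuristic equals ML for the state that does not close the
        # record and strictly exceeds it for the state that does
        b = extract_bouts(StateSeries(states))
        ml_ra = self._ml_or_none(b, "ra")
        ml_ar = self._ml_or_none(b, "ar")
        rad_r, rad_a = rad(b, "ra"), rad(b, "ar")
        # strict inflation requires T_state > n_state (some bout longer than
        # one epoch); with all bouts of length one both ratios equal 1
        if b.last_state == "r":
            assert ml_ar is not None
            assert rad_a.value == pytest.approx(ml_ar.value, abs=1e-15)
            if ml_ra is not None:
                if b.T_r > b.n_r:
                    assert rad_r.value > ml_ra.value
                else:
                    assert rad_r.value == ml_ra.value == 1.0
        else:
            assert ml_ra is not None
            assert rad_r.value == pytest.approx(ml_ra.value, abs=1e-15)
            if ml_ar is not None:
                if b.T_a > b.n_a:
                    assert rad_a.value > ml_ar.value
                else:
                    assert rad_a.value == ml_ar.value == 1.0

    @given(mixed_vectors)
    @settings(max_examples=100, deadline=None)
    def test_bayes_converges_to_ml(self, states):
        b = extract_bouts(StateSeries(states))
        for direction in ("ra", "ar"):
            ml = self._ml_or_none(b, direction)
            if ml is None:
                continue
            bay = bayes_tp(b, direction, 1e-6)
            assert abs(bay.value - ml.value) < 1e-6

    @given(mixed_vectors)
    @settings(max_examples=150, deadline=None)
    def test_ml_matches_pair_scan_oracle(self, states):
        b = extract_bouts(StateSeries(states))
        for direction, active in (("ra", False), ("ar", True)):
            leaving, opportunities = pair_scan_tp(states, active)
            est = self._ml_or_none(b, direction)
            if opportunities == 0:
                assert est is None
            else:
                assert est.numerator == leaving
                assert est.denominator == opportunities


class TestWindowedTP:
    def test_all_rest_sleep_gives_unit_active_tp(self):
        wake = [True, False, True, True]
        sleep = [False] * 4
        y = StateSeries(np.array(wake + sleep))
        w = WindowAnnotation([(0, 4, "wake"), (4, 8, "sleep")])
        tps = windowed_tp(y, w, lambda_=0.5)
        assert tps.tp_ar_sleep.value == 1.0  # activity unobserved in sleep

    def test_single_window_reduces_to_whole_series_bayes(self, rng):
        states = rng.random(50) > 0.5
        y = StateSeries(states)
        w = WindowAnnotation([(0, 50, "wake")])
        tps = windowed_tp(y, w, lambda_=0.5)
        b = extract_bouts(y)
        assert tps.tp_ra_wake.value == pytest.approx(
            bayes_tp(b, "ra", 0.5).value, abs=1e-15)
        assert tps.tp_ar_wake.value == pytest.approx(
            bayes_tp(b, "ar", 0.5).value, abs=1e-15)
        assert tps.tp_ra_sleep is None and tps.tp_ar_sleep is None

    def test_totals_match_per_interval_oracle(self, rng):
        # two wake intervals, each engineered to end mid-activity-bout
        states = rng.random(40) > 0.4
        states[8:12] = True    # spans the first wake boundary at 10
        states[28:32] = True   # spans the second wake boundary at 30
        y = StateSeries(states)
        intervals = [(0, 10, "wake"), (10, 20, "sleep"),
                     (20, 30, "wake"), (30, 40, "sleep")]
        w = WindowAnnotation(intervals)
        lam = 0.5
        tps = windowed_tp(y, w, lam)
        # brute-force per-interval enumeration of activity runs in wake
        n = total = censored = 0
        for s, e, lab in intervals:
            if lab != "wake":
                continue
            seg = states[s:e]
            in_run = False
            for i, v in enumerate(seg):
                if v and not in_run:
                    n += 1
                    in_run = True
                elif not v:
                    in_run = False
                total += int(v)
            if in_run:
                censored += 1
        expected = (n - censored + lam) / (total - censored + lam)
        assert tps.tp_ar_wake.value == pytest.approx(expected, abs=1e-15)

    def test_bad_lambda_rejected(self, rng):
        y = StateSeries(rng.random(10) > 0.5)
        w = WindowAnnotation([(0, 10, "wake")])
        with pytest.raises(ValueError):
            windowed_tp(y, w, lambda_=0.0)
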