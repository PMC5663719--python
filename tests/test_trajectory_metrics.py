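"""Pitch/syntax correction metrics, binning, cohort summaries, null model."""

import numpy as np
import pandas as pd
import pytest

from songchairs.learning_simulator import SimParams, simulate
from songchairs.synthetic_data import SynthConfig, constant_truth, \
    generate_rendition_stream
from songchairs.trajectory_metrics import (SyntaxCorrection, binned_series,
                                           cohort_percentages,
                                           daily_pitch_medians,
                                           endpoint_summary,
                                           fraction_pitch_corrected,
                                           null_call_probability,
                                           pitch_vs_syntax_curve,
                                           rendition_pitch_fraction,
                                           rendition_syntax_indicators,
                                           syntax_fractions,
                                           syntax_shift_scale,
                                           syntax_spec_for_task,
                                           vacancy_histogram)


def _stream(bouts, day=0, pitch=None):
    """Annotation frame from bout label lists."""
    rows = []
    for b, labs in enumerate(bouts):
        for p, lab in enumerate(labs):
            rows.append({"day": day, "bout_id": b, "position_in_bout": p,
                         "label": lab, "onset_ms": 200.0 * p,
                         "offset_ms": 200.0 * p + 100.0,
                         "true_f0_hz": pitch.get(lab, np.nan) if pitch else np.nan,
                         "is_call": False})
    return pd.DataFrame(rows)


class TestPitchCorrection:
    def test_fraction_endpoints_and_midpoint(self):
        s = fraction_pitch_corrected(pd.Series([0.0, 1.0, 2.0]), 0.0, 2.0)
        assert s.tolist() == [0.0, 0.5, 1.0]

    def test_equal_source_target_rejected(self):
        with pytest.raises(ValueError):
            fraction_pitch_corrected(pd.Series([1.0]), 2.0, 2.0)

    def test_unclamped_overshoot(self):
        s = fraction_pitch_corrected(pd.Series([3.0, -1.0]), 0.0, 2.0)
        assert s.tolist() == [1.5, -0.5]

    def test_daily_medians_from_annotations(self, tasks):
        cfg = SynthConfig(seed=1, renditions_per_day=30)
        truth = constant_truth(tasks["1"], 2,
                               pitch_override={"C": np.array([0.0, 2.0])})
        df = generate_rendition_stream(tasks["1"], truth, 2, cfg)
        med = daily_pitch_medians(df, ["C"], 600.0)
        assert med.loc[0] == pytest.approx(0.0, abs=0.15)
        assert med.loc[1] == pytest.approx(2.0, abs=0.15)


class TestSyntaxFractions:
    SPEC = SyntaxCorrection(frozenset({"C"}), "A", "B")  # task-1 rule for C/C+

    def test_all_source_order_scores_zero(self):
        df = _stream([["A", "B", "C", "A", "B", "C"]] * 3)
        syn = syntax_fractions(df, self.SPEC)
        assert syn.loc[0].tolist() == [0.0, 0.0, 0.0]

    def test_all_target_order_scores_one(self):
        df = _stream([["A", "C", "B", "A", "C", "B"]] * 3)
        syn = syntax_fractions(df, self.SPEC)
        assert syn.loc[0].tolist() == [1.0, 1.0, 1.0]

    def test_converging_only_gives_half(self):
        # C preceded by A (target) but followed by A (wrap of source-like
        # order ACA...): diverging fraction 0 -> overall 0.5
        df = _stream([["A", "C", "A", "C", "A", "C"]])
        syn = syntax_fractions(df, self.SPEC)
        assert syn.loc[0, "converging"] == 1.0
        assert syn.loc[0, "diverging"] == 0.0
        assert syn.loc[0, "overall"] == 0.5

    def test_day_without_focal_absent_not_zero(self):
        df = _stream([["A", "B", "A", "B"]], day=3)
        syn = syntax_fractions(df, self.SPEC)
        assert 3 not in syn.index

    def test_bout_edges_excluded_from_one_side_only(self):
        # single C at bout start: no predecessor -> converging undefined
        df = _stream([["C", "B"]])
        syn = syntax_fractions(df, self.SPEC)
        assert np.isnan(syn.loc[0, "converging"])
        assert syn.loc[0, "diverging"] == 1.0


class TestSyntaxShiftScale:
    def test_equals_correct_fraction_without_incorrect_set(self):
        spec = SyntaxCorrection(frozenset({"C"}), "A", "B")
        df = _stream([["A", "C", "B", "A", "C", "B"]])
        assert syntax_shift_scale(df, spec).loc[0] == \
            syntax_fractions(df, spec).loc[0, "overall"] == 1.0

    def test_endpoints(self, tasks):
        # task-3 rule for a bird whose B chose the out-of-context target B+
        spec = syntax_spec_for_task(tasks["3"], "B", "B+")
        assert spec.incorrect_set == frozenset({("A", "B"), ("B", "C")})
        all_incorrect = _stream([["A", "B", "C", "A", "B", "C"]])
        assert syntax_shift_scale(all_incorrect, spec).loc[0] == -1.0
        # target syntax for B+: preceded by C, followed by (wrap) A
        all_correct = _stream([["C", "B", "A", "C", "B", "A"]])
        assert syntax_shift_scale(all_correct, spec).loc[0] == 1.0

    def test_neutral_transitions_score_zero(self, tasks):
        spec = syntax_spec_for_task(tasks["3"], "B", "B+")
        neutral = _stream([["Z", "B", "Q", "Z", "B", "Q"]])
        assert syntax_shift_scale(neutral, spec).loc[0] == 0.0

    def test_overlapping_incorrect_set_rejected(self):
        with pytest.raises(ValueError):
            SyntaxCorrection(frozenset({"C"}), "A", "B",
                             incorrect_set=frozenset({("A", "C")}))

    def test_task1_has_no_incorrect_set(self, tasks):
        spec = syntax_spec_for_task(tasks["1"], "C", "C+")
        assert spec.converging_target == "A"
        assert spec.diverging_target == "B"
        assert spec.incorrect_set == frozenset()


class TestBinnedSeries:
    def test_forty_samples_three_windows(self):
        x = np.arange(40.0)
        out = binned_series(x, bin=30, overlap=25)
        assert len(out) == 3
        assert out[0] == np.median(x[:30])
        assert out[1] == np.median(x[5:35])

    def test_too_short_yields_nothing(self):
        assert binned_series(np.arange(29.0), 30, 25).size == 0

    def test_constant_series(self):
        out = binned_series(np.full(60, 7.0), 30, 25)
        assert (out == 7.0).all()

    def test_window_count_matches_closed_form_exhaustively(self):
        for n in range(0, 201):
            out = binned_series(np.zeros(n), 30, 25)
            expected = (n - 30) // 5 + 1 if n >= 30 else 0
            assert len(out) == expected, n

    def test_invalid_overlap_rejected(self):
        with pytest.raises(ValueError):
            binned_series(np.zeros(50), 30, 30)


class TestPitchVsSyntaxCurve:
    def test_summary_over_midwindow(self):
        pitch = np.array([0.1, 0.5, 0.52, 0.9])
        syntax = np.array([0.0, 0.2, 0.4, 1.0])
        _, s = pitch_vs_syntax_curve(pitch, syntax)
        assert s == pytest.approx(0.3)

    def test_absent_when_pitch_never_reaches_window(self):
        _, s = pitch_vs_syntax_curve(np.array([0.0, 0.2]), np.array([0.0, 0.0]))
        assert s is None

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            pitch_vs_syntax_curve(np.zeros(3), np.zeros(4))


class TestEndpointSummary:
    def test_matched_simulation_scores_one_one(self):
        pitch = {"C": 600.0 * 2 ** (2 / 12)}
        df = _stream([["A", "C", "B", "A", "C", "B"]] * 3, pitch=pitch)
        spec = SyntaxCorrection(frozenset({"C"}), "A", "B")
        out = endpoint_summary(df, ["C"], 600.0, 0.0, 2.0, spec=spec)
        assert out["pitch_correction"] == pytest.approx(1.0, abs=1e-6)
        assert out["syntax_correction"] == 1.0

    def test_frozen_at_source_scores_zero_zero(self):
        df = _stream([["A", "B", "C", "A", "B", "C"]] * 3,
                     pitch={"C": 600.0})
        spec = SyntaxCorrection(frozenset({"C"}), "A", "B")
        out = endpoint_summary(df, ["C"], 600.0, 0.0, 2.0, spec=spec)
        assert out["pitch_correction"] == pytest.approx(0.0, abs=1e-6)
        assert out["syntax_correction"] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            endpoint_summary(pd.DataFrame(), ["C"], 600.0, 0.0, 2.0)

    def test_recovers_programmed_endpoint(self, tasks):
        """Programmed endpoint (pitch 0.8, syntax 0.3) recovered within
        +-0.05 at 60 renditions/day."""
        task = tasks["1"]
        n_days = 3
        truth = constant_truth(task, n_days,
                               pitch_override={"C": np.full(n_days, 0.8 * 2.0)})
        # grammar: 30% target transitions around C, 70% source
        t = {"A": {"B": 0.7, "C": 0.3}, "B": {"C": 0.7, "A": 0.3},
             "C": {"A": 0.7, "B": 0.3}}
        truth.transitions = [t] * n_days
        cfg = SynthConfig(seed=21, renditions_per_day=60)
        df = generate_rendition_stream(task, truth, n_days, cfg)
        spec = syntax_spec_for_task(task, "C", "C+")
        out = endpoint_summary(df, ["C"], 600.0, 0.0, 2.0, spec=spec,
                               last_n_days=n_days)
        assert out["pitch_correction"] == pytest.approx(0.8, abs=0.05)
        assert out["syntax_correction"] == pytest.approx(0.3, abs=0.05)


class TestCohort:
    @pytest.mark.parametrize("count, n, pct", [
        (20, 26, 77), (4, 26, 15), (0, 10, 0), (1, 2, 50),
    ])
    def test_percentages(self, count, n, pct):
        flags = [True] * count + [False] * (n - count)
        assert cohort_percentages(flags) == (pct, count, n)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cohort_percentages([])

    @pytest.mark.parametrize("n, p", [(7, 0.0078125), (1, 0.5), (0, 1.0)])
    def test_null_call_probability(self, n, p):
        assert null_call_probability(n) == p

    def test_null_probability_printed_precision(self):
        assert round(null_call_probability(7), 3) == 0.008


class TestVacancyHistogram:
    def _endpoint(self):
        rows = []
        # focal B shifted +2, call at -2, other harmonic at +5 (outside both)
        for i, (lab, st, call) in enumerate(
                [("B", 2.0, False)] * 10 + [("call0", -2.0, True)] * 5
                + [("call1", 5.0, True)] * 4):
            rows.append({"day": 9, "bout_id": i, "position_in_bout": 0,
                         "label": lab, "onset_ms": 0.0, "offset_ms": 100.0,
                         "true_f0_hz": 600.0 * 2 ** (st / 12),
                         "is_call": call})
        return pd.DataFrame(rows)

    def test_masses_in_expected_bins(self):
        h = vacancy_histogram(self._endpoint(), ["B"], "call0", 600.0,
                              source_pitch=0.0, direction=+2.0)
        edges, focal = h["focal"]
        centers = (edges[:-1] + edges[1:]) / 2
        assert centers[np.argmax(focal)] == pytest.approx(2.0, abs=0.5)
        _, call = h["call"]
        assert centers[np.argmax(call)] == pytest.approx(-2.0, abs=0.5)
        _, other = h["other"]
        assert centers[np.argmax(other)] == pytest.approx(5.0, abs=0.5)

    def test_direction_flip_mirrors(self):
        up = vacancy_histogram(self._endpoint(), ["B"], "call0", 600.0, 0.0, +1)
        dn = vacancy_histogram(self._endpoint(), ["B"], "call0", 600.0, 0.0, -1)
        assert up["focal"][1].tolist() == dn["focal"][1][::-1].tolist()

    def test_no_call_empty_histogram(self):
        h = vacancy_histogram(self._endpoint(), ["B"], None, 600.0, 0.0, +1)
        assert h["call"][1].sum() == 0
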