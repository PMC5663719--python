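"""Simulated developmental trajectories and their qualitative signatures."""

import numpy as np
import pandas as pd
import pytest

from songchairs.learning_simulator import (SimParams, batch_simulate,
                                           lineage_target_bigrams, simulate)
from songchairs.trajectory_metrics import (binned_series, daily_pitch_medians,
                                           endpoint_summary,
                                           fraction_pitch_corrected,
                                           pitch_vs_syntax_curve,
                                           rendition_pitch_fraction,
                                           rendition_syntax_indicators,
                                           syntax_spec_for_task)


def _curve_summary(traj, task, focal, chosen):
    src = task.source.pitch_of(focal)
    tgt = task.target.pitch_of(chosen)
    spec = syntax_spec_for_task(task, focal, chosen)
    pf = rendition_pitch_fraction(traj.renditions, [focal], 600.0, src, tgt)
    si = rendition_syntax_indicators(traj.renditions, spec)
    n = min(len(pf), len(si))
    pb = binned_series(pf[:n], 30, 25)
    sb = binned_series(si[:n], 30, 25, stat="mean")
    m = min(len(pb), len(sb))
    _, summary = pitch_vs_syntax_curve(pb[:m], sb[:m])
    return summary


class TestSimulate:
    def test_task1_greedy_pitch_before_syntax(self, tasks):
        """The greedy learner reaches the target pitch while syntax is still
        mostly at source, and corrects syntax only afterwards."""
        params = SimParams(n_days=30, renditions_per_day=30, seed=3)
        traj = simulate(tasks["1"], "greedy", params)
        assert traj.mapping["C"] == "C+"
        med = daily_pitch_medians(traj.renditions, ["C"], 600.0)
        frac = fraction_pitch_corrected(med, 0.0, 2.0)
        assert frac.iloc[-1] > 0.9
        summary = _curve_summary(traj, tasks["1"], "C", "C+")
        assert summary is not None and summary < 0.2
        spec = syntax_spec_for_task(tasks["1"], "C", "C+")
        end = endpoint_summary(traj.renditions, ["C"], 600.0, 0.0, 2.0,
                               spec=spec)
        assert end["syntax_correction"] > 0.5  # syntax does rise later

    def test_task1_global_keeps_focal_pitch(self, tasks):
        params = SimParams(n_days=15, renditions_per_day=20, seed=5)
        traj = simulate(tasks["1"], "global", params)
        assert traj.mapping["C"] == "B"  # positional partner
        med = daily_pitch_medians(traj.renditions, ["C"], 600.0)
        assert abs(med.iloc[-1]) < 0.75  # no systematic shift toward +2

    def test_zero_pitch_rate_frozen_pitch(self, tasks):
        params = SimParams(n_days=15, renditions_per_day=20, seed=5,
                           pitch_rate=0.0, pitch_noise_sd=0.0)
        traj = simulate(tasks["1"], "greedy", params)
        end = endpoint_summary(traj.renditions, ["C"], 600.0, 0.0, 2.0)
        assert end["pitch_correction"] == pytest.approx(0.0, abs=0.1)

    def test_fixed_seed_identical_trajectories(self, tasks):
        params = SimParams(n_days=8, renditions_per_day=15, seed=77)
        a = simulate(tasks["3"], "greedy", params)
        b = simulate(tasks["3"], "greedy", params)
        assert a.mapping == b.mapping
        assert a.renditions.equals(b.renditions)
        assert a.renditions.to_csv() == b.renditions.to_csv()

    def test_locked_syntax_tracks_pitch(self, tasks):
        params = SimParams(n_days=30, renditions_per_day=30, seed=3,
                           syntax_mode="locked")
        traj = simulate(tasks["1"], "greedy", params)
        summary = _curve_summary(traj, tasks["1"], "C", "C+")
        assert summary == pytest.approx(0.5, abs=0.2)

    def test_task5_recruited_call_joins_motif(self, tasks):
        params = SimParams(n_days=25, renditions_per_day=30, seed=11)
        traj = simulate(tasks["5"], "greedy", params)
        assert set(traj.mapping.values()) == {"B+", "B-"}
        call = next(c for c in traj.mapping if c.startswith("call"))
        # after the recruitment lag the call's pitch approaches its target
        tgt = tasks["5"].target.pitch_of(traj.mapping[call])
        assert traj.truth.pitch[call][-1] == pytest.approx(tgt, abs=0.5)
        # and it is eventually performed inside bouts
        in_bouts = traj.renditions[(traj.renditions["label"] == call)
                                   & (~traj.renditions["is_call"])]
        assert len(in_bouts) > 0
        assert any(e["event"] == "recruit" for e in traj.events)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SimParams(p_transition_acquire=1.5)
        with pytest.raises(ValueError):
            SimParams(syntax_mode="sideways")


class TestLineageBigrams:
    def test_task1_greedy_lineage(self, tasks):
        got = lineage_target_bigrams(tasks["1"], {"C": "C+"})
        assert got == {("A", "C"), ("C", "B"), ("B", "A")}

    def test_unassigned_targets_keep_their_name(self, tasks):
        got = lineage_target_bigrams(tasks["3"], {"B": "B+"})
        # the vacant target B- stays under its own label
        assert {("A", "B-"), ("B-", "C")} <= got


class TestBatch:
    def test_single_bird_cohort_equals_bird(self, tasks):
        params = SimParams(n_days=6, renditions_per_day=10, seed=2)
        trajs, df = batch_simulate(tasks["1"], "greedy", 1, params)
        assert len(trajs) == 1
        assert df["pitch_correction"].mean() == df["pitch_correction"].iloc[0]

    def test_task3_equidistant_choice_unbiased(self, tasks):
        """Across 200 simulated birds each +-2 st target is chosen
        50% +- 7% of the time."""
        params = SimParams(n_days=4, seed=7)
        _, df = batch_simulate(tasks["3"], "greedy", 200, params,
                               emit_renditions=False)
        up = (df["chosen_target"] == "B+").mean()
        assert abs(up - 0.5) <= 0.07

    def test_task4_close_target_chosen(self, tasks):
        """Winner-take-all with 1 vs 2 semitone costs picks the close
        targets in >= 95% of birds (both task orientations)."""
        params = SimParams(n_days=4, seed=9)
        for tid, close in (("4.1", {"B": "B-1", "B+1": "B+2"}),
                           ("4.2", {"B+2": "B+1", "B-1": "B"})):
            _, df = batch_simulate(tasks[tid], "greedy", 100, params,
                                   emit_renditions=False)
            ok = df.pivot_table(index="bird", columns="syllable",
                                values="chosen_target", aggfunc="first")
            hit = (ok == pd.Series(close)).all(axis=1).mean()
            assert hit >= 0.95, tid

    def test_task5_both_targets_matched_by_focal_plus_call(self, tasks):
        """Every simulated bird matches both targets using exactly the focal
        syllable and one recruited call."""
        params = SimParams(n_days=25, renditions_per_day=15, seed=13)
        trajs, _ = batch_simulate(tasks["5"], "greedy", 10, params)
        for traj in trajs:
            assert set(traj.mapping.values()) == {"B+", "B-"}
            motors = set(traj.mapping.keys())
            assert "B" in motors and len(motors) == 2
            other = (motors - {"B"}).pop()
            assert other.startswith("call")
            for lab, tgt in traj.mapping.items():
                goal = tasks["5"].target.pitch_of(tgt)
                assert traj.truth.pitch[lab][-1] == pytest.approx(goal, abs=0.5)

    def test_invalid_cohort_size(self, tasks):
        with pytest.raises(ValueError):
            batch_simulate(tasks["1"], "greedy", 0, SimParams())
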