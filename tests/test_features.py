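import numpy as np
import pandas as pd
import pytest

from dyadarc import SimulationConfig, simulate_study
from dyadarc.features import (
    COMPOUND_LABELS,
    ClockMismatchError,
    attach_affect,
    classify_high_affect,
    compound_category,
    compress_win_streaks,
    timing_features,
)
from dyadarc.scoring import score_emotions

from conftest import make_trials


def scored_streams(study):
    return {pid: score_emotions(frames) for pid, frames in study.au_streams.items()}


class TestAttachAffect:
    @pytest.fixture(scope="class")
    @staticmethod
    def noiseless():
        cfg = SimulationConfig(
            n_couples=2, n_rounds=8, condition="break10", seed=21, au_noise_sd=0.0
        )
        study = simulate_study(cfg)
        affect = attach_affect(study.trials, scored_streams(study))
        return study, affect

    def test_noiseless_roundtrip_recovers_winner_negativity(self, noiseless):
        study, affect = noiseless
        truth = study.affect_truth.set_index(["couple_id", "round"])
        winners = affect[affect["role"] == "winner"].set_index(["couple_id", "round"])
        merged = winners.join(truth[["winner_neg_t1", "winner_neg_t2"]])
        assert np.allclose(merged["neg_T2"], merged["winner_neg_t2"], atol=1e-9)
        assert np.allclose(merged["neg_T1"], merged["winner_neg_t1"], atol=1e-9)

    def test_every_trial_yields_two_player_rows(self, noiseless):
        study, affect = noiseless
        assert len(affect) == 2 * len(study.trials)

    def test_video_dropout_marks_missing_not_zero(self):
        trials = make_trials(["A", "B"], [4, 5])
        emotions = {
            "A": pd.DataFrame({"timestamp": [20.0, 20.5], "positive": 1.0, "negative": 0.4}),
            "B": pd.DataFrame({"timestamp": [20.0, 20.5], "positive": 1.0, "negative": 0.4}),
        }
        affect = attach_affect(trials, emotions)
        # round 2 windows (~40 s) have no frames at all
        r2 = affect[affect["round"] == 2]
        assert r2["neg_T2"].isna().all()
        assert (r2["frames_T2"] == 0).all()

    def test_overlapping_t1_t2_windows_computed_independently(self):
        # immediate condition: selection 0.4 s after announcement
        trials = make_trials(["A"], [4])
        trials.loc[0, "t_blast_selected"] = trials.loc[0, "t_winner_announced"] + 0.4
        t1 = trials.loc[0, "t_winner_announced"]
        ts = np.array([t1 - 0.5, t1 + 0.2, t1 + 0.9, t1 + 1.3])
        emotions = {
            p: pd.DataFrame({"timestamp": ts, "positive": 0.0,
                             "negative": [0.0, 1.0, 2.0, 3.0]})
            for p in ("A", "B")
        }
        affect = attach_affect(trials, emotions).set_index("role")
        # T1 window [t1-1, t1+1] -> frames 0,1,2 ; T2 window [t1-0.6, t1+1.4] -> all 4
        assert affect.loc["winner", "neg_T1"] == pytest.approx(1.0)
        assert affect.loc["winner", "neg_T2"] == pytest.approx(1.5)

    def test_total_clock_mismatch_raises(self):
        trials = make_trials(["A", "B"], [4, 5])
        emotions = {
            "A": pd.DataFrame({"timestamp": [9000.0], "positive": 1.0, "negative": 0.0}),
            "B": pd.DataFrame({"timestamp": [9000.0], "positive": 1.0, "negative": 0.0}),
        }
        with pytest.raises(ClockMismatchError):
            attach_affect(trials, emotions)


class TestClassifyHighAffect:
    def test_threshold_oracle_single_outlier(self):
        # mean 0.2, sample SD sqrt(0.2) -> threshold ~0.6472
        res = classify_high_affect([0, 0, 0, 0, 1])
        assert res.threshold == pytest.approx(0.2 + np.sqrt(0.2), abs=1e-9)
        assert list(res.flags) == [False, False, False, False, True]

    def test_constant_series_flags_nothing(self):
        res = classify_high_affect([0.3] * 10)
        assert not res.flags.any()

    def test_strict_inequality_at_threshold(self):
        vals = [0.0, 1.0, 2.0]  # mean 1, sd 1 -> threshold 2, 2 is NOT flagged
        res = classify_high_affect(vals)
        assert res.threshold == pytest.approx(2.0)
        assert not res.flags.any()

    def test_missing_values_excluded_not_imputed(self):
        res = classify_high_affect([0.0, 0.0, 0.0, 0.0, 1.0, np.nan])
        assert res.flags.isna().iloc[5]
        assert res.threshold == pytest.approx(0.2 + np.sqrt(0.2), abs=1e-9)

    def test_order_invariance(self):
        vals = [0.1, 0.9, 0.2, 0.8, 0.3]
        a = classify_high_affect(vals)
        b = classify_high_affect(vals[::-1])
        assert a.threshold == pytest.approx(b.threshold)
        assert list(a.flags) == list(b.flags)[::-1]

    def test_per_group_scope(self):
        vals = [0, 0, 0, 0, 1, 10, 10, 10, 10, 20]
        groups = ["g1"] * 5 + ["g2"] * 5
        res = classify_high_affect(vals, groups=groups, scope="per_group")
        assert list(res.flags) == [False] * 4 + [True] + [False] * 4 + [True]

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            classify_high_affect([np.nan, np.nan])
        with pytest.raises(ValueError):
            classify_high_affect([0.5, np.nan])

    def test_simulator_defaults_flag_near_16_percent(self):
        cfg = SimulationConfig(n_couples=60, n_rounds=30, seed=13, emit_au=False)
        truth = simulate_study(cfg).affect_truth
        vals = pd.concat([truth["winner_neg_t2"], truth["loser_neg"]])
        frac = classify_high_affect(vals).fraction_flagged
        assert 0.08 < frac < 0.24  # calibration reference, not a sharp assertion


class TestCompressWinStreaks:
    def test_two_round_streak_means_blast(self):
        trials = make_trials(["A", "A"], [4, 6])
        comp = compress_win_streaks(trials)
        assert len(comp) == 1
        assert comp["mean_blast"].iloc[0] == pytest.approx(5.0)
        assert comp["n_rounds_in_streak"].iloc[0] == 2

    def test_alternating_winners_identity(self):
        winners = ["A", "B"] * 15
        blasts = [3, 5] * 15
        trials = make_trials(winners, blasts)
        comp = compress_win_streaks(trials)
        assert len(comp) == 30
        assert np.allclose(comp["mean_blast"], blasts)
        assert (comp["n_rounds_in_streak"] == 1).all()

    def test_hand_collapsed_oracle(self):
        trials = make_trials(["A", "A", "B", "A"], [2, 4, 7, 5])
        comp = compress_win_streaks(trials)
        assert list(comp["winner_id"]) == ["A", "B", "A"]
        assert list(comp["mean_blast"]) == [3.0, 7.0, 5.0]
        assert comp["n_rounds_in_streak"].sum() == 4

    def test_winners_alternate_in_output(self):
        cfg = SimulationConfig(n_couples=4, n_rounds=25, seed=6, emit_au=False)
        comp = compress_win_streaks(simulate_study(cfg).trials)
        for _, grp in comp.groupby("couple_id"):
            w = grp.sort_values("interval_index")["winner_id"].to_numpy()
            assert (w[1:] != w[:-1]).all()

    def test_weighted_grand_mean_conserved(self):
        rng = np.random.default_rng(5)
        winners = rng.choice(["A", "B"], size=40)
        blasts = rng.integers(1, 9, size=40)
        trials = make_trials(winners, blasts)
        comp = compress_win_streaks(trials)
        weighted = (comp["mean_blast"] * comp["n_rounds_in_streak"]).sum()
        assert weighted / comp["n_rounds_in_streak"].sum() == pytest.approx(blasts.mean())

    def test_affect_joined_and_averaged(self):
        trials = make_trials(["A", "A"], [4, 6])
        affect = pd.DataFrame(
            [
                {"couple_id": "c1", "round": 1, "role": "winner", "neg_T2": 0.2},
                {"couple_id": "c1", "round": 1, "role": "loser", "neg_T2": 0.6},
                {"couple_id": "c1", "round": 2, "role": "winner", "neg_T2": 0.4},
                {"couple_id": "c1", "round": 2, "role": "loser", "neg_T2": 0.8},
            ]
        )
        comp = compress_win_streaks(trials, affect)
        assert comp["mean_winner_neg"].iloc[0] == pytest.approx(0.3)
        assert comp["mean_loser_neg"].iloc[0] == pytest.approx(0.7)


class TestCompoundCategory:
    def affect_with_flags(self, flag_pairs):
        rows = []
        for i, (w, l) in enumerate(flag_pairs, start=1):
            rows.append({"couple_id": "c1", "round": i, "role": "winner", "high_neg": w})
            rows.append({"couple_id": "c1", "round": i, "role": "loser", "high_neg": l})
        df = pd.DataFrame(rows)
        df["high_neg"] = df["high_neg"].astype("boolean")
        return df

    def test_four_way_labels(self):
        labels = compound_category(
            self.affect_with_flags([(False, False), (False, True), (True, False), (True, True)])
        )
        assert list(labels) == ["neither", "loser_only", "winner_only", "both"]

    def test_enumeration_oracle_counts(self):
        pairs = [(False, False)] * 3 + [(False, True)] * 2 + [(True, False)] * 2 + [(True, True)]
        labels = compound_category(self.affect_with_flags(pairs))
        counts = labels.value_counts()
        assert (counts["neither"], counts["loser_only"], counts["winner_only"], counts["both"]) == (3, 2, 2, 1)

    def test_partition_sums_to_one(self):
        pairs = [(False, False), (True, True), (True, False), (False, True), (False, False)]
        labels = compound_category(self.affect_with_flags(pairs))
        props = labels.value_counts(normalize=True)
        assert props.sum() == pytest.approx(1.0)
        assert set(props.index) <= set(COMPOUND_LABELS)

    def test_missing_flag_excluded(self):
        affect = self.affect_with_flags([(True, True), (pd.NA, False)])
        labels = compound_category(affect)
        assert labels.iloc[0] == "both"
        assert pd.isna(labels.iloc[1])

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError):
            compound_category(pd.DataFrame({"couple_id": [], "round": [], "role": []}))


class TestTimingFeatures:
    def test_forced_break_arithmetic(self):
        trials = make_trials(["A"], [4], forced=10.0)
        trials.loc[0, "t_winner_announced"] = 100.0
        trials.loc[0, "t_blast_selected"] = 114.2
        out = timing_features(trials)
        assert out["elective_extra_s"].iloc[0] == pytest.approx(4.2)
        assert out["selection_latency_s"].iloc[0] == pytest.approx(14.2)

    def test_immediate_condition(self):
        trials = make_trials(["A"], [4])
        trials.loc[0, "t_blast_selected"] = trials.loc[0, "t_winner_announced"] + 1.8
        out = timing_features(trials)
        assert out["elective_extra_s"].iloc[0] == pytest.approx(1.8)

    def test_selection_exactly_at_break_end(self):
        trials = make_trials(["A"], [4], forced=5.0)
        trials.loc[0, "t_blast_selected"] = trials.loc[0, "t_winner_announced"] + 5.0
        out = timing_features(trials)
        assert out["elective_extra_s"].iloc[0] == pytest.approx(0.0)

    def test_negative_elective_extra_rejected(self):
        trials = make_trials(["A"], [4], forced=10.0)
        trials.loc[0, "t_blast_selected"] = trials.loc[0, "t_winner_announced"] + 3.0
        with pytest.raises(ValueError, match="c1#1"):
            timing_features(trials)
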