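import numpy as np
import pandas as pd
import pytest

from dyadarc import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A small full study with AU streams (forced break keeps T1/T2 apart)."""
    cfg = SimulationConfig(
        n_couples=4, n_rounds=20, condition="break10", seed=11, au_noise_sd=0.05
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def truth_affect_frame():
    """Helper turning a SimulatedStudy's ground truth into the long affect layout."""

    def _build(study) -> pd.DataFrame:
        rows = []
        for r in study.affect_truth.itertuples():
            rows.append(
                {
                    "couple_id": r.couple_id,
                    "round": r.round,
                    "player_id": r.winner_id,
                    "role": "winner",
                    "neg_T1": r.winner_neg_t1,
                    "neg_T2": r.winner_neg_t2,
                    "pos_T2": r.positive,
                    "frames_T1": 1,
                    "frames_T2": 1,
                }
            )
            rows.append(
                {
                    "couple_id": r.couple_id,
                    "round": r.round,
                    "player_id": r.loser_id,
                    "role": "loser",
                    "neg_T1": r.loser_neg,
                    "neg_T2": r.loser_neg,
                    "pos_T2": r.positive,
                    "frames_T1": 1,
                    "frames_T2": 1,
                }
            )
        return pd.DataFrame(rows)

    return _build


def make_trials(winners, blasts, couple_id="c1", condition="immediate",
                forced=0.0, round_gap=20.0):
    """Hand-built trial table with evenly spaced, well-ordered timestamps."""
    rows = []
    for i, (w, b) in enumerate(zip(winners, blasts), start=1):
        t_go = i * round_gap
        rows.append(
            {
                "couple_id": couple_id,
                "study": "test",
                "condition": condition,
                "round": i,
                "winner_id": w,
                "loser_id": "B" if w == "A" else "A",
                "rt_winner_ms": 280.0,
                "rt_loser_ms": 320.0,
                "blast": b,
                "t_go": t_go,
                "t_winner_announced": t_go + 0.3,
                "t_blast_selected": t_go + 0.3 + forced + 1.5,
                "forced_break_s": forced,
            }
        )
    return pd.DataFrame(rows)


def make_compressed(mean_blasts, couple_id="c1", winner_negs=None, loser_negs=None):
    """Hand-built alternating-winner compressed series."""
    n = len(mean_blasts)
    winner_negs = winner_negs if winner_negs is not None else [np.nan] * n
    loser_negs = loser_negs if loser_negs is not None else [np.nan] * n
    rows = []
    for i, mb in enumerate(mean_blasts, start=1):
        w = "A" if i % 2 == 1 else "B"
        rows.append(
            {
                "couple_id": couple_id,
                "interval_index": i,
                "winner_id": w,
                "loser_id": "B" if w == "A" else "A",
                "condition": "immediate",
                "mean_blast": float(mb),
                "mean_winner_neg": winner_negs[i - 1],
                "mean_loser_neg": loser_negs[i - 1],
                "n_rounds_in_streak": 1,
            }
        )
    return pd.DataFrame(rows)
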