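"""Trial-level features: windowed affect, high-affect flags, win-streak
compression, compounding categories and timing.

The trial-log schema is::

    couple_id, study, condition, round, winner_id, loser_id,
    rt_winner_ms, rt_loser_ms, blast, t_go, t_winner_announced,
    t_blast_selected, forced_break_s

with times in seconds on the session clock and 1-based round indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ClockMismatchError",
    "HighAffectResult",
    "attach_affect",
    "classify_high_affect",
    "compress_win_streaks",
    "compound_category",
    "timing_features",
]

COMPOUND_LABELS = ("neither", "loser_only", "winner_only", "both")


class ClockMismatchError(RuntimeError):
    """Raised when no trial window overlaps any emotion frame."""


def _window_means(ts: np.ndarray, pos_c: np.ndarray, neg_c: np.ndarray,
                  center: float, half_width: float) -> tuple[float, float, int]:
    """Windowed means via prefix sums over a sorted timestamp array."""
    lo = np.searchsorted(ts, center - half_width, side="left")
    hi = np.searchsorted(ts, center + half_width, side="right")
    n = int(hi - lo)
    if n == 0:
        return float("nan"), float("nan"), 0
    pos = (pos_c[hi] - pos_c[lo]) / n
    neg = (neg_c[hi] - neg_c[lo]) / n
    return float(pos), float(neg), n


def attach_affect(
    trials: pd.DataFrame,
    emotions: Mapping[str, pd.DataFrame],
    half_width: float = 1.0,
) -> pd.DataFrame:
    """Join trials with windowed affect for both players.

    ``emotions`` maps player id to a scored emotion table (output of
    :func:`dyadarc.scoring.score_emotions`).  For every trial and both
    players, the negative mean is computed in the winner-announcement
    window (T1) and the positive/negative means in the blast-selection
    window (T2), both ``+/- half_width`` s with closed endpoints.  The
    two windows may overlap (immediate condition); both are computed
    independently.  Empty windows yield NaN with a zero frame count --
    an explicit missing marker, never an imputed zero.

    Raises :class:`ClockMismatchError` if every window is empty, which
    indicates the trial and video clocks do not share an origin.
    """
    prepared: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for pid, emo in emotions.items():
        emo = emo.sort_values("timestamp")
        ts = emo["timestamp"].to_numpy(dtype=float)
        pos = np.concatenate([[0.0], np.cumsum(emo["positive"].to_numpy(dtype=float))])
        neg = np.concatenate([[0.0], np.cumsum(emo["negative"].to_numpy(dtype=float))])
        prepared[pid] = (ts, pos, neg)

    rows: list[dict] = []
    any_frames = False
    for trial in trials.itertuples(index=False):
        for role, pid in (("winner", trial.winner_id), ("loser", trial.loser_id)):
            if pid not in prepared:
                rows.append(
                    {
                        "couple_id": trial.couple_id,
                        "round": trial.round,
                        "player_id": pid,
                        "role": role,
                        "neg_T1": np.nan,
                        "neg_T2": np.nan,
                        "pos_T2": np.nan,
                        "frames_T1": 0,
                        "frames_T2": 0,
                    }
                )
                continue
            ts, pos_c, neg_c = prepared[pid]
            _, neg_t1, n1 = _window_means(
                ts, pos_c, neg_c, trial.t_winner_announced, half_width
            )
            pos_t2, neg_t2, n2 = _window_means(
                ts, pos_c, neg_c, trial.t_blast_selected, half_width
            )
            any_frames = any_frames or n1 > 0 or n2 > 0
            rows.append(
                {
                    "couple_id": trial.couple_id,
                    "round": trial.round,
                    "player_id": pid,
                    "role": role,
                    "neg_T1": neg_t1,
                    "neg_T2": neg_t2,
                    "pos_T2": pos_t2,
                    "frames_T1": n1,
                    "frames_T2": n2,
                }
            )
    if prepared and not any_frames:
        raise ClockMismatchError(
            "every affect window is empty; trial and video clocks appear misaligned"
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class HighAffectResult:
    """Flags plus the realized mean+1SD threshold(s)."""

    flags: pd.Series  # nullable boolean; pd.NA where the value is missing
    threshold: float | pd.Series

    @property
    def fraction_flagged(self) -> float:
        valid = self.flags.dropna()
        return float(valid.mean()) if len(valid) else float("nan")


def classify_high_affect(
    values, groups=None, scope: str = "pooled"
) -> HighAffectResult:
    """Flag values strictly greater than mean + 1 sample SD.

    ``scope="pooled"`` (default) estimates one threshold from all
    non-missing values; ``scope="per_group"`` estimates a threshold
    within each level of ``groups``.  Missing values are excluded from
    threshold estimation and receive a missing flag, never an imputed
    one.  With zero SD nothing is flagged.
    """
    vals = pd.Series(values, dtype=float).reset_index(drop=True)
    if vals.notna().sum() == 0:
        raise ValueError("all values are missing")
    if vals.notna().sum() < 2:
        raise ValueError("need >= 2 non-missing values to estimate a threshold")
    if scope == "pooled":
        thr = float(vals.mean() + vals.std(ddof=1))
        flags = pd.Series(
            np.where(vals.notna(), vals > thr, None), dtype="boolean"
        )
        return HighAffectResult(flags=flags, threshold=thr)
    if scope == "per_group":
        if groups is None:
            raise ValueError("scope='per_group' requires groups")
        grp = pd.Series(groups).reset_index(drop=True)
        thr_by = vals.groupby(grp).transform(lambda s: s.mean() + s.std(ddof=1))
        flags = pd.Series(
            np.where(vals.notna() & thr_by.notna(), vals > thr_by, None),
            dtype="boolean",
        )
        thresholds = vals.groupby(grp).agg(lambda s: s.mean() + s.std(ddof=1))
        return HighAffectResult(flags=flags, threshold=thresholds)
    raise ValueError("scope must be 'pooled' or 'per_group'")


def compress_win_streaks(
    trials: pd.DataFrame, affect: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Collapse maximal same-winner runs into alternating-winner intervals.

    Each interval carries the mean blast over the streak, the number of
    rounds collapsed, and -- when ``affect`` (long output of
    :func:`attach_affect`) is provided -- the mean winner and loser
    negativity (T2 window) over the streak.  Total rounds are conserved
    via ``n_rounds_in_streak``.
    """
    t = trials.sort_values(["couple_id", "round"]).reset_index(drop=True)
    if affect is not None:
        wide = affect.pivot(
            index=["couple_id", "round"], columns="role", values="neg_T2"
        ).rename(columns={"winner": "winner_neg", "loser": "loser_neg"}).reset_index()
        t = t.merge(wide, on=["couple_id", "round"], how="left")
    else:
        t["winner_neg"] = np.nan
        t["loser_neg"] = np.nan

    new_streak = (t["winner_id"] != t["winner_id"].shift()) | (
        t["couple_id"] != t["couple_id"].shift()
    )
    t["_streak"] = new_streak.cumsum()
    agg = (
        t.groupby(["couple_id", "_streak"], sort=True)
        .agg(
            winner_id=("winner_id", "first"),
            loser_id=("loser_id", "first"),
            condition=("condition", "first"),
            mean_blast=("blast", "mean"),
            mean_winner_neg=("winner_neg", "mean"),
            mean_loser_neg=("loser_neg", "mean"),
            n_rounds_in_streak=("round", "size"),
            first_round=("round", "min"),
        )
        .reset_index()
        .sort_values(["couple_id", "first_round"])
        .drop(columns=["_streak", "first_round"])
        .reset_index(drop=True)
    )
    agg["interval_index"] = agg.groupby("couple_id").cumcount() + 1
    cols = [
        "couple_id", "interval_index", "winner_id", "loser_id", "condition",
        "mean_blast", "mean_winner_neg", "mean_loser_neg", "n_rounds_in_streak",
    ]
    return agg[cols]


def compound_category(affect: pd.DataFrame) -> pd.Series:
    """Four-way compounding label per trial from both players' flags.

    ``affect`` is the long table from :func:`attach_affect` augmented
    with a nullable-boolean ``high_neg`` column.  Trials with a missing
    flag for either player are excluded (NaN label) with a log entry.
    The partition over defined trials is exhaustive and exclusive:
    ``neither | loser_only | winner_only | both``.
    """
    if "high_neg" not in affect.columns:
        raise ValueError("affect table must carry a 'high_neg' column")
    wide = affect.pivot(index=["couple_id", "round"], columns="role", values="high_neg")
    if "winner" not in wide.columns or "loser" not in wide.columns:
        raise ValueError("affect table must contain winner and loser rows")
    w = wide["winner"].astype("boolean")
    lo = wide["loser"].astype("boolean")
    defined = w.notna() & lo.notna()
    n_excluded = int((~defined).sum())
    if n_excluded:
        logger.info("compound_category: excluded %d trial(s) with missing flags", n_excluded)
    out = pd.Series(pd.NA, index=wide.index, dtype="object", name="compound")
    out[defined & ~w.fillna(False) & ~lo.fillna(False)] = "neither"
    out[defined & ~w.fillna(False) & lo.fillna(False)] = "loser_only"
    out[defined & w.fillna(False) & ~lo.fillna(False)] = "winner_only"
    out[defined & w.fillna(False) & lo.fillna(False)] = "both"
    return out


def timing_features(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-trial elective extra time and selection latency (seconds).

    ``elective_extra_s = t_blast_selected - t_winner_announced -
    forced_break_s`` and ``selection_latency_s = t_blast_selected -
    t_winner_announced``.  A negative elective extra indicates an
    impossible selection before the break ended and raises.
    """
    latency = trials["t_blast_selected"] - trials["t_winner_announced"]
    elective = latency - trials["forced_break_s"]
    if (elective < -1e-9).any():
        bad = trials.loc[elective < -1e-9, ["couple_id", "round"]]
        raise ValueError(
            "blast selected before the forced break ended for trials: "
            + ", ".join(f"{r.couple_id}#{r.round}" for r in bad.itertuples())
        )
    out = trials[["couple_id", "round"]].copy()
    out["elective_extra_s"] = elective.clip(lower=0.0).to_numpy()
    out["selection_latency_s"] = latency.to_numpy()
    return out
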