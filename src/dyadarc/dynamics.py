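"""Escalation/retaliation structure of the compressed blast series.

All operations consume the alternating-winner, streak-compressed series
produced by :func:`dyadarc.features.compress_win_streaks`.  The
escalation coefficient for an interval is the acting player's mean
blast minus the partner's previous mean blast, bounded in [-7, 7] on
the 1-8 blast grid; positive coefficients are escalation, negative
de-escalation and zero an exact match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "MatchingStatistics",
    "couple_asymmetry",
    "escalation_records",
    "escalation_summary",
    "matching_statistics",
]


def _classify(coef: np.ndarray, tolerance: float) -> np.ndarray:
    out = np.where(np.abs(coef) <= tolerance, "match",
                   np.where(coef > 0, "escalate", "de_escalate"))
    return out


def escalation_records(
    compressed: pd.DataFrame, match_tolerance: float = 0.0
) -> pd.DataFrame:
    """Per-interval escalation records from the compressed series.

    One record per interval from the second onward (the first has no
    predecessor).  Streak means may be non-integer, so "match" means
    exact equality by default; ``match_tolerance`` widens it to
    ``|coef| <= tolerance`` for the reading that treats near-equal
    means as matches.
    """
    if match_tolerance < 0:
        raise ValueError("match_tolerance must be >= 0")
    comp = compressed.sort_values(["couple_id", "interval_index"]).reset_index(drop=True)
    rows = []
    for couple_id, grp in comp.groupby("couple_id", sort=True):
        if len(grp) < 2:
            logger.info("escalation_records: couple %s has < 2 intervals; skipped", couple_id)
            continue
        blast = grp["mean_blast"].to_numpy(dtype=float)
        coef = blast[1:] - blast[:-1]
        for idx, actor, c in zip(
            grp["interval_index"].to_numpy()[1:], grp["winner_id"].to_numpy()[1:], coef
        ):
            rows.append(
                {
                    "couple_id": couple_id,
                    "interval_index": int(idx),
                    "player_id": actor,
                    "coefficient": float(c),
                }
            )
    if not rows:
        raise ValueError("compressed series too short: no interval has a predecessor")
    records = pd.DataFrame(rows)
    records["class"] = _classify(records["coefficient"].to_numpy(), match_tolerance)
    return records


def escalation_summary(records: pd.DataFrame, by: str | None = None) -> pd.DataFrame:
    """Match/escalate/de-escalate proportions and mean coefficient.

    ``by`` groups the summary (e.g. ``"player_id"`` or ``"couple_id"``);
    by default one pooled row is returned.  Proportions sum to 1.
    """
    if len(records) == 0:
        raise ValueError("no escalation records")

    def _one(grp: pd.DataFrame) -> pd.Series:
        n = len(grp)
        cls = grp["class"]
        return pd.Series(
            {
                "prop_match": float((cls == "match").sum() / n),
                "prop_escalate": float((cls == "escalate").sum() / n),
                "prop_de_escalate": float((cls == "de_escalate").sum() / n),
                "mean_coefficient": float(grp["coefficient"].mean()),
                "n_records": n,
            }
        )

    if by is None:
        return _one(records).to_frame().T
    grouped = records.groupby(by, sort=True)[["class", "coefficient"]].apply(_one)
    return grouped.reset_index()


def couple_asymmetry(records: pd.DataFrame) -> pd.DataFrame:
    """Order partners' mean escalation coefficients within each couple.

    Returns one row per couple with the higher- and lower-escalation
    partner's mean coefficient (ties broken by player id order).
    Couples where a partner has no records are excluded with a log
    entry.  The two returned columns form the series whose correlation
    indexes within-couple escalation asymmetry.
    """
    means = (
        records.groupby(["couple_id", "player_id"], sort=True)["coefficient"]
        .mean()
        .reset_index()
    )
    rows = []
    for couple_id, grp in means.groupby("couple_id", sort=True):
        if len(grp) != 2:
            logger.info(
                "couple_asymmetry: couple %s lacks records for both partners; excluded",
                couple_id,
            )
            continue
        grp = grp.sort_values(["coefficient", "player_id"], ascending=[False, True])
        hi, lo = grp.iloc[0], grp.iloc[1]
        rows.append(
            {
                "couple_id": couple_id,
                "higher_id": hi["player_id"],
                "lower_id": lo["player_id"],
                "higher_mean": float(hi["coefficient"]),
                "lower_mean": float(lo["coefficient"]),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class MatchingStatistics:
    """Matching correlations and the escalation-over-time slope."""

    grand_pairs: pd.DataFrame     # one row per participant: own/partner grand mean
    grand_r: float
    grand_p: float
    lagged_pairs: pd.DataFrame    # (previous partner mean blast, own mean blast)
    lagged_r: float
    lagged_p: float
    time_slope: float             # least-squares slope of blast on interval index
    time_slope_se: float
    time_slope_p: float
    degenerate: bool              # True when a correlation was undefined


def matching_statistics(
    compressed: pd.DataFrame, trials: pd.DataFrame
) -> MatchingStatistics:
    """Grand-mean and lagged matching correlations plus the time trend.

    (i) each participant's grand mean blast (over rounds they won) is
    paired with their partner's -- both partners contribute a point --
    and a Pearson correlation is taken across participants; (ii)
    compressed-interval pairs (partner's previous mean blast, own mean
    blast) are pooled and correlated; (iii) the least-squares slope of
    mean blast on interval index tests escalation over time.
    Degenerate variance leaves the affected correlation NaN and sets
    ``degenerate``.
    """
    grand = (
        trials.groupby(["couple_id", "winner_id"], sort=True)["blast"]
        .mean()
        .reset_index()
        .rename(columns={"winner_id": "player_id", "blast": "own_mean"})
    )
    n_per_couple = grand.groupby("couple_id")["player_id"].transform("size")
    grand = grand[n_per_couple == 2].reset_index(drop=True)
    if grand["couple_id"].nunique() < 3:
        raise ValueError("need >= 3 couples with both partners winning at least once")
    partner_mean = (
        grand.groupby("couple_id")["own_mean"].transform("sum") - grand["own_mean"]
    )
    grand["partner_mean"] = partner_mean

    degenerate = False
    if grand["own_mean"].std() == 0 or grand["partner_mean"].std() == 0:
        grand_r, grand_p = float("nan"), float("nan")
        degenerate = True
    else:
        grand_r, grand_p = sps.pearsonr(grand["own_mean"], grand["partner_mean"])

    comp = compressed.sort_values(["couple_id", "interval_index"]).reset_index(drop=True)
    prev = comp.groupby("couple_id")["mean_blast"].shift(1)
    lagged = pd.DataFrame(
        {
            "couple_id": comp["couple_id"],
            "interval_index": comp["interval_index"],
            "partner_prev": prev,
            "own": comp["mean_blast"],
        }
    ).dropna(subset=["partner_prev"]).reset_index(drop=True)
    if len(lagged) < 3 or lagged["partner_prev"].std() == 0 or lagged["own"].std() == 0:
        lagged_r, lagged_p = float("nan"), float("nan")
        degenerate = True
    else:
        lagged_r, lagged_p = sps.pearsonr(lagged["partner_prev"], lagged["own"])

    # least-squares slope; SE is couple-clustered (series are
    # autocorrelated within couples, plain OLS SEs are anti-conservative)
    xs = comp["interval_index"].to_numpy(dtype=float)
    ys = comp["mean_blast"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(xs), xs])
    ols = sm.OLS(ys, X).fit(
        cov_type="cluster", cov_kwds={"groups": comp["couple_id"].to_numpy()}
    )
    return MatchingStatistics(
        grand_pairs=grand,
        grand_r=float(grand_r),
        grand_p=float(grand_p),
        lagged_pairs=lagged,
        lagged_r=float(lagged_r),
        lagged_p=float(lagged_p),
        time_slope=float(ols.params[1]),
        time_slope_se=float(ols.bse[1]),
        time_slope_p=float(ols.pvalues[1]),
        degenerate=degenerate,
    )
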