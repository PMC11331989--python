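"""Pipeline orchestration and study-level summaries.

``run_pipeline`` wires the stages together (scoring -> affect joins ->
classification -> compression -> dynamics -> models) with per-stage
error context and a run log; ``summarize_study`` condenses the
intermediates into one summary-table analogue with the headline
compounding contrast.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from dyadarc import dynamics as dyn
from dyadarc import features as feat
from dyadarc import models as mdl
from dyadarc import scoring

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "percent_change", "run_pipeline", "summarize_study"]

FORCED_CONDITIONS = ("break5", "break10", "break15")


def percent_change(value: float, reference: float) -> float:
    """Percent change of ``value`` relative to ``reference``.

    Returns ``100 * (value - reference) / reference``; NaN when the
    reference is zero or either input is missing (undefined contrast,
    flagged rather than fabricated).
    """
    if reference == 0 or not np.isfinite(value) or not np.isfinite(reference):
        return float("nan")
    return 100.0 * (value - reference) / reference


@dataclass
class PipelineResult:
    summary: dict
    intermediates: Mapping[str, pd.DataFrame]
    log: list[str] = field(default_factory=list)


class StageError(RuntimeError):
    """Wraps a stage failure with the stage name."""


def _stage(name: str, fn, log: list[str], *args, **kwargs):
    try:
        out = fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - reported with stage context
        raise StageError(f"stage '{name}' failed: {exc}") from exc
    log.append(f"stage '{name}' ok")
    return out


def run_pipeline(
    trials: pd.DataFrame,
    au_streams: Mapping[str, pd.DataFrame] | None = None,
    rules: scoring.AUCombinationRules = scoring.DEFAULT_RULES,
    seed: int = 0,
    n_boot: int = 1000,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis on a trial log and optional AU streams.

    Without AU streams the affect-dependent stages are skipped with a
    warning and the dynamics stages still run.  Deterministic given
    inputs and ``seed``; when ``out_dir`` is given every intermediate
    table is persisted as CSV together with a JSON run log.
    """
    if trials is None or len(trials) == 0:
        raise ValueError("empty trial table")
    from dyadarc import __version__ as _version  # deferred: avoids import cycle

    # canonical row order makes summaries exactly invariant to input order
    trials = trials.sort_values(["couple_id", "round"]).reset_index(drop=True)
    log: list[str] = [f"dyadarc {_version}", f"seed={seed}", f"n_trials={len(trials)}"]
    intermediates: dict[str, pd.DataFrame] = {"trials": trials}

    affect = None
    if au_streams:
        emotions = {
            pid: _stage(f"score[{pid}]", scoring.score_emotions, log, frames, rules)
            for pid, frames in au_streams.items()
        }
        affect = _stage("attach_affect", feat.attach_affect, log, trials, emotions)
        neg = _stage(
            "classify_high_negative", feat.classify_high_affect, log, affect["neg_T2"]
        )
        pos = _stage(
            "classify_high_positive", feat.classify_high_affect, log, affect["pos_T2"]
        )
        affect = affect.copy()
        affect["high_neg"] = neg.flags
        # high positive additionally requires low negative
        affect["high_pos"] = pos.flags & ~neg.flags.fillna(True)
        log.append(f"neg_threshold={neg.threshold:.6g}")
        log.append(f"pos_threshold={pos.threshold:.6g}")
        intermediates["affect"] = affect
    else:
        logger.warning("no AU streams supplied; affect stages skipped")
        log.append("affect stages skipped (no AU streams)")

    compressed = _stage("compress_win_streaks", feat.compress_win_streaks, log,
                        trials, affect)
    intermediates["compressed"] = compressed
    records = _stage("escalation_records", dyn.escalation_records, log, compressed)
    intermediates["escalation_records"] = records
    intermediates["escalation_summary"] = _stage(
        "escalation_summary", dyn.escalation_summary, log, records
    )
    intermediates["couple_asymmetry"] = _stage(
        "couple_asymmetry", dyn.couple_asymmetry, log, records
    )
    matching = _stage("matching_statistics", dyn.matching_statistics, log,
                      compressed, trials)
    intermediates["matching"] = pd.DataFrame(
        [
            {
                "grand_r": matching.grand_r,
                "grand_p": matching.grand_p,
                "lagged_r": matching.lagged_r,
                "lagged_p": matching.lagged_p,
                "time_slope": matching.time_slope,
                "time_slope_se": matching.time_slope_se,
                "time_slope_p": matching.time_slope_p,
            }
        ]
    )
    intermediates["timing"] = _stage("timing_features", feat.timing_features, log, trials)

    if affect is not None:
        compound = _stage("compound_category", feat.compound_category, log, affect)
        intermediates["compound"] = compound.reset_index().rename(
            columns={0: "compound"}
        )
        if affect["neg_T2"].notna().sum() >= 10:
            med_data = _mediation_frame(trials, affect)
            if med_data["exposure"].nunique() == 2:
                mediation = _stage(
                    "fit_mediation", mdl.fit_mediation, log, med_data,
                    n_boot, seed,
                )
                intermediates["mediation"] = pd.DataFrame(
                    [
                        {
                            "c": mediation.c,
                            "a": mediation.a,
                            "b": mediation.b,
                            "c_prime": mediation.c_prime,
                            "indirect": mediation.indirect,
                            "indirect_ci_low": mediation.indirect_ci[0],
                            "indirect_ci_high": mediation.indirect_ci[1],
                        }
                    ]
                )
            else:
                log.append("mediation skipped (single exposure level)")

    summary = summarize_study(intermediates)
    result = PipelineResult(summary=summary, intermediates=intermediates, log=log)
    if out_dir is not None:
        _persist(result, Path(out_dir))
    return result


def _mediation_frame(trials: pd.DataFrame, affect: pd.DataFrame) -> pd.DataFrame:
    winner = affect[affect["role"] == "winner"][["couple_id", "round", "neg_T2"]]
    d = trials.merge(winner, on=["couple_id", "round"], how="left")
    return pd.DataFrame(
        {
            "couple_id": d["couple_id"],
            "exposure": (d["forced_break_s"] > 0).astype(int),
            "mediator": d["neg_T2"],
            "outcome": d["blast"].astype(float),
        }
    )


def _mean_sd(series: pd.Series) -> tuple[float, float]:
    s = pd.Series(series).dropna()
    if len(s) == 0:
        return float("nan"), float("nan")
    return float(s.mean()), float(s.std(ddof=1)) if len(s) > 1 else float("nan")


def summarize_study(intermediates: Mapping[str, pd.DataFrame]) -> dict:
    """Condense pipeline intermediates into a study summary.

    Reports blast mean/SD overall, per condition and pooled across
    forced breaks; positive/negative affect mean/SD; winner T1/T2
    negativity in immediate vs forced-break trials; the proportion of
    high-negative trials; escalation proportions; matching
    correlations; per-compound-category blast means and the headline
    percent-change contrast (both vs neither).  Cells whose inputs are
    absent are explicitly NaN, never silently dropped.
    """
    trials = intermediates["trials"]
    summary: dict = {}

    m, sd = _mean_sd(trials["blast"])
    summary["blast_mean"], summary["blast_sd"] = m, sd
    by_cond = {}
    for cond, grp in trials.groupby("condition"):
        cm, csd = _mean_sd(grp["blast"])
        by_cond[cond] = {"mean": cm, "sd": csd, "n": len(grp)}
    summary["blast_by_condition"] = by_cond
    pooled_break = trials[trials["condition"].isin(FORCED_CONDITIONS)]
    bm, bsd = _mean_sd(pooled_break["blast"])
    summary["blast_forced_break"] = {"mean": bm, "sd": bsd, "n": len(pooled_break)}

    affect = intermediates.get("affect")
    if affect is not None:
        pm, psd = _mean_sd(affect["pos_T2"])
        nm, nsd = _mean_sd(affect["neg_T2"])
        summary["positive_affect"] = {"mean": pm, "sd": psd}
        summary["negative_affect"] = {"mean": nm, "sd": nsd}
        flags = affect["high_neg"].dropna()
        summary["prop_high_negative"] = (
            float(flags.mean()) if len(flags) else float("nan")
        )
        winner = affect[affect["role"] == "winner"].merge(
            trials[["couple_id", "round", "condition"]], on=["couple_id", "round"]
        )
        t1t2 = {}
        for label, mask in (
            ("immediate", winner["condition"] == "immediate"),
            ("forced_break", winner["condition"].isin(FORCED_CONDITIONS)),
        ):
            sub = winner[mask]
            t1t2[label] = {
                "neg_T1_mean": float(sub["neg_T1"].mean()) if len(sub) else float("nan"),
                "neg_T2_mean": float(sub["neg_T2"].mean()) if len(sub) else float("nan"),
            }
        summary["winner_negativity"] = t1t2

    compound = intermediates.get("compound")
    if compound is not None and affect is not None:
        comp = compound.set_index(["couple_id", "round"])["compound"]
        blast = trials.set_index(["couple_id", "round"])["blast"]
        cat_stats = {}
        for label in feat.COMPOUND_LABELS:
            sel = blast[comp[comp == label].index.intersection(blast.index)]
            cm, csd = _mean_sd(sel)
            cat_stats[label] = {"mean": cm, "sd": csd, "n": len(sel)}
        summary["blast_by_compound"] = cat_stats
        summary["compound_percent_change"] = percent_change(
            cat_stats["both"]["mean"], cat_stats["neither"]["mean"]
        )

    esc = intermediates.get("escalation_summary")
    if esc is not None and len(esc):
        row = esc.iloc[0]
        summary["escalation"] = {
            "prop_match": float(row["prop_match"]),
            "prop_escalate": float(row["prop_escalate"]),
            "prop_de_escalate": float(row["prop_de_escalate"]),
            "mean_coefficient": float(row["mean_coefficient"]),
        }
    matching = intermediates.get("matching")
    if matching is not None and len(matching):
        row = matching.iloc[0]
        summary["matching"] = {
            "grand_r": float(row["grand_r"]),
            "lagged_r": float(row["lagged_r"]),
            "time_slope": float(row["time_slope"]),
        }
    return summary


def _persist(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, table in result.intermediates.items():
        table.to_csv(out_dir / f"{name}.csv", index=False)
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, default=_json_default)
    with open(out_dir / "run_log.txt", "w") as fh:
        fh.write("\n".join(result.log) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    raise TypeError(f"not JSON serializable: {type(obj)}")
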