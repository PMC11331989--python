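"""Generative simulator of dyadic competitive reaction-time sessions.

Produces trial logs and per-player facial action-unit (AU) intensity
streams with the statistical structure the downstream analysis assumes:
rigged win/loss mechanics, 1-8 blast selections with matching and
per-player escalation asymmetry, negativity with actor/partner
carry-over, exponential decay of negativity across forced and elective
breaks, and AU emission consistent with the default emotion-scoring
rules.  The generating parameters are returned alongside the data so
that inferential modules can assert parameter recovery.

All randomness flows through a single :class:`numpy.random.Generator`
seeded from the config, so identical configs reproduce identical
studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "FORCED_BREAK_S",
    "DEFAULT_CONDITION_WEIGHTS",
    "POSITIVE_AUS",
    "NEGATIVE_AUS",
    "AU_CODES",
    "SimulationConfig",
    "SimulatedStudy",
    "rig_winner",
    "decay_negativity",
    "simulate_study",
    "emit_au_frames",
]

#: Recognised break conditions and the forced delay (s) each imposes
#: between winner announcement and blast selection.
CONDITIONS = ("immediate", "break5", "break10", "break15")
FORCED_BREAK_S: Mapping[str, float] = {
    "immediate": 0.0,
    "break5": 5.0,
    "break10": 10.0,
    "break15": 15.0,
}

#: Default couple allocation weights across conditions (23/32/23/26).
DEFAULT_CONDITION_WEIGHTS: Mapping[str, float] = {
    "immediate": 23.0,
    "break5": 32.0,
    "break10": 23.0,
    "break15": 26.0,
}

#: AU channels that carry the positive (happiness) signal and the
#: negative (anger/disgust) signal respectively.
POSITIVE_AUS = (6, 12)
NEGATIVE_AUS = (4, 9, 23)

#: Full set of intensity channels emitted (the automated-FACS dialect);
#: channels outside POSITIVE_AUS/NEGATIVE_AUS carry pure noise so that
#: readers are exercised against irrelevant columns.
AU_CODES = (1, 2, 4, 5, 6, 7, 9, 10, 12, 14, 15, 17, 20, 23, 25, 26, 45)

# decay_rate default is calibrated so mean negativity falls from 0.48
# to 0.15 over a 10 s forced break: lambda = ln(0.48/0.15)/10.
_DEFAULT_DECAY = math.log(0.48 / 0.15) / 10.0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a simulated dyadic study.

    Intensities live on the 0-5 scale and blasts on the 1-8 grid; both
    are clipped after the linear-Gaussian dynamics are applied.
    """

    n_couples: int = 10
    n_rounds: int = 30
    #: Either a single condition label applied to every couple, or None
    #: to sample conditions using ``condition_weights``.
    condition: str | None = None
    condition_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_WEIGHTS)
    )
    #: Log-scale reaction-time parameters (ms): rt ~ LogNormal.
    rt_location: float = math.log(300.0)
    rt_scale: float = 0.15
    rig_window: float = 100.0
    #: Negativity carry-over (per compressed interval).
    actor_effect: float = 0.29
    partner_effect: float = 0.15
    neg_baseline: float = 0.15
    neg_noise_sd: float = 0.15
    #: Between-couple SD of the negativity baseline (couple-level
    #: random intercept of the carry-over process).
    couple_neg_sd: float = 0.1
    pos_baseline: float = 0.83
    #: Per-second exponential decay of the winner's negativity across
    #: the forced break plus any elective extra time.
    decay_rate: float = _DEFAULT_DECAY
    #: Blast-selection weights.
    blast_baseline: float = 2.0
    match_weight: float = 0.44
    own_neg_weight: float = 1.26
    partner_neg_weight: float = 0.5
    asymmetry_sd: float = 0.5
    blast_noise_sd: float = 1.2
    #: Mean of the exponential elective-extra-time distribution (s).
    elective_extra_rate: float = 2.0
    fps: int = 30
    #: Emission noise SD on AU channels.
    au_noise_sd: float = 0.1
    #: Unrecorded warm-up rounds per session so the negativity and
    #: blast-matching chains start at their stationary distributions
    #: (the recorded series then carries no built-in time trend).
    burn_in: int = 10
    #: Whether to emit per-player AU streams (heavy for large studies).
    emit_au: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_couples < 1:
            raise ValueError("n_couples must be >= 1")
        if self.n_rounds < 2:
            raise ValueError("n_rounds must be >= 2 (no lagged structure possible)")
        if self.rig_window < 0:
            raise ValueError("rig_window must be >= 0")
        if self.decay_rate < 0:
            raise ValueError("decay_rate must be >= 0")
        if self.fps < 1:
            raise ValueError("fps must be >= 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.condition is not None and self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        for name in self.condition_weights:
            if name not in CONDITIONS:
                raise ValueError(f"unknown condition in weights: {name!r}")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class SimulatedStudy:
    """A simulated study plus the ground truth that generated it.

    ``trials`` follows the trial-log CSV schema; ``au_streams`` maps
    player id to an AU-intensity table in the automated-FACS dialect;
    ``affect_truth`` holds the latent per-round emotion intensities
    (winner T1/T2 negativity, loser negativity, positive level) used by
    parameter-recovery tests; ``truth`` is the generating config.
    """

    trials: pd.DataFrame
    au_streams: Mapping[str, pd.DataFrame]
    affect_truth: pd.DataFrame
    truth: SimulationConfig


def rig_winner(
    rt_a: float, rt_b: float, rig_window: float, rng: np.random.Generator
) -> str:
    """Decide the round winner under partial rigging.

    If the reaction times differ by more than ``rig_window`` ms the
    faster player wins deterministically; otherwise the winner is drawn
    uniformly at random.  Returns ``"a"`` or ``"b"``.
    """
    if rt_a <= 0 or rt_b <= 0:
        raise ValueError("reaction times must be positive")
    if rig_window < 0:
        raise ValueError("rig_window must be >= 0")
    if abs(rt_a - rt_b) > rig_window:
        return "a" if rt_a < rt_b else "b"
    return "a" if rng.random() < 0.5 else "b"


def decay_negativity(neg_t1: float, elapsed: float, decay_rate: float) -> float:
    """Exponential decay of a negativity intensity over ``elapsed`` seconds.

    Returns ``neg_t1 * exp(-decay_rate * elapsed)``: the identity at
    zero delay, monotone non-increasing in ``elapsed`` for positive
    rates, and with 0 as a fixed point.
    """
    neg = np.asarray(neg_t1, dtype=float)
    if np.any(neg < 0) or np.any(neg > 5):
        raise ValueError("neg_t1 must lie in [0, 5]")
    if np.any(np.asarray(elapsed) < 0):
        raise ValueError("elapsed must be >= 0")
    if decay_rate < 0:
        raise ValueError("decay_rate must be >= 0")
    out = neg * np.exp(-decay_rate * np.asarray(elapsed, dtype=float))
    return float(out) if np.isscalar(neg_t1) or np.ndim(neg_t1) == 0 else out


def _clip_intensity(x: float) -> float:
    return float(min(5.0, max(0.0, x)))


def _clip_blast(x: float) -> int:
    return int(min(8, max(1, round(x))))


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Simulate a full dyadic study under ``config``.

    Per round: reaction times are drawn, the winner is decided by
    :func:`rig_winner`, negativity carries over linearly from the
    previous compressed interval (actor + partner terms, Gaussian
    noise, clipped to [0, 5]) and decays exponentially over the forced
    break plus elective extra time before the winner's blast selection;
    the blast is a round-then-clip linear function of the partner's
    previous blast, both players' negativity, a per-player asymmetry
    offset, and noise.

    Negativity is updated at win-streak boundaries and held constant
    within a streak, so the streak-compressed series downstream carries
    the generating values exactly.
    """
    rng = np.random.default_rng(config.seed)
    cond_names = list(config.condition_weights)
    cond_p = np.array([config.condition_weights[c] for c in cond_names], dtype=float)
    cond_p = cond_p / cond_p.sum()

    trial_rows: list[dict] = []
    truth_rows: list[dict] = []
    au_streams: dict[str, pd.DataFrame] = {}

    # the carry-over process starts at its own long-run mean (falls
    # back to the baseline when a+p >= 1)
    carry = config.actor_effect + config.partner_effect

    for c in range(config.n_couples):
        couple_id = f"c{c + 1:03d}"
        players = (f"{couple_id}_p1", f"{couple_id}_p2")
        condition = (
            config.condition
            if config.condition is not None
            else cond_names[rng.choice(len(cond_names), p=cond_p)]
        )
        forced = FORCED_BREAK_S[condition]
        asym = {p: rng.normal(0.0, config.asymmetry_sd) for p in players}
        couple_beta0 = config.neg_baseline + rng.normal(0.0, config.couple_neg_sd)
        neg_start = couple_beta0 / (1.0 - carry) if carry < 1.0 else couple_beta0
        neg = {p: _clip_intensity(neg_start) for p in players}
        # start the matching process at its stationary blast level so the
        # simulated series carries no built-in time trend
        forced0 = FORCED_BREAK_S[condition]
        neg_t2_mu = _clip_intensity(neg_start) * math.exp(
            -config.decay_rate * (forced0 + config.elective_extra_rate)
        )
        drive = (
            config.blast_baseline
            + config.own_neg_weight * neg_t2_mu
            + config.partner_neg_weight * _clip_intensity(neg_start)
        )
        if config.match_weight < 1.0:
            blast0 = drive / (1.0 - config.match_weight)
        else:
            blast0 = drive
        blast0 = float(min(8.0, max(1.0, blast0)))
        last_blast: dict[str, float] = {p: blast0 for p in players}
        prev_winner: str | None = None
        t = 0.0
        epochs: dict[str, list[dict]] = {p: [] for p in players}

        for r in range(1 - config.burn_in, config.n_rounds + 1):
            if r == 1:
                t = 0.0  # session clock starts at the first recorded round
            rt_a = rng.lognormal(config.rt_location, config.rt_scale)
            rt_b = rng.lognormal(config.rt_location, config.rt_scale)
            who = rig_winner(rt_a, rt_b, config.rig_window, rng)
            winner = players[0] if who == "a" else players[1]
            loser = players[1] if who == "a" else players[0]
            rt_winner, rt_loser = (rt_a, rt_b) if who == "a" else (rt_b, rt_a)

            if winner != prev_winner:
                # new compressed interval: actor/partner carry-over
                prev = dict(neg)
                for p, q in ((players[0], players[1]), (players[1], players[0])):
                    neg[p] = _clip_intensity(
                        couple_beta0
                        + config.actor_effect * prev[p]
                        + config.partner_effect * prev[q]
                        + rng.normal(0.0, config.neg_noise_sd)
                    )
                prev_winner = winner

            t_go = t + 1.0 + rng.uniform(0.0, 8.0)
            t_announced = t_go + max(rt_a, rt_b) / 1000.0
            elective = rng.exponential(config.elective_extra_rate)
            t_selected = t_announced + forced + elective

            winner_neg_t1 = neg[winner]
            winner_neg_t2 = decay_negativity(
                winner_neg_t1, forced + elective, config.decay_rate
            )
            loser_neg = neg[loser]

            partner_prev = last_blast[loser]
            blast_mu = (
                config.blast_baseline
                + config.match_weight * partner_prev
                + config.own_neg_weight * winner_neg_t2
                + config.partner_neg_weight * loser_neg
                + asym[winner]
            )
            blast = _clip_blast(blast_mu + rng.normal(0.0, config.blast_noise_sd))
            last_blast[winner] = float(blast)

            if r < 1:  # warm-up round: advance the dynamics, record nothing
                t = t_selected + 2.0
                continue

            trial_rows.append(
                {
                    "couple_id": couple_id,
                    "study": "simulated",
                    "condition": condition,
                    "round": r,
                    "winner_id": winner,
                    "loser_id": loser,
                    "rt_winner_ms": rt_winner,
                    "rt_loser_ms": rt_loser,
                    "blast": blast,
                    "t_go": t_go,
                    "t_winner_announced": t_announced,
                    "t_blast_selected": t_selected,
                    "forced_break_s": forced,
                }
            )
            truth_rows.append(
                {
                    "couple_id": couple_id,
                    "round": r,
                    "winner_id": winner,
                    "loser_id": loser,
                    "winner_neg_t1": winner_neg_t1,
                    "winner_neg_t2": winner_neg_t2,
                    "loser_neg": loser_neg,
                    "positive": config.pos_baseline,
                }
            )
            for p in players:
                p_neg_t1 = winner_neg_t1 if p == winner else loser_neg
                p_neg_t2 = winner_neg_t2 if p == winner else loser_neg
                epochs[p].append(
                    {
                        "t_start": t_announced - 1.0,
                        "t_end": t_announced + 1.0,
                        "positive": config.pos_baseline,
                        "negative": p_neg_t1,
                    }
                )
                epochs[p].append(
                    {
                        "t_start": t_selected - 1.0,
                        "t_end": t_selected + 1.0,
                        "positive": config.pos_baseline,
                        "negative": p_neg_t2,
                    }
                )
            t = t_selected + 2.0  # blast plays for 2 s

        if config.emit_au:
            for p in players:
                au_streams[p] = emit_au_frames(
                    pd.DataFrame(epochs[p]),
                    config,
                    rng,
                    t_start=0.0,
                    t_end=t,
                )

    trials = pd.DataFrame(trial_rows)
    affect_truth = pd.DataFrame(truth_rows)
    return SimulatedStudy(
        trials=trials, au_streams=au_streams, affect_truth=affect_truth, truth=config
    )


def emit_au_frames(
    epochs: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    t_start: float | None = None,
    t_end: float | None = None,
) -> pd.DataFrame:
    """Emit an AU-intensity frame table realizing an emotion trajectory.

    ``epochs`` has columns ``t_start, t_end, positive, negative`` (one
    row per expression epoch, seconds and 0-5 intensities).  Frames are
    laid on a uniform grid at ``config.fps`` with inclusive endpoints,
    spanning ``[t_start, t_end]`` (defaults: the epoch extremes).
    Within an epoch, AU6/AU12 carry the positive intensity plus noise
    and AU4/AU9/AU23 carry the negative intensity plus noise; between
    epochs the positive channels sit at ``pos_baseline`` and the
    negative channels at zero; unrelated AU columns carry pure noise.
    All values are clipped to [0, 5].  Overlapping epochs resolve to
    the later-starting one.
    """
    if len(epochs) == 0:
        raise ValueError("empty emotion trajectory")
    for col in ("t_start", "t_end", "positive", "negative"):
        if col not in epochs.columns:
            raise ValueError(f"epochs missing column {col!r}")
    if ((epochs["positive"] < 0) | (epochs["positive"] > 5)).any() or (
        (epochs["negative"] < 0) | (epochs["negative"] > 5)
    ).any():
        raise ValueError("epoch intensities must lie in [0, 5]")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    ep = epochs.sort_values("t_start").reset_index(drop=True)
    lo = float(ep["t_start"].min()) if t_start is None else float(t_start)
    hi = float(ep["t_end"].max()) if t_end is None else float(t_end)
    n = int(math.floor((hi - lo) * config.fps + 1e-9)) + 1
    ts = lo + np.arange(n) / config.fps

    starts = ep["t_start"].to_numpy()
    ends = ep["t_end"].to_numpy()
    idx = np.searchsorted(starts, ts + 1e-12, side="right") - 1
    in_epoch = (idx >= 0) & (ts <= np.where(idx >= 0, ends[np.clip(idx, 0, None)], -1.0) + 1e-12)
    pos = np.where(in_epoch, ep["positive"].to_numpy()[np.clip(idx, 0, None)], config.pos_baseline)
    neg = np.where(in_epoch, ep["negative"].to_numpy()[np.clip(idx, 0, None)], 0.0)

    data: dict[str, np.ndarray] = {
        "frame": np.arange(1, n + 1),
        "timestamp": ts,
        "confidence": np.full(n, 0.98),
        "success": np.ones(n, dtype=int),
    }
    # noise is common-mode within a valence: the fluctuation of one
    # display is shared across its AUs, which keeps max-combination
    # scoring unbiased
    pos_noise = rng.normal(0.0, config.au_noise_sd, n)
    neg_noise = rng.normal(0.0, config.au_noise_sd, n)
    for code in AU_CODES:
        if code in POSITIVE_AUS:
            vals = pos + pos_noise
        elif code in NEGATIVE_AUS:
            vals = neg + neg_noise
        else:
            vals = np.abs(rng.normal(0.0, config.au_noise_sd, n))
        data[f"AU{code:02d}_r"] = np.clip(vals, 0.0, 5.0)
    return pd.DataFrame(data)
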