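"""Prototypic emotion scoring from facial action-unit intensity tables.

Consumes the tabular output of automated FACS tools (intensity channels
``AUxx_r`` on a 0-5 scale, one row per video frame) and converts it to
per-frame happiness/anger/disgust intensities plus a combined
positive/negative pair, then summarises them over event windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AUCombinationRules",
    "DEFAULT_RULES",
    "EmptyTableError",
    "WindowIntensity",
    "read_au_table",
    "score_emotions",
    "window_intensity",
]


class EmptyTableError(ValueError):
    """Raised when an AU table contains no frames."""


@dataclass(frozen=True)
class AUCombinationRules:
    """AU combinations defining each prototypic emotion.

    Each emotion's intensity is the mean intensity of its required AUs
    (keeping the 0-5 scale).  ``negative_mode`` controls how anger and
    disgust combine into the negative channel: ``"max"`` (default;
    either moral emotion alone marks the display negative) or
    ``"mean"``.  Positive is identically happiness.
    """

    happiness: frozenset[int] = field(default_factory=lambda: frozenset({6, 12}))
    anger: frozenset[int] = field(default_factory=lambda: frozenset({4, 23}))
    disgust: frozenset[int] = field(default_factory=lambda: frozenset({9}))
    negative_mode: str = "max"

    def __post_init__(self) -> None:
        for name in ("happiness", "anger", "disgust"):
            aus = getattr(self, name)
            if not aus:
                raise ValueError(f"required AU set for {name} is empty")
            if not all(isinstance(a, (int, np.integer)) for a in aus):
                raise ValueError(f"AU codes for {name} must be integers")
            object.__setattr__(self, name, frozenset(int(a) for a in aus))
        if self.negative_mode not in ("max", "mean"):
            raise ValueError("negative_mode must be 'max' or 'mean'")

    @property
    def required_aus(self) -> frozenset[int]:
        return self.happiness | self.anger | self.disgust

    @property
    def required_columns(self) -> list[str]:
        return [f"AU{a:02d}_r" for a in sorted(self.required_aus)]


DEFAULT_RULES = AUCombinationRules()


def read_au_table(source, rules: AUCombinationRules = DEFAULT_RULES) -> pd.DataFrame:
    """Read an AU-intensity CSV into a frame table.

    The dialect has columns ``frame, timestamp, confidence, success,
    AU01_r ... AU45_r`` in any order.  Rows with ``success == 0`` are
    dropped and the count is logged and recorded in
    ``df.attrs["n_dropped"]``.  Missing AU columns required by
    ``rules`` raise a :class:`ValueError` naming them.
    """
    df = pd.read_csv(source)
    df.columns = [c.strip() for c in df.columns]
    for col in ("timestamp", "success", "confidence"):
        if col not in df.columns:
            raise ValueError(f"AU table missing required column {col!r}")
    missing = [c for c in rules.required_columns if c not in df.columns]
    if missing:
        raise ValueError(f"AU table missing required AU columns: {', '.join(missing)}")
    if len(df) == 0:
        raise EmptyTableError("AU table contains no frames")
    kept = df[df["success"] != 0].reset_index(drop=True)
    n_dropped = len(df) - len(kept)
    if n_dropped:
        logger.info("read_au_table: dropped %d frame(s) with success=0", n_dropped)
    kept.attrs["n_dropped"] = n_dropped
    return kept


def _emotion_mean(frames: pd.DataFrame, aus: Iterable[int]) -> np.ndarray:
    cols = [f"AU{a:02d}_r" for a in sorted(aus)]
    missing = [c for c in cols if c not in frames.columns]
    if missing:
        raise ValueError(f"frames missing required AU columns: {', '.join(missing)}")
    return frames[cols].to_numpy(dtype=float).mean(axis=1)


def score_emotions(
    frames: pd.DataFrame, rules: AUCombinationRules = DEFAULT_RULES
) -> pd.DataFrame:
    """Score prototypic emotions pointwise for every frame.

    Returns a table with ``timestamp, happiness, anger, disgust,
    positive, negative`` of the same length and order as the input.
    """
    happiness = _emotion_mean(frames, rules.happiness)
    anger = _emotion_mean(frames, rules.anger)
    disgust = _emotion_mean(frames, rules.disgust)
    if rules.negative_mode == "max":
        negative = np.maximum(anger, disgust)
    else:
        negative = (anger + disgust) / 2.0
    out = pd.DataFrame(
        {
            "timestamp": frames["timestamp"].to_numpy(dtype=float),
            "happiness": happiness,
            "anger": anger,
            "disgust": disgust,
            "positive": happiness,
            "negative": negative,
        }
    )
    return out


@dataclass(frozen=True)
class WindowIntensity:
    """Mean positive/negative intensity over an event window.

    ``n_frames == 0`` signals an empty window explicitly; the means are
    NaN in that case, never silently zero.
    """

    positive: float
    negative: float
    n_frames: int

    @property
    def empty(self) -> bool:
        return self.n_frames == 0


def window_intensity(
    emotions: pd.DataFrame, t_center: float, half_width: float = 1.0
) -> WindowIntensity:
    """Mean emotion intensities over the closed window ``t_center +/- half_width``."""
    if half_width <= 0:
        raise ValueError("half_width must be > 0")
    ts = emotions["timestamp"].to_numpy(dtype=float)
    mask = (ts >= t_center - half_width) & (ts <= t_center + half_width)
    n = int(mask.sum())
    if n == 0:
        return WindowIntensity(positive=float("nan"), negative=float("nan"), n_frames=0)
    return WindowIntensity(
        positive=float(emotions.loc[mask, "positive"].mean()),
        negative=float(emotions.loc[mask, "negative"].mean()),
        n_frames=n,
    )
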