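"""Score classifier output against labelled behaviour intervals.

Mirrors the video-validation protocol: predictions are reduced to 1 s
resolution by majority vote, predicted recumbency runs shorter than a
minimum period (default 31 s, the shortest recumbency bout in the validation
footage) are removed, and each labelled second is scored as
recumbent-vs-other.  The positive class is *recumbent*; all four confusion
counts are reported so either convention can be recovered.  Seconds outside
the labelled intervals are never scored, and boundary seconds count only if
a label covers at least half of them.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .classify import OTHER

__all__ = ["ConfusionMatrix", "score", "rasterize_to_seconds"]


@dataclasses.dataclass
class ConfusionMatrix:
    """Per-second confusion counts; positive class = recumbent."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def scored_seconds(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.scored_seconds

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "scored_seconds": self.scored_seconds,
        }


def rasterize_to_seconds(
    time: np.ndarray, positive: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Majority-vote a per-sample boolean onto the 1 s grid.

    Returns (second_start_times as int64 epoch seconds, boolean per second).
    A second is positive when at least half of its samples are positive.
    """
    t_ns = np.asarray(time, dtype="datetime64[ns]").astype("int64")
    sec = t_ns // 1_000_000_000
    uniq, inv = np.unique(sec, return_inverse=True)
    pos_counts = np.bincount(inv, weights=np.asarray(positive, dtype=float))
    tot_counts = np.bincount(inv)
    return uniq, pos_counts * 2 >= tot_counts


def _remove_short_runs(mask: np.ndarray, seconds: np.ndarray, min_period: float) -> np.ndarray:
    """Drop positive runs shorter than min_period seconds (1 Hz grid)."""
    out = mask.copy()
    n = len(mask)
    i = 0
    while i < n:
        if out[i]:
            j = i
            while j + 1 < n and out[j + 1] and seconds[j + 1] == seconds[j] + 1:
                j += 1
            if (j - i + 1) < min_period:
                out[i : j + 1] = False
            i = j + 1
        else:
            i += 1
    return out


def score(
    predicted_posture: np.ndarray,
    time: np.ndarray,
    labels: pd.DataFrame,
    min_period: float = 31.0,
) -> ConfusionMatrix:
    """Confusion matrix of predicted recumbency against labelled intervals.

    ``labels`` has columns ``start``, ``end``, ``truth_class`` (values
    ``recumbent`` / ``other``).  Raises when prediction and labels do not
    overlap in time.
    """
    labels = labels.copy()
    labels["start"] = pd.to_datetime(labels["start"])
    labels["end"] = pd.to_datetime(labels["end"])
    if labels.empty or (labels["end"] - labels["start"]).sum().total_seconds() <= 0:
        raise ValueError("no labelled duration to score")

    seconds, pred = rasterize_to_seconds(time, np.asarray(predicted_posture) != OTHER)
    pred = _remove_short_runs(pred, seconds, min_period)

    # truth per 1 s cell: labelled iff covered >= 0.5 s by a label interval
    truth = np.full(len(seconds), -1, dtype=np.int8)  # -1 = unscored
    sec_lo = seconds.astype("int64")
    for row in labels.itertuples():
        lo = row.start.value / 1e9
        hi = row.end.value / 1e9
        cover = np.clip(np.minimum(hi, sec_lo + 1) - np.maximum(lo, sec_lo), 0.0, 1.0)
        hit = cover >= 0.5
        truth[hit] = 1 if row.truth_class == "recumbent" else 0

    scored = truth >= 0
    if not scored.any():
        raise ValueError("predictions and labels do not overlap in time")
    p, t = pred[scored], truth[scored].astype(bool)
    return ConfusionMatrix(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)),
        fn=int(np.sum(~p & t)),
    )
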