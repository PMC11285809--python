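"""Posture classification and sleep-bout detection.

Pigs and wild boar sleep in either sternal recumbency (on the chest, head
down) or lateral recumbency (on the side).  Sleep is classified behaviourally
from two cues: a recumbent posture, read from pitch/roll of the static
acceleration vector, and sustained stillness, read from smoothed VeDBA.

Rules
-----
* lateral recumbency:  |roll| > 15 deg (checked first, so the two posture
  rules never overlap);
* sternal recumbency:  pitch < 0 deg and |roll| < 15 deg;
* stillness: smoothed VeDBA < 0.2 g;
* a candidate sleep period is a maximal run of recumbent-and-still samples
  (posture may switch between sternal and lateral without ending the run --
  postural adjustments during sleep are tolerated);
* candidates shorter than 5 min are discarded;
* the first 5 min of each surviving candidate are discarded (recumbent pigs
  need 4--5 min to transition from wakefulness to sleep), and candidates with
  nothing left after trimming are dropped.

All thresholds are configurable through :class:`ClassifierConfig`; the
defaults are the field values above.  Inequalities are strict exactly as
stated (pitch < 0, |roll| boundaries exclusive, VeDBA < 0.2 counts as still).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .kinematics import KinematicSeries

__all__ = [
    "OTHER",
    "STERNAL",
    "LATERAL",
    "POSTURE_NAMES",
    "ClassifierConfig",
    "SleepBout",
    "classify_posture",
    "detect_bouts",
    "bout_oracle",
]

logger = logging.getLogger(__name__)

# per-sample posture codes
OTHER, STERNAL, LATERAL = 0, 1, 2
POSTURE_NAMES = {OTHER: "other", STERNAL: "sternal_recumbent", LATERAL: "lateral_recumbent"}


@dataclasses.dataclass
class ClassifierConfig:
    """Thresholds for posture and sleep-bout classification.

    Angles in degrees, VeDBA in g, durations in seconds.
    """

    pitch_max_sternal: float = 0.0
    roll_abs_max_sternal: float = 15.0
    roll_abs_min_lateral: float = 15.0
    vedba_still_max: float = 0.2
    min_bout: float = 300.0
    onset_trim: float = 300.0
    #: if True, also drop bouts whose *post-trim* duration is < min_bout
    #: (default keeps any candidate whose pre-trim duration passed the filter)
    drop_short_after_trim: bool = False

    def __post_init__(self) -> None:
        for name in ("pitch_max_sternal", "roll_abs_max_sternal",
                     "roll_abs_min_lateral", "vedba_still_max"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.min_bout < 0 or self.onset_trim < 0:
            raise ValueError("min_bout and onset_trim must be >= 0")


@dataclasses.dataclass
class SleepBout:
    """One contiguous classified sleep interval after trimming rules.

    ``raw_start`` is the onset of recumbent stillness; ``start`` is
    raw_start + onset trim, the point from which time counts as sleep.
    """

    animal_id: str
    raw_start: pd.Timestamp
    start: pd.Timestamp
    end: pd.Timestamp
    dominant_posture: str = "sternal_recumbent"
    truncated: bool = False

    def __post_init__(self) -> None:
        self.raw_start = pd.Timestamp(self.raw_start)
        self.start = pd.Timestamp(self.start)
        self.end = pd.Timestamp(self.end)
        if self.end <= self.start:
            raise ValueError(f"bout end {self.end} not after start {self.start}")

    @property
    def duration(self) -> float:
        """Post-trim duration in seconds."""
        return (self.end - self.start).total_seconds()


def classify_posture(
    kin: KinematicSeries | None = None,
    config: ClassifierConfig | None = None,
    *,
    pitch: np.ndarray | None = None,
    roll: np.ndarray | None = None,
) -> np.ndarray:
    """Per-sample posture state (OTHER / STERNAL / LATERAL).

    Lateral recumbency is checked first, so with the default symmetric 15 deg
    thresholds the two recumbency rules are mutually exclusive by
    construction.  NaN pitch/roll samples are classified OTHER; their count
    is logged.
    """
    config = config or ClassifierConfig()
    if kin is not None:
        pitch, roll = kin.pitch, kin.roll
    if pitch is None or roll is None:
        raise ValueError("provide either a KinematicSeries or pitch and roll arrays")
    pitch = np.asarray(pitch, dtype=float)
    roll = np.asarray(roll, dtype=float)
    if pitch.shape != roll.shape:
        raise ValueError("pitch and roll lengths differ")

    bad = ~(np.isfinite(pitch) & np.isfinite(roll))
    if np.any(bad):
        logger.warning("%d samples with NaN pitch/roll classified as other", bad.sum())

    out = np.full(pitch.shape, OTHER, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        lateral = np.abs(roll) > config.roll_abs_min_lateral
        sternal = (
            (pitch < config.pitch_max_sternal)
            & (np.abs(roll) < config.roll_abs_max_sternal)
            & ~lateral
        )
    out[sternal & ~bad] = STERNAL
    out[lateral & ~bad] = LATERAL
    return out


def _resolve_inputs(posture, vedba_smoothed, time, sample_rate):
    posture = np.asarray(posture)
    vs = np.asarray(vedba_smoothed, dtype=float)
    time = np.asarray(time, dtype="datetime64[ns]")
    if not (len(posture) == len(vs) == len(time)):
        raise ValueError(
            f"misaligned series: posture {len(posture)}, vedba {len(vs)}, time {len(time)}"
        )
    if sample_rate is not None:
        dt_ns = int(round(1e9 / sample_rate))
    elif len(time) > 1:
        dt_ns = int(np.median(np.diff(time.astype("int64"))))
    else:
        dt_ns = int(1e9)
    return posture, vs, time, dt_ns


def _runs_to_bouts(runs, posture, time, dt_ns, config, animal_id, n):
    """Apply minimum-duration and onset-trim rules to candidate runs."""
    trim = np.timedelta64(int(config.onset_trim * 1e9), "ns")
    bouts: list[SleepBout] = []
    for i0, i1 in runs:
        raw_start = time[i0]
        end = time[i1] + np.timedelta64(dt_ns, "ns")
        duration = (end - raw_start).astype("int64") / 1e9
        if duration < config.min_bout:
            continue
        start = raw_start + trim
        if start >= end:
            continue
        if config.drop_short_after_trim and (
            (end - start).astype("int64") / 1e9 < config.min_bout
        ):
            continue
        seg = posture[i0 : i1 + 1]
        n_lat = int(np.count_nonzero(seg == LATERAL))
        dominant = LATERAL if n_lat * 2 > len(seg) else STERNAL
        bouts.append(
            SleepBout(
                animal_id=animal_id,
                raw_start=pd.Timestamp(raw_start),
                start=pd.Timestamp(start),
                end=pd.Timestamp(end),
                dominant_posture=POSTURE_NAMES[dominant],
                truncated=(i0 == 0 or i1 == n - 1),
            )
        )
    return bouts


def detect_bouts(
    posture: np.ndarray,
    vedba_smoothed: np.ndarray,
    time: np.ndarray,
    config: ClassifierConfig | None = None,
    *,
    sample_rate: float | None = None,
    animal_id: str = "animal",
) -> list[SleepBout]:
    """Detect sleep bouts from per-sample posture and smoothed VeDBA.

    A candidate is a maximal run of samples that are recumbent (sternal or
    lateral) with smoothed VeDBA below the stillness threshold.  A single
    supra-threshold sample terminates a run (the 2 s smoothing already
    absorbs transients).  Candidates shorter than ``config.min_bout`` are
    dropped, survivors lose their first ``config.onset_trim`` seconds, and
    anything left non-positive is dropped.  Bouts touching the first or last
    sample of the recording are flagged ``truncated``.
    """
    config = config or ClassifierConfig()
    posture, vs, time, dt_ns = _resolve_inputs(posture, vedba_smoothed, time, sample_rate)
    n = len(posture)
    if n == 0:
        return []

    still = (posture != OTHER) & (vs < config.vedba_still_max)
    edges = np.diff(still.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1)
    if still[0]:
        starts = np.concatenate([[0], starts])
    if still[-1]:
        ends = np.concatenate([ends, [n - 1]])
    runs = list(zip(starts.tolist(), ends.tolist()))
    return _runs_to_bouts(runs, posture, time, dt_ns, config, animal_id, n)


def bout_oracle(
    posture: np.ndarray,
    vedba_smoothed: np.ndarray,
    time: np.ndarray,
    config: ClassifierConfig | None = None,
    *,
    sample_rate: float | None = None,
    animal_id: str = "animal",
) -> list[SleepBout]:
    """Naive one-sample-at-a-time re-implementation of :func:`detect_bouts`.

    Same contract, no vectorisation; exists as an independent cross-check for
    the test suite and is deliberately written as a plain state machine.
    """
    config = config or ClassifierConfig()
    posture, vs, time, dt_ns = _resolve_inputs(posture, vedba_smoothed, time, sample_rate)
    n = len(posture)
    runs: list[tuple[int, int]] = []
    run_start: int | None = None
    for i in range(n):
        is_still = posture[i] != OTHER and vs[i] < config.vedba_still_max
        if is_still and run_start is None:
            run_start = i
        elif not is_still and run_start is not None:
            runs.append((run_start, i - 1))
            run_start = None
    if run_start is not None:
        runs.append((run_start, n - 1))
    return _runs_to_bouts(runs, posture, time, dt_ns, config, animal_id, n)
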