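"""Transform raw tri-axial acceleration into posture and movement signals.

Biologging tags record acceleration in units of *g* (1 g = 9.81 m s^-2)
on three body axes: surge (x, anterior--posterior), sway (y, lateral) and
heave (z, dorso-ventral).  The raw signal is the sum of a slowly varying
gravitational ("static") component, which encodes posture, and a fast
("dynamic") component produced by movement.  This module separates the two
with a centred running-mean filter, derives body pitch and roll from the
static vector via the arcsine convention, and computes the vectorial dynamic
body acceleration (VeDBA)

    VeDBA = sqrt(Ax^2 + Ay^2 + Az^2)

where Ax, Ay, Az are the per-axis dynamic components.  Smoothed VeDBA (a
running mean of raw VeDBA) is the movement-intensity signal used downstream
to detect stillness during recumbency.

Conventions
-----------
* The running mean is **centred**, with shrinking (partial) windows at the
  edges, so output length always equals input length and posture estimates
  carry no onset lag.
* Window lengths are specified in seconds and converted to an odd number of
  samples.
* pitch = arcsin(static_x / ||static||), roll = arcsin(static_y / ||static||),
  both in degrees; negative pitch is head-down, positive roll is right side
  down.  Arguments are clamped to [-1, 1] before the arcsine, which guards
  against calibration drift; normalisation by ||static|| can be switched off.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "AccelTrace",
    "KinematicSeries",
    "running_mean",
    "static_acceleration",
    "pitch_roll",
    "vedba",
    "compute_kinematics",
]

#: CSV column names for the three acceleration axes, in g.
ACC_COLUMNS = ("ax_g", "ay_g", "az_g")


@dataclasses.dataclass
class AccelTrace:
    """A validated tri-axial acceleration time series.

    Parameters
    ----------
    time : np.ndarray of datetime64[ns]
        Sample timestamps, strictly increasing.
    acc : np.ndarray, shape (n, 3)
        Acceleration in g on the (surge, sway, heave) axes.
    sample_rate : float
        Nominal sampling rate in Hz.
    animal_id : str
        Identifier of the tagged individual.
    jitter_tol : float
        Tolerated relative deviation of inter-sample intervals from
        1/sample_rate.  Larger gaps should be split into separate traces
        (see :func:`boarsleep.io.read_trace`).
    """

    time: np.ndarray
    acc: np.ndarray
    sample_rate: float
    animal_id: str = "animal"
    jitter_tol: float = 0.1

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype="datetime64[ns]")
        self.acc = np.atleast_2d(np.asarray(self.acc, dtype=float))
        if self.acc.shape[1] != 3:
            raise ValueError(f"acc must have 3 columns, got {self.acc.shape}")
        if len(self.time) != len(self.acc):
            raise ValueError("time and acc lengths differ")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.acc)):
            raise ValueError("non-finite acceleration values")
        dt_ns = np.diff(self.time.astype("int64"))
        if np.any(dt_ns <= 0):
            i = int(np.argmax(dt_ns <= 0))
            raise ValueError(f"timestamps not strictly increasing at sample {i + 1}")
        if len(dt_ns):
            nominal = 1e9 / self.sample_rate
            worst = np.max(np.abs(dt_ns - nominal)) / nominal
            if worst > self.jitter_tol:
                raise ValueError(
                    f"inter-sample interval deviates {worst:.1%} from nominal "
                    f"(tolerance {self.jitter_tol:.0%}); split the trace at gaps first"
                )

    def __len__(self) -> int:
        return len(self.time)

    @property
    def dt(self) -> float:
        """Nominal sample interval in seconds."""
        return 1.0 / self.sample_rate

    @property
    def duration(self) -> float:
        """Span from first sample to one interval past the last, seconds."""
        span_ns = (self.time[-1] - self.time[0]).astype("int64")
        return span_ns / 1e9 + self.dt

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.time,
                ACC_COLUMNS[0]: self.acc[:, 0],
                ACC_COLUMNS[1]: self.acc[:, 1],
                ACC_COLUMNS[2]: self.acc[:, 2],
            }
        )


def _odd_window_samples(window: float, sample_rate: float) -> int:
    """Window length in samples: round(window * fs), forced odd, at least 1."""
    w = int(round(window * sample_rate))
    w = max(w, 1)
    if w % 2 == 0:
        w += 1
    return w


def running_mean(x: np.ndarray, window_samples: int) -> np.ndarray:
    """Centred running mean with shrinking windows at the edges.

    At index i the mean is taken over samples [i-h, i+h] intersected with the
    valid range, h = (window_samples - 1) // 2, so output length equals input
    length and edge values are partial means rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if window_samples < 1:
        raise ValueError("window_samples must be >= 1")
    if window_samples % 2 == 0:
        raise ValueError("window_samples must be odd")
    h = (window_samples - 1) // 2
    cs = np.concatenate([np.zeros((1,) + x.shape[1:]), np.cumsum(x, axis=0)])
    idx = np.arange(n)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h, n - 1)
    counts = (hi - lo + 1).astype(float)
    if x.ndim > 1:
        counts = counts[:, None]
    return (cs[hi + 1] - cs[lo]) / counts


def static_acceleration(trace: AccelTrace, window: float = 2.0) -> np.ndarray:
    """Estimate the gravitational (static) component per axis.

    A centred running mean over ``window`` seconds (default 2 s) is applied to
    the raw 3-axis signal.  Raises if the trace is shorter than one window.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    w = _odd_window_samples(window, trace.sample_rate)
    if len(trace) < w:
        raise ValueError(
            f"trace has {len(trace)} samples, shorter than one {w}-sample window"
        )
    return running_mean(trace.acc, w)


def pitch_roll(
    static: np.ndarray, normalize: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Body pitch and roll (degrees) from the static acceleration vector.

    pitch = arcsin(x / ||s||), roll = arcsin(y / ||s||).  With
    ``normalize=False`` the raw g values are used instead of the normalised
    components (assumes ||s|| = 1 g).  Zero-magnitude static vectors yield
    NaN with a warning, never silently.
    """
    static = np.atleast_2d(np.asarray(static, dtype=float))
    if normalize:
        norm = np.linalg.norm(static, axis=1)
        zero = norm == 0
        if np.any(zero):
            warnings.warn(
                f"{int(zero.sum())} zero-magnitude static vectors -> NaN pitch/roll",
                RuntimeWarning,
                stacklevel=2,
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            sx = np.where(zero, np.nan, static[:, 0] / np.where(zero, 1.0, norm))
            sy = np.where(zero, np.nan, static[:, 1] / np.where(zero, 1.0, norm))
    else:
        sx, sy = static[:, 0], static[:, 1]
    pitch = np.degrees(np.arcsin(np.clip(sx, -1.0, 1.0)))
    roll = np.degrees(np.arcsin(np.clip(sy, -1.0, 1.0)))
    return pitch, roll


def vedba(
    trace: AccelTrace, static: np.ndarray, smooth_window: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorial dynamic body acceleration and its smoothed form.

    The dynamic component is raw minus static per axis; VeDBA is its
    Euclidean norm per sample; smoothed VeDBA is a centred running mean of
    raw VeDBA over ``smooth_window`` seconds (default 2 s), with the same
    edge policy as :func:`static_acceleration`.
    """
    static = np.asarray(static, dtype=float)
    if static.shape != trace.acc.shape:
        raise ValueError(
            f"static shape {static.shape} does not match trace {trace.acc.shape}"
        )
    dyn = trace.acc - static
    v = np.linalg.norm(dyn, axis=1)
    w = _odd_window_samples(smooth_window, trace.sample_rate)
    return v, running_mean(v, w)


@dataclasses.dataclass
class KinematicSeries:
    """Per-sample kinematic signals derived from one trace."""

    time: np.ndarray
    raw: np.ndarray
    static: np.ndarray
    dynamic: np.ndarray
    pitch: np.ndarray
    roll: np.ndarray
    vedba: np.ndarray
    vedba_smoothed: np.ndarray
    sample_rate: float
    animal_id: str = "animal"

    def __len__(self) -> int:
        return len(self.time)

    def to_frame(self) -> pd.DataFrame:
        """One row per sample with raw, static, dynamic and derived signals."""
        cols = {"timestamp": self.time}
        for k, ax in enumerate(("x", "y", "z")):
            cols[f"a{ax}_g"] = self.raw[:, k]
        for k, ax in enumerate(("x", "y", "z")):
            cols[f"static_{ax}"] = self.static[:, k]
        for k, ax in enumerate(("x", "y", "z")):
            cols[f"dyn_{ax}"] = self.dynamic[:, k]
        cols["pitch_deg"] = self.pitch
        cols["roll_deg"] = self.roll
        cols["vedba_g"] = self.vedba
        cols["vedba_smoothed_g"] = self.vedba_smoothed
        return pd.DataFrame(cols)


def compute_kinematics(
    trace: AccelTrace,
    window: float = 2.0,
    smooth_window: float = 2.0,
    normalize_angles: bool = True,
) -> KinematicSeries:
    """Run the full decomposition on one trace.

    Static acceleration (centred running mean), pitch/roll from the static
    vector, dynamic = raw - static, VeDBA and smoothed VeDBA.
    """
    static = static_acceleration(trace, window=window)
    pitch, roll = pitch_roll(static, normalize=normalize_angles)
    v, vs = vedba(trace, static, smooth_window=smooth_window)
    return KinematicSeries(
        time=trace.time,
        raw=trace.acc,
        static=static,
        dynamic=trace.acc - static,
        pitch=pitch,
        roll=roll,
        vedba=v,
        vedba_smoothed=vs,
        sample_rate=trace.sample_rate,
        animal_id=trace.animal_id,
    )
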