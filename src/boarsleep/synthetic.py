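"""Synthetic biologger data with known ground truth.

Three generators live here, one per downstream stage:

* :func:`generate_trace` turns a scripted behaviour schedule into a 20 Hz
  tri-axial acceleration stream with posture-dependent gravity orientation,
  band-limited (2--5 Hz) activity bursts, smooth orientation ramps between
  behaviours, and additive sensor noise;
* :func:`schedule_to_truth_bouts` applies the sleep-bout rules (merge
  recumbent entries, 5-min minimum, 5-min onset trim) directly to the
  schedule intervals -- pure interval arithmetic, no signal processing -- so
  it can serve as an independent oracle for the signal-based classifier;
* :func:`simulate_dhglm_data` draws daily observations from the
  double-hierarchical Gaussian model (fixed effects on mean and log residual
  SD, correlated per-individual intercepts on both) so the sampler's
  parameter recovery can be checked against known truth.

Axis convention: x = surge, y = sway, z = heave; upright posture puts gravity
mostly on z.  Behaviour orientations are synthetic stand-ins chosen to sit
firmly inside / outside the posture-classification regions, not to mimic real
boar geometry: non-recumbent behaviours pitch +30 deg, sternal recumbency
pitch -30 deg, lateral recumbency roll +60 deg.

Orientation transitions interpolate the gravity vector linearly over a 2 s
ramp whose midpoint -- where the pitch-sign classification boundary is
crossed -- falls exactly half a sample before the schedule boundary.  Because
a centred running mean reproduces linear segments exactly, the classifier's
estimated posture flips at precisely the scheduled boundary sample, which
makes noiseless end-to-end recovery exact.  Entries into or out of lateral
recumbency route through the sternal orientation so that every entry/exit
crossing uses the same symmetric pitch ramp.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .classify import SleepBout
from .kinematics import AccelTrace

__all__ = [
    "BEHAVIOURS",
    "RECUMBENT_BEHAVIOURS",
    "ScheduleEntry",
    "BehaviourSchedule",
    "TraceGenConfig",
    "DhglmSimConfig",
    "make_schedule",
    "boar_schedule",
    "generate_trace",
    "schedule_to_truth_bouts",
    "schedule_to_labels",
    "make_dhglm_design",
    "simulate_dhglm_data",
]

BEHAVIOURS = ("active", "sternal_still", "lateral_still", "standing_still", "transition")
RECUMBENT_BEHAVIOURS = frozenset({"sternal_still", "lateral_still"})

# base (pitch, roll) in degrees per behaviour; all non-recumbent behaviours
# share one upright orientation so recumbency entry/exit ramps are symmetric
_BASE_ANGLES = {
    "active": (30.0, 0.0),
    "standing_still": (30.0, 0.0),
    "transition": (30.0, 0.0),
    "sternal_still": (-30.0, 0.0),
    "lateral_still": (0.0, 60.0),
}
# fraction of activity_amplitude per behaviour
_ACTIVITY_SCALE = {"active": 1.0, "transition": 0.15}

_RAMP_HALF = 1.0  # seconds each side of a transition midpoint
_ENV_MARGIN = 3.0  # activity envelope is zero within this margin of entry edges
_ENV_RISE = 2.0  # cosine ramp length of the activity envelope


def _angles_to_vec(pitch_deg: float, roll_deg: float) -> np.ndarray:
    """Unit gravity vector for a posture given pitch and roll."""
    p, r = np.radians(pitch_deg), np.radians(roll_deg)
    v = np.array([np.sin(p), np.cos(p) * np.sin(r), np.cos(p) * np.cos(r)])
    return v / np.linalg.norm(v)


@dataclasses.dataclass(frozen=True)
class ScheduleEntry:
    start: pd.Timestamp
    end: pd.Timestamp
    behaviour: str


@dataclasses.dataclass
class BehaviourSchedule:
    """An ordered, contiguous script of behaviours for one animal."""

    entries: list[ScheduleEntry]
    animal_id: str = "animal"

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("schedule has no entries")
        entries = sorted(self.entries, key=lambda e: e.start)
        for e in entries:
            if e.behaviour not in BEHAVIOURS:
                raise ValueError(f"unknown behaviour {e.behaviour!r}")
            if e.end <= e.start:
                raise ValueError(f"zero or negative-length entry at {e.start}")
        for a, b in zip(entries, entries[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping entries at {b.start}")
            if b.start != a.end:
                raise ValueError(f"gap in schedule between {a.end} and {b.start}")
        self.entries = entries

    @property
    def span(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        return self.entries[0].start, self.entries[-1].end

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": self.animal_id,
                "start": [e.start for e in self.entries],
                "end": [e.end for e in self.entries],
                "behaviour": [e.behaviour for e in self.entries],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, animal_id: str | None = None) -> "BehaviourSchedule":
        if animal_id is None:
            ids = df["animal_id"].unique()
            if len(ids) != 1:
                raise ValueError("frame holds several animals; pass animal_id")
            animal_id = str(ids[0])
        else:
            df = df[df["animal_id"] == animal_id]
        entries = [
            ScheduleEntry(pd.Timestamp(r.start), pd.Timestamp(r.end), str(r.behaviour))
            for r in df.itertuples()
        ]
        return cls(entries=entries, animal_id=str(animal_id))


def make_schedule(
    segments: list[tuple[str, float]],
    start: str | pd.Timestamp = "2020-06-01 00:00:00",
    animal_id: str = "animal",
) -> BehaviourSchedule:
    """Build a schedule from (behaviour, duration-in-minutes) segments."""
    t = pd.Timestamp(start)
    entries = []
    for behaviour, minutes in segments:
        end = t + pd.Timedelta(minutes=minutes)
        entries.append(ScheduleEntry(t, end, behaviour))
        t = end
    return BehaviourSchedule(entries=entries, animal_id=animal_id)


@dataclasses.dataclass
class TraceGenConfig:
    """Generator settings for one accelerometer trace.

    noise_sd is per-axis Gaussian sensor noise (g); activity_amplitude scales
    the 2--5 Hz oscillation during active behaviour (g); posture_angle_jitter
    (degrees) perturbs each entry's base orientation; seed fixes the output
    stream bit-for-bit.
    """

    sample_rate: float = 20.0
    noise_sd: float = 0.02
    activity_amplitude: float = 0.8
    posture_angle_jitter: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.activity_amplitude < 0 or self.posture_angle_jitter < 0:
            raise ValueError("amplitudes must be >= 0")


def _entry_vectors(schedule: BehaviourSchedule, jitter: float, rng) -> list[np.ndarray]:
    vecs = []
    for e in schedule.entries:
        p, r = _BASE_ANGLES[e.behaviour]
        if jitter > 0:
            p += rng.normal(0.0, jitter)
            r += rng.normal(0.0, jitter)
        vecs.append(_angles_to_vec(p, r))
    return vecs


def _transition_waypoints(schedule, vecs, t0_s, dt):
    """Waypoint (time, vector) pairs implementing the orientation ramps."""
    sternal_vec = _angles_to_vec(*_BASE_ANGLES["sternal_still"])
    wt: list[float] = []
    wv: list[np.ndarray] = []
    entries = schedule.entries
    for k in range(1, len(entries)):
        prev, nxt = entries[k - 1], entries[k]
        v_prev, v_next = vecs[k - 1], vecs[k]
        if np.allclose(v_prev, v_next):
            continue
        # midpoint half a sample before the boundary: the pitch-sign crossing
        # of the linear ramp lands between the last pre-boundary sample and
        # the first post-boundary sample
        c = (nxt.start - entries[0].start).total_seconds() - dt / 2.0
        prev_lat = prev.behaviour == "lateral_still"
        next_lat = nxt.behaviour == "lateral_still"
        prev_rec = prev.behaviour in RECUMBENT_BEHAVIOURS
        next_rec = nxt.behaviour in RECUMBENT_BEHAVIOURS
        if next_lat and not prev_rec:
            pts = [(c - _RAMP_HALF, v_prev), (c + _RAMP_HALF, sternal_vec),
                   (c + 2 * _RAMP_HALF, v_next)]
        elif prev_lat and not next_rec:
            pts = [(c - 2 * _RAMP_HALF, v_prev), (c - _RAMP_HALF, sternal_vec),
                   (c + _RAMP_HALF, v_next)]
        else:
            pts = [(c - _RAMP_HALF, v_prev), (c + _RAMP_HALF, v_next)]
        wt.extend(t for t, _ in pts)
        wv.extend(v for _, v in pts)
    if any(b <= a for a, b in zip(wt, wt[1:])):
        raise ValueError(
            "schedule entries too short for orientation ramps (need > ~4 s each)"
        )
    return np.array(wt), np.array(wv)


def _activity_envelope(t_rel: np.ndarray, duration: float) -> np.ndarray:
    """Cosine-ramped envelope, zero within 3 s of the entry edges."""

    def ramp(x):
        u = np.clip((x - _ENV_MARGIN) / _ENV_RISE, 0.0, 1.0)
        return 0.5 - 0.5 * np.cos(np.pi * u)

    return np.minimum(ramp(t_rel), ramp(duration - t_rel))


def generate_trace(schedule: BehaviourSchedule, config: TraceGenConfig | None = None) -> AccelTrace:
    """Synthesize a tri-axial acceleration trace for a behaviour schedule.

    Still entries carry pure gravity (unit magnitude before noise); active
    entries superimpose band-limited oscillation under an envelope that
    vanishes near entry edges; transitions ramp the gravity vector linearly
    over 2 s.  Deterministic given ``config.seed``.
    """
    config = config or TraceGenConfig()
    rng = np.random.default_rng(config.seed)
    start, end = schedule.span
    fs, dt = config.sample_rate, 1.0 / config.sample_rate
    n = int(round((end - start).total_seconds() * fs))
    if n == 0:
        raise ValueError("schedule span too short for one sample")
    dt_ns = int(round(1e9 / fs))
    time = np.datetime64(start, "ns") + np.arange(n) * np.timedelta64(dt_ns, "ns")
    t_s = np.arange(n) * dt

    vecs = _entry_vectors(schedule, config.posture_angle_jitter, rng)
    wt, wv = _transition_waypoints(schedule, vecs, 0.0, dt)
    if len(wt) == 0:
        gravity = np.tile(vecs[0], (n, 1))
    else:
        gravity = np.column_stack([np.interp(t_s, wt, wv[:, k]) for k in range(3)])

    acc = gravity.copy()
    for e, _v in zip(schedule.entries, vecs):
        scale = _ACTIVITY_SCALE.get(e.behaviour, 0.0)
        amp = scale * config.activity_amplitude
        if amp == 0.0:
            continue
        s_rel = (e.start - start).total_seconds()
        dur = (e.end - e.start).total_seconds()
        i0 = int(np.ceil(s_rel * fs - 1e-9))
        i1 = min(int(np.ceil((s_rel + dur) * fs - 1e-9)), n)
        tt = t_s[i0:i1] - s_rel
        env = _activity_envelope(tt, dur)
        per_axis = amp / np.sqrt(3.0)
        for ax in range(3):
            sig = np.zeros_like(tt)
            for _tone in range(2):
                f = rng.uniform(2.0, 5.0)
                ph = rng.uniform(0.0, 2.0 * np.pi)
                sig += np.sin(2.0 * np.pi * f * tt + ph)
            acc[i0:i1, ax] += env * per_axis * sig / np.sqrt(2.0)

    if config.noise_sd > 0:
        acc = acc + rng.normal(0.0, config.noise_sd, size=acc.shape)

    return AccelTrace(time=time, acc=acc, sample_rate=fs, animal_id=schedule.animal_id)


def schedule_to_truth_bouts(
    schedule: BehaviourSchedule,
    min_bout: float = 300.0,
    onset_trim: float = 300.0,
) -> list[SleepBout]:
    """Sleep bouts implied directly by the schedule intervals.

    Consecutive recumbent entries (sternal or lateral) merge into one
    candidate period; periods shorter than ``min_bout`` seconds are dropped;
    survivors lose ``onset_trim`` seconds at the start.  Implemented as pure
    interval arithmetic so it is an oracle for the signal-based classifier.
    """
    if min_bout < 0 or onset_trim < 0:
        raise ValueError("min_bout and onset_trim must be >= 0")
    merged: list[list] = []  # [start, end, lateral_seconds]
    for e in schedule.entries:
        if e.behaviour not in RECUMBENT_BEHAVIOURS:
            continue
        lat = (e.end - e.start).total_seconds() if e.behaviour == "lateral_still" else 0.0
        if merged and merged[-1][1] == e.start:
            merged[-1][1] = e.end
            merged[-1][2] += lat
        else:
            merged.append([e.start, e.end, lat])
    bouts = []
    trim = pd.Timedelta(seconds=onset_trim)
    for s, e, lat in merged:
        dur = (e - s).total_seconds()
        if dur < min_bout:
            continue
        start = s + trim
        if start >= e:
            continue
        dominant = "lateral_recumbent" if lat * 2 > dur else "sternal_recumbent"
        bouts.append(
            SleepBout(
                animal_id=schedule.animal_id,
                raw_start=s,
                start=start,
                end=e,
                dominant_posture=dominant,
            )
        )
    return bouts


def schedule_to_labels(schedule: BehaviourSchedule) -> pd.DataFrame:
    """Interval labels (recumbent vs other) emulating video annotation."""
    rows = [
        {
            "animal_id": schedule.animal_id,
            "start": e.start,
            "end": e.end,
            "truth_class": "recumbent" if e.behaviour in RECUMBENT_BEHAVIOURS else "other",
        }
        for e in schedule.entries
    ]
    return pd.DataFrame(rows)


def boar_schedule(
    days: int = 7,
    start: str | pd.Timestamp = "2020-06-01 00:00:00",
    animal_id: str = "boar",
    seed: int = 0,
    day_window: tuple[float, float] = (6.0, 18.0),
) -> BehaviourSchedule:
    """A realistic multi-day behaviour script for a mostly nocturnal boar.

    Alternates rest and activity with duration distributions that differ
    between daylight (long rests, short active breaks) and darkness (short
    rests, long activity), yielding roughly 8--11 h of qualifying sleep per
    day spread over ~20 bouts, concentrated in daylight.
    """
    rng = np.random.default_rng(seed)
    t = pd.Timestamp(start)
    t_end = t + pd.Timedelta(days=days)
    segments: list[tuple[str, float]] = []
    resting = bool(rng.integers(0, 2))
    while t < t_end:
        hour = t.hour + t.minute / 60.0
        is_day = day_window[0] <= hour < day_window[1]
        if resting:
            median = 30.0 if is_day else 9.0
            minutes = float(np.clip(rng.lognormal(np.log(median), 0.6), 1.0, 180.0))
            behaviour = "sternal_still" if rng.random() < 0.8 else "lateral_still"
        else:
            median = 7.0 if is_day else 35.0
            minutes = float(np.clip(rng.lognormal(np.log(median), 0.6), 0.5, 240.0))
            u = rng.random()
            behaviour = "active" if u < 0.8 else ("standing_still" if u < 0.9 else "transition")
        # whole-second durations keep every entry boundary on the sample grid
        seconds = max(round(minutes * 60.0), 6)
        remaining = int((t_end - t).total_seconds())
        if seconds >= remaining - 6:
            seconds = remaining
        segments.append((behaviour, seconds))
        t = t + pd.Timedelta(seconds=seconds)
        resting = not resting
    t = pd.Timestamp(start)
    entries = []
    for behaviour, seconds in segments:
        end = t + pd.Timedelta(seconds=seconds)
        entries.append(ScheduleEntry(t, end, behaviour))
        t = end
    return BehaviourSchedule(entries=entries, animal_id=animal_id)


# ---------------------------------------------------------------------------
# DHGLM simulation
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class DhglmSimConfig:
    """Generative settings for the double-hierarchical Gaussian model.

    beta_mean / beta_sigma map covariate names (use "intercept" for the
    constant) to coefficients; sigma coefficients act on the log residual SD.
    sd_intercept_mean / sd_intercept_sigma are the SDs of the per-individual
    random intercepts on the mean (response units) and on log sigma; rho is
    their correlation; ar1, if set, is the within-individual lag-1
    autocorrelation of standardised residuals.
    """

    n_individuals: int = 40
    days_per_individual: int = 80
    beta_mean: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"intercept": 10.0, "temp": -0.8, "daylen": 0.5}
    )
    beta_sigma: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"intercept": 0.3, "temp": 0.15}
    )
    sd_intercept_mean: float = 1.0
    sd_intercept_sigma: float = 0.3
    rho: float = 0.4
    ar1: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.rho) > 1:
            raise ValueError("|rho| must be <= 1")
        if self.sd_intercept_mean < 0 or self.sd_intercept_sigma < 0:
            raise ValueError("random-intercept SDs must be >= 0")
        if abs(self.rho) == 1 and self.sd_intercept_mean > 0 and self.sd_intercept_sigma > 0:
            raise ValueError("rho = +/-1 with nonzero SDs gives a singular covariance")
        if self.ar1 is not None and not (-1 < self.ar1 < 1):
            raise ValueError("ar1 must lie in (-1, 1)")


def make_dhglm_design(config: DhglmSimConfig) -> pd.DataFrame:
    """One row per individual-day with standard-normal covariates."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    names = sorted(
        (set(config.beta_mean) | set(config.beta_sigma)) - {"intercept"}
    )
    m, d = config.n_individuals, config.days_per_individual
    df = pd.DataFrame(
        {
            "individual": np.repeat([f"ind{i:03d}" for i in range(m)], d),
            "day": np.tile(np.arange(d), m),
        }
    )
    for name in names:
        df[name] = rng.standard_normal(m * d)
    return df


def _design_matrix(design: pd.DataFrame, beta: dict[str, float]) -> tuple[np.ndarray, np.ndarray]:
    cols = []
    for name in beta:
        if name == "intercept":
            cols.append(np.ones(len(design)))
        else:
            if name not in design.columns:
                raise ValueError(f"covariate {name!r} missing from design table")
            cols.append(design[name].to_numpy(dtype=float))
    X = np.column_stack(cols)
    b = np.array(list(beta.values()), dtype=float)
    return X, b


def simulate_dhglm_data(
    config: DhglmSimConfig, design: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, dict]:
    """Draw observations from the double-hierarchical Gaussian model.

    y_ij ~ Normal(X_ij b_mean + a_i,  exp(Z_ij b_sigma + b_i)^2) with
    (a_i, b_i) bivariate normal (SDs sd_intercept_mean / sd_intercept_sigma,
    correlation rho) and optional AR(1) on standardised residuals within
    individual.  Returns the observation table (column ``y`` appended to the
    design) and a dict with the latent truth (a, b, individual order).
    Deterministic given ``config.seed``.
    """
    if design is None:
        design = make_dhglm_design(config)
    rng = np.random.default_rng(config.seed)
    ids, idx = np.unique(design["individual"].to_numpy(), return_inverse=True)
    m = len(ids)

    sa, sb, rho = config.sd_intercept_mean, config.sd_intercept_sigma, config.rho
    z1, z2 = rng.standard_normal(m), rng.standard_normal(m)
    a = sa * z1
    b = sb * (rho * z1 + np.sqrt(max(1.0 - rho**2, 0.0)) * z2)

    X, bm = _design_matrix(design, config.beta_mean)
    Z, bs = _design_matrix(design, config.beta_sigma)
    mu = X @ bm + a[idx]
    sd = np.exp(Z @ bs + b[idx])

    eta = rng.standard_normal(len(design))
    if config.ar1 is not None:
        phi = config.ar1
        r = np.empty_like(eta)
        for i in range(m):
            sel = np.flatnonzero(idx == i)
            ri = np.empty(len(sel))
            ri[0] = eta[sel[0]]
            for t in range(1, len(sel)):
                ri[t] = phi * ri[t - 1] + np.sqrt(1.0 - phi**2) * eta[sel[t]]
            r[sel] = ri
    else:
        r = eta

    out = design.copy()
    out["y"] = mu + sd * r
    truth = {
        "individuals": ids,
        "a": a,
        "b": b,
        "beta_mean": dict(config.beta_mean),
        "beta_sigma": dict(config.beta_sigma),
        "sd_intercept_mean": sa,
        "sd_intercept_sigma": sb,
        "rho": rho,
        "ar1": config.ar1,
    }
    return out, truth
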