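"""Per-animal, per-24 h sleep quantity, efficiency, quality and timing.

From a list of sleep bouts this module derives, for every local civil day
(midnight to midnight):

* **TST** -- total sleep time in hours (sleep quantity);
* **n_bouts** -- number of sleep bouts starting that day (fragmentation /
  efficiency: fewer bouts = more consolidated sleep);
* **longest_bout** -- duration in minutes of the longest bout of the day
  (sleep quality: the best opportunity for deep sleep), plus its natural log
  for modelling;
* **DS** -- distribution of sleep: the percentage of the day's sleep that
  falls between sunrise and sunset (diurnality of sleep timing).

Bout attribution rules: a bout spanning midnight contributes its sleep
seconds to each day it overlaps; it is *counted* (and eligible for
longest_bout, with its within-day portion) only in the day containing its
post-trim start.  The first and last calendar days of the recording span are
dropped as incomplete 24 h periods.  Day boundaries are local civil time
(DST-aware through the IANA timezone database), sunrise/sunset come from the
NOAA solar-position algorithm.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

from .classify import SleepBout

__all__ = ["DailySleepRecord", "sun_times", "daily_metrics"]

#: solar zenith at sunrise/sunset including refraction and solar radius
_ZENITH_DEG = 90.833


@dataclasses.dataclass
class DailySleepRecord:
    """Sleep summary for one animal and one local calendar day."""

    animal_id: str
    date: _dt.date
    tst: float  # hours
    n_bouts: int
    longest_bout: float  # minutes, within-day portion of the longest bout
    log_longest_bout: float  # ln(minutes); NaN when no bout starts this day
    ds: float  # percent of the day's sleep between sunrise and sunset; NaN if tst == 0
    day_length: float  # hours
    civil_day_hours: float = 24.0  # 23 or 25 across DST transitions

    def __post_init__(self) -> None:
        if not (0.0 <= self.tst <= self.civil_day_hours + 1e-9):
            raise ValueError(f"tst {self.tst} outside the civil day on {self.date}")
        if self.n_bouts < 0:
            raise ValueError("n_bouts must be >= 0")
        if self.tst > 0 and not np.isnan(self.ds) and not (-1e-9 <= self.ds <= 100 + 1e-9):
            raise ValueError(f"ds {self.ds} outside [0, 100]")


def _solar_terms(day_of_year: int, hours_utc: float, leap: bool):
    """NOAA fractional-year Fourier series: declination (rad), eqtime (min)."""
    denom = 366.0 if leap else 365.0
    g = 2.0 * np.pi / denom * (day_of_year - 1 + (hours_utc - 12.0) / 24.0)
    decl = (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * np.cos(g)
        - 0.032077 * np.sin(g)
        - 0.014615 * np.cos(2 * g)
        - 0.040849 * np.sin(2 * g)
    )
    return decl, eqtime


def sun_times(
    date: _dt.date | str,
    lat: float,
    lon: float,
    tz: str = "UTC",
) -> tuple[pd.Timestamp, pd.Timestamp, float]:
    """Sunrise, sunset (tz-aware) and day length in hours for one date.

    Standard NOAA solar geometry with the conventional 90.833 deg zenith
    (atmospheric refraction plus the solar radius).  Raises for polar
    day/night, naming the date.
    """
    date = pd.Timestamp(date).date()
    doy = date.timetuple().tm_yday
    leap = date.year % 4 == 0 and (date.year % 100 != 0 or date.year % 400 == 0)
    decl, eqtime = _solar_terms(doy, 12.0, leap)

    lat_r = np.radians(lat)
    cos_ha = np.cos(np.radians(_ZENITH_DEG)) / (np.cos(lat_r) * np.cos(decl)) - np.tan(
        lat_r
    ) * np.tan(decl)
    if not -1.0 <= cos_ha <= 1.0:
        raise ValueError(f"polar day or night at lat {lat} on {date}: no sunrise/sunset")
    ha_deg = np.degrees(np.arccos(cos_ha))

    midnight_utc = pd.Timestamp(date, tz="UTC")
    sunrise = midnight_utc + pd.Timedelta(minutes=720.0 - 4.0 * (lon + ha_deg) - eqtime)
    sunset = midnight_utc + pd.Timedelta(minutes=720.0 - 4.0 * (lon - ha_deg) - eqtime)
    day_length = (sunset - sunrise).total_seconds() / 3600.0
    zone = ZoneInfo(tz)
    return sunrise.tz_convert(zone), sunset.tz_convert(zone), day_length


def _overlap_seconds(bouts_s: np.ndarray, bouts_e: np.ndarray, lo, hi) -> np.ndarray:
    lo_ns, hi_ns = lo.value, hi.value
    s = np.maximum(bouts_s, lo_ns)
    e = np.minimum(bouts_e, hi_ns)
    return np.maximum(e - s, 0) / 1e9


def daily_metrics(
    bouts: list[SleepBout],
    span: tuple[pd.Timestamp, pd.Timestamp],
    lat: float,
    lon: float,
    tz: str = "UTC",
    drop_edge_days: bool = True,
    day_anchor: str = "midnight",
) -> list[DailySleepRecord]:
    """Aggregate sleep bouts into daily records for one animal.

    ``span`` is the recording interval (naive timestamps are interpreted in
    ``tz``).  ``day_anchor`` is ``"midnight"`` (civil days, default) or
    ``"noon"`` (noon-to-noon windows, for nocturnal-sleep analyses; record
    dates then name the window's starting day).  First and last (partial)
    days are dropped unless ``drop_edge_days=False``.
    """
    if day_anchor not in ("midnight", "noon"):
        raise ValueError("day_anchor must be 'midnight' or 'noon'")
    zone = ZoneInfo(tz)

    def _localize(ts: pd.Timestamp) -> pd.Timestamp:
        ts = pd.Timestamp(ts)
        return ts.tz_localize(zone) if ts.tzinfo is None else ts.tz_convert(zone)

    span_lo, span_hi = _localize(span[0]), _localize(span[1])
    if span_hi <= span_lo:
        raise ValueError("empty recording span")

    animal_ids = {b.animal_id for b in bouts}
    if len(animal_ids) > 1:
        raise ValueError("daily_metrics expects bouts from a single animal")
    animal_id = animal_ids.pop() if animal_ids else "animal"

    starts = np.array([_localize(b.start).value for b in bouts], dtype="int64")
    ends = np.array([_localize(b.end).value for b in bouts], dtype="int64")
    if len(starts) and (starts.min() < span_lo.value - 1 or ends.max() > span_hi.value + 1):
        raise ValueError("bouts extend outside the recording span")

    anchor_h = 0 if day_anchor == "midnight" else 12
    first_day = span_lo.date()
    last_day = span_hi.date()
    n_days = (last_day - first_day).days + 1
    days = [first_day + _dt.timedelta(days=k) for k in range(n_days)]
    if drop_edge_days:
        days = days[1:-1]

    records = []
    for day in days:
        lo = pd.Timestamp(_dt.datetime.combine(day, _dt.time(hour=anchor_h)), tz=zone)
        hi = pd.Timestamp(
            _dt.datetime.combine(day + _dt.timedelta(days=1), _dt.time(hour=anchor_h)),
            tz=zone,
        )
        civil_hours = (hi - lo).total_seconds() / 3600.0

        day_secs = _overlap_seconds(starts, ends, lo, hi)
        tst = float(day_secs.sum()) / 3600.0

        in_day = (starts >= lo.value) & (starts < hi.value)
        n_bouts = int(in_day.sum())
        longest_min = float(day_secs[in_day].max()) / 60.0 if n_bouts else 0.0
        log_longest = float(np.log(longest_min)) if longest_min > 0 else float("nan")

        sunrise, sunset, day_length = sun_times(day, lat, lon, tz)
        if tst > 0:
            # the window may straddle two daylight periods under a noon anchor
            light_s = 0.0
            for d in (day, day + _dt.timedelta(days=1)):
                sr, ss, _ = sun_times(d, lat, lon, tz)
                a, b = max(sr, lo), min(ss, hi)
                if b > a:
                    light_s += float(_overlap_seconds(starts, ends, a, b).sum())
            ds = 100.0 * light_s / (tst * 3600.0)
        else:
            ds = float("nan")

        records.append(
            DailySleepRecord(
                animal_id=animal_id,
                date=day,
                tst=tst,
                n_bouts=n_bouts,
                longest_bout=longest_min,
                log_longest_bout=log_longest,
                ds=ds,
                day_length=day_length,
                civil_day_hours=civil_hours,
            )
        )
    return records


def records_to_frame(records: list[DailySleepRecord]) -> pd.DataFrame:
    """Daily records as a DataFrame (one row per animal-day)."""
    return pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in records],
            "date": [r.date for r in records],
            "tst_h": [r.tst for r in records],
            "n_bouts": [r.n_bouts for r in records],
            "longest_bout_min": [r.longest_bout for r in records],
            "log_longest_bout": [r.log_longest_bout for r in records],
            "ds_pct": [r.ds for r in records],
            "day_length_h": [r.day_length for r in records],
        }
    )
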