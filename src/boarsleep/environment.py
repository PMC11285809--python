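"""Daily environmental covariates and model-ready design matrices.

Aggregates hourly weather records into daily summaries (means for
temperature, humidity, snow depth and cloud cover; totals for
precipitation), computes the cloud-adjusted moon phase

    moon_adj = moon_phase * (1 - cloud_cover / 100)

which scales the lunar phase (0 = new, 1 = full) down by fractional cloud
cover to approximate realized night brightness, and builds standardised
design matrices (mean part and sigma part) for the hierarchical models.
Continuous covariates are centred and scaled to SD 1; quadratic terms are
raw squares of the standardised covariate; categorical covariates are
one-hot encoded against a stated reference level.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = [
    "aggregate_hourly",
    "moon_adjusted",
    "FormulaSpec",
    "DesignMatrices",
    "build_design",
    "merge_sleep_environment",
]

_HOURLY_MEAN_FIELDS = {
    "temp_c": "temp_mean",
    "humidity_pct": "humidity_mean",
    "snow_cm": "snow_mean",
    "cloud_pct": "cloud_mean",
}


def aggregate_hourly(
    hourly: pd.DataFrame, completeness_floor: float = 0.75
) -> pd.DataFrame:
    """Collapse hourly weather records to one row per site and date.

    Expects columns ``timestamp``, ``site`` and any of ``temp_c``,
    ``humidity_pct``, ``snow_cm``, ``cloud_pct`` (daily means) and
    ``precip_mm`` (daily total).  Days with fewer than
    ``completeness_floor`` * 24 hourly records are flagged ``incomplete``;
    days with no records at all simply do not appear (callers must treat
    absent site-dates as missing, never as zero).
    """
    df = hourly.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["date"] = df["timestamp"].dt.date
    grouped = df.groupby(["site", "date"], sort=True)

    out = pd.DataFrame(index=grouped.size().index)
    out["n_hours"] = grouped.size()
    for src, dst in _HOURLY_MEAN_FIELDS.items():
        if src in df.columns:
            out[dst] = grouped[src].mean()
    if "precip_mm" in df.columns:
        out["precip_total"] = grouped["precip_mm"].sum()
    out["incomplete"] = out["n_hours"] < completeness_floor * 24
    return out.reset_index()


def moon_adjusted(moon_phase, cloud_cover):
    """Cloud-adjusted moon phase: phase minus cloud cover's share of it.

    ``moon_phase`` in [0, 1], ``cloud_cover`` in percent [0, 100]; returns
    phase * (1 - cloud/100), elementwise for array inputs.
    """
    phase = np.asarray(moon_phase, dtype=float)
    cloud = np.asarray(cloud_cover, dtype=float)
    if np.any((phase < 0) | (phase > 1)):
        raise ValueError("moon_phase must lie in [0, 1]")
    if np.any((cloud < 0) | (cloud > 100)):
        raise ValueError("cloud_cover must lie in [0, 100] percent")
    out = phase * (1.0 - cloud / 100.0)
    return float(out) if out.ndim == 0 else out


@dataclasses.dataclass
class FormulaSpec:
    """Which covariates enter the mean and sigma linear predictors.

    ``quadratic`` lists covariates whose standardised square is added as an
    extra column (raw polynomial on the standardised scale).  ``categorical``
    maps column names to their reference level for one-hot coding.
    """

    response: str
    mean_covariates: list[str]
    sigma_covariates: list[str] = dataclasses.field(default_factory=list)
    quadratic: list[str] = dataclasses.field(default_factory=list)
    categorical: dict[str, str] = dataclasses.field(default_factory=dict)


@dataclasses.dataclass
class DesignMatrices:
    """Standardised design matrices plus the statistics to undo the scaling."""

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    x_names: list[str]
    z_names: list[str]
    scaling: dict[str, tuple[float, float]]  # name -> (mean, sd)
    individuals: np.ndarray | None

    def destandardise(self, name: str, values):
        mean, sd = self.scaling[name]
        return np.asarray(values) * sd + mean


def _encode(df: pd.DataFrame, names: list[str], spec: FormulaSpec, scaling: dict):
    cols: list[np.ndarray] = [np.ones(len(df))]
    labels = ["intercept"]
    for name in names:
        if name in spec.categorical:
            ref = spec.categorical[name]
            levels = sorted(df[name].astype(str).unique())
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} absent from {name!r}")
            for lv in levels:
                if lv == ref:
                    continue
                cols.append((df[name].astype(str) == lv).to_numpy(dtype=float))
                labels.append(f"{name}[{lv}]")
            continue
        x = df[name].to_numpy(dtype=float)
        mean, sd = float(np.mean(x)), float(np.std(x, ddof=0))
        if sd == 0:
            raise ValueError(f"covariate {name!r} has zero variance")
        scaling[name] = (mean, sd)
        z = (x - mean) / sd
        cols.append(z)
        labels.append(name)
        if name in spec.quadratic:
            cols.append(z**2)
            labels.append(f"{name}^2")
    return np.column_stack(cols), labels


def build_design(
    table: pd.DataFrame, spec: FormulaSpec, id_col: str = "animal_id"
) -> DesignMatrices:
    """Build mean-part and sigma-part design matrices from the merged table.

    Continuous covariates are standardised (statistics stored for the inverse
    transform); quadratic columns are squares of the standardised covariate;
    an intercept column is always first.  Zero-variance covariates raise,
    naming the offender.
    """
    if table[spec.response].isna().any():
        raise ValueError("response contains missing values")
    scaling: dict[str, tuple[float, float]] = {}
    X, x_names = _encode(table, spec.mean_covariates, spec, scaling)
    Z, z_names = _encode(table, spec.sigma_covariates, spec, scaling)
    y = table[spec.response].to_numpy(dtype=float)
    ymean, ysd = float(np.mean(y)), float(np.std(y, ddof=0))
    scaling[spec.response] = (ymean, ysd)
    return DesignMatrices(
        y=y,
        X=X,
        Z=Z,
        x_names=x_names,
        z_names=z_names,
        scaling=scaling,
        individuals=table[id_col].to_numpy() if id_col in table.columns else None,
    )


def merge_sleep_environment(
    daily_sleep: pd.DataFrame,
    env: pd.DataFrame,
    site_of_animal: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Join daily sleep records with the environmental table on (site, date).

    ``daily_sleep`` needs ``animal_id`` and ``date`` columns plus either a
    ``site`` column or a ``site_of_animal`` mapping.  Inner join; exactly one
    row per animal-day present in both tables, duplicates raise.
    """
    sleep = daily_sleep.copy()
    if "site" not in sleep.columns:
        if site_of_animal is None:
            raise ValueError("daily_sleep has no 'site' column and no mapping given")
        sleep["site"] = sleep["animal_id"].map(site_of_animal)
        if sleep["site"].isna().any():
            missing = sleep.loc[sleep["site"].isna(), "animal_id"].unique()
            raise ValueError(f"no site mapping for animals: {list(missing)}")
    if sleep.duplicated(["animal_id", "date"]).any():
        raise ValueError("duplicate animal-day rows in daily_sleep")
    if env.duplicated(["site", "date"]).any():
        raise ValueError("duplicate site-date rows in environment table")
    merged = sleep.merge(env, on=["site", "date"], how="inner", validate="m:1")
    return merged
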