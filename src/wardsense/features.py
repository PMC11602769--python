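"""Hourly sensor feature engineering.

Turns a minute-cadence :class:`~wardsense.cohort.SensorStream` into the
29-dimensional hourly feature series the sequence models consume (31
with age and sex appended downstream):

* 8 window statistics (first, last, mean, median, max, min, SD, number
  of unique values) for total acceleration and for heart rate (16),
* cumulative calories, sleep index, steps and distance per hour (4),
* location variance and time-fraction in each of the 4 semantic zones
  (room, hallway, other, no signal) (5),
* Shannon location entropy and its normalized form over daily and
  8-hour periods, broadcast to the hours each period covers (4).

Missing cells (device-off episodes, empty periods) are completed with
an iterative soft-thresholded-SVD matrix completion (soft-impute), and
participants whose raw streams are more than 50% missing are excluded
before modelling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .cohort import CohortBundle, SensorStream

ZONE_ALPHABET = ("room", "hallway", "other", "no_signal")
LN4 = math.log(4.0)

STAT_NAMES = ("first", "last", "mean", "median", "max", "min", "sd", "nunique")

#: the 29 hourly sensor features, fixed order (serialized with models)
FEATURE_REGISTRY: tuple[str, ...] = (
    tuple(f"{s}_ACC" for s in STAT_NAMES)
    + tuple(f"{s}_HEARTBEAT" for s in STAT_NAMES)
    + ("calories", "sleep_index", "steps", "distance")
    + ("location_variance",)
    + tuple(f"place_{z}" for z in ZONE_ALPHABET)
    + ("Location_Entropy_Daily", "Location_Normalized_Entropy_Daily",
       "Location_Entropy_8hr", "Location_Normalized_Entropy_8hr")
)
assert len(FEATURE_REGISTRY) == 29

#: full model-input registry: sensor features + the 2 nonsensor columns
INPUT_REGISTRY: tuple[str, ...] = FEATURE_REGISTRY + ("age", "sex")

# device-native resolutions used when counting unique values
HR_RESOLUTION = 1.0       # bpm
ACC_RESOLUTION = 0.01     # g

# valid ranges enforced on imputed cells (observed cells are never altered)
_BOUNDS: dict[str, tuple[float | None, float | None]] = {
    **{f"nunique_{c}": (0.0, None) for c in ("ACC", "HEARTBEAT")},
    **{f"sd_{c}": (0.0, None) for c in ("ACC", "HEARTBEAT")},
    "calories": (0.0, None), "steps": (0.0, None), "distance": (0.0, None),
    "sleep_index": (30.0 / 24.0, 100.0 / 24.0),
    "location_variance": (0.0, None),
    **{f"place_{z}": (0.0, 1.0) for z in ZONE_ALPHABET},
    "Location_Entropy_Daily": (0.0, LN4),
    "Location_Entropy_8hr": (0.0, LN4),
    "Location_Normalized_Entropy_Daily": (0.0, 1.0),
    "Location_Normalized_Entropy_8hr": (0.0, 1.0),
}


class DataValidationError(ValueError):
    """Raised when an input stream violates a feature-stage contract."""


@dataclass
class FeatureConfig:
    """Tunables of the feature stage (soft-impute and exclusion)."""

    exclusion_threshold: float = 0.50   # exclude if missing fraction strictly exceeds
    impute_rank_max: int = 10
    impute_lam_ratio: float = 0.1       # lambda = ratio * sigma_1(zero-filled matrix)
    impute_tol: float = 1e-5
    impute_max_iter: int = 100


@dataclass
class FeatureSeries:
    """Hourly 29-column feature matrix for one participant."""

    participant_id: str
    features: pd.DataFrame            # DatetimeIndex (hour starts) x FEATURE_REGISTRY
    missing_fraction: float           # raw-stream device-off fraction, pre-imputation

    @property
    def hour_index(self) -> pd.DatetimeIndex:
        return self.features.index

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / f"{self.participant_id}.csv"
        self.features.rename_axis("hour").to_csv(path, float_format="%.8g")
        import json
        (out / f"{self.participant_id}.json").write_text(json.dumps(
            {"participant_id": self.participant_id,
             "missing_fraction": self.missing_fraction,
             "n_hours": int(len(self.features))}))
        return path

    @classmethod
    def load(cls, out_dir: str | Path, participant_id: str) -> "FeatureSeries":
        import json
        out = Path(out_dir)
        df = pd.read_csv(out / f"{participant_id}.csv", index_col="hour",
                         parse_dates=["hour"])
        meta = json.loads((out / f"{participant_id}.json").read_text())
        return cls(participant_id, df[list(FEATURE_REGISTRY)],
                   float(meta["missing_fraction"]))


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def total_acceleration(ax, ay, az):
    """Magnitude of the summed acceleration vector, √(ax²+ay²+az²).

    Missing whenever any component is missing.
    """
    ax, ay, az = (np.asarray(v, dtype=float) for v in (ax, ay, az))
    return np.sqrt(ax ** 2 + ay ** 2 + az ** 2)


def window_stats(values, nunique_resolution: float | None = None) -> np.ndarray:
    """The 8 within-window statistics in registry order:
    first, last, mean, median, max, min, SD (sample, n−1), nunique.

    Missing samples are ignored; an all-missing window yields 8 NaN.
    ``nunique_resolution`` rounds values to the device's native
    resolution before counting distinct values.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return np.full(8, np.nan)
    sd = float(np.std(v, ddof=1)) if v.size > 1 else np.nan
    q = v if nunique_resolution is None else np.round(v / nunique_resolution)
    return np.array([v[0], v[-1], float(np.mean(v)), float(np.median(v)),
                     float(np.max(v)), float(np.min(v)), sd,
                     float(np.unique(q).size)])


def sleep_index_score(duration_hours):
    """Map cumulative daily sleep duration (hours) onto the device's
    30–100 score: 30 at ≤2.25 h, 100 at ≥7.5 h, linear in between."""
    d = np.asarray(duration_hours, dtype=float)
    score = 30.0 + 70.0 * (d - 2.25) / (7.5 - 2.25)
    return np.clip(score, 30.0, 100.0)


def _window_slice(stream: SensorStream, window) -> pd.DataFrame:
    start, end = (pd.Timestamp(t) for t in window)
    df = stream.data
    m = (df["timestamp"] >= start) & (df["timestamp"] < end)
    return df.loc[m]


def cumulative_features(stream: SensorStream, window) -> dict[str, float]:
    """Cumulative calories, sleep-index contribution, steps and distance
    over a half-open window ``[start, end)``.

    The sleep-index contribution is the participant's daily sleep-index
    score prorated uniformly over the day's 24 hourly rows, so the
    cumulative value over a full day equals the daily score. Counts and
    distance are 0 for a window with no samples; the sleep index is
    missing there.
    """
    sub = _window_slice(stream, window)
    for col in ("calories", "steps", "distance"):
        if (sub[col].dropna() < 0).any():
            raise DataValidationError(f"negative increments in '{col}'")
    if len(sub) == 0:
        return {"calories": 0.0, "sleep_index": float("nan"),
                "steps": 0.0, "distance": 0.0}
    out = {}
    for col in ("calories", "steps", "distance"):
        s = sub[col].sum(min_count=1)
        out[col] = float(s) if pd.notna(s) else float("nan")
    day = pd.Timestamp(window[0]).floor("D")
    daily = daily_sleep_index(stream)
    score = daily.get(day, float("nan"))
    hours = (pd.Timestamp(window[1]) - pd.Timestamp(window[0])) / pd.Timedelta(hours=1)
    out["sleep_index"] = float(score) * hours / 24.0
    return out


def daily_sleep_index(stream: SensorStream) -> pd.Series:
    """Per-calendar-day sleep-index score from the stream's sleep flag.

    Days with no observed samples are missing.
    """
    df = stream.data
    day = df["timestamp"].dt.floor("D")
    flagged = df["sleep_flag"].groupby(day).sum(min_count=1) / 60.0  # hours
    observed = df["sleep_flag"].groupby(day).count()
    score = pd.Series(sleep_index_score(flagged.to_numpy()), index=flagged.index)
    score[observed == 0] = np.nan
    return score


def location_features(stream: SensorStream, window) -> dict[str, float]:
    """Location variance (var x + var y over non-missing fixes, sample
    denominator) and the fraction of observed window time spent in each
    semantic zone."""
    sub = _window_slice(stream, window)
    x = sub["loc_x"].dropna()
    y = sub["loc_y"].dropna()
    var = float(x.var(ddof=1) + y.var(ddof=1)) if len(x) > 1 else float("nan")
    zones = sub["zone"].dropna()
    out = {"location_variance": var}
    if len(zones) == 0:
        for z in ZONE_ALPHABET:
            out[f"place_{z}"] = float("nan")
    else:
        counts = zones.value_counts()
        for z in ZONE_ALPHABET:
            out[f"place_{z}"] = float(counts.get(z, 0)) / len(zones)
    return out


def location_entropy(stream: SensorStream, period: str = "daily") -> pd.DataFrame:
    """Shannon entropy (natural log) of the time-fraction distribution
    over the 4 semantic zones within each period, plus the normalized
    form (entropy / ln 4).

    ``period`` is ``"daily"`` (midnight-delimited) or ``"8hr"``
    (delimited at 00:00, 08:00, 16:00). Periods with no observed zone
    samples are missing. Returns a frame indexed by period start.
    """
    if period not in ("daily", "8hr"):
        raise ValueError(f"unknown period {period!r}")
    df = stream.data
    ts = df["timestamp"]
    if period == "daily":
        key = ts.dt.floor("D")
    else:
        key = ts.dt.floor("D") + pd.to_timedelta((ts.dt.hour // 8) * 8, unit="h")
    zones = df["zone"]
    tab = pd.crosstab(key[zones.notna()], zones.dropna())
    for z in ZONE_ALPHABET:
        if z not in tab.columns:
            tab[z] = 0
    tab = tab[list(ZONE_ALPHABET)]
    totals = tab.sum(axis=1)
    p = tab.div(totals, axis=0).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.nansum(np.where(p > 0, p * np.log(p), 0.0), axis=1)
    out = pd.DataFrame({"entropy": h, "normalized_entropy": h / LN4},
                       index=tab.index)
    full_idx = pd.Index(sorted(key.unique()), name="period")
    return out.reindex(full_idx)


# ---------------------------------------------------------------------------
# soft-impute
# ---------------------------------------------------------------------------

def soft_impute(X: np.ndarray, rank_max: int = 10, lam: float | None = None,
                tol: float = 1e-5, max_iter: int = 100, standardize: bool = True,
                column_names: Iterable[str] | None = None) -> np.ndarray:
    """Complete missing cells by iterative soft-thresholded SVD.

    Repeat {fill missing cells with the current low-rank estimate; SVD;
    shrink singular values by ``lam`` and truncate to ``rank_max``;
    rebuild} until the relative Frobenius change falls below ``tol``.
    Observed cells are restored exactly. ``lam`` defaults to
    ``0.1 × σ₁`` of the zero-filled matrix. Columns are standardized
    before completion and de-standardized after.
    """
    X = np.asarray(X, dtype=float)
    names = list(column_names) if column_names is not None else \
        [str(j) for j in range(X.shape[1])]
    miss = np.isnan(X)
    dead = miss.all(axis=0)
    if dead.any():
        bad = [names[j] for j in np.flatnonzero(dead)]
        raise DataValidationError(f"fully missing column(s): {bad}")
    if not miss.any():
        return X.copy()

    if standardize:
        mu = np.nanmean(X, axis=0)
        sd = np.nanstd(X, axis=0)
        sd = np.where(sd > 0, sd, 1.0)
    else:
        mu = np.zeros(X.shape[1])
        sd = np.ones(X.shape[1])
    Z = (X - mu) / sd
    obs = ~miss
    filled = np.where(obs, Z, 0.0)
    if lam is None:
        s1 = np.linalg.svd(filled, compute_uv=False)[0]
        lam = 0.1 * s1
    M = np.zeros_like(filled)
    for _ in range(max_iter):
        work = np.where(obs, Z, M)
        U, s, Vt = np.linalg.svd(work, full_matrices=False)
        s = np.maximum(s - lam, 0.0)[:rank_max]
        M_new = (U[:, :len(s)] * s) @ Vt[:len(s)]
        denom = max(np.linalg.norm(M), 1.0)
        delta = np.linalg.norm(M_new - M) / denom
        M = M_new
        if delta < tol:
            break
    out = M * sd + mu
    out[obs] = X[obs]          # observed cells restored exactly
    return out


def impute_missing(features: pd.DataFrame, config: FeatureConfig | None = None
                   ) -> pd.DataFrame:
    """Soft-impute a feature matrix; imputed cells of bounded columns
    are clipped to the column's valid range, observed cells untouched."""
    cfg = config or FeatureConfig()
    X = features.to_numpy(dtype=float)
    miss = np.isnan(X)
    if miss.any():
        mu = np.nanmean(X, axis=0)
        sd = np.nanstd(X, axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        filled = np.where(miss, 0.0, (X - mu) / sd)
        s1 = np.linalg.svd(filled, compute_uv=False)[0]
        lam = cfg.impute_lam_ratio * s1
    else:
        lam = 0.0
    done = soft_impute(X, rank_max=cfg.impute_rank_max, lam=lam,
                       tol=cfg.impute_tol, max_iter=cfg.impute_max_iter,
                       column_names=features.columns)
    for j, col in enumerate(features.columns):
        lo, hi = _BOUNDS.get(col, (None, None))
        if lo is not None or hi is not None:
            m = miss[:, j]
            done[m, j] = np.clip(done[m, j], lo if lo is not None else -np.inf,
                                 hi if hi is not None else np.inf)
    return pd.DataFrame(done, index=features.index, columns=features.columns)


# ---------------------------------------------------------------------------
# exclusion
# ---------------------------------------------------------------------------

def exclude_participants(missing_fractions: Mapping[str, float],
                         threshold: float = 0.50
                         ) -> tuple[list[str], pd.DataFrame]:
    """Retain participants whose raw-stream missing fraction does not
    strictly exceed ``threshold``; return the retained ids and a log."""
    rows = []
    retained = []
    for pid, frac in missing_fractions.items():
        excluded = frac > threshold
        rows.append({"participant_id": pid, "missing_fraction": frac,
                     "excluded": excluded,
                     "reason": f"missing fraction {frac:.3f} > {threshold:.2f}"
                     if excluded else ""})
        if not excluded:
            retained.append(pid)
    return retained, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full hourly assembly
# ---------------------------------------------------------------------------

def build_feature_series(stream: SensorStream,
                         config: FeatureConfig | None = None,
                         impute: bool = True) -> FeatureSeries:
    """One row per hour of the stay, 29 registry-ordered columns;
    soft-impute applied after assembly."""
    cfg = config or FeatureConfig()
    df = stream.data
    if len(df) < 60:
        raise DataValidationError("stay must cover at least 1 hour")
    ts = df["timestamp"]
    hour = ts.dt.floor("h")

    acc = total_acceleration(df["accel_x"], df["accel_y"], df["accel_z"])
    work = pd.DataFrame({"hour": hour, "acc": acc, "hr": df["heart_rate"]})

    def _stats(col: str, res: float) -> pd.DataFrame:
        g = work.groupby("hour")[col]
        agg = g.agg(first="first", last="last", mean="mean", median="median",
                    max="max", min="min", sd=lambda v: v.std(ddof=1))
        nun = work.assign(q=np.round(work[col] / res)).groupby("hour")["q"].nunique()
        agg["nunique"] = nun.astype(float)
        agg.loc[g.count() == 0, :] = np.nan
        return agg

    acc_stats = _stats("acc", ACC_RESOLUTION)
    hr_stats = _stats("hr", HR_RESOLUTION)

    hours = pd.date_range(hour.iloc[0], hour.iloc[-1], freq="1h")
    out = pd.DataFrame(index=hours)
    for s in STAT_NAMES:
        out[f"{s}_ACC"] = acc_stats[s].reindex(hours)
    for s in STAT_NAMES:
        out[f"{s}_HEARTBEAT"] = hr_stats[s].reindex(hours)

    # cumulatives
    for col in ("calories", "steps", "distance"):
        if (df[col].dropna() < 0).any():
            raise DataValidationError(f"negative increments in '{col}'")
        s = df.groupby(hour)[col].sum(min_count=1).reindex(hours)
        out[col] = s
    daily = daily_sleep_index(stream)
    out["sleep_index"] = daily.reindex(hours.floor("D")).to_numpy() / 24.0

    # location variance + place fractions
    gx = df.groupby(hour)["loc_x"]
    gy = df.groupby(hour)["loc_y"]
    var = (gx.var(ddof=1) + gy.var(ddof=1)).reindex(hours)
    out["location_variance"] = var
    zones = df["zone"]
    tab = pd.crosstab(hour[zones.notna()], zones.dropna())
    for z in ZONE_ALPHABET:
        if z not in tab.columns:
            tab[z] = 0
    tot = tab[list(ZONE_ALPHABET)].sum(axis=1)
    for z in ZONE_ALPHABET:
        out[f"place_{z}"] = (tab[z] / tot).reindex(hours)

    # entropies broadcast from their periods
    for period, tag in (("daily", "Daily"), ("8hr", "8hr")):
        ent = location_entropy(stream, period)
        if period == "daily":
            key = hours.floor("D")
        else:
            key = hours.floor("D") + pd.to_timedelta((hours.hour // 8) * 8, unit="h")
        out[f"Location_Entropy_{tag}"] = ent["entropy"].reindex(key).to_numpy()
        out[f"Location_Normalized_Entropy_{tag}"] = \
            ent["normalized_entropy"].reindex(key).to_numpy()

    out = out[list(FEATURE_REGISTRY)]

    # raw missing fraction: device-off = all sensor channels absent
    off = df[["heart_rate", "accel_x", "steps"]].isna().all(axis=1)
    missing_fraction = float(off.mean())

    if impute:
        out = impute_missing(out, cfg)
    return FeatureSeries(participant_id=stream.participant_id,
                         features=out, missing_fraction=missing_fraction)


def featurize_cohort(bundle: CohortBundle,
                     config: FeatureConfig | None = None
                     ) -> tuple[dict[str, FeatureSeries], pd.DataFrame]:
    """Featurize every stream in a cohort and apply the missing-data
    exclusion rule. Returns retained series and the exclusion log."""
    cfg = config or FeatureConfig()
    fractions = {}
    for pid, stream in bundle.streams.items():
        off = stream.data[["heart_rate", "accel_x", "steps"]].isna().all(axis=1)
        fractions[pid] = float(off.mean())
    retained, log = exclude_participants(fractions, cfg.exclusion_threshold)
    series = {pid: build_feature_series(bundle.streams[pid], cfg)
              for pid in retained}
    return series, log
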