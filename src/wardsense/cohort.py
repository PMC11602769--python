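"""Synthetic acute-ward cohort generator.

Simulates multi-ward inpatient cohorts wearing wrist devices: latent
symptom trajectories on the four rating scales, minute-resolution sensor
streams (heart rate, 3-axis acceleration, indoor location, device
cumulatives, a sleep flag), device-removal missingness, and the weekly +
event-triggered assessment schedule. The generator plants known,
monotone couplings from latent severity onto behaviour (sleep duration,
activity level, zone-switch rate, resting heart rate) so that every
downstream stage — feature engineering, example construction, model
fitting and evaluation — can be tested for signal recovery without any
clinical data.

Latent dynamics are AR(1) noise around a drifting baseline plus
compound-Poisson relapse jumps: the simplest process that yields both
gradual improvement during admission and occasional deterioration
events at tunable rates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .scales import DEFAULT_SCALE_RANGES, SCALE_NAMES

STREAM_COLUMNS = [
    "timestamp", "heart_rate", "accel_x", "accel_y", "accel_z",
    "loc_x", "loc_y", "zone", "calories", "steps", "distance", "sleep_flag",
]

ZONES = ("room", "hallway", "other")
ADMISSION_HOUR = 12  # admissions happen at noon, local clock


class ConfigError(ValueError):
    """Invalid simulator configuration."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WardProfile:
    """Static description of one ward and its sensor idiosyncrasies."""

    ward_id: str
    hr_baseline: float = 72.0          # resting HR offset of the ward population, bpm
    activity_scale: float = 1.0        # dimensionless multiplier on daytime activity
    missingness_rate: float = 0.15     # long-run fraction of device-off time
    room_layout: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"room": (0.0, 0.0), "hallway": (10.0, 0.0), "other": (10.0, 8.0)}
    )
    recruitment_window: tuple[date, date] = (date(2023, 5, 26), date(2024, 8, 5))

    def __post_init__(self) -> None:
        if not 0.0 <= self.missingness_rate < 1.0:
            raise ConfigError(f"missingness_rate must be in [0,1), got {self.missingness_rate}")
        if not 40.0 <= self.hr_baseline <= 120.0:
            raise ConfigError(f"hr_baseline must be in [40,120], got {self.hr_baseline}")
        missing = set(ZONES) - set(self.room_layout)
        if missing:
            raise ConfigError(f"room_layout lacks required zones: {sorted(missing)}")
        if self.recruitment_window[0] > self.recruitment_window[1]:
            raise ConfigError("recruitment_window start after end")


@dataclass
class SymptomTrajectory:
    """Hourly latent severity paths for one participant, all four scales."""

    participant_id: str
    times: pd.DatetimeIndex                      # hourly, admission..discharge inclusive
    latent_severity: dict[str, np.ndarray]       # scale -> severity path, clipped to range
    coupling: dict[str, dict[str, float]]        # scale -> channel -> effect size
    jump_events: list[tuple[int, float]] = field(default_factory=list)  # (hour idx, max jump size)

    @property
    def stay_hours(self) -> int:
        return len(self.times) - 1


@dataclass
class SensorStream:
    """Minute-cadence raw multichannel stream for one participant.

    ``data`` holds the columns in STREAM_COLUMNS order; missing values
    are NaN (zone: None). ``missing_fraction`` is the realized fraction
    of device-off time, recorded by :func:`apply_missingness`.
    """

    participant_id: str
    data: pd.DataFrame
    missing_fraction: float = 0.0

    def __post_init__(self) -> None:
        ts = self.data["timestamp"]
        if not ts.is_monotonic_increasing or ts.duplicated().any():
            raise ValueError("timestamps must be strictly increasing")


@dataclass(frozen=True)
class Assessment:
    """One rating event: all four scale totals at a timestamp."""

    participant_id: str
    time: pd.Timestamp
    scores: dict[str, int]
    trigger: str  # "weekly" | "event"


@dataclass
class CohortConfig:
    """Everything needed to generate one cohort reproducibly.

    Couplings are effects per unit *normalized* severity (score divided
    by the scale's range, so 0..1): ``sleep_hours`` shifts nightly sleep
    need in hours, ``activity`` multiplies the waking activity level,
    ``location_switch`` multiplies the zone-switch rate, ``resting_hr``
    shifts heart rate in bpm.
    """

    n_participants: int = 20
    wards: list[WardProfile] = field(default_factory=lambda: default_wards())
    seed: int = 0
    stay_mean_days: float = 21.0
    stay_sd_days: float = 17.5
    stay_min_days: int = 3
    stay_max_days: int = 60

    scale_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_SCALE_RANGES))
    # initial severity marginals, loosely matching acute-ward admission levels
    init_mean: dict[str, float] = field(default_factory=lambda: {
        "BPRS": 21.0, "HAMA": 11.0, "MADRS": 18.0, "YMRS": 11.0})
    init_sd: dict[str, float] = field(default_factory=lambda: {
        "BPRS": 9.0, "HAMA": 6.0, "MADRS": 10.0, "YMRS": 8.0})

    # latent dynamics
    drift_per_day: float = -0.4         # improvement under treatment, points/day
    ar_phi: float = 0.98                # hourly AR(1) persistence of the noise part
    noise_sd: float = 0.25              # hourly innovation SD, score points
    scale_corr: float = 0.35            # exchangeable cross-scale innovation correlation
    jump_rate_per_day: float = 0.05     # relapse events per day
    jump_mean: dict[str, float] = field(default_factory=lambda: {
        "BPRS": 7.0, "HAMA": 4.0, "MADRS": 4.0, "YMRS": 4.0})

    # severity -> behaviour couplings (per unit normalized severity).
    # Each scale loads on a distinct channel combination so the four
    # severities are jointly identifiable from behaviour: psychotic
    # symptoms mainly drive location switching/diversity, anxiety the
    # resting heart rate, depression daytime activity (down) with
    # hypersomnia, mania sleep loss with overactivity.
    coupling: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "BPRS": {"sleep_hours": 0.0, "activity": 0.1, "location_switch": 1.5, "resting_hr": 2.0},
        "HAMA": {"sleep_hours": -0.5, "activity": 0.0, "location_switch": 0.0, "resting_hr": 20.0},
        "MADRS": {"sleep_hours": 1.5, "activity": -1.0, "location_switch": -0.4, "resting_hr": 0.0},
        "YMRS": {"sleep_hours": -3.5, "activity": 0.6, "location_switch": 0.3, "resting_hr": 2.0},
    })

    # emission model
    base_sleep_hours: float = 7.5
    base_activity: float = 0.5          # dimensionless waking activity level
    circadian_act_amp: float = 0.5      # relative day/night modulation of activity
    circadian_hr_amp: float = 6.0       # bpm amplitude of the HR circadian sinusoid
    hr_activity_gain: float = 12.0      # bpm per unit of activity above the daily mean
    sleep_hr_dip: float = 8.0           # bpm reduction while asleep
    hr_noise_sd: float = 3.0            # per-minute HR measurement noise, bpm
    accel_unit_g: float = 0.06          # accel component SD per unit activity, g
    steps_per_min_per_act: float = 8.0
    stride_m: float = 0.7
    kcal_per_min: float = 1.1
    kcal_per_step: float = 0.04
    base_switch_per_hour: float = 2.0
    p_nosignal: float = 0.03            # transient location dropout while worn

    # missingness (device removal)
    missing_episode_mean_min: float = 45.0
    informative_missingness: bool = False   # if True, removal rate doubles at high severity

    # assessment schedule
    rater_noise_sd: float = 2.0
    event_assessment_prob: float = 0.5
    event_threshold: float = 5.0        # minimum jump size that can trigger an extra rating

    # demographics (marginals are not a fidelity goal, but they shift
    # initial severity so that age/sex carry real signal for the
    # between-subject Score task: (points per year from the cohort mean
    # age, points added for female sex))
    age_mean: float = 33.0
    age_sd: float = 14.0
    female_p: float = 0.55
    demo_effects: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "BPRS": (0.0, 0.0), "HAMA": (0.0, 2.0),
        "MADRS": (0.15, 3.0), "YMRS": (-0.15, -2.0)})

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        if not self.wards:
            raise ConfigError("ward list must be non-empty")
        if self.stay_min_days < 1:
            raise ConfigError("stays must last at least 1 day")

    # -- presets -----------------------------------------------------------
    @classmethod
    def strong_signal(cls, n_participants: int = 40, seed: int = 0) -> "CohortConfig":
        """Strong planted coupling, low noise, fixed 4-week stays.

        The configuration under which the pipeline is expected to
        recover the planted sensor-symptom association: couplings are
        tripled, relapse jumps doubled, measurement/rater noise cut,
        and the wards are homogeneous so ward-level distribution shift
        does not act as an extra noise source.
        """
        wards = [dataclasses.replace(w, hr_baseline=72.0, activity_scale=1.0,
                                     missingness_rate=0.10)
                 for w in default_wards()]
        cfg = cls(n_participants=n_participants, seed=seed, wards=wards,
                  stay_mean_days=28.0, stay_sd_days=0.0,
                  stay_min_days=28, stay_max_days=28,
                  noise_sd=0.15, hr_noise_sd=1.0, rater_noise_sd=0.5)
        cfg.jump_mean = {s: 2.0 * v for s, v in cfg.jump_mean.items()}
        cfg.coupling = {s: {k: 3.0 * v for k, v in ch.items()}
                        for s, ch in cfg.coupling.items()}
        cfg.demo_effects = {s: (2.0 * a, 2.0 * f)
                            for s, (a, f) in cfg.demo_effects.items()}
        return cfg

    @classmethod
    def null_signal(cls, n_participants: int = 40, seed: int = 0) -> "CohortConfig":
        """Same conditions as :meth:`strong_signal` but zero coupling."""
        cfg = cls.strong_signal(n_participants=n_participants, seed=seed)
        cfg.coupling = {s: {k: 0.0 for k in ch} for s, ch in cfg.coupling.items()}
        return cfg


def default_wards() -> list[WardProfile]:
    """Four wards across three notional hospitals, with the kind of
    baseline heterogeneity multi-site wearable data shows."""
    return [
        WardProfile("h1_w1", hr_baseline=70.0, activity_scale=1.0, missingness_rate=0.12,
                    recruitment_window=(date(2023, 5, 26), date(2024, 8, 5))),
        WardProfile("h2_wM", hr_baseline=66.0, activity_scale=0.85, missingness_rate=0.18,
                    recruitment_window=(date(2023, 6, 15), date(2024, 8, 5))),
        WardProfile("h2_wF", hr_baseline=74.0, activity_scale=0.9, missingness_rate=0.18,
                    recruitment_window=(date(2023, 6, 15), date(2024, 8, 5))),
        WardProfile("h3_w1", hr_baseline=78.0, activity_scale=1.15, missingness_rate=0.10,
                    recruitment_window=(date(2023, 9, 1), date(2024, 8, 5))),
    ]


@dataclass
class CohortBundle:
    """One generated cohort: streams, ratings, metadata and its config."""

    streams: dict[str, SensorStream]
    assessments: pd.DataFrame   # participant_id, timestamp, BPRS, HAMA, MADRS, YMRS, trigger
    metadata: pd.DataFrame      # participant_id, age, sex, ward, recruitment_date
    config: CohortConfig


# ---------------------------------------------------------------------------
# latent trajectory
# ---------------------------------------------------------------------------

def simulate_symptom_trajectory(participant_id: str, config: CohortConfig,
                                ward: WardProfile, rng: np.random.Generator,
                                stay_days: int | None = None,
                                admission: pd.Timestamp | None = None,
                                age: float | None = None,
                                sex: str | None = None) -> SymptomTrajectory:
    """Draw the four correlated latent severity paths for one stay.

    Each path is ``initial + drift*t + AR(1) noise + relapse jumps``,
    clipped to the scale's configured range. Jump events are shared
    across scales (a relapse raises everything, by per-scale amounts).
    Age and sex, when given, shift the initial severity through
    ``config.demo_effects``.
    """
    if stay_days is None:
        stay_days = _draw_stay_days(config, rng)
    if stay_days < 1:
        raise ConfigError(f"stay length must be >= 1 day, got {stay_days}")
    if admission is None:
        admission = pd.Timestamp(2024, 1, 1, ADMISSION_HOUR)

    n_hours = stay_days * 24
    times = pd.date_range(admission, periods=n_hours + 1, freq="1h")
    k = len(SCALE_NAMES)

    init = np.array([rng.normal(config.init_mean[s], config.init_sd[s]) for s in SCALE_NAMES])
    for j, s in enumerate(SCALE_NAMES):
        slope, female_shift = config.demo_effects.get(s, (0.0, 0.0))
        if age is not None:
            init[j] += slope * (age - config.age_mean)
        if sex is not None:
            init[j] += female_shift * (1.0 if sex == "F" else -1.0)
    # exchangeable-correlation innovations
    corr = np.full((k, k), config.scale_corr) + (1 - config.scale_corr) * np.eye(k)
    chol = np.linalg.cholesky(corr)
    innov = (rng.standard_normal((n_hours + 1, k)) @ chol.T) * config.noise_sd
    z = np.zeros((n_hours + 1, k))
    for t in range(1, n_hours + 1):
        z[t] = config.ar_phi * z[t - 1] + innov[t]

    jumps = np.zeros((n_hours + 1, k))
    events: list[tuple[int, float]] = []
    p_jump = config.jump_rate_per_day / 24.0
    hit = rng.random(n_hours + 1) < p_jump
    for t in np.flatnonzero(hit):
        # concentrated around the per-scale mean (min half the mean) so
        # relapse events are clinically meaningful step changes rather
        # than a mass of negligible bumps
        sizes = np.array([config.jump_mean[s] * (0.5 + rng.exponential(0.5))
                          for s in SCALE_NAMES])
        jumps[t:] += sizes
        events.append((int(t), float(sizes.max())))

    drift = config.drift_per_day * np.arange(n_hours + 1) / 24.0
    latent = {}
    for j, s in enumerate(SCALE_NAMES):
        lo, hi = config.scale_ranges[s]
        path = init[j] + drift + z[:, j] + jumps[:, j]
        latent[s] = np.clip(path, lo, hi)

    return SymptomTrajectory(participant_id=participant_id, times=times,
                             latent_severity=latent, coupling=config.coupling,
                             jump_events=events)


def _draw_stay_days(config: CohortConfig, rng: np.random.Generator) -> int:
    d = rng.normal(config.stay_mean_days, config.stay_sd_days)
    return int(np.clip(round(d), config.stay_min_days, config.stay_max_days))


# ---------------------------------------------------------------------------
# sensor emission
# ---------------------------------------------------------------------------

def emit_sensor_stream(traj: SymptomTrajectory, ward: WardProfile,
                       rng: np.random.Generator, config: CohortConfig) -> SensorStream:
    """Emit the minute-cadence multichannel stream for one trajectory.

    Heart rate = ward baseline + circadian sinusoid + activity term +
    severity-coupled shift + sleep dip + noise. Acceleration components
    are zero-mean with SD proportional to the momentary activity level
    (plus gravity on z), so mean total acceleration rises monotonically
    with activity. Location follows a per-minute Markov chain over the
    ward's zones with a severity-coupled switch rate; device cumulatives
    are derived from the activity profile.
    """
    n_min = traj.stay_hours * 60
    if n_min <= 0:
        raise ValueError("trajectory grid does not cover a positive stay")
    ts = pd.date_range(traj.times[0], periods=n_min, freq="1min")
    hod = ts.hour.to_numpy() + ts.minute.to_numpy() / 60.0
    hour_idx = np.arange(n_min) // 60

    # normalized severity per minute, per scale
    nsev = {s: traj.latent_severity[s][hour_idx] /
            (config.scale_ranges[s][1] - config.scale_ranges[s][0])
            for s in SCALE_NAMES}
    cpl = traj.coupling
    sleep_shift = sum(cpl[s]["sleep_hours"] * nsev[s] for s in SCALE_NAMES)
    act_mult = 1.0 + sum(cpl[s]["activity"] * nsev[s] for s in SCALE_NAMES)
    switch_mult = 1.0 + sum(cpl[s]["location_switch"] * nsev[s] for s in SCALE_NAMES)
    hr_shift = sum(cpl[s]["resting_hr"] * nsev[s] for s in SCALE_NAMES)

    # --- sleep: one interval per night, duration coupled to severity
    asleep = np.zeros(n_min, dtype=bool)
    n_nights = traj.stay_hours // 24 + 1
    for night in range(n_nights):
        onset_min = night * 1440 + int((23.0 - ADMISSION_HOUR) % 24 * 60)
        if onset_min >= n_min:
            break
        onset_min += int(rng.normal(0.0, 30.0))
        need = config.base_sleep_hours + sleep_shift[min(max(onset_min, 0), n_min - 1)]
        need = float(np.clip(need + rng.normal(0.0, 0.25), 0.0, 11.0))
        a, b = max(onset_min, 0), min(onset_min + int(need * 60), n_min)
        asleep[a:b] = True

    # --- activity level (dimensionless), circadian + severity coupling
    day_curve = 1.0 + config.circadian_act_amp * np.cos(2 * np.pi * (hod - 14.0) / 24.0)
    act = ward.activity_scale * config.base_activity * day_curve * np.clip(act_mult, 0.05, None)
    act = np.where(asleep, 0.02 * ward.activity_scale * config.base_activity, act)
    act = np.clip(act, 0.0, None)

    # --- heart rate
    act_ref = ward.activity_scale * config.base_activity  # daily-mean activity at zero coupling
    hr = (ward.hr_baseline
          + config.circadian_hr_amp * np.cos(2 * np.pi * (hod - 16.0) / 24.0)
          + config.hr_activity_gain * (act - act_ref)
          + hr_shift
          - config.sleep_hr_dip * asleep
          + rng.normal(0.0, config.hr_noise_sd, n_min))
    hr = np.clip(hr, 35.0, 220.0)

    # --- acceleration (g): gravity on z, movement noise scaled by activity
    sd = config.accel_unit_g * act
    ax = rng.standard_normal(n_min) * sd
    ay = rng.standard_normal(n_min) * sd
    az = 1.0 + rng.standard_normal(n_min) * sd * 0.5

    # --- location Markov chain over ward zones
    zones = list(ward.room_layout.keys())
    lam = config.base_switch_per_hour * np.clip(switch_mult, 0.0, None)
    lam = np.where(asleep, lam * 0.05, lam)
    p_switch = 1.0 - np.exp(-lam / 60.0)
    u = rng.random(n_min)
    pick = rng.integers(0, max(len(zones) - 1, 1), size=n_min)
    zone_idx = np.zeros(n_min, dtype=np.int64)
    cur = zones.index("room")
    for t in range(n_min):
        if u[t] < p_switch[t] and len(zones) > 1:
            j = pick[t]
            cur = j if j < cur else j + 1  # uniform over the other zones
        zone_idx[t] = cur
    zone = np.array(zones, dtype=object)[zone_idx]
    anchors = np.array([ward.room_layout[z] for z in zones])
    loc = anchors[zone_idx] + rng.normal(0.0, 1.5, size=(n_min, 2))
    nosig = rng.random(n_min) < config.p_nosignal
    zone = np.where(nosig, "no_signal", zone)
    loc[nosig] = np.nan

    # --- device cumulatives
    steps = rng.poisson(config.steps_per_min_per_act * act).astype(float)
    steps[asleep] = 0.0
    distance = steps * config.stride_m
    calories = config.kcal_per_min + config.kcal_per_step * steps

    df = pd.DataFrame({
        "timestamp": ts,
        "heart_rate": hr,
        "accel_x": ax, "accel_y": ay, "accel_z": az,
        "loc_x": loc[:, 0], "loc_y": loc[:, 1],
        "zone": zone,
        "calories": calories, "steps": steps, "distance": distance,
        "sleep_flag": asleep.astype(float),
    })
    return SensorStream(participant_id=traj.participant_id, data=df)


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

def apply_missingness(stream: SensorStream, ward: WardProfile,
                      rng: np.random.Generator,
                      config: CohortConfig | None = None) -> SensorStream:
    """Blank contiguous device-off episodes (shower, leaving the ward,
    refusal) across all channels.

    Off/on times follow an alternating renewal process with exponential
    episode lengths (mean ``missing_episode_mean_min``) and exponential
    worn periods sized so the long-run off fraction equals the ward's
    ``missingness_rate``. The realized fraction is recorded on the
    returned stream.
    """
    rate = ward.missingness_rate
    if rate >= 1.0:
        raise ConfigError("missingness_rate must be < 1")
    df = stream.data.copy()
    n = len(df)
    if rate <= 0.0 or n == 0:
        return SensorStream(stream.participant_id, df, missing_fraction=0.0)

    mean_off = config.missing_episode_mean_min if config is not None else 45.0
    mean_on = mean_off * (1.0 - rate) / rate
    mask = np.zeros(n, dtype=bool)
    t = 0
    off = rng.random() < rate  # start state at stationarity
    while t < n:
        dur = max(1, int(round(rng.exponential(mean_off if off else mean_on))))
        if off:
            mask[t:t + dur] = True
        t += dur
        off = not off

    sensor_cols = [c for c in STREAM_COLUMNS if c != "timestamp"]
    df.loc[mask, [c for c in sensor_cols if c != "zone"]] = np.nan
    df["zone"] = df["zone"].astype(object)
    df.loc[mask, "zone"] = None
    return SensorStream(stream.participant_id, df, missing_fraction=float(mask.mean()))


# ---------------------------------------------------------------------------
# assessments
# ---------------------------------------------------------------------------

def schedule_assessments(traj: SymptomTrajectory, config: CohortConfig,
                         rng: np.random.Generator) -> list[Assessment]:
    """Baseline rating at admission, then weekly; extra event-triggered
    ratings after large relapse jumps. Observed totals are the latent
    severity plus rater noise, rounded and clipped to the scale range."""
    stay_h = traj.stay_hours
    if stay_h < 24:
        raise ConfigError("stay must be at least 1 day")
    hours = list(range(0, stay_h + 1, 7 * 24))
    triggers = {h: "weekly" for h in hours}
    # event ratings happen the day after the relapse event, once the
    # triggering intervention has been documented
    for t, size in traj.jump_events:
        h = min(t + 24, stay_h)
        if size > config.event_threshold and h not in triggers \
                and rng.random() < config.event_assessment_prob:
            triggers[h] = "event"
    out = []
    for h in sorted(triggers):
        scores = {}
        for s in SCALE_NAMES:
            lo, hi = config.scale_ranges[s]
            raw = traj.latent_severity[s][h] + rng.normal(0.0, config.rater_noise_sd)
            scores[s] = int(np.clip(round(raw), lo, hi))
        out.append(Assessment(participant_id=traj.participant_id,
                              time=traj.times[h], scores=scores,
                              trigger=triggers[h]))
    return out


# ---------------------------------------------------------------------------
# whole cohort
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate ``n_participants`` complete records: streams with
    missingness applied, assessment tables, and metadata with the
    per-ward recruitment dates that enable the temporal split."""
    if not config.wards:
        raise ConfigError("ward list must be non-empty")
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_participants)
    streams: dict[str, SensorStream] = {}
    rows_meta, rows_assess = [], []
    for i, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        pid = f"p{i:03d}"
        ward = config.wards[i % len(config.wards)]
        w0, w1 = ward.recruitment_window
        rec_date = w0 + timedelta(days=int(rng.integers(0, (w1 - w0).days + 1)))
        admission = pd.Timestamp(datetime(rec_date.year, rec_date.month, rec_date.day,
                                          ADMISSION_HOUR))
        stay = _draw_stay_days(config, rng)
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 13.0, 85.0))
        sex = "F" if rng.random() < config.female_p else "M"
        traj = simulate_symptom_trajectory(pid, config, ward, rng,
                                           stay_days=stay, admission=admission,
                                           age=age, sex=sex)
        stream = emit_sensor_stream(traj, ward, rng, config)
        rate_cfg = config
        if config.informative_missingness:
            sev = np.mean(traj.latent_severity["BPRS"]) / config.scale_ranges["BPRS"][1]
            ward = dataclasses.replace(
                ward, missingness_rate=min(0.95, ward.missingness_rate * (1 + 2 * sev)))
        stream = apply_missingness(stream, ward, rng, rate_cfg)
        streams[pid] = stream
        for a in schedule_assessments(traj, config, rng):
            rows_assess.append({"participant_id": pid, "timestamp": a.time,
                                **a.scores, "trigger": a.trigger})
        rows_meta.append({"participant_id": pid, "age": round(age, 1), "sex": sex,
                          "ward": ward.ward_id, "recruitment_date": rec_date.isoformat()})
    assessments = pd.DataFrame(rows_assess)
    metadata = pd.DataFrame(rows_meta)
    return CohortBundle(streams=streams, assessments=assessments,
                        metadata=metadata, config=config)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_cohort(bundle: CohortBundle, out_dir: str | Path) -> Path:
    """Write the bundle as plain CSV files (one stream file per
    participant) plus the config as YAML."""
    out = Path(out_dir)
    (out / "streams").mkdir(parents=True, exist_ok=True)
    for pid, stream in bundle.streams.items():
        df = stream.data.copy()
        df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
        df.to_csv(out / "streams" / f"{pid}.csv", index=False, float_format="%.6g")
    a = bundle.assessments.copy()
    a["timestamp"] = pd.to_datetime(a["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    a.to_csv(out / "assessments.csv", index=False)
    bundle.metadata.to_csv(out / "metadata.csv", index=False)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config_to_dict(bundle.config), fh, sort_keys=True)
    frac = {pid: s.missing_fraction for pid, s in bundle.streams.items()}
    pd.Series(frac, name="missing_fraction").rename_axis("participant_id") \
        .to_csv(out / "missingness.csv")
    return out


def load_cohort(in_dir: str | Path) -> CohortBundle:
    """Read a bundle written by :func:`save_cohort` (or supplied in the
    same formats)."""
    src = Path(in_dir)
    frac = pd.read_csv(src / "missingness.csv", index_col=0)["missing_fraction"] \
        if (src / "missingness.csv").exists() else pd.Series(dtype=float)
    streams = {}
    for f in sorted((src / "streams").glob("*.csv")):
        pid = f.stem
        df = pd.read_csv(f, parse_dates=["timestamp"])
        df["zone"] = df["zone"].where(df["zone"].notna(), None)
        streams[pid] = SensorStream(pid, df,
                                    missing_fraction=float(frac.get(pid, 0.0)))
    assessments = pd.read_csv(src / "assessments.csv", parse_dates=["timestamp"])
    metadata = pd.read_csv(src / "metadata.csv")
    cfg = CohortConfig()
    if (src / "config.yaml").exists():
        with open(src / "config.yaml") as fh:
            cfg = config_from_dict(yaml.safe_load(fh))
    return CohortBundle(streams=streams, assessments=assessments,
                        metadata=metadata, config=cfg)


def config_to_dict(config: CohortConfig) -> dict:
    d = dataclasses.asdict(config)
    d["wards"] = []
    for w in config.wards:
        wd = dataclasses.asdict(w)
        wd["recruitment_window"] = [w.recruitment_window[0].isoformat(),
                                    w.recruitment_window[1].isoformat()]
        wd["room_layout"] = {z: list(xy) for z, xy in w.room_layout.items()}
        d["wards"].append(wd)
    d["scale_ranges"] = {s: list(r) for s, r in config.scale_ranges.items()}
    return d


def config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    wards = []
    for wd in d.get("wards", []):
        wd = dict(wd)
        wd["recruitment_window"] = tuple(date.fromisoformat(x)
                                         for x in wd["recruitment_window"])
        wd["room_layout"] = {z: tuple(xy) for z, xy in wd["room_layout"].items()}
        wards.append(WardProfile(**wd))
    if wards:
        d["wards"] = wards
    if "scale_ranges" in d:
        d["scale_ranges"] = {s: tuple(r) for s, r in d["scale_ranges"].items()}
    return CohortConfig(**d)
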