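"""Model-input construction.

Links every assessment to the 672 hours (4 weeks) of sensor features
preceding it, builds the two label families — Deterioration (did the
scale total strictly increase versus the participant's previous
assessment?) and Score (the absolute total) — and assigns the temporal
cross-validation / external-validation split by recruitment date.
Histories shorter than 4 weeks are zero-padded on the oldest side;
padding is inserted *after* feature standardization, so padded rows
stay exactly zero in the model input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .cohort import Assessment, CohortBundle
from .features import FEATURE_REGISTRY, INPUT_REGISTRY, FeatureSeries
from .scales import SCALE_NAMES

HISTORY_HOURS = 672            # 4 weeks of hourly rows
DEFAULT_CUTOFF = date(2024, 5, 1)  # recruitment cutoff for the temporal split

SEX_CODE = {"M": 0.0, "F": 1.0}


@dataclass
class Example:
    """One (672 × 31 input, labels) training instance tied to an assessment."""

    participant_id: str
    assessment_time: pd.Timestamp
    features: np.ndarray               # (n_real, 29) most-recent-first-padded later
    pad_rows: int                      # zero rows prepended to reach 672
    age: float
    sex: float                         # 0 = male, 1 = female
    score_labels: dict[str, int]
    deterioration_labels: dict[str, bool | None]
    split_tag: str = "cv"              # "cv" | "external"
    ward_id: str = ""
    trigger: str = "weekly"

    def __post_init__(self) -> None:
        if self.pad_rows + len(self.features) != HISTORY_HOURS:
            raise ValueError("pad_rows + real rows must equal 672")

    @property
    def n_real(self) -> int:
        return len(self.features)

    def input_matrix(self) -> np.ndarray:
        """Raw (unstandardized) 672 × 31 input: zero padding, sensor
        features, then constant age/100 and sex columns."""
        x = np.zeros((HISTORY_HOURS, len(INPUT_REGISTRY)))
        if self.n_real:
            x[self.pad_rows:, :29] = self.features
        x[:, 29] = self.age / 100.0
        x[:, 30] = self.sex
        return x


def link_history(assessment: Assessment, series: FeatureSeries,
                 age: float, sex: float | str) -> Example:
    """Attach the 672 feature hours ending at the assessment hour.

    The assessment timestamp is floored to the hour; rows older than 4
    weeks are dropped, shorter histories are zero-padded on the oldest
    side.
    """
    t = pd.Timestamp(assessment.time).floor("h")
    idx = series.hour_index
    if t < idx[0]:
        raise ValueError(
            f"assessment at {t} precedes admission {idx[0]} "
            f"for {assessment.participant_id}")
    window = series.features.loc[t - pd.Timedelta(hours=HISTORY_HOURS): t - pd.Timedelta(hours=1)]
    rows = window.to_numpy(dtype=float)
    if len(rows) > HISTORY_HOURS:
        rows = rows[-HISTORY_HOURS:]
    sex_f = SEX_CODE[sex] if isinstance(sex, str) else float(sex)
    return Example(participant_id=assessment.participant_id,
                   assessment_time=t, features=rows,
                   pad_rows=HISTORY_HOURS - len(rows),
                   age=float(age), sex=sex_f,
                   score_labels=dict(assessment.scores),
                   deterioration_labels={s: None for s in SCALE_NAMES},
                   trigger=assessment.trigger)


def deterioration_labels(assessments: list[Assessment]
                         ) -> list[dict[str, bool | None]]:
    """Per-assessment strict-increase labels versus the previous
    assessment, per scale; the first assessment is undefined (None),
    ties are False. Input must be time-ordered."""
    times = [pd.Timestamp(a.time) for a in assessments]
    if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("assessments must be sorted by time")
    out: list[dict[str, bool | None]] = []
    for i, a in enumerate(assessments):
        if i == 0:
            out.append({s: None for s in SCALE_NAMES})
        else:
            prev = assessments[i - 1].scores
            out.append({s: bool(a.scores[s] > prev[s]) for s in SCALE_NAMES})
    return out


@dataclass
class ExampleDataset:
    """All retained examples plus the participant exclusion log."""

    examples: list[Example]
    dropped: pd.DataFrame = field(default_factory=pd.DataFrame)

    def split(self, tag: str) -> list[Example]:
        return [e for e in self.examples if e.split_tag == tag]

    def participants(self, tag: str | None = None) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.examples:
            if tag is None or e.split_tag == tag:
                seen.setdefault(e.participant_id)
        return list(seen)

    def __len__(self) -> int:
        return len(self.examples)


def build_dataset(bundle: CohortBundle,
                  feature_series: dict[str, FeatureSeries],
                  cutoff_date: date = DEFAULT_CUTOFF) -> ExampleDataset:
    """One Example per retained assessment, tagged cv/external by
    recruitment date (all of a participant's examples share one tag).
    Participants with fewer than 2 assessments are dropped and logged.
    """
    meta = bundle.metadata.set_index("participant_id")
    rows_dropped = []
    examples: list[Example] = []
    for pid, series in feature_series.items():
        sub = bundle.assessments[bundle.assessments["participant_id"] == pid]
        sub = sub.sort_values("timestamp")
        if len(sub) < 2:
            rows_dropped.append({"participant_id": pid,
                                 "reason": f"only {len(sub)} assessment(s)"})
            continue
        assessments = [
            Assessment(participant_id=pid, time=pd.Timestamp(r.timestamp),
                       scores={s: int(getattr(r, s)) for s in SCALE_NAMES},
                       trigger=r.trigger)
            for r in sub.itertuples()]
        labels = deterioration_labels(assessments)
        m = meta.loc[pid]
        rec = pd.Timestamp(m["recruitment_date"]).date()
        tag = "cv" if rec < cutoff_date else "external"
        for a, lab in zip(assessments, labels):
            ex = link_history(a, series, age=float(m["age"]), sex=m["sex"])
            ex.deterioration_labels = lab
            ex.split_tag = tag
            ex.ward_id = str(m["ward"])
            examples.append(ex)
    ds = ExampleDataset(examples=examples, dropped=pd.DataFrame(rows_dropped))
    tags = {e.split_tag for e in examples}
    if examples and len(tags) < 2:
        warnings.warn(f"recruitment cutoff {cutoff_date} leaves one split empty "
                      f"(all examples tagged {tags.pop()!r})", stacklevel=2)
    return ds


class FeatureScaler:
    """Per-feature z-scoring of the 29 sensor columns, fit on real
    (non-padded) rows of the training examples only.

    Transformed inputs keep padded rows at exactly zero; age/100 and
    sex pass through unscaled (they are already bounded).
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, examples: list[Example]) -> "FeatureScaler":
        if not examples:
            raise ValueError("cannot fit scaler on an empty example list")
        rows = np.concatenate([e.features for e in examples if e.n_real > 0], axis=0)
        self.mean_ = rows.mean(axis=0)
        sd = rows.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, example: Example) -> np.ndarray:
        if self.mean_ is None:
            raise ValueError("scaler not fitted")
        x = np.zeros((HISTORY_HOURS, len(INPUT_REGISTRY)))
        if example.n_real:
            x[example.pad_rows:, :29] = (example.features - self.mean_) / self.scale_
        x[:, 29] = example.age / 100.0
        x[:, 30] = example.sex
        return x

    def transform_batch(self, examples: list[Example]) -> np.ndarray:
        return np.stack([self.transform(e) for e in examples])
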