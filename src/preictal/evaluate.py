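"""Alarm generation and SPH/SOP-based scoring of seizure predictions.

Segment scores on a chronological, non-overlapping timeline are smoothed
into alarms with a k-of-n persistence rule plus a refractory period. An
alarm raised at time ``t`` is a true prediction iff some seizure onset
falls inside the closed window ``[t + SPH, t + SPH + SOP]`` (seconds);
a seizure counts as predicted iff at least one true alarm maps to it.
Reported metrics are seizure-wise sensitivity (percent), false alarms per
monitored interictal hour, and the rank-based (Mann-Whitney) ROC AUC of
raw segment scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import SeizureEvent
from .windowing import TrialConfig

__all__ = [
    "AlarmRule",
    "AlarmSeries",
    "Adjudication",
    "EvalReport",
    "fire_alarms",
    "adjudicate",
    "sensitivity",
    "fpr_per_hour",
    "auc",
    "loocv_folds",
    "aggregate",
]


@dataclass(frozen=True)
class AlarmRule:
    """Fire when >= k of the last n segment labels are positive.

    ``threshold`` binarizes scores; ``refractory_s`` suppresses further
    alarms after a firing (pass ``(SPH+SOP)*60`` for the standard choice).
    ``k = n = 1`` reduces to naive per-segment alarming.
    """

    k: int = 8
    n: int = 10
    threshold: float = 0.5
    refractory_s: float = 1800.0

    def __post_init__(self) -> None:
        if not 1 <= self.k <= self.n:
            raise ValueError("need 1 <= k <= n")
        if self.refractory_s < 0:
            raise ValueError("refractory_s must be >= 0")


@dataclass
class AlarmSeries:
    alarms: list[float]
    rule: AlarmRule

    def __post_init__(self) -> None:
        for a, b in zip(self.alarms, self.alarms[1:]):
            if b - a < self.rule.refractory_s:
                raise ValueError("alarms violate the refractory period")


def fire_alarms(
    t_starts: np.ndarray,
    scores: np.ndarray,
    rule: AlarmRule,
    win_s: float = 5.0,
) -> AlarmSeries:
    """Turn a chronological score sequence into an alarm series.

    ``t_starts`` must be strictly increasing with non-overlapping windows;
    the alarm time is the end of the segment window that completed the
    k-of-n count.
    """
    t_starts = np.asarray(t_starts, float)
    scores = np.asarray(scores, float)
    if t_starts.shape != scores.shape:
        raise ValueError("t_starts and scores must have the same length")
    if np.any(np.diff(t_starts) < win_s - 1e-9):
        raise ValueError("segments must be chronological and non-overlapping")
    positive = scores >= rule.threshold
    alarms: list[float] = []
    next_allowed = -np.inf
    for i in range(positive.size):
        lo = max(0, i - rule.n + 1)
        if int(positive[lo:i + 1].sum()) >= rule.k:
            t_alarm = t_starts[i] + win_s
            if t_alarm >= next_allowed:
                alarms.append(float(t_alarm))
                next_allowed = t_alarm + rule.refractory_s
    return AlarmSeries(alarms=alarms, rule=rule)


@dataclass
class Adjudication:
    true_alarms: list[float]
    false_alarms: list[float]
    predicted_seizures: int
    total_seizures: int
    predicted_onsets: list[float] = field(default_factory=list)


def adjudicate(
    alarms: AlarmSeries | list[float],
    events: list[SeizureEvent],
    trial: TrialConfig,
) -> Adjudication:
    """Classify each alarm as true/false and count predicted seizures.

    The SOP window is closed at both ends: an onset exactly at
    ``t + SPH`` or ``t + SPH + SOP`` validates the alarm.
    """
    times = alarms.alarms if isinstance(alarms, AlarmSeries) else list(alarms)
    onsets = np.array([e.onset for e in events], float)
    true_a: list[float] = []
    false_a: list[float] = []
    hit = np.zeros(onsets.size, bool)
    for t in times:
        lo, hi = t + trial.sph_s, t + trial.sph_s + trial.sop_s
        inside = (onsets >= lo - 1e-9) & (onsets <= hi + 1e-9)
        if inside.any():
            true_a.append(t)
            hit |= inside
        else:
            false_a.append(t)
    return Adjudication(
        true_alarms=true_a,
        false_alarms=false_a,
        predicted_seizures=int(hit.sum()),
        total_seizures=len(events),
        predicted_onsets=[float(o) for o in onsets[hit]],
    )


def sensitivity(predicted: int, total: int) -> float:
    """Seizure-wise sensitivity in percent."""
    if total <= 0:
        raise ValueError("sensitivity undefined for zero seizures")
    return 100.0 * predicted / total


def fpr_per_hour(false_alarms: int, interictal_hours: float) -> float:
    """False alarms per monitored interictal hour."""
    if interictal_hours <= 0:
        raise ValueError("fpr_per_hour undefined for zero monitored hours")
    return false_alarms / interictal_hours


def auc(scores, labels) -> float:
    """Rank-based ROC AUC (ties count 0.5); needs both classes present."""
    from sklearn.metrics import roc_auc_score

    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("AUC undefined: only one class present")
    return float(roc_auc_score(labels, np.asarray(scores, float)))


def loocv_folds(patients: list[str]) -> list[tuple[list[str], str]]:
    """Leave-one-patient-out folds: (train_ids, held-out test_id)."""
    if len(patients) < 2:
        raise ValueError("LOOCV needs at least 2 patients")
    if len(set(patients)) != len(patients):
        raise ValueError("patient ids must be unique")
    return [
        ([p for p in patients if p != test], test)
        for test in patients
    ]


@dataclass
class EvalReport:
    """Per-patient sensitivity/FPR/AUC plus their unweighted averages."""

    per_patient: dict[str, dict[str, float]]
    trial: TrialConfig
    classifier_kind: str = "fc"
    averages: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.per_patient and not self.averages:
            self.averages = aggregate(self.per_patient)

    def to_frame(self):
        import pandas as pd

        rows = dict(self.per_patient)
        rows["Avg"] = self.averages
        return pd.DataFrame.from_dict(rows, orient="index")[
            ["sensitivity_pct", "fpr_per_h", "auc"]
        ]

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "trial": {"sph_min": self.trial.sph_min,
                          "sop_min": self.trial.sop_min},
                "classifier_kind": self.classifier_kind,
                "per_patient": self.per_patient,
                "averages": self.averages,
            },
            indent=1,
        )


def aggregate(per_patient: dict[str, dict[str, float]]) -> dict[str, float]:
    """Unweighted means across patients, rounded as reported in results
    tables: sensitivity to 2 decimals, FPR and AUC to 3."""
    if not per_patient:
        raise ValueError("cannot aggregate an empty report")
    keys = ("sensitivity_pct", "fpr_per_h", "auc")
    out = {}
    for key in keys:
        vals = [row[key] for row in per_patient.values() if key in row]
        if not vals:
            continue
        mean = float(np.mean(vals))
        out[key] = round(mean, 2 if key == "sensitivity_pct" else 3)
    return out
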