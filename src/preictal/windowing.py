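"""Sliding-window segmentation and preictal/interictal labeling.

A :class:`TrialConfig` (SPH, SOP) anchors the preictal window to each
seizure onset: the preictal interval is
``[onset - (SPH+SOP)*60, onset - SPH*60)`` seconds, half-open. Training
sets are balanced exactly, escalating preictal overlap through a fixed
grid when the preictal span is short; test sets use non-overlapping
windows only. All interval arithmetic is done in sample indices
(``floor(t * fs)``) so no window ever crosses an interval boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import Recording, SeizureEvent

logger = logging.getLogger(__name__)

__all__ = [
    "TrialConfig",
    "WindowSpec",
    "Segment",
    "SegmentSet",
    "OVERLAP_GRID",
    "save_segment_set",
    "load_segment_set",
    "preictal_interval",
    "interictal_intervals",
    "segment_interval",
    "build_balanced_trainset",
    "build_testset",
]

#: Deterministic escalation schedule for preictal training overlap.
OVERLAP_GRID = (0.0, 0.25, 0.5, 0.75, 0.9)

PREICTAL = "preictal"
INTERICTAL = "interictal"

#: Every labeling scheme requires at least this much pre-onset signal.
MIN_PREONSET_MIN = 30.0


@dataclass(frozen=True)
class TrialConfig:
    """SPH/SOP pair in minutes.

    Trial 1 is SPH=5, SOP=25; trial 2 is SPH=10, SOP=20. Their sum may not
    exceed the 30-minute pre-onset span every usable seizure must have.
    """

    sph_min: float
    sop_min: float

    def __post_init__(self) -> None:
        if self.sph_min < 0 or self.sop_min <= 0:
            raise ValueError("need sph_min >= 0 and sop_min > 0")
        if self.sph_min + self.sop_min > MIN_PREONSET_MIN:
            raise ValueError("sph_min + sop_min must be <= 30 minutes")

    @classmethod
    def trial(cls, number: int) -> "TrialConfig":
        if number == 1:
            return cls(sph_min=5.0, sop_min=25.0)
        if number == 2:
            return cls(sph_min=10.0, sop_min=20.0)
        raise ValueError(f"unknown trial {number}; expected 1 or 2")

    @property
    def sph_s(self) -> float:
        return self.sph_min * 60.0

    @property
    def sop_s(self) -> float:
        return self.sop_min * 60.0


@dataclass(frozen=True)
class WindowSpec:
    """Segment geometry: window length in seconds; test overlap is always 0."""

    win_s: float = 5.0

    def win_samples(self, fs: float) -> int:
        n = self.win_s * fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError(f"win_s*fs must be an integer, got {n}")
        return int(round(n))


@dataclass
class Segment:
    """One labeled window: ``x`` is (n_channels, win_samples)."""

    x: np.ndarray
    label: str
    t_start: float
    patient_id: str
    recording_id: str = ""
    from_overlap: bool = False


@dataclass
class SegmentSet:
    """A labeled collection of segments for one split of one trial."""

    segments: list[Segment]
    trial: TrialConfig
    split: str  # "train" | "test"

    def __post_init__(self) -> None:
        if self.split not in ("train", "test"):
            raise ValueError(f"split must be 'train' or 'test', got {self.split!r}")

    def __len__(self) -> int:
        return len(self.segments)

    def count(self, label: str) -> int:
        return sum(1 for s in self.segments if s.label == label)

    @property
    def X(self) -> np.ndarray:
        """Stacked (n, n_channels, win_samples) float32 array."""
        return np.stack([s.x for s in self.segments]).astype(np.float32)

    @property
    def y(self) -> np.ndarray:
        """Binary labels: 1 = preictal, 0 = interictal."""
        return np.array([1 if s.label == PREICTAL else 0 for s in self.segments])

    def manifest(self):
        """Per-segment provenance table (pandas DataFrame)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "patient_id": [s.patient_id for s in self.segments],
                "recording_id": [s.recording_id for s in self.segments],
                "t_start": [s.t_start for s in self.segments],
                "label": [s.label for s in self.segments],
                "from_overlap": [s.from_overlap for s in self.segments],
                "split": self.split,
            }
        )


def save_segment_set(segment_set: SegmentSet, out_dir) -> None:
    """Persist a SegmentSet as an array container plus a CSV manifest."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(out_dir / "segments.npz", X=segment_set.X)
    manifest = segment_set.manifest()
    manifest["sph_min"] = segment_set.trial.sph_min
    manifest["sop_min"] = segment_set.trial.sop_min
    manifest.to_csv(out_dir / "manifest.csv", index=False)


def load_segment_set(in_dir) -> SegmentSet:
    from pathlib import Path

    import pandas as pd

    in_dir = Path(in_dir)
    with np.load(in_dir / "segments.npz") as arrays:
        X = arrays["X"]
    manifest = pd.read_csv(in_dir / "manifest.csv")
    segments = [
        Segment(x=X[i], label=row.label, t_start=float(row.t_start),
                patient_id=str(row.patient_id),
                recording_id=str(row.recording_id),
                from_overlap=bool(row.from_overlap))
        for i, row in enumerate(manifest.itertuples())
    ]
    trial = TrialConfig(sph_min=float(manifest.sph_min[0]),
                        sop_min=float(manifest.sop_min[0]))
    return SegmentSet(segments=segments, trial=trial,
                      split=str(manifest.split[0]))


def preictal_interval(event: SeizureEvent, trial: TrialConfig):
    """Preictal span for one seizure: ``[onset-(SPH+SOP)*60, onset-SPH*60)``.

    Returns ``None`` (with a logged warning) when the recording does not
    contain the full span before the onset — such seizures are skipped.
    """
    lead_s = trial.sph_s + trial.sop_s
    if event.onset < lead_s:
        logger.warning(
            "seizure at %.1f s in %r skipped: needs %.0f s of pre-onset data",
            event.onset, event.recording_id, lead_s,
        )
        return None
    return (event.onset - lead_s, event.onset - trial.sph_s)


def interictal_intervals(
    events: list[SeizureEvent],
    recording: Recording,
    margin_min: float = 60.0,
) -> list[tuple[float, float]]:
    """Maximal spans at least ``margin_min`` away from any ictal/preictal span.

    The exclusion zone around each seizure covers the full 30-minute
    pre-onset window (the widest preictal definition), the ictal interval
    itself, and ``margin_min`` minutes on both sides.
    """
    margin_s = margin_min * 60.0
    dur = recording.duration
    zones = []
    for e in events:
        lo = e.onset - MIN_PREONSET_MIN * 60.0 - margin_s
        hi = e.offset + margin_s
        zones.append((max(0.0, lo), min(dur, hi)))
    zones.sort()
    merged: list[list[float]] = []
    for lo, hi in zones:
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    out: list[tuple[float, float]] = []
    cursor = 0.0
    for lo, hi in merged:
        if lo > cursor:
            out.append((cursor, lo))
        cursor = max(cursor, hi)
    if cursor < dur:
        out.append((cursor, dur))
    return out


def segment_interval(
    recording: Recording,
    interval: tuple[float, float],
    spec: WindowSpec,
    overlap: float,
    label: str | None = None,
) -> list[Segment]:
    """Cut one interval into windows with the given overlap fraction.

    Stride is ``win * (1 - overlap)`` rounded to whole samples; windows lie
    fully inside the interval. Intervals shorter than one window yield an
    empty list.
    """
    if not 0.0 <= overlap < 1.0:
        raise ValueError(f"overlap must be in [0, 1), got {overlap}")
    lo, hi = interval
    if lo < -1e-9 or hi > recording.duration + 1e-9:
        raise ValueError(f"interval {interval} outside recording [0, {recording.duration}]")
    fs = recording.fs
    win = spec.win_samples(fs)
    start = int(np.floor(lo * fs))
    stop = int(np.floor(hi * fs))
    stride = max(1, int(round(win * (1.0 - overlap))))
    segs: list[Segment] = []
    s = start
    while s + win <= stop:
        segs.append(
            Segment(
                x=recording.data[:, s:s + win],
                label=label or "",
                t_start=s / fs,
                patient_id=recording.patient_id,
                recording_id=recording.recording_id,
                from_overlap=overlap > 0.0,
            )
        )
        s += stride
    return segs


def _collect_intervals(recordings_events, trial, margin_min):
    """Per-recording preictal and interictal interval lists."""
    pre: list[tuple[Recording, tuple[float, float]]] = []
    inter: list[tuple[Recording, tuple[float, float]]] = []
    for recording, events in recordings_events:
        for event in events:
            span = preictal_interval(event, trial)
            if span is not None and span[0] >= 0.0:
                pre.append((recording, span))
        for span in interictal_intervals(events, recording, margin_min):
            inter.append((recording, span))
    return pre, inter


def build_balanced_trainset(
    recordings_events: list[tuple[Recording, list[SeizureEvent]]],
    trial: TrialConfig,
    spec: WindowSpec = WindowSpec(),
    seed: int = 0,
    max_per_class: int | None = None,
    margin_min: float = 60.0,
) -> SegmentSet:
    """Balanced training set with variable-overlap preictal augmentation.

    The interictal target is the non-overlapping interictal segment count
    (capped by ``max_per_class``). The smallest overlap in
    :data:`OVERLAP_GRID` that lifts the preictal count to the target is
    used for preictal windows; both classes are then subsampled (seeded,
    uniform, order-preserving) to the exact common count.
    """
    pre_iv, inter_iv = _collect_intervals(recordings_events, trial, margin_min)
    if not pre_iv:
        raise ValueError("no usable preictal interval in the training data")

    inter_segs = [
        s
        for rec, span in inter_iv
        for s in segment_interval(rec, span, spec, 0.0, label=INTERICTAL)
    ]
    target = len(inter_segs)
    if max_per_class is not None:
        target = min(target, max_per_class)

    pre_segs: list[Segment] = []
    for overlap in OVERLAP_GRID:
        pre_segs = [
            s
            for rec, span in pre_iv
            for s in segment_interval(rec, span, spec, overlap, label=PREICTAL)
        ]
        if len(pre_segs) >= target:
            break
    n = min(target, len(pre_segs))
    if n == 0:
        raise ValueError("training data yields zero balanced segment pairs")

    rng = np.random.default_rng(seed)

    def subsample(segs: list[Segment], k: int) -> list[Segment]:
        if len(segs) <= k:
            return list(segs)
        keep = np.sort(rng.choice(len(segs), size=k, replace=False))
        return [segs[i] for i in keep]

    segments = subsample(pre_segs, n) + subsample(inter_segs, n)
    return SegmentSet(segments=segments, trial=trial, split="train")


def build_testset(
    recordings_events: list[tuple[Recording, list[SeizureEvent]]],
    trial: TrialConfig,
    spec: WindowSpec = WindowSpec(),
    margin_min: float = 60.0,
) -> SegmentSet:
    """Non-overlapping labeled test segments in chronological order.

    No balancing is applied; segments keep their start times so alarm
    timelines can be reconstructed downstream.
    """
    pre_iv, inter_iv = _collect_intervals(recordings_events, trial, margin_min)
    segments: list[Segment] = []
    for rec, span in pre_iv:
        segments.extend(segment_interval(rec, span, spec, 0.0, label=PREICTAL))
    for rec, span in inter_iv:
        segments.extend(segment_interval(rec, span, spec, 0.0, label=INTERICTAL))
    segments.sort(key=lambda s: (s.patient_id, s.recording_id, s.t_start))
    return SegmentSet(segments=segments, trial=trial, split="test")
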