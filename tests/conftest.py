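"""Shared test fixtures: small in-memory recordings and toy segment sets."""

from __future__ import annotations

import numpy as np
import pytest

from preictal.io import CHB_MIT_16, Recording, SeizureEvent
from preictal.windowing import Segment, SegmentSet, TrialConfig


def make_recording(duration_s: float, fs: float = 256.0, seed: int = 0,
                   patient_id: str = "p0", recording_id: str = "p0_r0",
                   n_channels: int = 16) -> Recording:
    """White-noise recording with the canonical 16-channel montage."""
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    names = list(CHB_MIT_16)[:n_channels]
    return Recording(
        patient_id=patient_id,
        data=rng.standard_normal((n_channels, n)).astype(np.float32) * 20.0,
        fs=fs,
        channel_names=names,
        recording_id=recording_id,
    )


def make_toy_set(n_per_class: int = 40, n_samples: int = 64, seed: int = 0,
                 split: str = "train", patient_id: str = "p0",
                 shuffle_labels: bool = False) -> SegmentSet:
    """Linearly separable toy segments (16 x n_samples).

    Interictal windows are white noise; preictal windows carry a strong
    32 Hz rhythm with a phase that is fixed per channel across segments,
    so a matched (linear) filter separates the classes and the
    separation survives per-window standardization.
    """
    rng = np.random.default_rng(seed)
    phase = np.random.default_rng(99).uniform(0, 2 * np.pi, size=(16, 1))
    t = np.arange(n_samples) / 256.0
    segments = []
    for i in range(2 * n_per_class):
        label = "preictal" if i % 2 else "interictal"
        x = rng.standard_normal((16, n_samples))
        if label == "preictal":
            x = 0.3 * x + 2.0 * np.sin(2 * np.pi * 32.0 * t + phase)
        segments.append(
            Segment(x=x.astype(np.float32), label=label, t_start=5.0 * i,
                    patient_id=patient_id, recording_id=f"{patient_id}_r0")
        )
    if shuffle_labels:
        labels = [s.label for s in segments]
        rng.shuffle(labels)
        for s, lab in zip(segments, labels):
            s.label = lab
    return SegmentSet(segments=segments, trial=TrialConfig.trial(1), split=split)


@pytest.fixture
def toy_train_set() -> SegmentSet:
    return make_toy_set(n_per_class=40, seed=3)


@pytest.fixture
def one_seizure_recording() -> tuple[Recording, list[SeizureEvent]]:
    """A 40-minute recording with one annotated seizure at t=1860 s."""
    rec = make_recording(2400.0, seed=7)
    return rec, [SeizureEvent(1860.0, 1920.0, rec.recording_id)]
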