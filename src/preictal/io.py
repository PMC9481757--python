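"""Reading and writing EEG recordings and seizure annotations.

Recordings are held in memory as a :class:`Recording` — a plain
``(n_channels, n_samples)`` microvolt array plus metadata — matching the
scalp-EEG conventions of the CHB-MIT corpus (256 Hz, 16 shared bipolar
channels). EDF files are read through :mod:`mne`; fixtures are written with
a minimal 16-bit EDF writer so round trips need no optional export
dependency. Seizure annotations are parsed either from CHB-MIT style
plain-text summaries or from this package's JSON dialect.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Recording",
    "SeizureEvent",
    "ChannelMap",
    "MissingChannelError",
    "AnnotationError",
    "default_channel_map",
    "read_edf",
    "read_annotations",
    "write_annotations",
    "write_fixture",
]

#: The 16 bipolar derivations present in every CHB-MIT montage, in the
#: fixed order used for the channel axis of all segment matrices.
CHB_MIT_16 = (
    "FP1-F7", "F7-T7", "T7-P7", "P7-O1",
    "FP1-F3", "F3-C3", "C3-P3", "P3-O1",
    "FP2-F4", "F4-C4", "C4-P4", "P4-O2",
    "FP2-F8", "F8-T8", "T8-P8", "P8-O2",
)


class MissingChannelError(KeyError):
    """A canonical channel is absent from a recording."""


class AnnotationError(ValueError):
    """A seizure annotation file is malformed or inconsistent."""


@dataclass(frozen=True)
class SeizureEvent:
    """One annotated seizure, in seconds from the start of its recording."""

    onset: float
    offset: float
    recording_id: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.onset < self.offset):
            raise AnnotationError(
                f"invalid seizure interval [{self.onset}, {self.offset}] "
                f"in recording {self.recording_id!r}"
            )


@dataclass
class Recording:
    """A continuous multichannel EEG recording in microvolts.

    ``data`` is ``(n_channels, n_samples)``; times are seconds, 0-based and
    recording-local, with sample index ``floor(t * fs)``.
    """

    patient_id: str
    data: np.ndarray
    fs: float
    channel_names: list[str]
    start_time: float = 0.0
    recording_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_channels, n_samples)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.channel_names)} "
                "channel names"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if np.isnan(self.data).any():
            raise ValueError("recording contains NaN samples")
        if not self.recording_id:
            self.recording_id = self.patient_id

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs


@dataclass(frozen=True)
class ChannelMap:
    """Canonical channel list plus aliases for raw labels.

    Matching is case-insensitive and ignores surrounding whitespace; aliases
    map raw labels (e.g. ``"EEG FP1-F7"``) onto canonical names.
    """

    canonical_names: tuple[str, ...]
    aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.canonical_names) != 16:
            raise ValueError(
                f"expected 16 canonical channels, got {len(self.canonical_names)}"
            )
        canon = {c.upper() for c in self.canonical_names}
        targets = [v.upper() for v in self.aliases.values()]
        if not set(targets) <= canon:
            raise ValueError("alias targets must be canonical names")
        if len(targets) != len(set(targets)):
            raise ValueError("aliases must be injective onto canonical names")

    def resolve(self, raw_labels: list[str]) -> list[int]:
        """Indices of ``raw_labels`` in canonical order.

        Raises :class:`MissingChannelError` naming the first canonical
        channel that cannot be found.
        """
        alias_up = {k.strip().upper(): v.upper() for k, v in self.aliases.items()}
        lookup: dict[str, int] = {}
        for i, lab in enumerate(raw_labels):
            key = lab.strip().upper()
            key = alias_up.get(key, key)
            lookup.setdefault(key, i)
        order = []
        for name in self.canonical_names:
            idx = lookup.get(name.upper())
            if idx is None:
                raise MissingChannelError(
                    f"canonical channel {name!r} not found among {raw_labels}"
                )
            order.append(idx)
        return order


def default_channel_map() -> ChannelMap:
    """The 16 bipolar channels shared across CHB-MIT montages."""
    aliases = {f"EEG {name}": name for name in CHB_MIT_16}
    return ChannelMap(canonical_names=CHB_MIT_16, aliases=aliases)


# ---------------------------------------------------------------------------
# EDF


def read_edf(path: str | Path, channel_map: ChannelMap | None = None,
             patient_id: str | None = None) -> Recording:
    """Read an EDF file, selecting and ordering the canonical channels.

    Extra channels are dropped; missing canonical channels raise
    :class:`MissingChannelError`. Sample values are returned in microvolts.
    """
    import mne

    path = Path(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    cmap = channel_map or default_channel_map()
    order = cmap.resolve(list(raw.ch_names))
    data_uv = raw.get_data()[order] * 1e6  # MNE loads EEG in volts
    return Recording(
        patient_id=patient_id or path.stem.split("_")[0],
        data=data_uv,
        fs=float(raw.info["sfreq"]),
        channel_names=list(cmap.canonical_names),
        recording_id=path.stem,
    )


def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def _write_edf(path: Path, recording: Recording) -> None:
    """Write a 16-bit EDF file (one 1-second data record per second).

    Restricted to integer sampling rates and whole-second recordings, which
    is all the fixture machinery needs; each channel gets a symmetric
    physical range so quantization error is at most ``max|x| / 32767``.
    """
    fs = recording.fs
    if fs != int(fs):
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(fs)
    n_ch, n_samp = recording.data.shape
    if n_samp % fs != 0:
        raise ValueError(
            "EDF writer requires a whole number of seconds "
            f"({n_samp} samples at {fs} Hz)"
        )
    n_records = n_samp // fs

    phys_max = np.maximum(np.abs(recording.data).max(axis=1), 1e-6)
    # keep the printed value representable in the 8-char header field
    phys_max = np.array([float(f"{v:.6g}") for v in phys_max])
    phys_max = np.maximum(phys_max, np.abs(recording.data).max(axis=1))

    header_bytes = 256 * (1 + n_ch)
    with open(path, "wb") as fh:
        fh.write(_edf_field("0", 8))
        fh.write(_edf_field(recording.patient_id[:80], 80))
        fh.write(_edf_field(recording.recording_id[:80], 80))
        fh.write(_edf_field("01.01.00", 8))
        fh.write(_edf_field("00.00.00", 8))
        fh.write(_edf_field(header_bytes, 8))
        fh.write(_edf_field("", 44))
        fh.write(_edf_field(n_records, 8))
        fh.write(_edf_field(1, 8))  # record duration, seconds
        fh.write(_edf_field(n_ch, 4))
        for name in recording.channel_names:
            fh.write(_edf_field(name[:16], 16))
        for _ in range(n_ch):
            fh.write(_edf_field("", 80))  # transducer
        for _ in range(n_ch):
            fh.write(_edf_field("uV", 8))
        for v in phys_max:
            fh.write(_edf_field(f"{-v:.6g}", 8))
        for v in phys_max:
            fh.write(_edf_field(f"{v:.6g}", 8))
        for _ in range(n_ch):
            fh.write(_edf_field(-32767, 8))
        for _ in range(n_ch):
            fh.write(_edf_field(32767, 8))
        for _ in range(n_ch):
            fh.write(_edf_field("", 80))  # prefiltering
        for _ in range(n_ch):
            fh.write(_edf_field(fs, 8))
        for _ in range(n_ch):
            fh.write(_edf_field("", 32))

        scale = 32767.0 / phys_max
        digital = np.rint(recording.data * scale[:, None])
        digital = np.clip(digital, -32767, 32767).astype("<i2")
        # EDF interleaves per-record blocks: rec0 ch0..chN, rec1 ch0..chN, ...
        blocks = digital.reshape(n_ch, n_records, fs).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(blocks).tobytes())


# ---------------------------------------------------------------------------
# annotations

_CHB_FILE_RE = re.compile(r"File Name:\s*(\S+)", re.IGNORECASE)
_CHB_START_RE = re.compile(
    r"Seizure(?:\s+\d+)?\s+Start Time:\s*([0-9.]+)\s*sec", re.IGNORECASE
)
_CHB_END_RE = re.compile(
    r"Seizure(?:\s+\d+)?\s+End Time:\s*([0-9.]+)\s*sec", re.IGNORECASE
)


def _check_disjoint(events: list[SeizureEvent]) -> list[SeizureEvent]:
    events = sorted(events, key=lambda e: (e.recording_id, e.onset))
    for a, b in zip(events, events[1:]):
        if a.recording_id == b.recording_id and b.onset < a.offset:
            raise AnnotationError(
                f"overlapping seizures in {a.recording_id!r}: "
                f"[{a.onset}, {a.offset}] and [{b.onset}, {b.offset}]"
            )
    return sorted(events, key=lambda e: e.onset)


def _parse_chb_summary(text: str) -> list[SeizureEvent]:
    events: list[SeizureEvent] = []
    current_file = ""
    pending_start: float | None = None
    for line in text.splitlines():
        m = _CHB_FILE_RE.search(line)
        if m:
            if pending_start is not None:
                raise AnnotationError(
                    f"seizure start without end in {current_file!r}"
                )
            current_file = m.group(1).removesuffix(".edf")
            continue
        m = _CHB_START_RE.search(line)
        if m:
            if pending_start is not None:
                raise AnnotationError("two seizure starts without an end")
            pending_start = float(m.group(1))
            continue
        m = _CHB_END_RE.search(line)
        if m:
            if pending_start is None:
                raise AnnotationError("seizure end without a start")
            end = float(m.group(1))
            if end <= pending_start:
                raise AnnotationError(
                    f"seizure end {end} not after start {pending_start}"
                )
            events.append(SeizureEvent(pending_start, end, current_file))
            pending_start = None
    if pending_start is not None:
        raise AnnotationError("trailing seizure start without an end")
    return events


def read_annotations(path: str | Path) -> list[SeizureEvent]:
    """Parse seizure events from a CHB-MIT text summary or a JSON sidecar.

    Events are returned sorted by onset; overlapping events within one
    recording raise :class:`AnnotationError`.
    """
    path = Path(path)
    text = path.read_text()
    stripped = text.lstrip()
    if path.suffix == ".json" or stripped.startswith(("{", "[")):
        payload = json.loads(text)
        rows = payload["events"] if isinstance(payload, dict) else payload
        events = []
        for row in rows:
            if row["offset_s"] <= row["onset_s"]:
                raise AnnotationError(
                    f"event offset {row['offset_s']} not after onset "
                    f"{row['onset_s']}"
                )
            events.append(
                SeizureEvent(
                    float(row["onset_s"]), float(row["offset_s"]),
                    str(row.get("recording_id", "")),
                )
            )
    else:
        events = _parse_chb_summary(text)
    return _check_disjoint(events)


def write_annotations(events: list[SeizureEvent], path: str | Path) -> Path:
    """Write events to the JSON annotation dialect."""
    path = Path(path)
    payload = {
        "events": [
            {
                "recording_id": e.recording_id,
                "onset_s": e.onset,
                "offset_s": e.offset,
            }
            for e in sorted(events, key=lambda e: e.onset)
        ]
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def write_fixture(recording: Recording, events: list[SeizureEvent],
                  out_dir: str | Path) -> tuple[Path, Path]:
    """Write an EDF + JSON annotation pair for one recording.

    Returns ``(edf_path, json_path)``. Reading the pair back reproduces the
    shapes, sampling rate and events exactly, and sample values within the
    16-bit quantization of the per-channel physical range.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    edf_path = out_dir / f"{recording.recording_id}.edf"
    json_path = out_dir / f"{recording.recording_id}.json"
    _write_edf(edf_path, recording)
    tagged = [
        SeizureEvent(e.onset, e.offset, e.recording_id or recording.recording_id)
        for e in events
    ]
    write_annotations(tagged, json_path)
    return edf_path, json_path
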