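"""Seeded synthetic scalp-EEG cohorts with seizures and domain shift.

Each simulated patient has fixed "traits" drawn from their seed: a 16x16
spatial mixing matrix for the 1/f^beta background sources, a 10 Hz
rhythm with per-channel amplitude and phase, a persistent patient-specific
narrowband background rhythm (beta-burst-like activity in whichever
spectral niche the preictal signature does not occupy), per-channel
weights for the preictal signature, and a signature band. The preictal
signature is band-limited noise (default 6 Hz wide around 30 Hz, the band
center displaced by the ``shift`` parameter to emulate inter-patient
domain shift) whose amplitude ramps linearly from zero to ``effect_size``
times the background RMS over the 30 minutes before each onset. A slow
multiplicative gain drift models electrode-impedance variation so overall
amplitude scale is never a reliable class cue. Ictal spans are a
high-amplitude 3 Hz oscillation and are annotated as seizure events.

Everything is reproducible bit-for-bit from the master seed. The layout
follows the fixture convention: one recording per seizure (pre-onset +
ictal + padding) plus seizure-free interictal recordings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .io import Recording, SeizureEvent, CHB_MIT_16, write_fixture

__all__ = ["SimConfig", "PatientTraits", "simulate_patient",
           "simulate_interictal", "simulate_cohort"]

RAMP_S = 30.0 * 60.0  # signature ramp duration before each onset


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator (times in minutes, amps in uV)."""

    n_channels: int = 16
    fs: float = 256.0
    n_seizures: int = 1
    pre_onset_min: float = 40.0
    ictal_min: float = 5.0
    post_min: float = 1.0
    effect_size: float = 3.0
    shift: float = 0.0
    noise_exponent: float = 1.0
    base_center_hz: float = 30.0
    bandwidth_hz: float = 6.0
    rhythm_hz: float = 10.0
    background_rms_uv: float = 20.0
    ictal_amp: float = 2.0
    am_depth: float = 0.15
    am_period_s: float = 600.0
    bg_band_amp: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels != 16 or self.fs != 256.0:
            raise ValueError("simulator emulates 16 channels at 256 Hz")
        if self.pre_onset_min < 30.0:
            raise ValueError("pre_onset_min must be >= 30 (labeling needs a "
                             "full 30-minute pre-onset span)")
        if self.effect_size < 0 or self.shift < 0:
            raise ValueError("effect_size and shift must be >= 0")
        if self.n_seizures < 0 or self.ictal_min <= 0:
            raise ValueError("invalid seizure layout")

    @property
    def center_hz(self) -> float:
        """Preictal signature band center for this patient."""
        return float(np.clip(self.base_center_hz + self.shift, 15.0, 45.0))

    @property
    def bg_center_hz(self) -> float:
        """Center of the patient's persistent background rhythm.

        Interictal EEG has narrowband structure of its own (beta bursts,
        spindle-like activity); modelling it forces classifiers to be
        frequency-specific instead of flagging any high-frequency power.
        The background rhythm occupies whichever of the two spectral
        niches (around 30 Hz and around 45 Hz) the preictal signature
        does not use.
        """
        return 45.0 if self.center_hz < 37.5 else 30.0


@dataclass
class PatientTraits:
    """Per-patient ground truth, fixed across that patient's recordings."""

    mixing: np.ndarray          # (16, 16) background source mixing
    rhythm_amp: np.ndarray      # (16,) relative 10 Hz amplitude
    rhythm_phase: np.ndarray    # (16,)
    signature_w: np.ndarray     # (16,) preictal signature channel weights
    ictal_w: np.ndarray         # (16,)
    bg_band_w: np.ndarray       # (16,) background-rhythm channel weights
    center_hz: float
    bandwidth_hz: float
    bg_center_hz: float

    def descriptor(self, cfg: SimConfig) -> dict:
        return {
            "center_hz": self.center_hz,
            "bandwidth_hz": self.bandwidth_hz,
            "bg_center_hz": self.bg_center_hz,
            "effect_size": cfg.effect_size,
            "shift": cfg.shift,
            "signature_weights": self.signature_w.tolist(),
        }


def patient_traits(cfg: SimConfig, patient_seed: int) -> PatientTraits:
    rng = np.random.default_rng([patient_seed, 11])
    mixing = rng.normal(0.0, 1.0, (cfg.n_channels, cfg.n_channels))
    mixing /= np.linalg.norm(mixing, axis=1, keepdims=True)
    return PatientTraits(
        mixing=mixing,
        rhythm_amp=rng.uniform(0.2, 0.8, cfg.n_channels),
        rhythm_phase=rng.uniform(0.0, 2 * np.pi, cfg.n_channels),
        signature_w=rng.uniform(0.5, 1.0, cfg.n_channels),
        ictal_w=rng.uniform(0.5, 1.0, cfg.n_channels),
        bg_band_w=rng.uniform(0.2, 1.0, cfg.n_channels),
        center_hz=cfg.center_hz,
        bandwidth_hz=cfg.bandwidth_hz,
        bg_center_hz=cfg.bg_center_hz,
    )


def _pink_noise(rng: np.random.Generator, n: int, fs: float, beta: float
                ) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[0] = 0.0
    spec[1:] *= freqs[1:] ** (-beta / 2.0)
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                lo: float, hi: float) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < lo) | (freqs > hi)] = 0.0
    x = np.fft.irfft(spec, n)
    return x / max(x.std(), 1e-12)


def _background(cfg: SimConfig, traits: PatientTraits,
                rng: np.random.Generator, n: int) -> np.ndarray:
    sources = np.stack([
        _pink_noise(rng, n, cfg.fs, cfg.noise_exponent)
        for _ in range(cfg.n_channels)
    ])
    x = traits.mixing @ sources
    x /= x.std(axis=1, keepdims=True)
    x *= cfg.background_rms_uv
    t = np.arange(n) / cfg.fs
    rhythm = np.sin(2 * np.pi * cfg.rhythm_hz * t[None, :]
                    + traits.rhythm_phase[:, None])
    x += (traits.rhythm_amp[:, None] * cfg.background_rms_uv) * rhythm
    if cfg.bg_band_amp > 0:
        bg = _band_noise(rng, n, cfg.fs,
                         traits.bg_center_hz - cfg.bandwidth_hz / 2.0,
                         traits.bg_center_hz + cfg.bandwidth_hz / 2.0)
        x += (traits.bg_band_w[:, None]
              * cfg.bg_band_amp * cfg.background_rms_uv) * bg[None, :]
    return x


def _gain_drift(cfg: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """Slow multiplicative amplitude drift common to all channels.

    Real scalp recordings show gain/impedance drift on the scale of
    minutes; modelling it keeps overall signal scale from being a reliable
    class cue after per-recording normalization.
    """
    phase = rng.uniform(0.0, 2 * np.pi)
    t = np.arange(n) / cfg.fs
    return 1.0 + cfg.am_depth * np.sin(2 * np.pi * t / cfg.am_period_s + phase)


def simulate_patient(
    cfg: SimConfig,
    patient_id: str = "sim00",
    recording_id: str | None = None,
    traits: PatientTraits | None = None,
    stream: int = 0,
) -> tuple[Recording, list[SeizureEvent], dict]:
    """One continuous recording with ``cfg.n_seizures`` seizures.

    Each seizure occupies a ``pre_onset + ictal + post`` block; the
    preictal signature ramps over the 30 minutes before each onset.
    ``stream`` separates the noise of multiple recordings of the same
    patient while ``traits`` (derived from the seed when omitted) stay
    shared.
    """
    traits = traits or patient_traits(cfg, cfg.seed)
    rng = np.random.default_rng([cfg.seed, 101, stream])
    fs = cfg.fs
    block_s = (cfg.pre_onset_min + cfg.ictal_min + cfg.post_min) * 60.0
    block_n = int(round(block_s * fs))
    n = max(block_n * cfg.n_seizures, int(round(60.0 * fs)))
    data = _background(cfg, traits, rng, n)
    drift = _gain_drift(cfg, rng, n)
    t = np.arange(n) / fs

    events: list[SeizureEvent] = []
    rec_id = recording_id or f"{patient_id}_r{stream:02d}"
    for k in range(cfg.n_seizures):
        block_t0 = k * block_s
        onset = block_t0 + cfg.pre_onset_min * 60.0
        offset = onset + cfg.ictal_min * 60.0
        events.append(SeizureEvent(onset, offset, rec_id))

        sig = _band_noise(rng, n, fs,
                          traits.center_hz - traits.bandwidth_hz / 2.0,
                          traits.center_hz + traits.bandwidth_hz / 2.0)
        ramp = np.clip((t - (onset - RAMP_S)) / RAMP_S, 0.0, 1.0)
        ramp[(t < block_t0) | (t >= onset)] = 0.0
        amp = cfg.effect_size * cfg.background_rms_uv * ramp
        data += traits.signature_w[:, None] * (amp * sig)[None, :]

    data *= drift[None, :]
    for event in events:
        ictal_mask = (t >= event.onset) & (t < event.offset)
        wave = np.sin(2 * np.pi * 3.0 * t) + 0.4 * np.sin(2 * np.pi * 6.0 * t)
        data[:, ictal_mask] += (
            traits.ictal_w[:, None]
            * cfg.ictal_amp * cfg.background_rms_uv
            * wave[None, ictal_mask]
        )

    recording = Recording(
        patient_id=patient_id,
        data=data.astype(np.float32),
        fs=fs,
        channel_names=list(CHB_MIT_16),
        recording_id=rec_id,
    )
    return recording, events, traits.descriptor(cfg)


def simulate_interictal(
    cfg: SimConfig,
    duration_min: float,
    patient_id: str = "sim00",
    recording_id: str | None = None,
    traits: PatientTraits | None = None,
    stream: int = 0,
) -> Recording:
    """A seizure-free background recording for the same patient."""
    traits = traits or patient_traits(cfg, cfg.seed)
    rng = np.random.default_rng([cfg.seed, 101, stream])
    n = int(round(duration_min * 60.0 * cfg.fs))
    data = _background(cfg, traits, rng, n)
    data *= _gain_drift(cfg, rng, n)[None, :]
    return Recording(
        patient_id=patient_id,
        data=data.astype(np.float32),
        fs=cfg.fs,
        channel_names=list(CHB_MIT_16),
        recording_id=recording_id or f"{patient_id}_r{stream:02d}",
    )


def simulate_cohort(
    n_source: int,
    n_target: int,
    cfg: SimConfig,
    out_dir: str | Path,
    target_shift: float | None = None,
    target_seizures: int = 6,
    interictal_files: int = 1,
    target_interictal_files: int = 2,
    interictal_min: float = 30.0,
) -> dict:
    """Write a fixture cohort to disk and return its manifest.

    Source patients share ``shift = 0``; target patients get
    ``target_shift`` (default: ``cfg.shift`` if positive, else 10 Hz).
    One EDF+JSON pair per seizure, plus seizure-free interictal files.
    The same master seed regenerates the identical cohort.
    """
    out_dir = Path(out_dir)
    if target_shift is None:
        target_shift = cfg.shift if cfg.shift > 0 else 10.0
    manifest: dict = {"master_seed": cfg.seed, "patients": []}
    for p in range(n_source + n_target):
        is_target = p >= n_source
        pid = f"sim{p:02d}"
        shift = float(target_shift) if is_target else 0.0
        pseed = int(cfg.seed * 1009 + p) % (2 ** 31)
        pcfg = replace(cfg, shift=shift, seed=pseed, n_seizures=1)
        traits = patient_traits(pcfg, pseed)
        pdir = out_dir / pid
        entry = {"id": pid, "role": "target" if is_target else "source",
                 "shift": shift, "seizure_recordings": [],
                 "interictal_recordings": []}
        n_seiz = target_seizures if is_target else cfg.n_seizures
        n_inter = target_interictal_files if is_target else interictal_files
        for s in range(n_seiz):
            rec, events, _ = simulate_patient(
                pcfg, pid, recording_id=f"{pid}_s{s:02d}",
                traits=traits, stream=s)
            write_fixture(rec, events, pdir)
            entry["seizure_recordings"].append(rec.recording_id)
        for j in range(n_inter):
            rec = simulate_interictal(
                pcfg, interictal_min, pid,
                recording_id=f"{pid}_i{j:02d}", traits=traits,
                stream=100 + j)
            write_fixture(rec, [], pdir)
            entry["interictal_recordings"].append(rec.recording_id)
        manifest["patients"].append(entry)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
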