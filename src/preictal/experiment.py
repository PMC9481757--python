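"""End-to-end experiment pipelines on simulated cohorts.

This module glues the pieces together the way the study protocol does:
simulate a cohort, preprocess, window, train the generalizable classifier
on the source patients, evaluate it on held-out patients, adapt it to the
target patient from a few seizures, and score everything with alarm-based
sensitivity, FPR/h and segment AUC.

The benchmark sizes used here (31-minute pre-onset blocks, 1-minute ictal
spans, 2 seizures per source patient, at most 300 training segments per
class, reduced epochs with early stopping) are the package's desk-scale
study conditions; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .evaluate import AlarmRule, adjudicate, auc, fire_alarms, fpr_per_hour, \
    sensitivity
from .fewshot import TransferProtocol, finetune, split_target_seizures
from .io import Recording, SeizureEvent
from .model import EncoderSpec, HeadSpec, ModelBundle, TrainConfig, \
    train_generalizable
from .preprocess import FilterSpec, bandpass_notch, normalize
from .synth import SimConfig, patient_traits, simulate_interictal, \
    simulate_patient
from .windowing import TrialConfig, WindowSpec, build_balanced_trainset, \
    segment_interval

__all__ = [
    "PatientData",
    "make_patient",
    "prepare_recording",
    "evaluate_patient",
    "loocv_generalizable",
    "run_fewshot_benchmark",
    "BENCHMARK_SIM",
    "BENCHMARK_ENCODER",
    "BENCHMARK_HEAD_HIDDEN",
]

#: Desk-scale simulator conditions for the few-shot benchmark.
BENCHMARK_SIM = SimConfig(
    pre_onset_min=31.0, ictal_min=1.0, post_min=0.5,
)
#: Target-patient signature band displacement (Hz) in the benchmark:
#: moves the preictal band from the source cohort's 30 Hz center to 45 Hz.
BENCHMARK_SHIFT = 15.0
#: Reduced encoder/head widths keeping one-CPU training tractable.
BENCHMARK_ENCODER = EncoderSpec(channels=(4, 8))
BENCHMARK_HEAD_HIDDEN = (32, 16)


@dataclass
class PatientData:
    """All recordings of one simulated patient, preprocessed."""

    patient_id: str
    seizure_recordings: list[tuple[Recording, list[SeizureEvent]]]
    interictal_recordings: list[Recording]
    shift: float = 0.0
    role: str = "source"

    @property
    def events(self) -> list[SeizureEvent]:
        return [e for _, evs in self.seizure_recordings for e in evs]

    def pairs(self, interictal: bool = True):
        out = list(self.seizure_recordings)
        if interictal:
            out += [(rec, []) for rec in self.interictal_recordings]
        return out


def prepare_recording(recording: Recording,
                      filt: FilterSpec = FilterSpec()) -> Recording:
    """The preprocessing applied exactly once: bandpass+notch, then z-score."""
    return normalize(bandpass_notch(recording, filt))


def make_patient(
    cfg: SimConfig,
    patient_id: str,
    patient_seed: int,
    shift: float = 0.0,
    n_seizures: int = 2,
    n_interictal: int = 1,
    interictal_min: float = 30.0,
    filt: FilterSpec = FilterSpec(),
) -> PatientData:
    """Simulate and preprocess one patient (one recording per seizure)."""
    pcfg = replace(cfg, shift=shift, seed=patient_seed, n_seizures=1)
    traits = patient_traits(pcfg, patient_seed)
    seiz = []
    for s in range(n_seizures):
        rec, events, _ = simulate_patient(
            pcfg, patient_id, recording_id=f"{patient_id}_s{s:02d}",
            traits=traits, stream=s)
        seiz.append((prepare_recording(rec, filt), events))
    inter = [
        prepare_recording(
            simulate_interictal(
                pcfg, interictal_min, patient_id,
                recording_id=f"{patient_id}_i{j:02d}", traits=traits,
                stream=100 + j),
            filt,
        )
        for j in range(n_interictal)
    ]
    return PatientData(patient_id, seiz, inter, shift=shift,
                       role="target" if shift > 0 else "source")


def evaluate_patient(
    bundle: ModelBundle,
    seizure_pairs: list[tuple[Recording, list[SeizureEvent]]],
    interictal_recordings: list[Recording],
    trial: TrialConfig,
    spec: WindowSpec = WindowSpec(),
    rule: AlarmRule | None = None,
) -> dict:
    """Alarm-based metrics for one patient's test recordings.

    Sensitivity comes from the seizure recordings (scored over the whole
    pre-onset span), false alarms and monitored hours from the seizure-free
    interictal recordings, and AUC from the labeled non-overlapping test
    segments of both.
    """
    if rule is None:
        threshold = 0.0 if bundle.head_spec.kind == "svm" else 0.5
        rule = AlarmRule(threshold=threshold,
                         refractory_s=trial.sph_s + trial.sop_s)

    from .windowing import preictal_interval

    auc_scores: list[np.ndarray] = []
    auc_labels: list[np.ndarray] = []
    predicted = total = 0
    for rec, events in seizure_pairs:
        total += len(events)
        horizon = min(e.onset for e in events)
        segs = segment_interval(rec, (0.0, horizon), spec, 0.0)
        if not segs:
            continue
        s = bundle.predict_scores(np.stack([g.x for g in segs]))
        series = fire_alarms([g.t_start for g in segs], s, rule, spec.win_s)
        adj = adjudicate(series, events, trial)
        predicted += adj.predicted_seizures
        # preictal segments (fully inside a preictal interval) enter the AUC
        spans = [preictal_interval(e, trial) for e in events]
        spans = [sp for sp in spans if sp is not None]
        t0 = np.array([g.t_start for g in segs])
        in_pre = np.zeros(len(segs), bool)
        for lo, hi in spans:
            in_pre |= (t0 >= lo - 1e-9) & (t0 + spec.win_s <= hi + 1e-9)
        auc_scores.append(s[in_pre])
        auc_labels.append(np.ones(int(in_pre.sum()), int))

    false_alarms = 0
    hours = 0.0
    for rec in interictal_recordings:
        segs = segment_interval(rec, (0.0, rec.duration), spec, 0.0)
        if not segs:
            continue
        s = bundle.predict_scores(np.stack([g.x for g in segs]))
        series = fire_alarms([g.t_start for g in segs], s, rule, spec.win_s)
        adj = adjudicate(series, [], trial)
        false_alarms += len(adj.false_alarms)
        hours += rec.duration / 3600.0
        auc_scores.append(s)
        auc_labels.append(np.zeros(s.size, int))

    seg_auc = auc(np.concatenate(auc_scores), np.concatenate(auc_labels))
    return {
        "sensitivity_pct": sensitivity(predicted, total) if total else float("nan"),
        "fpr_per_h": fpr_per_hour(false_alarms, hours) if hours > 0 else float("nan"),
        "auc": seg_auc,
        "predicted_seizures": predicted,
        "total_seizures": total,
        "false_alarms": false_alarms,
        "interictal_hours": hours,
    }


def loocv_generalizable(
    patients: list[PatientData],
    trial: TrialConfig,
    cfg: TrainConfig,
    head: HeadSpec = HeadSpec(),
    encoder: EncoderSpec = EncoderSpec(),
    spec: WindowSpec = WindowSpec(),
    max_per_class: int | None = 300,
) -> dict[str, dict]:
    """Leave-one-patient-out evaluation of the generalizable model."""
    from .evaluate import loocv_folds

    by_id = {p.patient_id: p for p in patients}
    report: dict[str, dict] = {}
    for train_ids, test_id in loocv_folds([p.patient_id for p in patients]):
        pairs = [pair for pid in train_ids for pair in by_id[pid].pairs()]
        train_set = build_balanced_trainset(
            pairs, trial, spec, seed=cfg.seed, max_per_class=max_per_class)
        bundle = train_generalizable(train_set, cfg, head, encoder)
        held = by_id[test_id]
        report[test_id] = evaluate_patient(
            bundle, held.seizure_recordings, held.interictal_recordings,
            trial, spec)
    return report


@dataclass
class BenchmarkResult:
    auc_source: float
    auc_target_generalizable: float
    auc_target_fewshot: float
    target_metrics: dict = field(default_factory=dict)
    per_seed: list[dict] = field(default_factory=list)


def _benchmark_once(seed: int, trial: TrialConfig, classifier: str,
                    n_sources: int, epochs: int,
                    max_per_class: int) -> dict:
    cfg = replace(BENCHMARK_SIM, seed=seed)
    spec = WindowSpec()
    sources = [
        make_patient(cfg, f"src{p:02d}", (seed * 1009 + p) % (2 ** 31),
                     shift=0.0, n_seizures=1, interictal_min=25.0)
        for p in range(n_sources)
    ]
    heldout = make_patient(cfg, "held00",
                           (seed * 1009 + n_sources) % (2 ** 31),
                           shift=0.0, n_seizures=2)
    target = make_patient(cfg, "tgt00",
                          (seed * 1009 + n_sources + 1) % (2 ** 31),
                          shift=BENCHMARK_SHIFT, n_seizures=6, n_interictal=2)

    train_cfg = TrainConfig(seed=seed % (2 ** 31), epochs=epochs,
                            early_stop_patience=3)
    head = HeadSpec(kind=classifier, fc_hidden=BENCHMARK_HEAD_HIDDEN)
    pairs = [pair for p in sources for pair in p.pairs()]
    train_set = build_balanced_trainset(
        pairs, trial, spec, seed=train_cfg.seed, max_per_class=max_per_class)
    bundle = train_generalizable(train_set, train_cfg, head, BENCHMARK_ENCODER)

    held_metrics = evaluate_patient(
        bundle, heldout.seizure_recordings, heldout.interictal_recordings,
        trial, spec)

    protocol = TransferProtocol(
        source_patients=frozenset(p.patient_id for p in sources),
        target_patient=target.patient_id,
    )
    tune_events, test_events = split_target_seizures(target.events, protocol)
    tune_ids = {e.recording_id for e in tune_events}
    test_ids = {e.recording_id for e in test_events}
    tune_pairs = [(r, e) for r, e in target.seizure_recordings
                  if r.recording_id in tune_ids]
    test_pairs = [(r, e) for r, e in target.seizure_recordings
                  if r.recording_id in test_ids]
    tune_inter = target.interictal_recordings[:1]
    test_inter = target.interictal_recordings[1:]

    before = evaluate_patient(bundle, test_pairs, test_inter, trial, spec)

    tune_set = build_balanced_trainset(
        tune_pairs + [(rec, []) for rec in tune_inter], trial, spec,
        seed=train_cfg.seed, max_per_class=max_per_class)
    tuned = finetune(bundle, tune_set, train_cfg, protocol)
    after = evaluate_patient(tuned, test_pairs, test_inter, trial, spec)

    return {
        "seed": seed,
        "auc_source": held_metrics["auc"],
        "auc_target_generalizable": before["auc"],
        "auc_target_fewshot": after["auc"],
        "sensitivity_fewshot_pct": after["sensitivity_pct"],
        "fpr_fewshot_per_h": after["fpr_per_h"],
        "sensitivity_generalizable_pct": before["sensitivity_pct"],
        "fpr_generalizable_per_h": before["fpr_per_h"],
        "epochs_run": bundle.train_meta["epochs_run"],
        "n_train_segments": len(train_set),
    }


def run_fewshot_benchmark(
    seed: int = 0,
    n_seeds: int = 5,
    trial: TrialConfig | None = None,
    classifier: str = "svm",
    n_sources: int = 4,
    epochs: int = 8,
    max_per_class: int = 300,
) -> BenchmarkResult:
    """The few-shot transfer benchmark on a synthetic cohort.

    For each of ``n_seeds`` seeds: train the generalizable model on
    ``n_sources`` source patients, measure segment AUC on a held-out
    source-distribution patient, on the shifted target's 3 test seizures
    before fine-tuning, and again after fine-tuning on the target's first
    3 seizures. Seed-averaged AUCs plus the last seed's alarm metrics are
    returned.
    """
    trial = trial or TrialConfig.trial(1)
    per_seed = [
        _benchmark_once((seed + k) % (2 ** 31), trial, classifier,
                        n_sources, epochs, max_per_class)
        for k in range(n_seeds)
    ]
    mean = lambda key: float(np.mean([r[key] for r in per_seed]))
    return BenchmarkResult(
        auc_source=mean("auc_source"),
        auc_target_generalizable=mean("auc_target_generalizable"),
        auc_target_fewshot=mean("auc_target_fewshot"),
        target_metrics={
            "sensitivity_fewshot_pct": mean("sensitivity_fewshot_pct"),
            "fpr_fewshot_per_h": mean("fpr_fewshot_per_h"),
            "sensitivity_generalizable_pct": mean("sensitivity_generalizable_pct"),
            "fpr_generalizable_per_h": mean("fpr_generalizable_per_h"),
        },
        per_seed=per_seed,
    )
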