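"""Few-shot adaptation of the generalizable model to a new patient.

The convolutional encoder (and its batch-normalization statistics) is
frozen — parameter sharing between the source cohort and the target
patient — and only the classifier is updated from a few of the target
patient's seizures: the FC head continues training at a reduced learning
rate on cached encoder features, or the SVM is refitted on them.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace

import numpy as np

from .io import SeizureEvent
from .model import ENCODER_GROUPS, ModelBundle, TrainConfig, _run_epochs
from .windowing import SegmentSet

__all__ = [
    "TransferProtocol",
    "ContaminationError",
    "split_target_seizures",
    "finetune",
    "count_trainable",
]


class ContaminationError(ValueError):
    """Tuning data contains segments that must not be there."""


@dataclass(frozen=True)
class TransferProtocol:
    """Who transfers to whom, and how the target's seizures are split."""

    source_patients: frozenset
    target_patient: str
    n_tune_seizures: int = 3
    n_test_seizures: int = 3
    split_mode: str = "chronological"  # or "random"
    frozen_groups: tuple[str, ...] = ENCODER_GROUPS

    def __post_init__(self) -> None:
        if self.target_patient in self.source_patients:
            raise ValueError(
                f"target patient {self.target_patient!r} appears in the "
                "source cohort"
            )
        if min(self.n_tune_seizures, self.n_test_seizures) < 1:
            raise ValueError("need at least one tuning and one test seizure")
        if self.split_mode not in ("chronological", "random"):
            raise ValueError(f"unknown split_mode {self.split_mode!r}")


def split_target_seizures(
    events: list[SeizureEvent],
    protocol: TransferProtocol,
    seed: int = 0,
) -> tuple[list[SeizureEvent], list[SeizureEvent]]:
    """Disjoint (tune_events, test_events) for the target patient.

    Chronological mode (the default, and seed-independent) assigns the
    earliest ``n_tune_seizures`` to tuning and the next ``n_test_seizures``
    to testing; random mode shuffles with the seed first.
    """
    need = protocol.n_tune_seizures + protocol.n_test_seizures
    if len(events) < need:
        raise ValueError(
            f"target patient has {len(events)} seizures but the protocol "
            f"requires {need} ({protocol.n_tune_seizures} tune + "
            f"{protocol.n_test_seizures} test)"
        )
    ordered = sorted(events, key=lambda e: (e.recording_id, e.onset))
    if protocol.split_mode == "random":
        rng = np.random.default_rng(seed)
        ordered = [ordered[i] for i in rng.permutation(len(ordered))]
    tune = ordered[: protocol.n_tune_seizures]
    test = ordered[protocol.n_tune_seizures: need]
    return tune, test


def finetune(
    bundle: ModelBundle,
    tune_set: SegmentSet,
    cfg: TrainConfig,
    protocol: TransferProtocol,
) -> ModelBundle:
    """Adapt a trained bundle to the target patient, encoder frozen.

    Returns a new bundle whose encoder parameters are bit-identical to the
    input's. The FC head is fine-tuned with Adam at ``learning_rate / 10``
    for at most 20 epochs on cached encoder features; an SVM head is
    refitted on those features. The tune set must be balanced and contain
    only target-patient segments.
    """
    if len(tune_set) == 0:
        raise ValueError("tune_set is empty")
    patients = {s.patient_id for s in tune_set.segments}
    if patients != {protocol.target_patient}:
        raise ContaminationError(
            f"tune_set patients {sorted(patients)} != "
            f"[{protocol.target_patient!r}]"
        )
    n_pre, n_int = tune_set.count("preictal"), tune_set.count("interictal")
    if n_pre != n_int:
        raise ValueError(f"unbalanced tune_set: {n_pre} vs {n_int}")

    net = copy.deepcopy(bundle.net)
    X = tune_set.X[:, None, :, :]
    y = tune_set.y
    feats = net.encode(X)

    new = ModelBundle(
        encoder_spec=bundle.encoder_spec,
        head_spec=bundle.head_spec,
        net=net,
        frozen_mask=frozenset(protocol.frozen_groups),
        train_meta=dict(bundle.train_meta),
    )
    if bundle.head_spec.kind == "svm":
        from sklearn.svm import SVC

        svm = SVC(kernel=bundle.head_spec.svm_kernel, C=bundle.head_spec.svm_C,
                  random_state=cfg.seed)
        svm.fit(feats, y)
        new.svm = svm
        new.train_meta["finetune"] = {"seed": cfg.seed, "kind": "svm_refit"}
    else:
        ft_cfg = replace(cfg, learning_rate=cfg.learning_rate / 10.0,
                         epochs=min(cfg.epochs, 20))
        rng = np.random.default_rng(cfg.seed + 2)
        head_names = [n for n in net.param_names()
                      if n.split(".")[0] not in protocol.frozen_groups]

        def fwd(batch, train, fwd_rng):
            return net.head_forward(batch, train, fwd_rng)

        def bwd(dlogits, cache):
            _, grads = net.head_backward(dlogits, cache)
            return grads

        train_losses, val_losses = _run_epochs(
            net, feats, y, None, np.empty(0, int), ft_cfg, head_names,
            ft_cfg.learning_rate, ft_cfg.epochs, rng, fwd, bwd,
        )
        new.train_meta["finetune"] = {
            "seed": cfg.seed,
            "epochs_run": len(train_losses),
            "train_losses": train_losses,
        }
    return new


def count_trainable(bundle: ModelBundle,
                    protocol: TransferProtocol | None = None) -> int:
    """Number of parameters the adaptation step may update.

    With the encoder frozen this is the head size: the FC head's parameter
    count, or for an SVM head the dimension of the linear decision function
    it is fitted in (feature length + intercept). With nothing frozen it is
    the total network parameter count.
    """
    frozen = set(protocol.frozen_groups) if protocol is not None else set(
        bundle.frozen_mask)
    if bundle.head_spec.kind == "svm" and frozen:
        return bundle.net.feature_dim + 1
    return int(sum(
        v.size for n, v in bundle.net.params.items()
        if n.split(".")[0] not in frozen
    ))
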