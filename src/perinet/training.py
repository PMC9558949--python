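"""Patient-wise cross-validation, class balancing, augmentation and training.

The evaluation protocol is a rotating, patient-wise 10-fold cross-validation:
in iteration *i* fold *i* is the test set, fold *(i-1) mod k* the validation
set, and the remaining eight folds the training set, so that every patient
appears exactly once as test and exactly once as validation across the ten
iterations.  Folds are built at the patient level — all samples of a patient
(per-lesion boxes, 2D slices) travel together — which rules out leakage of a
subject between training and evaluation.

The training set is balanced by replicating randomly chosen minority-class
(LN+) samples until the class counts are equal, and augmented on the fly with
random in-plane flips and right-angle rotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .bounding import BoundedSample
from .nets import Network, build, NET_FOR_OPTION
from . import nn

__all__ = [
    "FoldPlan",
    "TrainConfig",
    "build_folds",
    "balance_training",
    "augment",
    "train_network",
    "train_one_fold",
    "grid_search",
]


@dataclass
class FoldPlan:
    """A k-fold patient partition with the rotating validation assignment."""

    folds: list[list[str]]
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)

    def iteration(self, i: int) -> tuple[list[str], list[str], list[str]]:
        """(train_ids, val_ids, test_ids) for iteration ``i``."""
        if not 0 <= i < self.k:
            raise IndexError(f"iteration {i} out of range for k={self.k}")
        test = list(self.folds[i])
        val = list(self.folds[(i - 1) % self.k])
        train = [
            pid
            for j, fold in enumerate(self.folds)
            if j not in (i, (i - 1) % self.k)
            for pid in fold
        ]
        return train, val, test

    def all_patients(self) -> list[str]:
        return [pid for fold in self.folds for pid in fold]


def build_folds(
    patient_ids: Sequence[str],
    labels: Sequence[int],
    k: int = 10,
    seed: int = 0,
    groups: dict[str, str] | None = None,
) -> FoldPlan:
    """Label-stratified patient-wise fold assignment.

    Within each class, patients are shuffled by ``seed`` and dealt
    round-robin to folds 0..k-1, so remainders land in the earliest folds.
    ``groups`` optionally maps a lesion-level patient id to its original
    subject (bilateral cases); grouped ids are dealt as one unit and share a
    fold, preventing cross-fold leakage of a subject.
    """
    patient_ids = [str(p) for p in patient_ids]
    labels = [int(l) for l in labels]
    if len(patient_ids) != len(labels):
        raise ValueError("patient_ids and labels differ in length")
    if len(set(patient_ids)) != len(patient_ids):
        raise ValueError("duplicate patient ids")
    if len(patient_ids) < k:
        raise ValueError(f"need at least k={k} patients, got {len(patient_ids)}")
    groups = groups or {}
    # unit = original subject; label of a unit = max over members (LN+ wins)
    unit_members: dict[str, list[str]] = {}
    unit_label: dict[str, int] = {}
    for pid, lab in zip(patient_ids, labels):
        unit = groups.get(pid, pid)
        unit_members.setdefault(unit, []).append(pid)
        unit_label[unit] = max(unit_label.get(unit, 0), lab)
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(k)]
    for lab in sorted(set(unit_label.values()), reverse=True):
        units = sorted(u for u, l in unit_label.items() if l == lab)
        rng.shuffle(units)
        for pos, unit in enumerate(units):
            folds[pos % k].extend(unit_members[unit])
    return FoldPlan(folds=folds, seed=seed)


@dataclass
class TrainConfig:
    """Training hyperparameters.

    Defaults are the full-scale settings: Adam at learning rate 1e-6 with
    weight decay 1e-4, cross-entropy loss, up to 500 epochs, batch size 16
    for the 3D networks and 32 for the 2D one, flip/rotation augmentation
    with probability 0.5 each.  ``width_scale`` builds a channel-scaled
    network of the same family for reduced-scale experiments.
    """

    max_epochs: int = 500
    batch_size: int = 16
    learning_rate: float = 1e-6
    weight_decay: float = 1e-4
    augment_prob: float = 0.5
    width_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.max_epochs, self.batch_size) < 1 or self.learning_rate <= 0:
            raise ValueError(f"invalid training configuration: {self}")
        if self.weight_decay < 0 or not 0 <= self.augment_prob <= 1:
            raise ValueError(f"invalid training configuration: {self}")


def default_config_for(option: str, **overrides) -> TrainConfig:
    """The full-scale configuration for a bounding option (batch 32 for 2ds)."""
    cfg = TrainConfig(batch_size=32 if option == "2ds" else 16)
    return replace(cfg, **overrides)


def balance_training(
    samples: list[BoundedSample], seed: int = 0
) -> list[BoundedSample]:
    """Equalize class counts by replicating random minority-class samples.

    The majority class is untouched and no sample is dropped; replication
    samples the minority with replacement under ``seed``.
    """
    pos = [s for s in samples if s.label == 1]
    neg = [s for s in samples if s.label == 0]
    if not pos or not neg:
        raise ValueError("balancing needs both classes in the training set")
    minority, majority = (pos, neg) if len(pos) < len(neg) else (neg, pos)
    deficit = len(majority) - len(minority)
    rng = np.random.default_rng(seed)
    extra = [minority[i] for i in rng.integers(0, len(minority), size=deficit)]
    return samples + extra


def augment(data: np.ndarray, rng: np.random.Generator, prob: float = 0.5) -> np.ndarray:
    """Random in-plane flips and right-angle rotation of one sample.

    Independently with probability ``prob`` each: a vertical flip, a
    horizontal flip, and a rotation by 90, 180 or 270 degrees (chosen
    uniformly).  Transforms act on the first two spatial axes — the in-plane
    axes for both 3D volumes and 2D slices — identically across the four
    channels (and across slices of a volume), so shape and value range are
    preserved.  Order: flips, then rotation.
    """
    out = data
    if rng.random() < prob:
        out = np.flip(out, axis=1)  # vertical: first in-plane axis
    if rng.random() < prob:
        out = np.flip(out, axis=2)  # horizontal: second in-plane axis
    if rng.random() < prob:
        k = int(rng.integers(1, 4))
        out = np.rot90(out, k=k, axes=(1, 2))
    return np.ascontiguousarray(out)


@dataclass
class TrainTrace:
    """Per-epoch training record of one fold."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = float("inf")


def _stack_batch(samples: list[BoundedSample], rng, prob) -> np.ndarray:
    if rng is None:
        return np.stack([s.data for s in samples]).astype(np.float32)
    return np.stack([augment(s.data, rng, prob) for s in samples]).astype(np.float32)


def _eval_loss(net: Network, samples: list[BoundedSample], batch_size: int) -> float:
    losses, n = 0.0, 0
    for i in range(0, len(samples), batch_size):
        chunk = samples[i : i + batch_size]
        x = _stack_batch(chunk, None, 0)
        y = np.array([s.label for s in chunk])
        loss, _ = nn.softmax_cross_entropy(net.logits(x), y)
        losses += loss * len(chunk)
        n += len(chunk)
    return losses / n


def train_network(
    net: Network,
    train_samples: list[BoundedSample],
    val_samples: list[BoundedSample],
    config: TrainConfig,
) -> TrainTrace:
    """Train ``net`` in place; keep the weights with the best validation loss.

    Cross-entropy loss, Adam with weight decay, balanced+augmented training
    batches; the validation loss is tracked every epoch and the checkpoint
    with the lowest value within ``max_epochs`` is restored at the end.
    Raises on an empty training set or a non-finite loss.
    """
    if not train_samples:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(
        net.model.parameters(),
        lr=config.learning_rate,
        weight_decay=config.weight_decay,
    )
    trace = TrainTrace()
    best_state = net.model.get_state()
    order = np.arange(len(train_samples))
    for epoch in range(config.max_epochs):
        rng.shuffle(order)
        epoch_loss, seen = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            chunk = [train_samples[j] for j in order[i : i + config.batch_size]]
            x = _stack_batch(chunk, rng, config.augment_prob)
            y = np.array([s.label for s in chunk])
            logits = net.logits(x, train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, y)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    f"lr={config.learning_rate} may be too high"
                )
            net.model.backward(dlogits)
            opt.step(net.model.gradients())
            epoch_loss += loss * len(chunk)
            seen += len(chunk)
        trace.train_loss.append(epoch_loss / seen)
        if val_samples:
            vl = _eval_loss(net, val_samples, config.batch_size)
        else:
            vl = trace.train_loss[-1]
        trace.val_loss.append(vl)
        if vl < trace.best_val_loss:
            trace.best_val_loss = vl
            trace.best_epoch = epoch
            best_state = net.model.get_state()
    net.model.set_state(best_state)
    return trace


def samples_by_patient(
    samples: list[BoundedSample],
) -> dict[str, list[BoundedSample]]:
    by: dict[str, list[BoundedSample]] = {}
    for s in samples:
        by.setdefault(s.patient_id, []).append(s)
    return by


def train_one_fold(
    samples: list[BoundedSample],
    plan: FoldPlan,
    iteration: int,
    option: str,
    config: TrainConfig,
) -> tuple[Network, TrainTrace]:
    """Run one cross-validation iteration for one bounding option.

    Assembles the training/validation sample lists from the fold plan,
    balances the training set, trains the option's network and returns it
    with its per-epoch trace.
    """
    by_patient = samples_by_patient(samples)
    train_ids, val_ids, _ = plan.iteration(iteration)
    train = [s for pid in train_ids for s in by_patient.get(pid, [])]
    val = [s for pid in val_ids for s in by_patient.get(pid, [])]
    if not train:
        raise ValueError(f"iteration {iteration}: no training samples")
    train = balance_training(train, seed=config.seed + iteration)
    spec = build(NET_FOR_OPTION[option], width_scale=config.width_scale)
    net = Network(spec, seed=config.seed + iteration)
    trace = train_network(net, train, val, config)
    return net, trace


def grid_search(
    samples: list[BoundedSample],
    plan: FoldPlan,
    option: str,
    grid: list[TrainConfig],
    iterations: Sequence[int] | None = None,
) -> TrainConfig:
    """Pick the configuration with the lowest mean validation loss.

    Every grid point is trained on the given CV iterations (all k by
    default); ties break toward the smaller learning rate, then the smaller
    batch size.
    """
    if not grid:
        raise ValueError("empty configuration grid")
    iterations = list(iterations if iterations is not None else range(plan.k))
    results = []
    for cfg in grid:
        losses = []
        for it in iterations:
            _, trace = train_one_fold(samples, plan, it, option, cfg)
            losses.append(trace.best_val_loss)
        results.append((float(np.mean(losses)), cfg.learning_rate, cfg.batch_size, cfg))
    results.sort(key=lambda r: (r[0], r[1], r[2]))
    return results[0][3]
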