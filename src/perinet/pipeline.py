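"""End-to-end orchestration: cohort -> bounding samples -> CV training ->
patient-level evaluation.

This is the programmatic entry point the command-line interface wraps; it
also backs the reduced-scale class-recovery experiments.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .bounding import BoundedSample, run_option
from .dce_data import DCESeries, load_cohort, make_stack
from .evaluation import EvalReport, evaluate_patients
from .nets import NET_FOR_OPTION
from .synthetic import PhantomConfig, generate_cohort
from .training import (
    FoldPlan,
    TrainConfig,
    build_folds,
    samples_by_patient,
    train_one_fold,
)

__all__ = [
    "RunConfig",
    "extract_samples",
    "run_cross_validation",
    "evaluate_with_networks",
    "run_end_to_end",
]


@dataclass
class RunConfig:
    """One full experiment: a cohort, a bounding option, training settings."""

    option: str = "svb"
    out_dir: str = "perinet_run"
    metadata_csv: str | None = None  # load a cohort; None -> simulate one
    k_folds: int = 10
    seed: int = 0
    train: TrainConfig = field(default_factory=TrainConfig)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)

    def __post_init__(self) -> None:
        if self.option not in NET_FOR_OPTION:
            raise ValueError(
                f"unknown bounding option {self.option!r}; "
                f"valid: {sorted(NET_FOR_OPTION)}"
            )

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        train = TrainConfig(**doc.pop("train", {}))
        phantom = PhantomConfig(**doc.pop("phantom", {}))
        return RunConfig(train=train, phantom=phantom, **doc)

    def to_dict(self) -> dict:
        return {
            **{k: v for k, v in asdict(self).items() if k not in ("train", "phantom")},
            "train": asdict(self.train),
            "phantom": asdict(self.phantom),
        }


def extract_samples(
    series_list: list[DCESeries], option: str
) -> list[BoundedSample]:
    """Apply one bounding option to every patient of a cohort."""
    samples: list[BoundedSample] = []
    for series in series_list:
        samples.extend(run_option(make_stack(series), option))
    return samples


def run_cross_validation(
    series_list: list[DCESeries],
    option: str,
    config: TrainConfig,
    k: int = 10,
    seed: int = 0,
    groups: dict[str, str] | None = None,
) -> tuple[EvalReport, FoldPlan]:
    """Patient-wise rotating k-fold CV of one bounding option.

    Trains one network per iteration, predicts the held-out test patients,
    aggregates sample predictions per patient (majority vote for the hard
    call, mean positive probability for the curves) and pools every patient
    exactly once into the report.
    """
    samples = extract_samples(series_list, option)
    labels = {s.patient_id: s.label for s in series_list}
    plan = build_folds(
        [s.patient_id for s in series_list],
        [labels[s.patient_id] for s in series_list],
        k=k,
        seed=seed,
        groups=groups,
    )
    nets = {
        it: train_one_fold(samples, plan, it, option, config)[0]
        for it in range(plan.k)
    }
    report = evaluate_with_networks(
        samples, labels, plan, nets, option=option, batch_size=config.batch_size
    )
    return report, plan


def evaluate_with_networks(
    samples: list[BoundedSample],
    labels: dict[str, int],
    plan: FoldPlan,
    nets: dict[int, object],
    option: str = "",
    batch_size: int = 16,
) -> EvalReport:
    """Score every test fold with its trained network and build the report.

    ``nets`` maps the CV iteration index to the network that was trained
    with that iteration's training fold; each patient is scored exactly
    once, by the network that never saw it.
    """
    by_patient = samples_by_patient(samples)
    pids, truth, votes, scores = [], [], [], []
    fold_of: dict[str, int] = {}
    for it, net in sorted(nets.items()):
        _, _, test_ids = plan.iteration(it)
        for pid in test_ids:
            pat_samples = by_patient.get(pid, [])
            if not pat_samples:
                continue
            probs = _predict(net, pat_samples, batch_size)
            pids.append(pid)
            truth.append(labels[pid])
            votes.append(_majority(probs))
            scores.append(float(probs[:, 1].mean()))
            fold_of[pid] = it
    return evaluate_patients(pids, truth, votes, scores, fold_of, option=option)


def _predict(net, samples: list[BoundedSample], batch_size: int) -> np.ndarray:
    chunks = []
    for i in range(0, len(samples), batch_size):
        x = np.stack([s.data for s in samples[i : i + batch_size]]).astype(np.float32)
        chunks.append(net.forward(x))
    return np.concatenate(chunks, axis=0)


def _majority(probs: np.ndarray) -> int:
    from .evaluation import majority_vote

    return majority_vote(list(np.argmax(probs, axis=1)))


def run_end_to_end(config: RunConfig) -> EvalReport:
    """Execute the full pipeline for one option and write all artifacts.

    Simulates (or loads) the cohort, extracts the option's samples, runs the
    patient-wise CV, and writes the evaluation report, ROC/PR figures and a
    provenance file to ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.metadata_csv:
        series_list = load_cohort(config.metadata_csv)
    else:
        phantom = PhantomConfig(**{**asdict(config.phantom), "seed": config.seed})
        series_list, _meta = generate_cohort(phantom)
    report, _plan = run_cross_validation(
        series_list,
        config.option,
        config.train,
        k=config.k_folds,
        seed=config.seed,
    )
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
    from .evaluation import plot_curves

    plot_curves(report, out)
    provenance = {
        "config": config.to_dict(),
        "python": platform.python_version(),
        "numpy": np.__version__,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return report
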