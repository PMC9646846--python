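"""Privileged-information distillation from the EEG consensus teacher into a
video-only student.

The teacher — the subjects' consensus over per-subject EEG classifiers — is
available only at training time.  Its logits, smoothed by a softmax
temperature ``T``, become soft labels ``s_i``; the student ``f`` sees video
features only and minimises

    (1/n) sum_i [ (1 - lam) * CE(y_i, softmax(f(x_i)))
                  + lam * CE(s_i, softmax(f(x_i))) ],

a convex combination of hard-label and soft-target cross-entropy controlled
by the imitation factor ``lam`` in [0, 1].  At ``lam = 0`` this is plain
supervised training; at ``lam = 1`` the hard labels are unused.  The
temperature is applied to the teacher only (the student's softmax runs at
T = 1 by default; ``student_temperature`` enables the conventional variant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consensus import consensus_predict
from .models import LogitsRecord, NeuralClassifier, softmax

__all__ = [
    "DistillationConfig",
    "make_teacher_soft_labels",
    "distillation_objective",
    "distill_student",
    "run_grid",
]


@dataclass
class DistillationConfig:
    temperatures: tuple[float, ...] = (1.0, 2.0, 5.0, 10.0, 20.0, 50.0)
    imitation_factors: tuple[float, ...] = (0.25, 0.50, 0.75, 1.00)
    n_runs: int = 5
    seed: int = 0
    student_hidden: int | None = None  # None -> linear student
    max_epochs: int = 200
    learning_rate: float = 5e-3
    weight_decay: float = 1e-3

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.temperatures):
            raise ValueError("temperatures must be positive")
        if any(not 0 <= lam <= 1 for lam in self.imitation_factors):
            raise ValueError("imitation factors must lie in [0, 1]")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


def make_teacher_soft_labels(
    records: list[LogitsRecord],
    temperature: float,
    stimulus_ids: list[int],
) -> dict[int, np.ndarray]:
    """Soft labels ``s_i``: temperature softmax of the consensus (subject-
    averaged) teacher logits, one distribution per requested stimulus."""
    grouped: dict[int, list[LogitsRecord]] = {}
    for r in records:
        grouped.setdefault(r.stimulus_id, []).append(r)
    missing = [j for j in stimulus_ids if j not in grouped]
    if missing:
        raise ValueError(f"no teacher logits for stimuli {missing}")
    return {
        j: softmax(consensus_predict(grouped[j]).mean_logits, temperature)
        for j in stimulus_ids
    }


def distillation_objective(
    logits: np.ndarray,
    y: np.ndarray,
    soft_targets: np.ndarray,
    imitation: float,
) -> tuple[float, np.ndarray]:
    """Value and logit-gradient of the distillation loss at fixed outputs.

    Both terms are cross-entropies against ``softmax(logits)`` — the hard
    term against one-hot ``y``, the soft term against ``s_i`` — averaged
    over instances.  The analytic gradient per instance is
    ``[(1-lam)(p - onehot) + lam (p - s)] / n``, which the finite-difference
    tests verify.
    """
    if not 0 <= imitation <= 1:
        raise ValueError(f"imitation factor must lie in [0, 1], got {imitation}")
    logits = np.asarray(logits, dtype=float)
    n, n_classes = logits.shape
    onehot = np.eye(n_classes)[np.asarray(y, dtype=int)]
    p = softmax(logits)
    logp = logits - logits.max(axis=1, keepdims=True)
    logp = logp - np.log(np.exp(logp).sum(axis=1, keepdims=True))
    hard = -(onehot * logp).sum(axis=1).mean()
    soft = -(soft_targets * logp).sum(axis=1).mean()
    loss = (1.0 - imitation) * hard + imitation * soft
    grad = ((1.0 - imitation) * (p - onehot) + imitation * (p - soft_targets)) / n
    return float(loss), grad


def distill_student(
    X: np.ndarray,
    y: np.ndarray,
    soft_labels: np.ndarray,
    imitation: float,
    n_classes: int,
    seed: int = 0,
    hidden_size: int | None = None,
    max_epochs: int = 200,
    learning_rate: float = 5e-3,
    weight_decay: float = 0.0,
    X_val=None,
    y_val=None,
) -> NeuralClassifier:
    """Train a video-only student against the mixed hard/soft objective."""
    model = NeuralClassifier(
        n_classes=n_classes,
        hidden_size=hidden_size,
        seed=seed,
        max_epochs=max_epochs,
        learning_rate=learning_rate,
        weight_decay=weight_decay,
    )
    return model.fit(
        X, y, soft_targets=soft_labels, imitation=imitation, X_val=X_val, y_val=y_val
    )


@dataclass
class GridResult:
    table: pd.DataFrame            # rows: T, lambda, acc mean/sd on val and test
    best: dict = field(default_factory=dict)
    baseline: dict = field(default_factory=dict)


def run_grid(
    config: DistillationConfig,
    teacher_records: list[LogitsRecord],
    video_features: dict[int, np.ndarray],
    stimulus_labels: dict[int, int],
    train_ids: list[int],
    val_ids: list[int],
    test_ids: list[int],
    n_classes: int,
) -> GridResult:
    """Sweep the (T, lambda) grid; report mean +/- sd test accuracy per cell
    over ``n_runs`` seeds, select the best cell on validation accuracy, and
    train the lambda = 0 baseline under the same seeds."""
    Xtr = np.stack([video_features[j] for j in train_ids])
    ytr = np.array([stimulus_labels[j] for j in train_ids])
    Xva = np.stack([video_features[j] for j in val_ids])
    yva = np.array([stimulus_labels[j] for j in val_ids])
    Xte = np.stack([video_features[j] for j in test_ids])
    yte = np.array([stimulus_labels[j] for j in test_ids])

    run_seeds = np.random.SeedSequence(config.seed).generate_state(config.n_runs) % (2**31)

    # students run a fixed epoch budget: the validation split is reserved for
    # selecting the (T, lambda) cell, not for early stopping, so the two uses
    # of validation accuracy cannot feed each other
    def train_eval(soft, lam, seed):
        model = distill_student(
            Xtr, ytr, soft, lam, n_classes, seed=int(seed),
            hidden_size=config.student_hidden, max_epochs=config.max_epochs,
            learning_rate=config.learning_rate, weight_decay=config.weight_decay,
        )
        return (
            float(np.mean(model.predict(Xva) == yva)),
            float(np.mean(model.predict(Xte) == yte)),
        )

    onehot_soft = np.eye(n_classes)[ytr]
    base_val, base_test = zip(*(train_eval(onehot_soft, 0.0, s) for s in run_seeds))
    baseline = {
        "val_mean": float(np.mean(base_val)),
        "test_mean": float(np.mean(base_test)),
        "test_sd": float(np.std(base_test, ddof=0)),
    }

    rows = []
    for T in config.temperatures:
        soft_map = make_teacher_soft_labels(teacher_records, T, train_ids)
        soft = np.stack([soft_map[j] for j in train_ids])
        for lam in config.imitation_factors:
            vals, tests = zip(*(train_eval(soft, lam, s) for s in run_seeds))
            rows.append(
                (T, lam, float(np.mean(vals)), float(np.mean(tests)),
                 float(np.std(tests, ddof=0)))
            )
    table = pd.DataFrame(
        rows, columns=["temperature", "imitation", "val_mean", "test_mean", "test_sd"]
    )
    best_row = table.loc[table["val_mean"].idxmax()]
    best = {
        "temperature": float(best_row["temperature"]),
        "imitation": float(best_row["imitation"]),
        "val_mean": float(best_row["val_mean"]),
        "test_mean": float(best_row["test_mean"]),
        "test_sd": float(best_row["test_sd"]),
    }
    return GridResult(table=table, best=best, baseline=baseline)
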