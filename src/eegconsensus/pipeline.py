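"""End-to-end orchestration: generate -> preprocess -> encode -> per-subject
teachers -> consensus -> fusion -> distillation -> report.

Feature extraction is vectorised over epochs (band-pass filtering runs on
stacked channel matrices), which keeps the default study size — 50 subjects,
6000 epochs of 62 x 750 samples — tractable on one CPU core.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .consensus import accuracy_vs_n_subjects, consensus_predict, per_class_roc
from .distillation import DistillationConfig, run_grid
from .fusion import DatasetSplit, KernelFusionClassifier, logit_fusion, make_split
from .models import ClassifierSpec, LogitsRecord, train_classifier
from .preprocessing import HANDCRAFTED_BANDS, bandpass, _normalize_array
from .features import de_from_bandpassed
from .synthetic import GeneratorConfig, SyntheticDataset, generate_dataset

__all__ = [
    "PipelineConfig",
    "extract_de_features",
    "train_subject_models",
    "consensus_vs_single_auc",
    "evaluate_fusion",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    split_proportions: tuple[int, int, int] = (140, 40, 60)
    n_grid: tuple[int, ...] = (1, 2, 5, 10, 15, 20, 25)
    resamples: int = 20
    normalize_before_bandpass: bool = True
    distillation: DistillationConfig = field(default_factory=DistillationConfig)
    run_distillation: bool = True
    run_fusion: bool = True
    teacher_spec: ClassifierSpec = field(default_factory=lambda: ClassifierSpec(kind="de_mlp"))
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "generator" in raw:
            kwargs["generator"] = GeneratorConfig(**raw.pop("generator"))
        if "distillation" in raw:
            kwargs["distillation"] = DistillationConfig(**raw.pop("distillation"))
        if "teacher_spec" in raw:
            kwargs["teacher_spec"] = ClassifierSpec(**raw.pop("teacher_spec"))
        for key in ("split_proportions", "n_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        kwargs.update(raw)
        return cls(**kwargs)


def extract_de_features(
    dataset: SyntheticDataset,
    bands=None,
    normalize: bool = True,
    chunk: int = 40,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Differential-entropy feature matrix for every epoch.

    Returns ``X`` of shape (n_epochs, n_channels * n_bands) — channel-major
    within each band, bands in table order — and a metadata frame with
    subject_id / stimulus_id / class_label per row.  ``normalize`` applies
    the per-channel [-1, 1] range scaling before band-pass filtering (the
    default pipeline order).
    """
    bands = HANDCRAFTED_BANDS if bands is None else bands
    fs = dataset.config.sampling_rate
    epochs = dataset.epochs
    n_bands = len(bands)
    n_ch = dataset.config.n_channels
    X = np.empty((len(epochs), n_ch * n_bands))
    for start in range(0, len(epochs), chunk):
        batch = epochs[start : start + chunk]
        windows = np.stack([e.stimulus_window for e in batch]).astype(float)
        if normalize:
            windows = _normalize_array(windows)
        for b, band in enumerate(bands.values()):
            xb = bandpass(windows, band, fs)
            X[start : start + chunk, b * n_ch : (b + 1) * n_ch] = de_from_bandpassed(xb)
    meta = pd.DataFrame(
        {
            "subject_id": [e.subject_id for e in epochs],
            "stimulus_id": [e.stimulus_id for e in epochs],
            "class_label": [e.class_label for e in epochs],
        }
    )
    return X, meta


def train_subject_models(
    X: np.ndarray,
    meta: pd.DataFrame,
    split: DatasetSplit,
    spec: ClassifierSpec,
    crossfit_train_logits: bool = True,
    n_folds: int = 4,
) -> tuple[dict[int, object], list[LogitsRecord]]:
    """One classifier per subject, trained on that subject's training-split
    epochs (validation epochs drive early stopping), then scored on every
    epoch of the subject.  Features are standardised with the subject's
    training statistics.

    With ``crossfit_train_logits`` (the default), the logits reported for
    *training* stimuli come from fold models that never saw the scored
    epoch: each subject's training stimuli are split into ``n_folds`` folds
    and each fold is scored by a model fitted on the remaining folds.
    Without it, a memorising teacher emits near-one-hot scores for its own
    training epochs, which would empty the soft labels that the distillation
    stage feeds on.  Validation and test logits always come from the full
    per-subject model.
    """
    train_ids, val_ids = set(split.train_stimuli), set(split.val_stimuli)
    models: dict[int, object] = {}
    records: list[LogitsRecord] = []
    for subject in sorted(meta["subject_id"].unique()):
        rows = meta.index[meta["subject_id"] == subject].to_numpy()
        stim = meta.loc[rows, "stimulus_id"].to_numpy()
        y = meta.loc[rows, "class_label"].to_numpy()
        tr = np.isin(stim, list(train_ids))
        va = np.isin(stim, list(val_ids))
        mean = X[rows[tr]].mean(axis=0)
        sd = X[rows[tr]].std(axis=0)
        sd[sd == 0] = 1.0
        Xs = (X[rows] - mean) / sd
        sub_spec = ClassifierSpec(**{**asdict(spec), "seed": spec.seed + int(subject)})
        model = train_classifier(sub_spec, Xs[tr], y[tr], Xs[va], y[va])
        models[int(subject)] = model
        logits = model.predict_logits(Xs)

        if crossfit_train_logits:
            tr_idx = np.nonzero(tr)[0]
            # deterministic fold assignment: stratify by interleaving the
            # label-sorted training rows across folds
            order = tr_idx[np.argsort(y[tr_idx], kind="stable")]
            for fold in range(n_folds):
                held = order[fold::n_folds]
                fit = np.setdiff1d(order, held)
                fold_spec = ClassifierSpec(
                    **{**asdict(spec), "seed": spec.seed + int(subject) + 7919 * (fold + 1)}
                )
                fold_model = train_classifier(
                    fold_spec, Xs[fit], y[fit], Xs[va], y[va]
                )
                logits[held] = fold_model.predict_logits(Xs[held])

        for i, row in enumerate(rows):
            records.append(
                LogitsRecord(
                    logits=logits[i],
                    model_id=f"subject-{subject}",
                    subject_id=int(subject),
                    stimulus_id=int(stim[i]),
                )
            )
    return models, records


def _records_for(records: list[LogitsRecord], stimulus_ids) -> list[LogitsRecord]:
    wanted = set(stimulus_ids)
    return [r for r in records if r.stimulus_id in wanted]


def single_subject_accuracy(
    records: list[LogitsRecord], labels: dict[int, int]
) -> float:
    """Mean over subjects of each model's own-epoch accuracy (the EEG-only
    figure of merit before any consensus)."""
    by_subject: dict[int, list[LogitsRecord]] = {}
    for r in records:
        by_subject.setdefault(r.subject_id, []).append(r)
    accs = [
        float(np.mean([int(np.argmax(r.logits)) == labels[r.stimulus_id] for r in recs]))
        for recs in by_subject.values()
    ]
    return float(np.mean(accs))


def consensus_vs_single_auc(
    records: list[LogitsRecord], labels: dict[int, int]
) -> tuple[float, float]:
    """Macro one-vs-rest AUC of the full-consensus scores versus the mean
    single-subject macro AUC, on the same test records."""
    grouped: dict[int, list[LogitsRecord]] = {}
    for r in records:
        grouped.setdefault(r.stimulus_id, []).append(r)
    stim_ids = sorted(grouped)
    cons_scores = np.stack([consensus_predict(grouped[j]).probabilities for j in stim_ids])
    cons_labels = np.array([labels[j] for j in stim_ids])
    auc_consensus = per_class_roc(cons_scores, cons_labels).attrs["macro_auc"]

    by_subject: dict[int, list[LogitsRecord]] = {}
    for r in records:
        by_subject.setdefault(r.subject_id, []).append(r)
    single = []
    for recs in by_subject.values():
        scores = np.stack([r.logits for r in recs])
        labs = np.array([labels[r.stimulus_id] for r in recs])
        single.append(per_class_roc(scores, labs).attrs["macro_auc"])
    return float(auc_consensus), float(np.mean(single))


def evaluate_fusion(
    dataset: SyntheticDataset,
    split: DatasetSplit,
    X_de: np.ndarray,
    meta: pd.DataFrame,
    eeg_test_logits: dict[int, np.ndarray] | None = None,
    video_test_logits: dict[int, np.ndarray] | None = None,
    seed: int = 0,
) -> dict[str, float]:
    """Stimulus-level fusion study.

    The EEG block is each stimulus's subject-averaged DE feature vector, the
    video block its video feature vector.  Linear SVMs are trained per block
    and on the Gram-averaged fused kernel; if per-stimulus logits of the two
    single-modality classifiers are supplied, late logit fusion is evaluated
    on them, otherwise on SVM decision scores.
    """
    labels = dataset.stimulus_labels
    stim_ids = sorted(labels)
    de_by_stim = {
        j: X_de[meta.index[meta["stimulus_id"] == j]].mean(axis=0) for j in stim_ids
    }
    video = {s.stimulus_id: s.video_features for s in dataset.stimuli}

    def block(ids, source):
        return np.stack([source[j] for j in ids])

    tr, te = list(split.train_stimuli), list(split.test_stimuli)
    ytr = np.array([labels[j] for j in tr])
    yte = np.array([labels[j] for j in te])

    from .models import SVMClassifier

    n_classes = dataset.config.n_classes
    single_acc = {}
    single_logits = {}
    for name, source in (("eeg", de_by_stim), ("video", video)):
        Xtr, Xte = block(tr, source), block(te, source)
        mean, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
        sd[sd == 0] = 1.0
        model = SVMClassifier(n_classes, seed=seed).fit((Xtr - mean) / sd, ytr)
        scores = model.predict_logits((Xte - mean) / sd)
        single_acc[name] = float(np.mean(np.argmax(scores, axis=1) == yte))
        single_logits[name] = scores

    fused = KernelFusionClassifier()
    fused.fit([block(tr, de_by_stim), block(tr, video)], ytr)
    kernel_pred = fused.predict([block(te, de_by_stim), block(te, video)])
    kernel_acc = float(np.mean(kernel_pred == yte))

    if eeg_test_logits is not None and video_test_logits is not None:
        a = np.stack([eeg_test_logits[j] for j in te])
        b = np.stack([video_test_logits[j] for j in te])
    else:
        a, b = single_logits["eeg"], single_logits["video"]
    _, fused_pred = logit_fusion(a, b)
    logit_acc = float(np.mean(fused_pred == yte))

    return {
        "eeg_only_acc": single_acc["eeg"],
        "video_only_acc": single_acc["video"],
        "kernel_fusion_acc": kernel_acc,
        "logit_fusion_acc": logit_acc,
    }


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Run every stage on one synthetic dataset and return the report dict.

    The report mirrors the headline comparison: EEG only (mean per-subject
    accuracy), video only (student baseline), subjects' consensus, fusion,
    and — when enabled — the distillation grid summary.  With ``out_dir``
    set, curves and tables are also written as CSV.
    """
    gen_cfg = config.generator
    dataset = generate_dataset(gen_cfg)
    labels = dataset.stimulus_labels
    split = make_split(
        sorted(labels), labels, proportions=config.split_proportions, seed=config.seed
    )
    X, meta = extract_de_features(dataset, normalize=config.normalize_before_bandpass)
    spec = ClassifierSpec(**{**asdict(config.teacher_spec), "n_classes": gen_cfg.n_classes,
                             "seed": config.seed})
    _, records = train_subject_models(X, meta, split, spec)
    test_records = _records_for(records, split.test_stimuli)

    curve = accuracy_vs_n_subjects(
        test_records, labels, list(config.n_grid), config.resamples, seed=config.seed
    )
    auc_consensus, auc_single = consensus_vs_single_auc(test_records, labels)

    report: dict = {
        "seed": config.seed,
        "n_epochs": len(dataset.epochs),
        "n_stimuli": len(dataset.stimuli),
        "eeg_only_acc": single_subject_accuracy(test_records, labels),
        "consensus_acc": float(curve["accuracy_mean"].iloc[-1]),
        "macro_auc_consensus": auc_consensus,
        "macro_auc_single_subject": auc_single,
        "curve": curve,
    }

    if config.run_fusion:
        report["fusion"] = evaluate_fusion(dataset, split, X, meta, seed=config.seed)

    if config.run_distillation:
        video = {s.stimulus_id: s.video_features for s in dataset.stimuli}
        teacher_records = _records_for(records, split.train_stimuli)
        grid = run_grid(
            config.distillation,
            teacher_records,
            video,
            labels,
            list(split.train_stimuli),
            list(split.val_stimuli),
            list(split.test_stimuli),
            gen_cfg.n_classes,
        )
        report["distillation"] = {
            "baseline_test_acc": grid.baseline["test_mean"],
            "best_test_acc": grid.best["test_mean"],
            "best_temperature": grid.best["temperature"],
            "best_imitation": grid.best["imitation"],
            "grid": grid.table,
        }
        report["video_only_acc"] = grid.baseline["test_mean"]

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        curve.to_csv(out / "consensus_curve.csv", index=False)
        if config.run_distillation:
            report["distillation"]["grid"].to_csv(out / "distillation_grid.csv", index=False)
        summary = {
            k: v for k, v in report.items() if isinstance(v, (int, float))
        }
        if config.run_fusion:
            summary.update({f"fusion_{k}": v for k, v in report["fusion"].items()})
        if config.run_distillation:
            summary.update(
                {
                    f"distillation_{k}": v
                    for k, v in report["distillation"].items()
                    if isinstance(v, (int, float))
                }
            )
        pd.Series(summary).to_csv(out / "report.csv", header=False)
    return report
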