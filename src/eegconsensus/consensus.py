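"""Subjects'-consensus prediction and its evaluation.

For one stimulus, per-subject classifiers each score the epoch recorded
while *their* subject watched it; the consensus prediction averages those
logit vectors arithmetically and applies a softmax.  Subject-specific biases
are zero-mean across subjects, so the averaged logits converge on the
stimulus-level signal as the subject count grows — the accuracy-vs-subjects
curve and the per-class ROC analysis below quantify that effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .models import LogitsRecord, softmax

__all__ = [
    "ConsensusPrediction",
    "consensus_predict",
    "accuracy_vs_n_subjects",
    "per_class_roc",
]


@dataclass
class ConsensusPrediction:
    stimulus_id: int
    subject_ids_used: frozenset
    mean_logits: np.ndarray
    probabilities: np.ndarray

    @property
    def predicted_class(self) -> int:
        return int(np.argmax(self.mean_logits))


def consensus_predict(
    records: list[LogitsRecord],
    subset: set | None = None,
    mode: str = "logits",
) -> ConsensusPrediction:
    """Average per-subject scores for one stimulus and softmax the mean.

    ``mode="logits"`` averages raw logits (the primary definition);
    ``mode="probs"`` averages per-subject softmax probabilities instead, for
    studying the difference between the two conventions.
    """
    if not records:
        raise ValueError("no records given")
    stimulus_ids = {r.stimulus_id for r in records}
    if len(stimulus_ids) != 1:
        raise ValueError(f"records mix stimuli {sorted(stimulus_ids)}")
    available = {r.subject_id for r in records}
    if subset is None:
        subset = available
    subset = set(subset)
    if not subset:
        raise ValueError("empty subject subset")
    if not subset <= available:
        raise ValueError(f"subjects {sorted(subset - available)} have no records")
    chosen = [r for r in records if r.subject_id in subset]
    if mode == "logits":
        mean_logits = np.mean([r.logits for r in chosen], axis=0)
        probs = softmax(mean_logits)
    elif mode == "probs":
        probs = np.mean([softmax(r.logits) for r in chosen], axis=0)
        mean_logits = np.log(np.clip(probs, 1e-300, None))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ConsensusPrediction(
        stimulus_id=next(iter(stimulus_ids)),
        subject_ids_used=frozenset(subset),
        mean_logits=mean_logits,
        probabilities=probs,
    )


def _by_stimulus(records: list[LogitsRecord]) -> dict[int, list[LogitsRecord]]:
    grouped: dict[int, list[LogitsRecord]] = {}
    for r in records:
        grouped.setdefault(r.stimulus_id, []).append(r)
    return grouped


def accuracy_vs_n_subjects(
    records: list[LogitsRecord],
    stimulus_labels: dict[int, int],
    n_grid: list[int],
    resamples: int = 20,
    seed: int = 0,
    cap: bool = True,
) -> pd.DataFrame:
    """Consensus accuracy as a function of the number of subjects averaged.

    For each ``n`` in ``n_grid``, draws ``resamples`` random size-``n``
    subject subsets per stimulus, computes consensus accuracy over the given
    stimuli, and reports mean and standard deviation over resamples.  When a
    stimulus has fewer than ``n`` subjects, ``cap=True`` uses all of them;
    ``cap=False`` raises.  ``n`` equal to every stimulus's full subject count
    is deterministic (zero spread).
    """
    grouped = _by_stimulus(records)
    missing = set(grouped) - set(stimulus_labels)
    if missing:
        raise ValueError(f"no labels for stimuli {sorted(missing)}")
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_grid:
        accs = []
        for _ in range(resamples):
            correct = 0
            for j, recs in grouped.items():
                subjects = sorted({r.subject_id for r in recs})
                if n > len(subjects):
                    if not cap:
                        raise ValueError(
                            f"n={n} exceeds the {len(subjects)} subjects of stimulus {j}"
                        )
                    chosen = subjects
                else:
                    chosen = rng.choice(subjects, size=n, replace=False)
                pred = consensus_predict(recs, set(int(s) for s in chosen))
                correct += pred.predicted_class == stimulus_labels[j]
            accs.append(correct / len(grouped))
        rows.append((n, float(np.mean(accs)), float(np.std(accs, ddof=0))))
    return pd.DataFrame(rows, columns=["n_subjects", "accuracy_mean", "accuracy_sd"])


def per_class_roc(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """One-vs-rest per-class AUC (trapezoidal) plus the macro average.

    ``scores`` is instances x classes (softmax scores or logits — AUC is
    rank-based); classes absent from ``labels`` get NaN and are excluded
    from the macro average.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape[0] != labels.shape[0]:
        raise ValueError("scores and labels misaligned")
    n_classes = scores.shape[1]
    rows = []
    for k in range(n_classes):
        positives = labels == k
        if positives.all() or not positives.any():
            rows.append((k, np.nan, int(positives.sum())))
            continue
        rows.append((k, float(roc_auc_score(positives, scores[:, k])), int(positives.sum())))
    df = pd.DataFrame(rows, columns=["class_label", "auc", "n_positive"])
    df.attrs["macro_auc"] = float(df["auc"].mean(skipna=True))
    return df
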