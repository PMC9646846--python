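"""Dataset splitting and the two multimodal fusion baselines.

Stimuli are split 140-40-60 (train/validation/test, scaled proportionally
for other dataset sizes), stratified by class; the EEG splits are induced —
every epoch follows its stimulus, so no stimulus leaks across splits.

Kernel fusion standardises each modality's feature block, forms a linear
Gram matrix per block, averages the Grams and trains an SVM on the fused
kernel.  Averaging linear Grams is algebraically identical to the linear
kernel of the concatenated features scaled by 1/m.  Logit fusion averages
two models' logit vectors elementwise and arg-maxes (ties break to the
lowest class index).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

__all__ = [
    "DatasetSplit",
    "make_split",
    "KernelFusionClassifier",
    "logit_fusion",
]


@dataclass
class DatasetSplit:
    train_stimuli: tuple[int, ...]
    val_stimuli: tuple[int, ...]
    test_stimuli: tuple[int, ...]
    seed: int

    def __post_init__(self) -> None:
        sets = [set(self.train_stimuli), set(self.val_stimuli), set(self.test_stimuli)]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise ValueError("split parts are not disjoint")

    def part_of(self, stimulus_id: int) -> str:
        for name, part in (("train", self.train_stimuli), ("val", self.val_stimuli),
                           ("test", self.test_stimuli)):
            if stimulus_id in part:
                return name
        raise KeyError(f"stimulus {stimulus_id} not in any split part")


def make_split(
    stimulus_ids: list[int],
    class_labels: dict[int, int],
    proportions: tuple[int, int, int] = (140, 40, 60),
    seed: int = 0,
) -> DatasetSplit:
    """Stratified random three-way split of stimuli.

    ``proportions`` are interpreted as relative weights and rescaled to the
    stimulus count (140-40-60 on 240 stimuli is exact).  Within each class,
    stimuli are allocated to parts by largest remainder, so per-class counts
    deviate from exact proportionality by at most one.
    """
    props = np.asarray(proportions, dtype=float)
    if np.any(props <= 0):
        raise ValueError("proportions must be positive")
    fractions = props / props.sum()
    rng = np.random.default_rng(seed)

    by_class: dict[int, list[int]] = {}
    for j in stimulus_ids:
        by_class.setdefault(class_labels[j], []).append(j)
    if any(len(v) < 3 for v in by_class.values()):
        raise ValueError("every class needs at least as many stimuli as split parts")

    parts: list[list[int]] = [[], [], []]
    for label in sorted(by_class):
        members = np.array(sorted(by_class[label]))
        rng.shuffle(members)
        ideal = fractions * len(members)
        counts = np.floor(ideal).astype(int)
        remainder = ideal - counts
        for i in np.argsort(-remainder)[: len(members) - counts.sum()]:
            counts[i] += 1
        offsets = np.concatenate([[0], np.cumsum(counts)])
        for i in range(3):
            parts[i].extend(int(j) for j in members[offsets[i]:offsets[i + 1]])
    return DatasetSplit(
        train_stimuli=tuple(sorted(parts[0])),
        val_stimuli=tuple(sorted(parts[1])),
        test_stimuli=tuple(sorted(parts[2])),
        seed=seed,
    )


def _standardize(block: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return (block - mean) / sd


class KernelFusionClassifier:
    """SVM on the arithmetic mean of per-modality linear Gram matrices.

    Each feature block is standardised with training-set statistics before
    its Gram matrix is formed; the fused Gram must stay positive
    semi-definite within numerical tolerance (it is an average of PSD
    matrices, so a violation indicates misaligned inputs).
    """

    def __init__(self, C: float = 1.0, psd_tol: float = 1e-8):
        self.C = C
        self.psd_tol = psd_tol
        self._svm = SVC(kernel="precomputed", C=C)
        self._train_blocks: list[np.ndarray] | None = None
        self._stats: list[tuple[np.ndarray, np.ndarray]] | None = None

    def _check_blocks(self, blocks: list[np.ndarray]) -> list[np.ndarray]:
        if len(blocks) < 2:
            raise ValueError("kernel fusion needs at least two feature blocks")
        blocks = [np.asarray(b, dtype=float) for b in blocks]
        n = blocks[0].shape[0]
        if any(b.shape[0] != n for b in blocks):
            raise ValueError("feature blocks are misaligned on instances")
        return blocks

    def fused_gram(self, blocks_a: list[np.ndarray], blocks_b: list[np.ndarray] | None = None) -> np.ndarray:
        """Mean of per-block linear Grams between two instance sets."""
        if blocks_b is None:
            blocks_b = blocks_a
        grams = [a @ b.T for a, b in zip(blocks_a, blocks_b)]
        return np.mean(grams, axis=0)

    def fit(self, blocks: list[np.ndarray], y: np.ndarray) -> "KernelFusionClassifier":
        blocks = self._check_blocks(blocks)
        self._stats = []
        std_blocks = []
        for b in blocks:
            mean = b.mean(axis=0)
            sd = b.std(axis=0)
            sd[sd == 0] = 1.0
            self._stats.append((mean, sd))
            std_blocks.append(_standardize(b, mean, sd))
        self._train_blocks = std_blocks
        K = self.fused_gram(std_blocks)
        eig_min = float(np.linalg.eigvalsh(K).min())
        scale = max(float(np.abs(K).max()), 1.0)
        if eig_min < -self.psd_tol * scale:
            raise ValueError(f"fused Gram is not PSD (min eigenvalue {eig_min:.3e})")
        self._svm.fit(K, y)
        return self

    def predict(self, blocks: list[np.ndarray]) -> np.ndarray:
        if self._train_blocks is None:
            raise RuntimeError("classifier is not fitted")
        blocks = self._check_blocks(blocks)
        std_blocks = [
            _standardize(b, mean, sd) for b, (mean, sd) in zip(blocks, self._stats)
        ]
        K = self.fused_gram(std_blocks, self._train_blocks)
        return self._svm.predict(K)


def logit_fusion(logits_a: np.ndarray, logits_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Late fusion: elementwise mean of two models' logits over the same
    instances; returns (fused logits, argmax predictions)."""
    a = np.asarray(logits_a, dtype=float)
    b = np.asarray(logits_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"logit shapes differ: {a.shape} vs {b.shape}")
    fused = (a + b) / 2.0
    return fused, np.argmax(fused, axis=-1)
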