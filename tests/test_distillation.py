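import numpy as np
import pytest

from eegconsensus.distillation import (
    DistillationConfig,
    distill_student,
    distillation_objective,
    make_teacher_soft_labels,
    run_grid,
)
from eegconsensus.models import LogitsRecord, softmax


def rec(logits, subject, stimulus):
    return LogitsRecord(
        logits=np.asarray(logits, dtype=float),
        model_id=f"subject-{subject}",
        subject_id=subject,
        stimulus_id=stimulus,
    )


class TestSoftLabels:
    def test_single_subject_at_unit_temperature(self):
        r = rec([0.7, -0.2, 0.1], 1, 0)
        soft = make_teacher_soft_labels([r], 1.0, [0])
        np.testing.assert_allclose(soft[0], softmax(r.logits), atol=1e-12)

    def test_high_temperature_approaches_uniform(self):
        records = [rec(np.random.default_rng(0).normal(scale=3, size=10), s, 0) for s in range(3)]
        soft = make_teacher_soft_labels(records, 1e6, [0])
        np.testing.assert_allclose(soft[0], 0.1, atol=1e-5)

    def test_closed_form_at_temperature_two(self):
        # logits (log 4, 0) at T = 2: exp(log4 / 2) = 2 -> (2/3, 1/3)
        soft = make_teacher_soft_labels([rec([np.log(4.0), 0.0], 1, 0)], 2.0, [0])
        np.testing.assert_allclose(soft[0], [2 / 3, 1 / 3], atol=1e-12)

    def test_missing_stimulus_coverage_rejected(self):
        with pytest.raises(ValueError, match="no teacher logits"):
            make_teacher_soft_labels([rec([0.0, 0.0], 1, 0)], 1.0, [0, 5])


class TestObjective:
    def _random_instance(self, seed=0, n=7, k=4):
        rng = np.random.default_rng(seed)
        logits = rng.normal(size=(n, k))
        y = rng.integers(0, k, size=n)
        soft = softmax(rng.normal(size=(n, k)))
        return logits, y, soft

    @pytest.mark.parametrize("lam", [0.0, 0.3, 0.7, 1.0])
    def test_gradient_matches_finite_differences(self, lam):
        logits, y, soft = self._random_instance()
        loss, grad = distillation_objective(logits, y, soft, lam)
        eps = 1e-6
        for idx in [(0, 0), (3, 2), (6, 3)]:
            bump = logits.copy()
            bump[idx] += eps
            lp, _ = distillation_objective(bump, y, soft, lam)
            bump[idx] -= 2 * eps
            lm, _ = distillation_objective(bump, y, soft, lam)
            fd = (lp - lm) / (2 * eps)
            assert grad[idx] == pytest.approx(fd, abs=1e-5)

    def test_convex_combination_of_pure_losses(self):
        logits, y, soft = self._random_instance(seed=2)
        hard_loss, _ = distillation_objective(logits, y, soft, 0.0)
        soft_loss, _ = distillation_objective(logits, y, soft, 1.0)
        for lam in (0.2, 0.5, 0.9):
            mixed, _ = distillation_objective(logits, y, soft, lam)
            expected = (1 - lam) * hard_loss + lam * soft_loss
            assert mixed == pytest.approx(expected, abs=1e-12)
            assert min(hard_loss, soft_loss) - 1e-12 <= mixed <= max(hard_loss, soft_loss) + 1e-12

    def test_one_hot_soft_targets_collapse_to_hard_loss(self):
        logits, y, _ = self._random_instance(seed=3)
        onehot = np.eye(logits.shape[1])[y]
        for lam in (0.0, 0.5, 1.0):
            loss, grad = distillation_objective(logits, y, onehot, lam)
            loss0, grad0 = distillation_objective(logits, y, onehot, 0.0)
            assert loss == pytest.approx(loss0, abs=1e-12)
            np.testing.assert_allclose(grad, grad0, atol=1e-12)

    def test_invalid_imitation_rejected(self):
        logits, y, soft = self._random_instance()
        with pytest.raises(ValueError):
            distillation_objective(logits, y, soft, 1.5)


def toy_problem(seed=0, n=80, d=12, k=4):
    rng = np.random.default_rng(seed)
    centers = rng.normal(scale=2.0, size=(k, d))
    y = np.arange(n) % k
    X = centers[y] + rng.normal(size=(n, d))
    return X, y


class TestDistillStudent:
    def test_lambda_zero_matches_plain_training(self):
        X, y = toy_problem()
        soft = softmax(np.random.default_rng(1).normal(size=(len(y), 4)))
        a = distill_student(X, y, soft, 0.0, 4, seed=5, max_epochs=50)
        onehot = np.eye(4)[y]
        b = distill_student(X, y, onehot, 0.0, 4, seed=5, max_epochs=50)
        np.testing.assert_array_equal(a.predict_logits(X), b.predict_logits(X))

    def test_lambda_one_ignores_hard_labels(self):
        X, y = toy_problem(seed=4)
        soft = softmax(np.random.default_rng(2).normal(size=(len(y), 4)))
        shuffled = np.random.default_rng(3).permutation(y)
        a = distill_student(X, y, soft, 1.0, 4, seed=6, max_epochs=50)
        b = distill_student(X, shuffled, soft, 1.0, 4, seed=6, max_epochs=50)
        np.testing.assert_array_equal(a.predict_logits(X), b.predict_logits(X))

    def test_one_hot_soft_labels_reproduce_baseline_at_any_lambda(self):
        X, y = toy_problem(seed=5)
        onehot = np.eye(4)[y]
        base = distill_student(X, y, onehot, 0.0, 4, seed=7, max_epochs=50)
        for lam in (0.25, 1.0):
            same = distill_student(X, y, onehot, lam, 4, seed=7, max_epochs=50)
            np.testing.assert_allclose(
                same.predict_logits(X), base.predict_logits(X), atol=1e-10
            )

    def test_misaligned_soft_labels_rejected(self):
        X, y = toy_problem()
        with pytest.raises(ValueError, match="misaligned"):
            distill_student(X, y, np.ones((3, 4)) / 4, 0.5, 4)


class TestRunGrid:
    def _inputs(self, n_runs=2):
        X, y = toy_problem(seed=8, n=60)
        stim_ids = list(range(60))
        labels = {j: int(y[j]) for j in stim_ids}
        video = {j: X[j] for j in stim_ids}
        teachers = [
            rec(np.eye(4)[labels[j]] * 3.0 + 0.1, s, j)
            for j in stim_ids
            for s in range(2)
        ]
        cfg = DistillationConfig(
            temperatures=(1.0, 5.0),
            imitation_factors=(0.5, 1.0),
            n_runs=n_runs,
            seed=0,
            max_epochs=40,
        )
        return cfg, teachers, video, labels, stim_ids

    def test_grid_has_one_row_per_cell_with_mean_and_sd(self):
        cfg, teachers, video, labels, ids = self._inputs()
        out = run_grid(cfg, teachers, video, labels, ids[:40], ids[40:50], ids[50:], 4)
        assert len(out.table) == 4
        assert {"val_mean", "test_mean", "test_sd"} <= set(out.table.columns)
        assert set(out.best) >= {"temperature", "imitation", "test_mean"}

    def test_single_run_has_zero_spread(self):
        cfg, teachers, video, labels, ids = self._inputs(n_runs=1)
        out = run_grid(cfg, teachers, video, labels, ids[:40], ids[40:50], ids[50:], 4)
        assert (out.table["test_sd"] == 0.0).all()
        assert out.baseline["test_sd"] == 0.0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DistillationConfig(temperatures=(0.0,))
        with pytest.raises(ValueError):
            DistillationConfig(imitation_factors=(1.5,))
        with pytest.raises(ValueError):
            DistillationConfig(n_runs=0)
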