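"""Metrics, plateau schedule, and the training loop contract."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fundusdr as f


class TestAccuracy:
    def test_closed_forms(self):
        assert f.accuracy(f.ConfusionCounts(tp=1, tn=1)) == 1.0
        assert f.accuracy(f.ConfusionCounts(fp=2, fn=3)) == 0.0
        assert f.accuracy(f.ConfusionCounts(tp=3, tn=2, fp=1, fn=2)) == 0.625

    def test_empty_table_rejected(self):
        with pytest.raises(f.InvalidInputError):
            f.accuracy(f.ConfusionCounts())

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(1, 50))
    def test_matches_bruteforce_on_random_tables(self, tp, tn, fp, fn):
        c = f.ConfusionCounts(tp, tn, fp, fn)
        # independent route: rebuild the counts from explicit label vectors
        y = [1] * tp + [0] * tn + [0] * fp + [1] * fn
        p = [1] * tp + [0] * tn + [1] * fp + [0] * fn
        hits = sum(a == b for a, b in zip(y, p))
        assert f.accuracy(c) == pytest.approx(hits / len(y))

    def test_confusion_from_predictions(self):
        y = np.array([1, 1, 0, 0, 1])
        p = np.array([0.9, 0.2, 0.8, 0.1, 0.5])
        c = f.confusion_from_predictions(y, p)
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 1, 1, 1)


class TestCrossEntropy:
    def test_closed_forms(self):
        assert f.cross_entropy([1, 0], [0.5, 0.5]) == pytest.approx(math.log(2), rel=1e-9)
        assert f.cross_entropy([1], [0.25]) == pytest.approx(-math.log(0.25), rel=1e-9)
        assert f.cross_entropy([1, 0], [1.0, 0.0]) <= 1e-6  # clipped perfection

    def test_matches_bruteforce(self, rng):
        y = rng.integers(0, 2, 50)
        p = rng.uniform(0.01, 0.99, 50)
        direct = -np.mean([yi * math.log(pi) + (1 - yi) * math.log(1 - pi) for yi, pi in zip(y, p)])
        assert f.cross_entropy(y, p) == pytest.approx(direct, rel=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(f.InvalidInputError):
            f.cross_entropy([1, 0], [0.5])


class TestPlateauSchedule:
    def test_improving_metric_never_cuts(self):
        s = f.ScheduleState()
        for k in range(20):
            f.step_on_plateau(s, 1.0 - 0.01 * k)
        assert s.lr == 0.01

    def test_two_stagnant_epochs_halve_the_rate(self):
        s = f.ScheduleState()
        f.step_on_plateau(s, 1.0)  # first observation becomes best
        f.step_on_plateau(s, 1.0)
        assert s.lr == 0.01
        f.step_on_plateau(s, 1.0)
        assert s.lr == pytest.approx(0.005)

    def test_thirty_cuts_closed_form(self):
        s = f.ScheduleState()
        f.step_on_plateau(s, 1.0)
        for _ in range(60):
            f.step_on_plateau(s, 1.0)
        assert s.lr == pytest.approx(0.01 * 0.5**30, rel=1e-12)
        assert s.lr == pytest.approx(9.3132e-12, rel=1e-4)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 40), st.floats(0.1, 0.9), st.floats(1e-12, 1e-3))
    def test_k_cuts_match_closed_form(self, k, factor, floor):
        """lr after k cuts equals max(lr0 * factor^k, floor) exactly."""
        s = f.ScheduleState(factor=factor, floor=floor)
        f.step_on_plateau(s, 1.0)
        for _ in range(s.patience * k):
            f.step_on_plateau(s, 1.0)
        expected = 0.01
        for _ in range(k):
            expected = max(expected * factor, floor)
        assert s.lr == expected

    def test_floor_respected(self):
        s = f.ScheduleState(floor=1e-6)
        f.step_on_plateau(s, 1.0)
        for _ in range(200):
            f.step_on_plateau(s, 1.0)
        assert s.lr == 1e-6

    def test_small_improvement_counts_as_stagnation(self):
        s = f.ScheduleState(min_delta=1e-4)
        f.step_on_plateau(s, 1.0)
        f.step_on_plateau(s, 1.0 - 5e-5)
        f.step_on_plateau(s, 1.0 - 9e-5)
        assert s.lr == pytest.approx(0.005)

    def test_non_finite_metric_rejected(self):
        with pytest.raises(f.InvalidInputError):
            f.step_on_plateau(f.ScheduleState(), float("nan"))

    def test_invalid_state_rejected(self):
        with pytest.raises(f.ConfigError):
            f.ScheduleState(factor=1.5)


def _tiny_sets(rng, n_train=8, n_val=4):
    spec = f.SyntheticSpec(side=64, border_width=4, seed=0)
    tr = f.generate_samples(spec, n_train // 2, n_train // 2, rng=rng)
    va = f.generate_samples(spec, n_val // 2, n_val // 2, rng=rng)
    return f.samples_to_arrays(tr), f.samples_to_arrays(va)


@pytest.fixture(scope="module")
def tiny_run():
    (xt, yt), (xv, yv) = _tiny_sets(np.random.default_rng(0))

    def build_and_train():
        model = f.build_revised_model(
            f.ModelConfig(input_side=64, width_multiplier=0.1, init_seed=0)
        )
        cfg = f.TrainConfig(epochs=2, batch_size=4, seed=0)
        return model, f.train(model, (xt, yt), (xv, yv), cfg), (xv, yv)

    return build_and_train


class TestTrainLoop:
    def test_history_contract(self, tiny_run):
        _, history, _ = tiny_run()
        assert len(history) == 2
        for rec in history:
            assert all(
                math.isfinite(rec[k])
                for k in ("train_acc", "train_loss", "val_acc", "val_loss", "lr")
            )

    def test_same_seed_bit_identical(self, tiny_run):
        _, h1, _ = tiny_run()
        _, h2, _ = tiny_run()
        assert h1 == h2

    def test_lr_non_increasing(self, tiny_run):
        _, history, _ = tiny_run()
        lrs = [rec["lr"] for rec in history]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))

    def test_empty_dataset_rejected(self):
        with pytest.raises(f.InvalidInputError):
            f.train(
                None,
                (np.zeros((0, 3, 64, 64)), np.zeros(0)),
                (np.zeros((1, 3, 64, 64)), np.zeros(1)),
                f.TrainConfig(epochs=1),
            )


class TestEvaluate:
    class _Constant:
        """Stub model emitting a fixed probability."""

        def __init__(self, p):
            self.p = p

        def predict_proba(self, x):
            return np.full(len(x), self.p)

    def test_confident_correct_model(self):
        x = np.zeros((5, 1))
        y = np.ones(5)
        out = f.evaluate(self._Constant(0.9), x, y)
        assert out["accuracy"] == 1.0

    def test_constant_prediction_on_balanced_labels(self):
        x = np.zeros((10, 1))
        y = np.array([0, 1] * 5)
        out = f.evaluate(self._Constant(0.51), x, y)
        assert out["accuracy"] == 0.5  # thresholded constant predicts all 1

    def test_loss_of_half_is_ln2(self):
        x = np.zeros((6, 1))
        y = np.array([0, 1, 1, 0, 1, 0])
        out = f.evaluate(self._Constant(0.5), x, y)
        assert out["loss"] == pytest.approx(math.log(2), rel=1e-9)

    def test_empty_set_rejected(self):
        with pytest.raises(f.InvalidInputError):
            f.evaluate(self._Constant(0.5), np.zeros((0, 1)), np.zeros(0))
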