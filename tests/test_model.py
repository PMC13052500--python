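"""Leave-one-out random-forest evaluation, metrics, and paired AUC comparison."""

import numpy as np
import pandas as pd
import pytest

import kerapol as kp
from kerapol.model import CLASSES, ModelRun, _fold_seed
from kerapol.zernike import FeatureVector


def _toy_features(X, ids=None):
    """Wrap rows of X (n x 23) as MS-39 feature vectors (smallest schema)."""
    from kerapol.zernike import MS39_FIELDS

    n, p = X.shape
    assert p == 23
    ids = ids or [f"e{i}" for i in range(n)]
    return [
        FeatureVector("MS39_23", tuple(MS39_FIELDS), X[i], eye_id=ids[i])
        for i in range(n)
    ]


def _separable(n_per_class, gap=50.0, seed=0, noise_features=True):
    """Three classes offset by ``gap`` on the first feature.

    With ``noise_features`` False the remaining features are constant, so the
    first feature is the only possible split variable.
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(3 * n_per_class, 23)) if noise_features else np.zeros((3 * n_per_class, 23))
    y = []
    for k, c in enumerate(CLASSES):
        X[k * n_per_class : (k + 1) * n_per_class, 0] += k * gap + rng.normal(
            0, 1, n_per_class
        ) * (0 if noise_features else 1)
        y += [c] * n_per_class
    return _toy_features(X), y


class TestLoocv:
    def test_one_heldout_prediction_per_eye(self):
        feats, y = _separable(4)
        per_eye = kp.loocv_predict(feats, y)
        assert len(per_eye) == 12
        assert set(per_eye["eye_id"]) == {f.eye_id for f in feats}
        np.testing.assert_allclose(
            per_eye[[f"p_{c}" for c in CLASSES]].sum(axis=1), 1.0, atol=1e-9
        )

    def test_huge_margin_gives_perfect_loocv(self):
        """One hugely separating feature (others uninformative) -> accuracy 1."""
        feats, y = _separable(14, gap=50.0, noise_features=False)  # n = 42
        per_eye = kp.loocv_predict(feats, y)
        assert (per_eye["predicted"] == per_eye["true"]).all()

    def test_order_invariance(self):
        """Predictions per eye are unchanged when the eye order is permuted."""
        feats, y = _separable(3, gap=2.0, seed=5)
        a = kp.loocv_predict(feats, y).set_index("eye_id").sort_index()
        perm = np.random.default_rng(0).permutation(len(y))
        b = (
            kp.loocv_predict([feats[i] for i in perm], [y[i] for i in perm])
            .set_index("eye_id")
            .sort_index()
        )
        pd.testing.assert_frame_equal(a, b)

    def test_reproducible(self):
        feats, y = _separable(3, gap=1.0, seed=2)
        a = kp.loocv_predict(feats, y)
        b = kp.loocv_predict(feats, y)
        pd.testing.assert_frame_equal(a, b)

    def test_class_with_single_member_rejected(self):
        feats, y = _separable(2)
        y[1] = y[0]  # leaves one lonely class member? build explicitly:
        feats, y = _separable(2)
        y = ["healthy", "healthy", "skc", "skc", "kc", "healthy"]
        with pytest.raises(ValueError, match="kc"):
            kp.loocv_predict(feats, y)

    def test_mixed_schemas_rejected(self):
        feats, y = _separable(2)
        other = kp.assemble_psoct_features(
            *(kp.ZernikeCoefficients(6, np.zeros(28), "um", 0.0, 4.0),) * 3
        )
        with pytest.raises(ValueError, match="schema"):
            kp.loocv_predict(feats[:-1] + [other], y)

    def test_fold_seed_tied_to_eye_identity(self):
        assert _fold_seed(1, "eye1") != _fold_seed(1, "eye2")
        assert _fold_seed(1, "eye1") == _fold_seed(1, "eye1")
        assert _fold_seed(1, "eye1") != _fold_seed(2, "eye1")


class TestMetrics:
    def _per_eye_from_confusion(self, cm, conf=0.9):
        rows = []
        i = 0
        for t, row in zip(CLASSES, cm):
            for p, count in zip(CLASSES, row):
                for _ in range(count):
                    probs = {c: (1 - conf) / 2 for c in CLASSES}
                    probs[p] = conf
                    rows.append([f"e{i}", t, p] + [probs[c] for c in CLASSES])
                    i += 1
        return pd.DataFrame(
            rows, columns=["eye_id", "true", "predicted"] + [f"p_{c}" for c in CLASSES]
        )

    def test_perfect_predictions(self):
        per_eye = self._per_eye_from_confusion([[5, 0, 0], [0, 5, 0], [0, 0, 5]])
        m = kp.compute_metrics(per_eye)
        assert m.accuracy == 1.0 and m.macro_f1 == 1.0 and m.macro_auc == 1.0

    def test_hand_checked_confusion_arithmetic(self):
        cm = [[8, 2, 0], [1, 9, 0], [0, 0, 10]]
        m = kp.compute_metrics(self._per_eye_from_confusion(cm))
        assert m.per_class["healthy"]["recall"] == pytest.approx(0.8)
        assert m.per_class["healthy"]["precision"] == pytest.approx(8 / 9)
        assert m.per_class["skc"]["recall"] == pytest.approx(0.9)
        assert m.per_class["skc"]["precision"] == pytest.approx(9 / 11)
        f1_h = 2 * 0.8 * (8 / 9) / (0.8 + 8 / 9)
        assert m.per_class["healthy"]["f1"] == pytest.approx(f1_h)
        assert m.accuracy == pytest.approx(27 / 30)
        # macro values are exact arithmetic means of per-class values
        assert m.macro_recall == pytest.approx(np.mean([0.8, 0.9, 1.0]))

    def test_never_predicted_class_precision_zero_with_warning(self):
        cm = [[5, 0, 0], [5, 0, 0], [0, 0, 5]]
        with pytest.warns(UserWarning, match="never predicted"):
            m = kp.compute_metrics(self._per_eye_from_confusion(cm))
        assert m.per_class["skc"]["precision"] == 0.0

    def test_absent_true_class_is_an_error(self):
        per_eye = self._per_eye_from_confusion([[5, 0, 0], [0, 5, 0], [0, 0, 0]])
        with pytest.raises(ValueError, match="kc"):
            kp.compute_metrics(per_eye)

    def test_confusion_matrix_counts(self):
        per_eye = self._per_eye_from_confusion([[3, 1, 0], [0, 4, 0], [0, 2, 5]])
        cm = kp.confusion_matrix(per_eye)
        assert cm.tolist() == [[3, 1, 0], [0, 4, 0], [0, 2, 5]]
        assert cm.sum() == len(per_eye)

    def test_swapped_predictions_add_two_off_diagonal(self):
        base = self._per_eye_from_confusion([[4, 0, 0], [0, 4, 0], [0, 0, 4]])
        swapped = base.copy()
        swapped.loc[0, "predicted"] = "skc"
        swapped.loc[4, "predicted"] = "healthy"
        diff = kp.confusion_matrix(swapped) - kp.confusion_matrix(base)
        assert diff[0, 1] == 1 and diff[1, 0] == 1
        assert np.abs(diff).sum() == 4

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            kp.confusion_matrix(pd.DataFrame(columns=["true", "predicted"]))


def _run_from_probs(y, probs, ids=None):
    ids = ids or [f"e{i}" for i in range(len(y))]
    p = np.asarray(probs)
    rest = (1 - p) / 2
    df = pd.DataFrame(
        {
            "eye_id": ids,
            "true": y,
            "predicted": np.where(p > 0.5, "kc", "healthy"),
            "p_healthy": rest,
            "p_skc": rest,
            "p_kc": p,
        }
    )
    return ModelRun(schema="MS39_23", per_eye=df)


class TestDelong:
    def test_self_comparison_is_null(self):
        rng = np.random.default_rng(0)
        y = ["kc"] * 20 + ["healthy"] * 20
        run = _run_from_probs(y, rng.uniform(0, 1, 40))
        z, p, auc_a, auc_b = kp.compare_model_rocs(run, run, "kc")
        assert auc_a == auc_b and p == 1.0

    def test_rank_preserving_rescale_identical(self):
        rng = np.random.default_rng(1)
        y = ["kc"] * 25 + ["healthy"] * 25
        probs = rng.uniform(0, 1, 50)
        a = _run_from_probs(y, probs)
        b = _run_from_probs(y, probs**3)  # monotone transform keeps ranks
        z, p, auc_a, auc_b = kp.compare_model_rocs(a, b, "kc")
        assert auc_a == pytest.approx(auc_b)
        assert p == pytest.approx(1.0)

    def test_power_against_weak_model(self):
        """A clearly better model is detected (p < 0.05) in >= 90% of replicates."""
        n = 200
        hits = 0
        reps = 100
        for r in range(reps):
            rng = np.random.default_rng(100 + r)
            y = np.where(rng.uniform(size=n) < 0.4, "kc", "healthy")
            strong = np.clip(
                np.where(y == "kc", 0.8, 0.2) + rng.normal(0, 0.15, n), 0, 1
            )
            weak = np.clip(
                np.where(y == "kc", 0.55, 0.45) + rng.normal(0, 0.3, n), 0, 1
            )
            a = _run_from_probs(y, strong)
            b = _run_from_probs(y, weak)
            _, p, *_ = kp.compare_model_rocs(a, b, "kc")
            hits += p < 0.05
        assert hits >= 0.9 * reps

    def test_eye_set_mismatch_rejected(self):
        rng = np.random.default_rng(2)
        y = ["kc"] * 5 + ["healthy"] * 5
        a = _run_from_probs(y, rng.uniform(0, 1, 10))
        b = _run_from_probs(y, rng.uniform(0, 1, 10), ids=[f"x{i}" for i in range(10)])
        with pytest.raises(ValueError, match="eye set"):
            kp.compare_model_rocs(a, b, "kc")


class TestSeparationMonotonicity:
    def test_accuracy_rises_with_class_separation(self):
        """Mean LOOCV accuracy trends upward in class separation (Spearman)."""
        from scipy.stats import spearmanr

        gaps = np.linspace(0.0, 3.0, 10)
        mean_acc = []
        for gap in gaps:
            accs = []
            for seed in range(10):
                feats, y = _separable(5, gap=gap, seed=seed)
                cfg = kp.RFConfig(n_trees=25, base_seed=seed)
                per_eye = kp.loocv_predict(feats, y, cfg)
                accs.append((per_eye["predicted"] == per_eye["true"]).mean())
            mean_acc.append(np.mean(accs))
        rho, _ = spearmanr(gaps, mean_acc)
        assert rho > 0.8
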