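"""Per-device random-forest models with leave-one-out evaluation.

Each device's feature table is evaluated with leave-one-out cross-validation
(LOOCV): every eye is predicted by a forest trained on all other eyes, with
identical hyperparameters across devices (100 trees, Gini splits, unbounded
depth, scikit-learn defaults) so that device comparisons are not confounded
by model tuning.

Conventions documented here because the source protocol leaves them open:

* the multiclass AUC is one-vs-rest per class, macro-averaged;
* each fold's forest is seeded from ``(base_seed, eye_id)`` so predictions
  are reproducible and invariant to eye ordering;
* at exactly tied class probabilities the earlier class in the fixed order
  (healthy, skc, kc) wins;
* a class never predicted gets precision 0 (with a warning) rather than NaN;
* model-vs-model AUC comparison uses the DeLong correlated-ROC test on the
  shared eye set.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.ensemble import RandomForestClassifier

from .labeling import GROUPS, GroupLabel
from .zernike import FeatureVector

__all__ = [
    "RFConfig",
    "MetricsReport",
    "ModelRun",
    "loocv_predict",
    "compute_metrics",
    "confusion_matrix",
    "compare_model_rocs",
    "run_model",
]

CLASSES = list(GROUPS)
_PROB_COLS = [f"p_{c}" for c in CLASSES]


@dataclass(frozen=True)
class RFConfig:
    """Random-forest hyperparameters, fixed identically for every device."""

    n_trees: int = 100
    split_criterion: str = "gini"
    max_depth: int | None = None
    min_samples_split: int = 2
    min_samples_leaf: int = 1
    base_seed: int = 0


@dataclass(frozen=True)
class MetricsReport:
    """Per-class and macro-averaged discrimination metrics.

    ``per_class[c]`` holds auc/precision/recall/f1 for class ``c``; macro
    values are arithmetic means of the per-class values and ``accuracy`` is
    the overall fraction correct.
    """

    per_class: dict[str, dict[str, float]]
    macro_auc: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    accuracy: float


@dataclass
class ModelRun:
    """LOOCV output of one device model."""

    schema: str
    per_eye: pd.DataFrame  # eye_id, true, predicted, p_healthy, p_skc, p_kc
    metrics: MetricsReport = None  # type: ignore[assignment]
    confusion: np.ndarray = field(default=None)  # type: ignore[assignment]


def _fold_seed(base_seed: int, eye_id: str) -> int:
    """Deterministic per-fold seed tied to the eye identity, not its position."""
    return (zlib.crc32(f"{base_seed}:{eye_id}".encode()) ^ (base_seed & 0x7FFFFFFF)) & 0x7FFFFFFF


def _as_label(lab) -> str:
    return lab.label if isinstance(lab, GroupLabel) else str(lab)


def loocv_predict(
    features: list[FeatureVector],
    labels,
    cfg: RFConfig = RFConfig(),
) -> pd.DataFrame:
    """Held-out class probabilities for every eye under leave-one-out.

    ``features`` must share one schema; ``labels`` are group strings or
    :class:`~kerapol.labeling.GroupLabel` (no ``indeterminate``); every class
    needs at least two members so each training fold retains all classes.
    """
    if len(features) != len(labels):
        raise ValueError("features and labels must have equal length")
    schemas = {f.schema for f in features}
    if len(schemas) != 1:
        raise ValueError(f"features mix schemas: {sorted(schemas)}")
    y = np.array([_as_label(l) for l in labels])
    bad = set(y) - set(CLASSES)
    if bad:
        raise ValueError(f"labels outside the three-class set: {sorted(bad)}")
    counts = {c: int((y == c).sum()) for c in CLASSES if (y == c).sum() > 0}
    for c, n in counts.items():
        if n < 2:
            raise ValueError(f"class {c!r} has {n} member(s); need >= 2 for LOOCV")
    X = np.vstack([f.values for f in features])
    eye_ids = [f.eye_id if f.eye_id is not None else f"idx{i}" for i, f in enumerate(features)]
    if len(set(eye_ids)) != len(eye_ids):
        raise ValueError("eye ids must be unique")
    n = len(y)
    # canonical training order by eye_id: fold contents (and therefore the
    # bootstrap draws) depend on which eyes are present, not on input order
    canonical = sorted(range(n), key=lambda j: eye_ids[j])
    rows = []
    for i in range(n):
        keep = np.array([j for j in canonical if j != i], dtype=int)
        clf = RandomForestClassifier(
            n_estimators=cfg.n_trees,
            criterion=cfg.split_criterion,
            max_depth=cfg.max_depth,
            min_samples_split=cfg.min_samples_split,
            min_samples_leaf=cfg.min_samples_leaf,
            random_state=_fold_seed(cfg.base_seed, eye_ids[i]),
            n_jobs=1,
        )
        clf.fit(X[keep], y[keep])
        proba = clf.predict_proba(X[i : i + 1])[0]
        p = {c: 0.0 for c in CLASSES}
        for c, pr in zip(clf.classes_, proba):
            p[c] = float(pr)
        pred = max(CLASSES, key=lambda c: (p[c], -CLASSES.index(c)))
        rows.append([eye_ids[i], y[i], pred] + [p[c] for c in CLASSES])
    return pd.DataFrame(rows, columns=["eye_id", "true", "predicted"] + _PROB_COLS)


def confusion_matrix(per_eye: pd.DataFrame) -> np.ndarray:
    """3x3 counts, rows = true group, columns = predicted, fixed class order."""
    if len(per_eye) == 0:
        raise ValueError("no predictions to tabulate")
    cm = np.zeros((3, 3), dtype=int)
    ti = {c: k for k, c in enumerate(CLASSES)}
    for t, p in zip(per_eye["true"], per_eye["predicted"]):
        cm[ti[t], ti[p]] += 1
    return cm


def compute_metrics(per_eye: pd.DataFrame) -> MetricsReport:
    """One-vs-rest AUCs and confusion-matrix metrics from held-out predictions."""
    from sklearn.metrics import roc_auc_score

    missing = [c for c in CLASSES if not (per_eye["true"] == c).any()]
    if missing:
        raise ValueError(f"classes absent from truth, metrics undefined: {missing}")
    cm = confusion_matrix(per_eye)
    per_class: dict[str, dict[str, float]] = {}
    for k, c in enumerate(CLASSES):
        tp = cm[k, k]
        pred_k = cm[:, k].sum()
        true_k = cm[k, :].sum()
        if pred_k == 0:
            warnings.warn(f"class {c!r} never predicted; precision set to 0", stacklevel=2)
            prec = 0.0
        else:
            prec = tp / pred_k
        rec = tp / true_k
        f1 = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
        auc = float(roc_auc_score((per_eye["true"] == c).astype(int), per_eye[f"p_{c}"]))
        per_class[c] = {"auc": auc, "precision": float(prec), "recall": float(rec), "f1": float(f1)}
    macro = {
        m: float(np.mean([per_class[c][m] for c in CLASSES]))
        for m in ("auc", "precision", "recall", "f1")
    }
    accuracy = float(np.trace(cm) / cm.sum())
    return MetricsReport(per_class, macro["auc"], macro["precision"], macro["recall"], macro["f1"], accuracy)


def run_model(features, labels, cfg: RFConfig = RFConfig(), schema: str | None = None) -> ModelRun:
    """LOOCV + metrics + confusion matrix in one step."""
    per_eye = loocv_predict(features, labels, cfg)
    run = ModelRun(schema=schema or features[0].schema, per_eye=per_eye)
    run.metrics = compute_metrics(per_eye)
    run.confusion = confusion_matrix(per_eye)
    return run


# ---------------------------------------------------------------------------
# DeLong correlated-ROC comparison


def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    mid = np.empty(n, dtype=float)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        mid[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n, dtype=float)
    out[order] = mid
    return out


def _delong_components(pos: np.ndarray, neg: np.ndarray):
    """AUC and the DeLong structural components V10 (per positive), V01."""
    m, n = len(pos), len(neg)
    all_r = _midrank(np.concatenate([pos, neg]))
    rp = _midrank(pos)
    rn = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_r[:m] - rp) / n
    v01 = 1.0 - (all_r[m:] - rn) / m
    return auc, v10, v01


def compare_model_rocs(run_a: ModelRun, run_b: ModelRun, group: str):
    """Paired (DeLong) test for equality of one-vs-rest AUCs on shared eyes.

    Returns ``(z_statistic, p_value, auc_a, auc_b)``.  Both runs must cover
    the same eye set with the same ground truth; run B's rows are aligned to
    run A's eye order before the paired comparison.
    """
    if group not in CLASSES:
        raise ValueError(f"unknown group {group!r}")
    a = run_a.per_eye
    b = run_b.per_eye.set_index("eye_id")
    if set(a["eye_id"]) != set(b.index) or len(a) != len(b):
        raise ValueError("runs cover different eye sets")
    b = b.loc[a["eye_id"]]
    if not (a["true"].to_numpy() == b["true"].to_numpy()).all():
        raise ValueError("runs disagree on ground-truth labels")
    y = (a["true"] == group).to_numpy()
    if y.all() or not y.any():
        raise ValueError(f"group {group!r} needs both positives and negatives")
    pa = a[f"p_{group}"].to_numpy(dtype=float)
    pb = b[f"p_{group}"].to_numpy(dtype=float)
    auc_a, v10a, v01a = _delong_components(pa[y], pa[~y])
    auc_b, v10b, v01b = _delong_components(pb[y], pb[~y])
    m, n = int(y.sum()), int((~y).sum())
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 1e-15:
        z = 0.0 if abs(diff) < 1e-12 else np.inf * np.sign(diff)
        p = 1.0 if abs(diff) < 1e-12 else 0.0
    else:
        z = diff / np.sqrt(var)
        p = float(2.0 * norm.sf(abs(z)))
    return float(z), float(p), float(auc_a), float(auc_b)
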