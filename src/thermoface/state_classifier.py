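"""Three-state RBF-SVM classifier over the five ROI mean temperatures.

The classifier maps one frame's feature vector (nose, right cheek, left
cheek, forehead, chin mean temperatures in degrees C) to one of the states
baseline / stress / relax.  Reference configuration: RBF kernel, C = 100,
gamma = 10, evaluated with 5-fold cross-validation; features are fed in
degrees C without standardization by default (a ``standardize`` flag exists
because RBF behaviour is scale-sensitive — see the methods note).

Data splits are grouped by participant: all frames of a participant land on
the same side of any train/test or fold boundary, preventing identity leakage
across folds.  A row-level mode is provided for comparison only.

Evaluation produces a single pooled confusion matrix over all held-out
predictions plus per-class precision / recall / F1 and overall accuracy.
``reconstruct_confusion`` inverts printed per-class metrics back to the
unique small-integer confusion matrix consistent with them.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as skm
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .roi_extraction import ROI_NAMES

__all__ = [
    "CLASS_ORDER",
    "ClassifierConfig",
    "Model",
    "EvalReport",
    "split_by_participant",
    "train",
    "predict",
    "kfold_cv",
    "confusion_matrix",
    "classification_report",
    "reconstruct_confusion",
]

#: Fixed class order for every confusion matrix and report.
CLASS_ORDER = ("baseline", "relax", "stress")


@dataclass
class ClassifierConfig:
    kernel: str = "rbf"
    C: float = 100.0
    gamma: float = 10.0
    k_folds: int = 5
    standardize: bool = False
    grid: dict | None = None  # {"C": [...], "gamma": [...]}
    seed: int = 0
    grouped_folds: bool = True

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


@dataclass
class Model:
    """Fitted estimator plus the config and feature schema it was trained with."""

    estimator: object
    config: ClassifierConfig
    feature_names: tuple = ROI_NAMES
    chosen_params: dict = field(default_factory=dict)


def _features(table: pd.DataFrame) -> np.ndarray:
    X = table[list(ROI_NAMES)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    return X


def _make_estimator(config: ClassifierConfig, C=None, gamma=None):
    svc = SVC(
        kernel=config.kernel,
        C=C if C is not None else config.C,
        gamma=gamma if gamma is not None else config.gamma,
        random_state=config.seed,
    )
    if config.standardize:
        return Pipeline([("scale", StandardScaler()), ("svc", svc)])
    return svc


def split_by_participant(
    table: pd.DataFrame, n_train: int = 20, n_test: int = 5, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split into disjoint participant sets (all of a participant's frames together)."""
    participants = np.array(sorted(table["participant_id"].unique()))
    if len(participants) < n_train + n_test:
        raise ValueError(
            f"need >= {n_train + n_test} participants, have {len(participants)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(participants)
    train_ids = set(order[:n_train])
    test_ids = set(order[n_train : n_train + n_test])
    return (
        table[table["participant_id"].isin(train_ids)].copy(),
        table[table["participant_id"].isin(test_ids)].copy(),
    )


def _participant_folds(table: pd.DataFrame, k: int, seed: int) -> list[np.ndarray]:
    """Row masks for k folds of whole participants, shuffled by seed."""
    participants = np.array(sorted(table["participant_id"].unique()))
    rng = np.random.default_rng(seed)
    order = rng.permutation(participants)
    return [
        table["participant_id"].isin(chunk).to_numpy()
        for chunk in np.array_split(order, k)
    ]


def _row_folds(table: pd.DataFrame, k: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(table))
    masks = []
    for chunk in np.array_split(order, k):
        m = np.zeros(len(table), dtype=bool)
        m[chunk] = True
        masks.append(m)
    return masks


def _grid_search(table: pd.DataFrame, config: ClassifierConfig) -> dict:
    """Pick (C, gamma) by k-fold accuracy; ties go to smallest C, then gamma."""
    Cs = sorted(config.grid.get("C", [config.C]))
    gammas = sorted(config.grid.get("gamma", [config.gamma]))
    folds = (
        _participant_folds(table, config.k_folds, config.seed)
        if config.grouped_folds
        else _row_folds(table, config.k_folds, config.seed)
    )
    y = table["phase"].to_numpy()
    X = _features(table)
    best = None
    for C, gamma in itertools.product(Cs, gammas):
        correct = total = 0
        for test_mask in folds:
            est = _make_estimator(config, C=C, gamma=gamma)
            est.fit(X[~test_mask], y[~test_mask])
            correct += int((est.predict(X[test_mask]) == y[test_mask]).sum())
            total += int(test_mask.sum())
        acc = correct / total
        # strictly-greater keeps the first (smallest C, then gamma) on ties
        if best is None or acc > best[0]:
            best = (acc, C, gamma)
    return {"C": best[1], "gamma": best[2], "cv_accuracy": best[0]}


def train(train_table: pd.DataFrame, config: ClassifierConfig | None = None) -> Model:
    """Fit the multiclass RBF-SVM; optionally grid-search (C, gamma) first."""
    config = config or ClassifierConfig()
    y = train_table["phase"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain >= 2 classes")
    chosen = {}
    C = gamma = None
    if config.grid:
        chosen = _grid_search(train_table, config)
        C, gamma = chosen["C"], chosen["gamma"]
    est = _make_estimator(config, C=C, gamma=gamma)
    est.fit(_features(train_table), y)
    return Model(estimator=est, config=config, chosen_params=chosen)


def predict(model: Model, features) -> str | np.ndarray:
    """Predict the state for one feature mapping/Series or a DataFrame batch.

    Features are matched by ROI name, so column order is irrelevant.
    """
    if isinstance(features, pd.DataFrame):
        X = _features(features)
        return model.estimator.predict(X)
    if isinstance(features, pd.Series):
        features = features.to_dict()
    missing = [r for r in ROI_NAMES if r not in features]
    if missing:
        raise ValueError(f"missing features {missing}")
    x = np.array([[float(features[r]) for r in ROI_NAMES]])
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite feature values")
    return str(model.estimator.predict(x)[0])


def kfold_cv(table: pd.DataFrame, config: ClassifierConfig | None = None) -> "EvalReport":
    """Pooled k-fold cross-validation: one confusion matrix over all held-out rows.

    Folds hold out whole participants by default.  If some training portion
    misses a class, the folding is reshuffled with a fresh seed (up to 10
    attempts) with a warning.
    """
    config = config or ClassifierConfig()
    y = table["phase"].to_numpy()
    classes = set(np.unique(y))
    X = _features(table)

    seed = config.seed
    for attempt in range(10):
        folds = (
            _participant_folds(table, config.k_folds, seed)
            if config.grouped_folds
            else _row_folds(table, config.k_folds, seed)
        )
        if all(classes <= set(y[~m]) for m in folds):
            break
        warnings.warn(f"class missing from a training fold; refolding (attempt {attempt + 1})")
        seed += 1
    else:
        raise ValueError("could not build folds with every class in each training portion")

    y_pred = np.empty(len(y), dtype=object)
    for test_mask in folds:
        est = _make_estimator(config)
        est.fit(X[~test_mask], y[~test_mask])
        y_pred[test_mask] = est.predict(X[test_mask])
    cm = confusion_matrix(y, y_pred)
    return classification_report(cm)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def confusion_matrix(y_true, y_pred) -> np.ndarray:
    """3x3 counts, rows = true, cols = predicted, order ``CLASS_ORDER``."""
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences must have equal length")
    unknown = (set(y_true) | set(y_pred)) - set(CLASS_ORDER)
    if unknown:
        raise ValueError(f"unknown labels {sorted(map(str, unknown))}")
    return skm.confusion_matrix(y_true, y_pred, labels=list(CLASS_ORDER))


@dataclass
class EvalReport:
    """Confusion matrix with per-class and overall metrics (percent).

    ``precision``/``recall``/``f1`` hold exact percentages; the ``*_pct``
    views round to integer percent and ``recall_2dp`` to two decimals, the
    granularities used in published summary tables.  An undefined precision
    (class never predicted) is NaN, not 0.
    """

    confusion: np.ndarray
    precision: dict
    recall: dict
    f1: dict

    @property
    def overall_accuracy(self) -> float:
        return 100.0 * np.trace(self.confusion) / self.confusion.sum()

    @property
    def error_rate(self) -> float:
        return 100.0 - self.overall_accuracy

    @property
    def recall_2dp(self) -> dict:
        return {c: round(v, 2) for c, v in self.recall.items()}

    @property
    def precision_pct(self) -> dict:
        return {c: _int_pct(v) for c, v in self.precision.items()}

    @property
    def recall_pct(self) -> dict:
        return {c: _int_pct(v) for c, v in self.recall.items()}

    @property
    def f1_pct(self) -> dict:
        return {c: _int_pct(v) for c, v in self.f1.items()}

    def to_dict(self) -> dict:
        return {
            "class_order": list(CLASS_ORDER),
            "confusion": self.confusion.tolist(),
            "precision_pct": self.precision_pct,
            "recall_pct": self.recall_pct,
            "f1_pct": self.f1_pct,
            "recall_2dp": self.recall_2dp,
            "overall_accuracy": round(self.overall_accuracy, 2),
            "error_rate": round(self.error_rate, 2),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "class": c,
                "accuracy_recall_2dp": self.recall_2dp[c],
                "precision_pct": self.precision_pct[c],
                "recall_pct": self.recall_pct[c],
                "f1_pct": self.f1_pct[c],
            }
            for c in CLASS_ORDER
        ]
        return pd.DataFrame(rows)


def _int_pct(v: float):
    return v if np.isnan(v) else int(np.floor(v + 0.5))


def classification_report(cm: np.ndarray) -> EvalReport:
    """Per-class precision/recall/F1 (percent) and overall accuracy from a cm."""
    cm = np.asarray(cm, dtype=int)
    if cm.shape != (3, 3) or cm.sum() == 0 or np.any(cm < 0):
        raise ValueError("confusion matrix must be 3x3 with nonnegative counts")
    precision, recall, f1 = {}, {}, {}
    for idx, cls in enumerate(CLASS_ORDER):
        col = cm[:, idx].sum()
        row = cm[idx, :].sum()
        if col == 0:
            warnings.warn(f"no predictions for class {cls!r}: precision undefined")
            p = float("nan")
        else:
            p = 100.0 * cm[idx, idx] / col
        r = 100.0 * cm[idx, idx] / row if row else float("nan")
        if np.isnan(p) or np.isnan(r) or (p + r) == 0:
            f = float("nan")
        else:
            f = 2 * p * r / (p + r)
        precision[cls], recall[cls], f1[cls] = p, r, f
    return EvalReport(confusion=cm, precision=precision, recall=recall, f1=f1)


def f1_from_pair(precision_pct: float, recall_pct: float) -> float:
    """Harmonic mean of a printed precision/recall pair, in percent."""
    if precision_pct + recall_pct == 0:
        return float("nan")
    return 2 * precision_pct * recall_pct / (precision_pct + recall_pct)


def reconstruct_confusion(
    total: int,
    recall_2dp: dict,
    precision_pct: dict,
    max_class: int = 40,
) -> list[np.ndarray]:
    """All 3x3 integer confusion matrices consistent with printed metrics.

    Searches row sums up to ``max_class`` whose per-class recall matches the
    printed two-decimal value within 0.01 (covering round-vs-truncate
    ambiguity at the last digit) and whose column-wise precision rounds to the
    printed integer percent.  Row sums must add to ``total``.
    """
    targets_r = [recall_2dp[c] for c in CLASS_ORDER]
    targets_p = [precision_pct[c] for c in CLASS_ORDER]

    # candidate (row_sum, diagonal) pairs matching each recall
    candidates: list[list[tuple[int, int]]] = []
    for t in targets_r:
        opts = []
        for row in range(1, max_class + 1):
            for diag in range(0, row + 1):
                if abs(100.0 * diag / row - t) <= 0.01 + 1e-9:
                    opts.append((row, diag))
        candidates.append(opts)

    solutions = []
    for (r0, d0), (r1, d1), (r2, d2) in itertools.product(*candidates):
        if r0 + r1 + r2 != total:
            continue
        offs = [r0 - d0, r1 - d1, r2 - d2]
        # distribute each row's errors over its two off-diagonal cells
        splits = [
            [(a, off - a) for a in range(off + 1)] for off in offs
        ]
        for s0, s1, s2 in itertools.product(*splits):
            cm = np.array(
                [
                    [d0, s0[0], s0[1]],
                    [s1[0], d1, s1[1]],
                    [s2[0], s2[1], d2],
                ]
            )
            ok = True
            for j, tp in enumerate(targets_p):
                col = cm[:, j].sum()
                if col == 0 or _int_pct(100.0 * cm[j, j] / col) != tp:
                    ok = False
                    break
            if ok:
                solutions.append(cm)
    return solutions
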