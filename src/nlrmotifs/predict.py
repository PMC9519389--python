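"""Training, persistence and application of the per-motif MLP classifiers.

Each of the 17 motif classes gets its own binary classifier that scores every
residue of a sequence as a potential motif start. The network is a multilayer
perceptron with three hidden layers of 250, 125 and 100 neurons, ReLU
activations, Adam optimization at a constant learning rate of 0.001 and L2
regularization; it consumes the 40*(L+10)-dimensional window vectors of the
:mod:`nlrmotifs.windows` module.

The evaluation protocol splits the examples (sequences) into five equal
groups: groups 1-4 feed a fourfold cross-validation, group 5 is held out and
touched once for the final test report. Metrics are position-level precision,
recall (sensitivity), specificity, F1 and G = sqrt(precision * recall)
(switchable to the sqrt(recall * specificity) variant).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.neural_network import MLPClassifier
from sklearn.utils.validation import check_is_fitted

from .errors import InputError, ModelError
from .profiles import ProfileFeatures
from .registry import MotifDefinition
from .windows import DEFAULT_FLANK, window_matrix

MODEL_FORMAT_VERSION = 1
FEATURE_ORDER_TAG = "position-major/iteration/alphabetical-aa"


@dataclass(frozen=True)
class Hyperparams:
    """MLP hyperparameters (defaults follow the published architecture)."""

    hidden_layers: tuple[int, ...] = (250, 125, 100)
    activation: str = "relu"
    solver: str = "adam"
    learning_rate: float = 0.001
    l2_alpha: float = 1e-4
    batch_size: int = 512
    max_epochs: int = 500
    tol: float = 1e-5
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if any(h <= 0 for h in self.hidden_layers):
            raise InputError("hidden layer sizes must be positive")
        if self.learning_rate <= 0:
            raise InputError("learning rate must be positive")


@dataclass(frozen=True)
class SplitPlan:
    """Five disjoint example-index groups; 1-4 for CV, 5 held out."""

    groups: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        sizes = [len(g) for g in self.groups]
        if len(self.groups) != 5:
            raise InputError("a split plan must have exactly 5 groups")
        if max(sizes) - min(sizes) > 1:
            raise InputError("split groups must be balanced within one example")

    @property
    def test_group(self) -> np.ndarray:
        return self.groups[4]


def make_split(n_examples: int, seed: int) -> SplitPlan:
    """Deterministic, balanced 5-group split of ``range(n_examples)``."""
    if n_examples < 5:
        raise InputError(f"need at least 5 examples to split, got {n_examples}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_examples)
    return SplitPlan(tuple(np.sort(g) for g in np.array_split(perm, 5)))


@dataclass
class MetricsReport:
    """Position-level confusion counts and the derived scores."""

    tp: int
    fp: int
    tn: int
    fn: int
    precision: float = field(init=False)
    recall: float = field(init=False)
    specificity: float = field(init=False)
    f1: float = field(init=False)
    g: float = field(init=False)
    degenerate: list = field(default_factory=list)
    g_mode: str = "precision-recall"

    def __post_init__(self) -> None:
        tp, fp, tn, fn = self.tp, self.fp, self.tn, self.fn
        if tp + fp == 0:
            self.precision = 0.0
            self.degenerate.append("no-predicted-positives")
        else:
            self.precision = tp / (tp + fp)
        self.recall = tp / (tp + fn) if tp + fn else 0.0
        self.specificity = tn / (tn + fp) if tn + fp else 0.0
        if self.precision + self.recall == 0:
            self.f1 = 0.0
        else:
            self.f1 = 2 * self.precision * self.recall / (self.precision + self.recall)
        if self.g_mode == "precision-recall":
            self.g = math.sqrt(self.precision * self.recall)
        elif self.g_mode == "recall-specificity":
            self.g = math.sqrt(self.recall * self.specificity)
        else:
            raise InputError(f"unknown G-score mode {self.g_mode!r}")

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "precision": self.precision, "recall": self.recall,
            "specificity": self.specificity, "f1": self.f1, "g": self.g,
            "degenerate": list(self.degenerate),
        }


def evaluate(
    pred_probs: np.ndarray | Sequence[np.ndarray],
    true_starts: Sequence[int] | Sequence[Sequence[int]],
    threshold: float = 0.5,
    tolerance: int = 0,
    g_mode: str = "precision-recall",
) -> MetricsReport:
    """Position-level confusion metrics of per-residue start probabilities.

    Accepts either one probability vector with its true-start index list, or
    parallel lists of vectors/index-lists (counts are pooled). A predicted
    positive is a TP when a true start lies within ``tolerance`` positions;
    each true start missing a predicted positive within tolerance is an FN.
    """
    if len(pred_probs) and np.ndim(pred_probs[0]) == 0:
        pairs = [(np.asarray(pred_probs, dtype=float), list(true_starts))]
    else:
        if len(pred_probs) != len(true_starts):
            raise InputError("pred_probs and true_starts lengths differ")
        pairs = [(np.asarray(p, dtype=float), list(t))
                 for p, t in zip(pred_probs, true_starts)]
    tp = fp = tn = fn = 0
    for probs, starts in pairs:
        n = len(probs)
        called = np.nonzero(probs >= threshold)[0]
        truth = np.zeros(n, dtype=bool)
        for s in starts:
            truth[max(0, s - tolerance): s + tolerance + 1] = True
        hit_truth = truth[called] if len(called) else np.zeros(0, dtype=bool)
        tp_i = int(hit_truth.sum())
        fp_i = len(called) - tp_i
        matched = 0
        called_set = set(called.tolist())
        for s in starts:
            if any((s + d) in called_set for d in range(-tolerance, tolerance + 1)):
                matched += 1
        fn_i = len(starts) - matched
        tp += tp_i
        fp += fp_i
        fn += fn_i
        tn += n - len(called) - fn_i
    return MetricsReport(tp=tp, fp=fp, tn=tn, fn=fn, g_mode=g_mode)


class MotifStartClassifier(ClassifierMixin, BaseEstimator):
    """Sklearn-style per-motif MLP classifier over window vectors.

    Parameters mirror :class:`Hyperparams`; ``motif`` and ``motif_length``
    pin the classifier to one motif class and its expected feature
    dimensionality (40 * (motif_length + 10) with default flanks).
    """

    def __init__(
        self,
        motif: Optional[str] = None,
        motif_length: Optional[int] = None,
        flank: int = DEFAULT_FLANK,
        hidden_layer_sizes: tuple[int, ...] = (250, 125, 100),
        alpha: float = 1e-4,
        learning_rate_init: float = 0.001,
        batch_size: int = 512,
        max_iter: int = 500,
        tol: float = 1e-5,
        n_iter_no_change: int = 10,
        random_state: int = 0,
    ):
        self.motif = motif
        self.motif_length = motif_length
        self.flank = flank
        self.hidden_layer_sizes = hidden_layer_sizes
        self.alpha = alpha
        self.learning_rate_init = learning_rate_init
        self.batch_size = batch_size
        self.max_iter = max_iter
        self.tol = tol
        self.n_iter_no_change = n_iter_no_change
        self.random_state = random_state

    def _expected_dim(self) -> Optional[int]:
        if self.motif_length is None:
            return None
        return 40 * (self.motif_length + 2 * self.flank)

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y).astype(int)
        if X.ndim != 2 or len(X) != len(y):
            raise InputError("X must be 2-D with one label per row")
        expected = self._expected_dim()
        if expected is not None and X.shape[1] != expected:
            raise ModelError(
                f"feature dimension {X.shape[1]} does not match motif "
                f"{self.motif!r} (expected {expected})"
            )
        if len(np.unique(y)) < 2:
            raise InputError("training data must contain both classes")
        # Standardize the (-ln emission) features: they are all-positive with
        # spread-out scales, which conditions Adam poorly on rare-positive data.
        self.scaler_mean_ = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale <= 1e-8] = 1.0
        self.scaler_scale_ = scale
        X = (X - self.scaler_mean_) / self.scaler_scale_
        self.mlp_ = MLPClassifier(
            hidden_layer_sizes=tuple(self.hidden_layer_sizes),
            activation="relu",
            solver="adam",
            learning_rate="constant",
            learning_rate_init=self.learning_rate_init,
            alpha=self.alpha,
            batch_size=min(self.batch_size, len(X)),
            max_iter=self.max_iter,
            tol=self.tol,
            n_iter_no_change=self.n_iter_no_change,
            early_stopping=False,
            shuffle=True,
            random_state=self.random_state,
        )
        import warnings as _warnings
        from sklearn.exceptions import ConvergenceWarning

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", ConvergenceWarning)
            self.mlp_.fit(X, y)
        self.classes_ = self.mlp_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "mlp_")
        X = np.asarray(X)
        if X.shape[1] != self.n_features_in_:
            raise ModelError(
                f"feature dimension {X.shape[1]} does not match the fitted "
                f"model (expected {self.n_features_in_})"
            )
        X = (X - self.scaler_mean_) / self.scaler_scale_
        return self.mlp_.predict_proba(X)

    def predict(self, X):
        return (self.start_probability(X) >= 0.5).astype(int)

    def start_probability(self, X) -> np.ndarray:
        """P(window is a motif start) for each row of X."""
        proba = self.predict_proba(X)
        pos_col = int(np.nonzero(self.classes_ == 1)[0][0])
        return proba[:, pos_col]


@dataclass
class PredictorModel:
    """A trained per-motif predictor plus its training metadata."""

    motif: str
    motif_length: int
    hyperparams: Hyperparams
    estimator: MotifStartClassifier
    metadata: dict = field(default_factory=dict)


def _group_windows(plan: SplitPlan, example_ids: np.ndarray) -> list[np.ndarray]:
    """Window indices per split group, mapping example ids through the plan."""
    out = []
    for g in plan.groups:
        members = np.isin(example_ids, g)
        out.append(np.nonzero(members)[0])
    return out


def train_predictor(
    X: np.ndarray,
    labels: Sequence[int],
    definition: MotifDefinition,
    hp: Hyperparams,
    plan: SplitPlan,
    example_ids: Optional[Sequence[int]] = None,
    cv: bool = True,
    flank: int = DEFAULT_FLANK,
) -> tuple[PredictorModel, list[MetricsReport], MetricsReport]:
    """Train one motif predictor with the 5-group protocol.

    ``example_ids`` maps each window row to its example (sequence) index in
    the split plan; by default each window is its own example. Returns the
    final model (fit on groups 1-4), the four CV fold reports and the
    held-out test report (group 5, threshold 0.5). Fully deterministic given
    ``hp.seed``.
    """
    X = np.asarray(X)
    y = np.asarray(labels).astype(int)
    if len(X) != len(y):
        raise InputError("windows and labels lengths differ")
    expected = 20 * 2 * (definition.length + 2 * flank)
    if X.shape[1] != expected:
        raise ModelError(
            f"window dimension {X.shape[1]} does not match motif "
            f"{definition.name!r} (expected {expected})"
        )
    if example_ids is None:
        example_ids = np.arange(len(X))
    example_ids = np.asarray(example_ids)
    win_groups = _group_windows(plan, example_ids)
    for k, g in enumerate(win_groups):
        classes = np.unique(y[g])
        if len(classes) < 2:
            raise InputError(
                f"split group {k + 1} contains a single class; cannot train/evaluate"
            )

    def _make(seed: int) -> MotifStartClassifier:
        return MotifStartClassifier(
            motif=definition.name,
            motif_length=definition.length,
            flank=flank,
            hidden_layer_sizes=hp.hidden_layers,
            alpha=hp.l2_alpha,
            learning_rate_init=hp.learning_rate,
            batch_size=hp.batch_size,
            max_iter=hp.max_epochs,
            tol=hp.tol,
            n_iter_no_change=hp.patience,
            random_state=seed,
        )

    cv_reports: list[MetricsReport] = []
    if cv:
        for k in range(4):
            train_idx = np.concatenate([win_groups[j] for j in range(4) if j != k])
            fold = _make(hp.seed)
            fold.fit(X[train_idx], y[train_idx])
            probs = fold.start_probability(X[win_groups[k]])
            cv_reports.append(_window_report(probs, y[win_groups[k]]))

    train_idx = np.concatenate(win_groups[:4])
    est = _make(hp.seed)
    est.fit(X[train_idx], y[train_idx])
    test_probs = est.start_probability(X[win_groups[4]])
    test_report = _window_report(test_probs, y[win_groups[4]])
    model = PredictorModel(
        motif=definition.name,
        motif_length=definition.length,
        hyperparams=hp,
        estimator=est,
        metadata={
            "n_windows": int(len(X)),
            "n_examples": int(example_ids.max()) + 1 if len(example_ids) else 0,
            "cv_folds": len(cv_reports),
        },
    )
    return model, cv_reports, test_report


def _window_report(probs: np.ndarray, y: np.ndarray,
                   threshold: float = 0.5) -> MetricsReport:
    pred = probs >= threshold
    truth = y.astype(bool)
    return MetricsReport(
        tp=int(np.sum(pred & truth)),
        fp=int(np.sum(pred & ~truth)),
        tn=int(np.sum(~pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
    )


def predict_residue_probabilities(
    model: PredictorModel,
    features: ProfileFeatures,
    definition: MotifDefinition,
    flank: int = DEFAULT_FLANK,
) -> np.ndarray:
    """P(motif start) for every residue of the sequence (length-preserving)."""
    if model.motif != definition.name:
        raise ModelError(
            f"model is for motif {model.motif!r}, not {definition.name!r}"
        )
    if model.motif_length != definition.length:
        raise ModelError(
            f"model window length {model.motif_length} does not match the "
            f"registry definition of {definition.name!r} ({definition.length})"
        )
    X = window_matrix(features, definition, flank)
    return model.estimator.start_probability(X)


def save_model(model: PredictorModel, path) -> None:
    """Persist a trained predictor as a versioned archive."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "feature_order": FEATURE_ORDER_TAG,
        "motif": model.motif,
        "motif_length": model.motif_length,
        "hyperparams": asdict(model.hyperparams),
        "estimator": model.estimator,
        "metadata": model.metadata,
    }
    joblib.dump(payload, path)


def load_model(path) -> PredictorModel:
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ModelError(f"cannot read model archive {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ModelError(f"{path} is not a nlrmotifs model archive")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ModelError(
            f"model format version {payload['format_version']} unsupported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    hp = payload["hyperparams"]
    hp["hidden_layers"] = tuple(hp["hidden_layers"])
    return PredictorModel(
        motif=payload["motif"],
        motif_length=payload["motif_length"],
        hyperparams=Hyperparams(**hp),
        estimator=payload["estimator"],
        metadata=payload.get("metadata", {}),
    )
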