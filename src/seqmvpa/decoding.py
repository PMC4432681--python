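"""Cost-weighted linear classification under leave-one-run-out cross-validation.

The decoder is a linear maximum-margin classifier (SVM). Because the
decoded label is the participant's response-implied prediction, the two
classes are generally unbalanced; the misclassification penalty of each
class is therefore scaled by the ratio of pattern counts so that the
majority class does not dominate the decision rule.

Cross-validation leaves one scan run out per fold: the classifier is
trained on the trials of all remaining runs and tested on the held-out
run's trials. Accuracy is averaged across folds with equal fold weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, check_X_y

from .preprocess import PatternSet, prepare_patterns
from .simulate import Session


@dataclass
class ClassifierConfig:
    """Decoder settings: regularization strength and cost weighting.

    The regularization strength C is not critical for linear decoding of
    these patterns (a sensitivity check is part of the test suite); the
    default is a fixed moderate value.
    """

    C: float = 1.0
    cost_weighting: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("regularization strength must be positive")


class WeightedLinearDecoder(BaseEstimator, ClassifierMixin):
    """Linear SVM whose per-class error cost is weighted by class counts.

    With ``cost_weighting=True`` the penalty for misclassifying class ``c``
    is scaled by ``n_samples / (n_classes * n_c)``, i.e. the minority
    class's errors cost proportionally more, exactly compensating the
    class-count ratio.

    Fitted attributes: ``classes_``, ``coef_`` (1 x n_features weight
    vector), ``intercept_``, ``class_weight_``, ``n_features_in_``.
    """

    def __init__(self, C: float = 1.0, cost_weighting: bool = True):
        self.C = C
        self.cost_weighting = cost_weighting

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("training data contains a single class")
        if self.cost_weighting:
            weights = {c: len(y) / (len(classes) * n) for c, n in zip(classes, counts)}
        else:
            weights = None
        self._svc = SVC(kernel="linear", C=self.C, class_weight=weights)
        self._svc.fit(X, y)
        self.classes_ = self._svc.classes_
        self.coef_ = self._svc.coef_
        self.intercept_ = self._svc.intercept_
        self.class_weight_ = weights
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        return self._svc.decision_function(X)

    def predict(self, X):
        check_is_fitted(self, "coef_")
        return self._svc.predict(X)


def train_weighted_linear(patterns, labels, cfg: ClassifierConfig | None = None) -> WeightedLinearDecoder:
    """Fit the cost-weighted linear decoder on a pattern matrix."""
    cfg = cfg or ClassifierConfig()
    return WeightedLinearDecoder(C=cfg.C, cost_weighting=cfg.cost_weighting).fit(patterns, labels)


@dataclass
class DecodingResult:
    """Per-fold and mean accuracy of a cross-validated decoding analysis."""

    fold_accuracies: np.ndarray
    fold_runs: list
    n_test_per_fold: list[int]
    label_source: str
    volume_mode: str
    n_train_per_fold: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        acc = np.asarray(self.fold_accuracies, dtype=float)
        if np.any((acc < 0) | (acc > 1)):
            raise ValueError("fold accuracies must lie in [0, 1]")
        self.fold_accuracies = acc

    @property
    def mean_accuracy(self) -> float:
        """Accuracy averaged across cross-validation folds (equal fold weight)."""
        return float(self.fold_accuracies.mean())

    @property
    def n_folds(self) -> int:
        return len(self.fold_accuracies)

    def to_dict(self) -> dict:
        return {
            "mean_accuracy": self.mean_accuracy,
            "fold_accuracies": self.fold_accuracies.tolist(),
            "fold_runs": [int(r) for r in self.fold_runs],
            "n_test_per_fold": self.n_test_per_fold,
            "n_train_per_fold": self.n_train_per_fold,
            "label_source": self.label_source,
            "volume_mode": self.volume_mode,
        }


def _loro_folds(run_ids: np.ndarray):
    for run in np.unique(run_ids):
        yield run, run_ids != run, run_ids == run


def _resolve_patterns(data, window, average=True) -> PatternSet:
    if isinstance(data, Session):
        return prepare_patterns(data, window=window, average=average)
    if isinstance(data, PatternSet):
        return data
    raise TypeError("expected a Session or a PatternSet")


def leave_one_run_out(
    data: Session | PatternSet,
    label_source: str = "response",
    cfg: ClassifierConfig | None = None,
    correct_only: bool = False,
    *,
    voxels: np.ndarray | None = None,
    window: tuple[int, int] = (8, 13),
) -> DecodingResult:
    """Leave-one-run-out decoding of blank-interval patterns.

    ``label_source`` selects the decoded label: the response-implied
    prediction (``"response"``), the sequence-expected orientation
    (``"expected"``), or the control-task cue (``"cued"``).
    ``correct_only`` restricts both training and test to correct trials.
    ``voxels`` optionally restricts the pattern to a voxel subset (e.g. the
    top-300 most activated voxels).
    """
    cfg = cfg or ClassifierConfig()
    patterns = _resolve_patterns(data, window)
    if correct_only:
        patterns = patterns.subset(patterns.labels["correct"].to_numpy().astype(bool))
    X = patterns.X if voxels is None else patterns.X[:, voxels]
    y = patterns.label_values(label_source)
    if len(np.unique(patterns.run_ids)) < 2:
        raise ValueError("leave-one-run-out needs at least 2 runs")

    accs, runs, n_test, n_train = [], [], [], []
    for run, train_mask, test_mask in _loro_folds(patterns.run_ids):
        if len(np.unique(y[train_mask])) < 2:
            raise ValueError(f"fold {run}: training data contains a single class")
        model = WeightedLinearDecoder(C=cfg.C, cost_weighting=cfg.cost_weighting)
        model.fit(X[train_mask], y[train_mask])
        accs.append(float(np.mean(model.predict(X[test_mask]) == y[test_mask])))
        runs.append(run)
        n_test.append(int(test_mask.sum()))
        n_train.append(int(train_mask.sum()))
    mode = "averaged" if patterns.volume is None else f"volume-{patterns.volume}"
    return DecodingResult(np.asarray(accs), runs, n_test, label_source, mode, n_train)


def per_volume_decode(
    data: Session | dict[int, PatternSet],
    cfg: ClassifierConfig | None = None,
    label_source: str = "response",
    *,
    window: tuple[int, int] = (8, 13),
    voxels: np.ndarray | None = None,
) -> dict[int, DecodingResult]:
    """Decode each trial volume of the window separately.

    Returns one :class:`DecodingResult` per (shifted) trial volume index.
    Averaged-window decoding is typically at least as accurate because the
    across-volume mean suppresses noise.
    """
    if isinstance(data, Session):
        from .preprocess import prepare_patterns_per_volume

        data = prepare_patterns_per_volume(data, window=window)
    return {
        v: leave_one_run_out(ps, label_source, cfg, voxels=voxels)
        for v, ps in sorted(data.items())
    }
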