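"""Permutation-null significance, learning-curve fitting, paired comparisons.

Classifier significance is assessed nonparametrically: the correspondence
between trial patterns and labels is randomized and the full leave-one-run-
out decoding re-run for many iterations; an observed accuracy is deemed
significant when it exceeds the 97.5th percentile of this null
distribution. Behavioural learning is summarised by the logarithmic law
y = k*log(x) + c fitted by least squares across training runs, where k is
the curve's tangent at x = 1 and c the value of y at x = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .decoding import ClassifierConfig, WeightedLinearDecoder
from .preprocess import PatternSet, prepare_patterns
from .simulate import Session

DEFAULT_N_ITER = 10_000
SIGNIFICANCE_PERCENTILE = 97.5


@dataclass
class NullDistribution:
    """Accuracies of label-permuted decoding iterations."""

    accuracies: np.ndarray

    def __post_init__(self) -> None:
        acc = np.asarray(self.accuracies, dtype=float)
        if acc.size < 1:
            raise ValueError("need at least one iteration")
        if np.any((acc < 0) | (acc > 1)):
            raise ValueError("accuracies must lie in [0, 1]")
        self.accuracies = acc

    @property
    def n_iterations(self) -> int:
        return self.accuracies.size

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd(self) -> float:
        return float(self.accuracies.std(ddof=0))

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.accuracies, q))

    def is_significant(self, observed: float, q: float = SIGNIFICANCE_PERCENTILE) -> bool:
        """Observed accuracy above the q-th percentile of the null."""
        return bool(observed > self.percentile(q))

    def p_value(self, observed: float) -> float:
        """Permutation p-value with the +1 correction."""
        return float((1 + np.sum(self.accuracies >= observed)) / (1 + self.n_iterations))


def permutation_null(
    data: Session | PatternSet,
    cfg: ClassifierConfig | None = None,
    n_iter: int = DEFAULT_N_ITER,
    rng: np.random.Generator | None = None,
    *,
    label_source: str = "response",
    voxels: np.ndarray | None = None,
) -> NullDistribution:
    """Null distribution of decoding accuracy under label randomization.

    Each iteration shuffles the pattern-label correspondence across the
    whole session and re-runs the full leave-one-run-out decoding (the run
    structure of the cross-validation is preserved; voxel selection, being
    label-free, is reused). Accuracy per iteration is the fold-averaged
    accuracy, as in the observed analysis.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be at least 1")
    cfg = cfg or ClassifierConfig()
    rng = rng or np.random.default_rng()
    patterns = data if isinstance(data, PatternSet) else prepare_patterns(data)
    X = patterns.X if voxels is None else patterns.X[:, voxels]
    y = patterns.label_values(label_source)
    folds = [
        (patterns.run_ids != run, patterns.run_ids == run)
        for run in np.unique(patterns.run_ids)
    ]
    if len(folds) < 2:
        raise ValueError("need at least 2 runs")

    accs = np.empty(n_iter)
    for it in range(n_iter):
        y_perm = rng.permutation(y)
        fold_accs = []
        for train_mask, test_mask in folds:
            y_tr = y_perm[train_mask]
            if len(np.unique(y_tr)) < 2:
                # degenerate shuffle: constant training labels; the decoder
                # can only emit that class
                pred = np.full(int(test_mask.sum()), y_tr[0])
            else:
                model = WeightedLinearDecoder(C=cfg.C, cost_weighting=cfg.cost_weighting)
                model.fit(X[train_mask], y_tr)
                pred = model.predict(X[test_mask])
            fold_accs.append(np.mean(pred == y_perm[test_mask]))
        accs[it] = np.mean(fold_accs)
    return NullDistribution(accs)


@dataclass
class LearningCurveFit:
    """Least-squares fit of y = k*log(x) + c to per-run accuracies."""

    k: float
    c: float
    fitted: np.ndarray
    residual_ss: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.k * np.log(np.asarray(x, dtype=float)) + self.c


def fit_learning_curve(run_accuracies, x=None) -> LearningCurveFit:
    """Fit the logarithmic learning law across ordered training runs.

    ``x`` defaults to the 1-based run index. The model is linear in
    (log x, 1), so the least-squares solution is exact.
    """
    y = np.asarray(run_accuracies, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 runs to fit a learning curve")
    x = np.arange(1, y.size + 1, dtype=float) if x is None else np.asarray(x, dtype=float)
    design = np.column_stack([np.log(x), np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    return LearningCurveFit(k=float(coef[0]), c=float(coef[1]), fitted=fitted,
                            residual_ss=float(np.sum((y - fitted) ** 2)))


def paired_compare(pre_results, post_results) -> dict:
    """Two-sided paired t-test on per-subject accuracies.

    Returns the mean post-pre difference, the t statistic and p-value.
    Degenerate cases (zero variance of the differences) are handled: a zero
    constant difference gives t = 0, p = 1; a nonzero constant difference
    gives an infinite t and p = 0.
    """
    pre = np.asarray(pre_results, dtype=float)
    post = np.asarray(post_results, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("paired lists must have equal length")
    diff = post - pre
    mean_diff = float(diff.mean())
    if np.allclose(diff, diff[0]):
        if np.isclose(mean_diff, 0.0):
            return {"mean_difference": 0.0, "t": 0.0, "p": 1.0, "n": len(diff)}
        return {"mean_difference": mean_diff,
                "t": float(np.inf * np.sign(mean_diff)), "p": 0.0, "n": len(diff)}
    t, p = sps.ttest_rel(post, pre)
    return {"mean_difference": mean_diff, "t": float(t), "p": float(p), "n": len(diff)}
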