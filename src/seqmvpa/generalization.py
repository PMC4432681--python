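"""Recursive feature elimination and cross-decoding generalization.

Two questions are addressed here. First, which voxels carry information for
a classification, as judged by the magnitude of the linear classifier's
weights: recursive feature elimination (RFE) repeatedly trains the
cost-weighted linear decoder and discards the fraction of remaining voxels
with the smallest absolute weight, yielding an informativeness ranking.

Second, do the voxels that encode physical stimulus orientation also carry
the predicted orientation: a classifier is trained on stimulus-driven
localizer patterns and tested on blank-interval patterns of the prediction
task (cross-decoding). Voxels can be fixed, chosen from the localizer RFE
only, or chosen per cross-validation fold as the voxels informative in both
the physical and the predicted classification — with the held-out run
excluded from both the RFE and the decoding to avoid circularity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .decoding import ClassifierConfig, DecodingResult, WeightedLinearDecoder
from .preprocess import PatternSet


@dataclass
class RFERanking:
    """Outcome of recursive feature elimination over one voxel universe.

    ``elimination_order`` lists voxel indices in the order they were
    dropped (first = least informative); ``survivor_sets`` holds the voxel
    sets remaining after each elimination step (nested); ``ranks`` maps each
    voxel to its final rank (1 = most informative = eliminated last).
    """

    elimination_order: np.ndarray
    survivor_sets: list[np.ndarray]
    ranks: np.ndarray

    @property
    def n_voxels(self) -> int:
        return len(self.ranks)

    def top(self, n: int) -> np.ndarray:
        """The ``n`` best-ranked voxel indices (ascending rank)."""
        return np.argsort(self.ranks, kind="stable")[:n]


def rfe_rank(
    patterns: np.ndarray,
    labels: np.ndarray,
    cfg: ClassifierConfig | None = None,
    step_fraction: float = 0.1,
) -> RFERanking:
    """Rank voxels by iterative elimination of smallest-|weight| features.

    At each step the decoder is trained on the surviving voxels and
    ``step_fraction`` of them (at least one) with the smallest absolute
    weight are eliminated, until none remain. Within a step, voxels are
    eliminated in ascending |weight| order (ties broken by voxel index), so
    ``step_fraction = 1/n_voxels`` gives strict one-at-a-time elimination.
    """
    cfg = cfg or ClassifierConfig()
    X = np.asarray(patterns, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 voxels to rank")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    if not 0 < step_fraction <= 1:
        raise ValueError("step_fraction must lie in (0, 1]")

    active = np.arange(X.shape[1])
    eliminated: list[int] = []
    survivor_sets: list[np.ndarray] = []
    while len(active) > 0:
        model = WeightedLinearDecoder(C=cfg.C, cost_weighting=cfg.cost_weighting)
        model.fit(X[:, active], y)
        w = np.abs(model.coef_).ravel()
        n_drop = max(1, int(np.floor(step_fraction * len(active))))
        n_drop = min(n_drop, len(active))
        drop_local = np.argsort(w, kind="stable")[:n_drop]  # ascending |w|, index ties
        eliminated.extend(int(active[i]) for i in sorted(drop_local, key=lambda i: (w[i], active[i])))
        keep = np.ones(len(active), dtype=bool)
        keep[drop_local] = False
        active = active[keep]
        survivor_sets.append(active.copy())

    order = np.asarray(eliminated)
    ranks = np.empty(X.shape[1], dtype=int)
    ranks[order] = np.arange(X.shape[1], 0, -1)  # eliminated last -> rank 1
    return RFERanking(elimination_order=order, survivor_sets=survivor_sets, ranks=ranks)


def common_informative(
    ranking_physical: RFERanking,
    ranking_predicted: RFERanking,
    n: int = 300,
) -> np.ndarray:
    """Voxels informative in both rankings: top ``n`` by combined rank.

    The combined rank of a voxel is the worse (max) of its two ranks, which
    enforces joint informativeness; ties are broken by rank sum, then voxel
    index. If ``n`` exceeds the universe, the whole universe is returned
    with a warning.
    """
    if ranking_physical.n_voxels != ranking_predicted.n_voxels:
        raise ValueError("rankings must cover the same voxel universe")
    r1, r2 = ranking_physical.ranks, ranking_predicted.ranks
    combined = np.maximum(r1, r2)
    order = sorted(range(len(r1)), key=lambda i: (combined[i], r1[i] + r2[i], i))
    if n >= len(r1):
        if n > len(r1):
            warnings.warn(f"requested {n} voxels from a universe of {len(r1)}", stacklevel=2)
        return np.asarray(order)
    return np.asarray(order[:n])


def _fit_and_score(train_X, train_y, test_X, test_y, cfg: ClassifierConfig) -> float:
    model = WeightedLinearDecoder(C=cfg.C, cost_weighting=cfg.cost_weighting)
    model.fit(train_X, train_y)
    return float(np.mean(model.predict(test_X) == test_y))


def cross_decode(
    train_patterns: PatternSet,
    test_patterns: PatternSet,
    cfg: ClassifierConfig | None = None,
    *,
    voxel_set: np.ndarray | None = None,
    selection: str | None = None,
    n_voxels: int = 300,
    step_fraction: float = 0.1,
    train_label: str = "expected",
    test_label_source: str = "response",
) -> DecodingResult:
    """Train on stimulus-driven patterns, test on blank-interval patterns.

    ``selection`` controls voxel choice:

    * ``None`` — use ``voxel_set`` as given (or all voxels);
    * ``"physical"`` — RFE on the training (localizer) patterns only, take
      the top ``n_voxels``;
    * ``"common"`` — per held-out test run, RFE on the training patterns
      and RFE on the remaining test-session runs, then the ``n_voxels``
      informative in both (the held-out run is excluded from both the RFE
      and the decoding, avoiding circularity).

    Accuracy is reported per test-session run (equal weight), matching the
    cross-validation folds of the within-task analysis.
    """
    cfg = cfg or ClassifierConfig()
    y_train = train_patterns.label_values(train_label)
    y_test = test_patterns.label_values(test_label_source)
    if train_patterns.X.shape[1] != test_patterns.X.shape[1]:
        raise ValueError("train and test pattern sets cover different voxel universes")

    test_runs = np.unique(test_patterns.run_ids)
    accs, n_test, n_train = [], [], []

    if selection is None:
        voxels = np.arange(train_patterns.X.shape[1]) if voxel_set is None else np.asarray(voxel_set)
        model = WeightedLinearDecoder(C=cfg.C, cost_weighting=cfg.cost_weighting)
        model.fit(train_patterns.X[:, voxels], y_train)
        for run in test_runs:
            mask = test_patterns.run_ids == run
            accs.append(float(np.mean(model.predict(test_patterns.X[mask][:, voxels]) == y_test[mask])))
            n_test.append(int(mask.sum()))
            n_train.append(len(y_train))
    elif selection == "physical":
        ranking = rfe_rank(train_patterns.X, y_train, cfg, step_fraction)
        voxels = ranking.top(n_voxels)
        model = WeightedLinearDecoder(C=cfg.C, cost_weighting=cfg.cost_weighting)
        model.fit(train_patterns.X[:, voxels], y_train)
        for run in test_runs:
            mask = test_patterns.run_ids == run
            accs.append(float(np.mean(model.predict(test_patterns.X[mask][:, voxels]) == y_test[mask])))
            n_test.append(int(mask.sum()))
            n_train.append(len(y_train))
    elif selection == "common":
        ranking_physical = rfe_rank(train_patterns.X, y_train, cfg, step_fraction)
        for run in test_runs:
            held_out = test_patterns.run_ids == run
            ranking_predicted = rfe_rank(
                test_patterns.X[~held_out], y_test[~held_out], cfg, step_fraction
            )
            voxels = common_informative(ranking_physical, ranking_predicted, n_voxels)
            accs.append(_fit_and_score(
                train_patterns.X[:, voxels], y_train,
                test_patterns.X[held_out][:, voxels], y_test[held_out], cfg,
            ))
            n_test.append(int(held_out.sum()))
            n_train.append(len(y_train))
    else:
        raise ValueError(f"unknown selection mode: {selection!r}")

    return DecodingResult(
        np.asarray(accs), list(test_runs), n_test,
        label_source=f"{train_label}->{test_label_source}",
        volume_mode="averaged" if test_patterns.volume is None else f"volume-{test_patterns.volume}",
        n_train_per_fold=n_train,
    )


def loro_with_rfe_selection(
    patterns: PatternSet,
    cfg: ClassifierConfig | None = None,
    *,
    n_voxels: int = 50,
    step_fraction: float = 0.2,
    label_source: str = "response",
    include_test_in_selection: bool = False,
) -> DecodingResult:
    """Leave-one-run-out decoding with RFE-based voxel selection per fold.

    With ``include_test_in_selection=False`` the held-out run is excluded
    from the RFE (the fold-respecting procedure). Setting it to True
    deliberately reintroduces the held-out run into voxel selection — the
    classic double-dipping circularity — which inflates accuracy on null
    data and exists here only as a diagnostic contrast.
    """
    cfg = cfg or ClassifierConfig()
    y = patterns.label_values(label_source)
    runs = np.unique(patterns.run_ids)
    if len(runs) < 2:
        raise ValueError("leave-one-run-out needs at least 2 runs")
    accs, n_test, n_train = [], [], []
    for run in runs:
        test_mask = patterns.run_ids == run
        train_mask = ~test_mask
        sel_mask = np.ones_like(train_mask) if include_test_in_selection else train_mask
        ranking = rfe_rank(patterns.X[sel_mask], y[sel_mask], cfg, step_fraction)
        voxels = ranking.top(n_voxels)
        accs.append(_fit_and_score(
            patterns.X[train_mask][:, voxels], y[train_mask],
            patterns.X[test_mask][:, voxels], y[test_mask], cfg,
        ))
        n_test.append(int(test_mask.sum()))
        n_train.append(int(train_mask.sum()))
    return DecodingResult(
        np.asarray(accs), list(runs), n_test, label_source,
        "averaged" if patterns.volume is None else f"volume-{patterns.volume}",
        n_train_per_fold=n_train,
    )
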