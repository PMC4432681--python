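"""Voxel selection by stimulus-vs-fixation activation contrast.

Voxels entering the pattern classification are those significantly more
activated by gratings than by fixation (one-sided t-test, P < 0.05
uncorrected) in the block-design localizer, ranked by t-value; the top 300
are used, where decoding accuracy has saturated. Voxels flagged as lying at
the stimulus edge are rejected before testing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .decoding import ClassifierConfig, DecodingResult, leave_one_run_out
from .preprocess import (
    HEMODYNAMIC_SHIFT_VOLUMES,
    PatternSet,
    zscore_per_run,
)
from .simulate import Run

logger = logging.getLogger(__name__)

DEFAULT_N_VOXELS = 300
DEFAULT_ALPHA = 0.05


@dataclass
class VoxelStats:
    """Per-voxel activation statistics from the localizer contrast.

    ``rank`` is a permutation of voxel indices by descending t (rank 1 =
    most activated); excluded (edge) voxels are ranked after all eligible
    ones. ``selected`` marks eligible voxels with p below the threshold.
    """

    t: np.ndarray
    p: np.ndarray
    rank: np.ndarray
    selected: np.ndarray
    eligible: np.ndarray
    alpha: float = DEFAULT_ALPHA

    @property
    def n_voxels(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "voxel_id": np.arange(self.n_voxels),
            "t": self.t,
            "p": self.p,
            "rank": self.rank,
            "selected": self.selected,
            "eligible": self.eligible,
        })

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def activation_contrast(
    localizer_runs: list[Run],
    *,
    shift_volumes: int = HEMODYNAMIC_SHIFT_VOLUMES,
    exclude: np.ndarray | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> VoxelStats:
    """Two-sample t contrast of stimulus-block vs fixation-block volumes.

    Each run is z-scored first; stimulus and fixation volumes are taken
    after the hemodynamic shift (fixation windows are clipped at the run
    end). ``exclude`` marks voxels (e.g. stimulus-edge voxels) removed from
    ranking and selection before testing.
    """
    if not localizer_runs:
        raise ValueError("need at least one localizer run")
    stim_samples, fix_samples = [], []
    for run in localizer_runs:
        r = zscore_per_run(run)
        n_block = int(round(15.0 / r.tr))
        stim_vols: list[int] = []
        for _, row in r.trial_table.iterrows():
            v0 = int(round(row["onset"] / r.tr)) + shift_volumes
            stim_vols.extend(range(v0, min(v0 + n_block, r.n_volumes)))
        first_onset = int(round(r.trial_table["onset"].min() / r.tr))
        last_end = int(round((r.trial_table["onset"].max() +
                              r.trial_table["duration"].iloc[-1]) / r.tr))
        fix_vols = [v + shift_volumes for v in range(0, first_onset)]
        fix_vols += [v + shift_volumes for v in range(last_end, r.n_volumes)]
        fix_vols = [v for v in fix_vols if v < r.n_volumes]
        stim_samples.append(r.data[:, stim_vols])
        fix_samples.append(r.data[:, fix_vols])
    stim = np.concatenate(stim_samples, axis=1)
    fix = np.concatenate(fix_samples, axis=1)
    if stim.shape[1] < 2 or fix.shape[1] < 2:
        raise ValueError("each condition needs at least 2 volumes")
    t, p_two = sps.ttest_ind(stim, fix, axis=1)
    p = np.where(t > 0, p_two / 2.0, 1.0 - p_two / 2.0)  # one-sided: stim > fix

    eligible = np.ones(len(t), dtype=bool) if exclude is None else ~np.asarray(exclude, bool)
    # rank eligible voxels by descending t (stable: ties broken by voxel index),
    # excluded voxels after them
    order = sorted(range(len(t)), key=lambda i: (not eligible[i], -t[i], i))
    rank = np.empty(len(t), dtype=int)
    rank[np.asarray(order)] = np.arange(1, len(t) + 1)
    selected = eligible & (p < alpha)
    return VoxelStats(t=t, p=p, rank=rank, selected=selected, eligible=eligible, alpha=alpha)


def select_top(stats: VoxelStats, n: int = DEFAULT_N_VOXELS) -> np.ndarray:
    """Indices of the ``n`` suprathreshold voxels with highest t.

    Ties at the cutoff are broken by voxel index. If fewer than ``n`` voxels
    pass the threshold, all passers are returned with a warning.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    passers = np.flatnonzero(stats.selected)
    order = passers[np.lexsort((passers, -stats.t[passers]))]
    if len(order) < n:
        warnings.warn(
            f"only {len(order)} voxels pass the activation threshold (requested {n})",
            stacklevel=2,
        )
        return order
    return order[:n]


def accuracy_vs_patternsize(
    patterns: PatternSet,
    stats: VoxelStats,
    sizes: list[int],
    cfg: ClassifierConfig | None = None,
    label_source: str = "response",
) -> pd.DataFrame:
    """Decoding accuracy as a function of pattern size.

    Voxels are added in descending-t order among suprathreshold voxels;
    at each size a full leave-one-run-out decoding is run. Accuracy
    saturates once all informative voxels are included.
    """
    if list(sizes) != sorted(sizes):
        raise ValueError("sizes must be ascending")
    ranked = select_top(stats, n=max(int(np.sum(stats.selected)), 1))
    rows = []
    for size in sizes:
        voxels = ranked[: int(size)]
        result: DecodingResult = leave_one_run_out(
            patterns, label_source=label_source, cfg=cfg, voxels=voxels
        )
        rows.append({"pattern_size": int(size), "n_voxels_used": len(voxels),
                     "accuracy": result.mean_accuracy})
    return pd.DataFrame(rows)
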