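"""Run normalization, trial-pattern extraction and motion exclusion.

Each voxel time course is z-scored within run. Trial patterns are taken
from the no-stimulation interval: with TR 1.5 s the blank fully occupies
trial volumes 4-10 (1-based from trial onset); the 3-volume hemodynamic
shift (4.5 s) maps these to BOLD volumes 7-13, and volume 7 is excluded to
avoid spill-over from the preceding sequence, leaving the decoded window
8-13. A conservative window (10-12) additionally drops volumes 8, 9 and 13.

Motion exclusion applies the per-trial thresholds (1 mm translation, 1 deg
rotation, sharp volume-to-volume displacement above 0.5 mm) and drops runs
in which more than half of the trials are excluded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import Run, Session

logger = logging.getLogger(__name__)

HEMODYNAMIC_SHIFT_VOLUMES = 3
DEFAULT_WINDOW = (8, 13)
CONSERVATIVE_WINDOW = (10, 12)


@dataclass
class TrialPattern:
    """Selected-voxel response vector for one trial, with its labels."""

    vector: np.ndarray
    labels: dict
    run_id: int
    trial_id: int
    volumes: tuple[int, int]
    volume: int | None = None  # set when the pattern is a single volume


@dataclass
class PatternSet:
    """Trial patterns stacked into a matrix with a label table.

    ``X`` is (n_trials, n_voxels); ``labels`` has one row per trial with the
    decodable label columns (predicted / expected / cued / correct);
    ``run_ids`` gives the leave-one-run-out grouping.
    """

    X: np.ndarray
    labels: pd.DataFrame
    run_ids: np.ndarray
    volumes: tuple[int, int]
    volume: int | None = None

    @classmethod
    def from_patterns(cls, patterns: list[TrialPattern]) -> "PatternSet":
        if not patterns:
            raise ValueError("no patterns to stack")
        X = np.vstack([p.vector for p in patterns])
        labels = pd.DataFrame([p.labels for p in patterns])
        run_ids = np.asarray([p.run_id for p in patterns])
        return cls(X=X, labels=labels, run_ids=run_ids,
                   volumes=patterns[0].volumes, volume=patterns[0].volume)

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    def label_values(self, source: str) -> np.ndarray:
        """Label vector for a decoding label source.

        ``response`` — the response-implied prediction; ``expected`` — the
        sequence-expected orientation; ``cued`` — the control-task cue.
        """
        column = {"response": "predicted", "expected": "expected", "cued": "cued"}.get(source)
        if column is None:
            raise ValueError(f"unknown label source: {source!r}")
        values = self.labels[column].to_numpy()
        if pd.isna(values).any():
            raise ValueError(f"label source {source!r} undefined for some trials")
        return values.astype(int)

    def subset(self, mask: np.ndarray) -> "PatternSet":
        return PatternSet(self.X[mask], self.labels.loc[mask].reset_index(drop=True),
                          self.run_ids[mask], self.volumes, self.volume)


def zscore_per_run(run: Run) -> Run:
    """Z-score each voxel's time course within the run (mean 0, sd 1).

    Zero-variance voxels cannot be normalized; they are set to all-zeros
    and a warning is emitted (synthetic edge case, not an error).
    """
    if run.n_volumes < 2:
        raise ValueError("need at least 2 volumes to z-score")
    out = run.copy()
    mean = out.data.mean(axis=1, keepdims=True)
    sd = out.data.std(axis=1, keepdims=True)
    flat = (sd < 1e-12).ravel()
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance voxel(s) set to zero", stacklevel=2)
        sd[flat] = 1.0
    out.data = (out.data - mean) / sd
    out.data[flat] = 0.0
    out.meta["zscored"] = True
    return out


def zscore_session(session: Session) -> Session:
    return Session(session.task, session.phase, [zscore_per_run(r) for r in session.runs])


def shift_and_window(
    run: Run,
    shift_volumes: int = HEMODYNAMIC_SHIFT_VOLUMES,
    window: tuple[int, int] = DEFAULT_WINDOW,
    average: bool = True,
) -> list[TrialPattern]:
    """Extract blank-interval patterns for each trial of a run.

    ``window`` is expressed in 1-based trial volumes of the shifted series
    (the default 8-13 corresponds to no-stimulation volumes 5-10 plus the
    ``shift_volumes`` hemodynamic shift). With ``average=True`` one pattern
    per trial (the across-window mean) is returned; otherwise one pattern
    per window volume. Trials whose window exceeds the run are dropped with
    a log entry.
    """
    lo, hi = window
    if lo < 1 or hi < lo:
        raise ValueError("window must be 1-based and non-decreasing")
    if lo <= shift_volumes:
        raise ValueError("window starts before the hemodynamic shift has elapsed")
    patterns: list[TrialPattern] = []
    table = run.trial_table
    retained = table if "excluded" not in table.columns else table[~table["excluded"]]
    for trial_id, row in retained.iterrows():
        onset_vol = int(round(row["onset"] / run.tr))
        cols = onset_vol + np.arange(lo - 1, hi)
        if cols[-1] >= run.n_volumes:
            logger.info("run %s trial %s: window exceeds run length, trial dropped",
                        run.run_id, trial_id)
            continue
        labels = {
            k: row[k]
            for k in ("sequence_id", "expected", "cued", "test", "is_match",
                      "response", "predicted", "correct")
            if k in row.index
        }
        if average:
            patterns.append(TrialPattern(run.data[:, cols].mean(axis=1), labels,
                                         run.run_id, int(trial_id), window))
        else:
            for v, c in zip(range(lo, hi + 1), cols):
                patterns.append(TrialPattern(run.data[:, c].copy(), labels,
                                             run.run_id, int(trial_id), window, volume=v))
    return patterns


def exclude_by_motion(
    session: Session,
    translation_mm: float = 1.0,
    rotation_deg: float = 1.0,
    sharp_mm: float = 0.5,
) -> Session:
    """Apply motion exclusion to every run of a session.

    A trial is excluded when, within its volumes, any translation exceeds
    ``translation_mm``, any rotation exceeds ``rotation_deg``, or any
    volume-to-volume translation change exceeds ``sharp_mm`` ("sharp"
    motion). Runs in which more than 50% of trials are excluded are dropped
    entirely.
    """
    kept_runs: list[Run] = []
    for run in session.runs:
        if run.motion is None:
            raise ValueError(f"run {run.run_id} has no motion trace")
        trans = run.motion[["trans_x", "trans_y", "trans_z"]].to_numpy()
        rot = run.motion[["rot_x", "rot_y", "rot_z"]].to_numpy()
        sharp = np.abs(np.diff(trans, axis=0, prepend=trans[:1]))
        excluded = []
        for _, row in run.trial_table.iterrows():
            v0 = int(round(row["onset"] / run.tr))
            v1 = min(int(np.ceil((row["onset"] + row["duration"]) / run.tr)), run.n_volumes)
            bad = (
                np.any(np.abs(trans[v0:v1]) > translation_mm)
                or np.any(np.abs(rot[v0:v1]) > rotation_deg)
                or np.any(sharp[v0:v1] > sharp_mm)
            )
            excluded.append(bool(bad))
        out = run.copy()
        out.trial_table["excluded"] = excluded
        n_bad = int(np.sum(excluded))
        if n_bad > 0.5 * len(excluded):
            logger.info("run %s dropped: %d/%d trials excluded by motion",
                        run.run_id, n_bad, len(excluded))
            continue
        kept_runs.append(out)
    return Session(session.task, session.phase, kept_runs)


def prepare_patterns(
    session: Session,
    *,
    shift_volumes: int = HEMODYNAMIC_SHIFT_VOLUMES,
    window: tuple[int, int] = DEFAULT_WINDOW,
    average: bool = True,
    apply_motion_exclusion: bool = True,
) -> PatternSet:
    """Full preprocessing pipeline for one session.

    Z-scores each run, applies motion exclusion, and extracts blank-interval
    trial patterns.
    """
    if apply_motion_exclusion:
        session = exclude_by_motion(session)
    if session.n_runs < 2:
        raise ValueError("fewer than 2 runs survived exclusion")
    session = zscore_session(session)
    patterns: list[TrialPattern] = []
    for run in session.runs:
        patterns.extend(shift_and_window(run, shift_volumes, window, average))
    return PatternSet.from_patterns(patterns)


def prepare_patterns_per_volume(
    session: Session,
    *,
    shift_volumes: int = HEMODYNAMIC_SHIFT_VOLUMES,
    window: tuple[int, int] = DEFAULT_WINDOW,
    apply_motion_exclusion: bool = True,
) -> dict[int, PatternSet]:
    """Like :func:`prepare_patterns` but one PatternSet per window volume."""
    if apply_motion_exclusion:
        session = exclude_by_motion(session)
    if session.n_runs < 2:
        raise ValueError("fewer than 2 runs survived exclusion")
    session = zscore_session(session)
    patterns: list[TrialPattern] = []
    for run in session.runs:
        patterns.extend(shift_and_window(run, shift_volumes, window, average=False))
    by_volume: dict[int, list[TrialPattern]] = {}
    for p in patterns:
        by_volume.setdefault(p.volume, []).append(p)
    return {v: PatternSet.from_patterns(ps) for v, ps in sorted(by_volume.items())}


def localizer_block_patterns(
    runs: list[Run],
    shift_volumes: int = HEMODYNAMIC_SHIFT_VOLUMES,
    zscore: bool = True,
) -> PatternSet:
    """Block-averaged stimulus-driven patterns from localizer runs.

    Each 15 s block contributes one pattern: the mean of its 10 volumes
    after the hemodynamic shift, labelled with the block's orientation
    (stored in every label column a decoder may ask for).
    """
    patterns: list[TrialPattern] = []
    for run in runs:
        r = zscore_per_run(run) if zscore else run
        n_block_vols = int(round(15.0 / r.tr))
        for block_id, row in r.trial_table.iterrows():
            v0 = int(round(row["onset"] / r.tr)) + shift_volumes
            cols = np.arange(v0, v0 + n_block_vols)
            if cols[-1] >= r.n_volumes:
                logger.info("localizer run %s block %s window exceeds run; dropped",
                            r.run_id, block_id)
                continue
            o = int(row["orientation"])
            labels = {"expected": o, "predicted": o, "cued": o, "correct": True,
                      "is_match": None, "sequence_id": None, "test": None}
            patterns.append(TrialPattern(r.data[:, cols].mean(axis=1), labels,
                                         r.run_id, int(block_id), (shift_volumes + 1,
                                                                   shift_volumes + n_block_vols)))
    return PatternSet.from_patterns(patterns)
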