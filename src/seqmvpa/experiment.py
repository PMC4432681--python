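"""End-to-end orchestration: simulate -> preprocess -> select -> decode ->
generalize -> permutation -> summary tables.

``run_experiment`` produces a results bundle (pandas tables plus the config
snapshot and seeds) sufficient to regenerate every number it reports. All
randomness derives from a single seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .decoding import ClassifierConfig, DecodingResult, leave_one_run_out
from .generalization import cross_decode
from .preprocess import localizer_block_patterns, prepare_patterns
from .selection import activation_contrast, select_top
from .simulate import ExperimentData, SimulationConfig, simulate_experiment
from .stats import fit_learning_curve, permutation_null

logger = logging.getLogger(__name__)


@dataclass
class ExperimentReport:
    """Results bundle of one simulated participant."""

    decoding: pd.DataFrame
    generalization: pd.DataFrame
    behaviour: pd.DataFrame
    learning_fit: dict
    voxel_selection: dict
    permutation: pd.DataFrame | None
    config: dict
    seed: int | None
    log: list[str] = field(default_factory=list)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.decoding.to_csv(outdir / "decoding.csv", index=False)
        self.generalization.to_csv(outdir / "generalization.csv", index=False)
        self.behaviour.to_csv(outdir / "behaviour.csv", index=False)
        if self.permutation is not None:
            self.permutation.to_csv(outdir / "permutation.csv", index=False)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(
                {
                    "learning_fit": self.learning_fit,
                    "voxel_selection": self.voxel_selection,
                    "config": self.config,
                    "seed": self.seed,
                    "log": self.log,
                },
                fh, indent=2,
            )


def run_experiment(
    cfg: SimulationConfig | None = None,
    seed: int | None = None,
    *,
    clf: ClassifierConfig | None = None,
    n_voxels: int = 300,
    n_permutation: int = 0,
    outdir=None,
    data: ExperimentData | None = None,
) -> ExperimentReport:
    """Run the complete simulated experiment and summarise it.

    Decodes both tasks in both sessions with every applicable label source
    (response-implied and sequence-expected for the prediction task, cued
    for the control task), cross-decodes from localizer patterns, fits the
    behavioural learning curve, and — if ``n_permutation`` > 0 — computes a
    permutation null for the post-training prediction session.
    """
    cfg = cfg or SimulationConfig()
    clf = clf or ClassifierConfig()
    log: list[str] = []
    if data is None:
        data = simulate_experiment(cfg, seed=seed)
    rng = np.random.default_rng(None if seed is None else seed + 1)

    stats = activation_contrast(data.localizer_runs, exclude=data.population.edge_flag)
    voxels = select_top(stats, n=n_voxels)
    log.append(f"voxel selection: {int(stats.selected.sum())} suprathreshold, "
               f"{len(voxels)} used")

    label_sources = {"prediction": ["response", "expected"], "control": ["cued"]}
    decoding_rows = []
    pattern_sets = {}
    for task in ("prediction", "control"):
        for phase in ("pre", "post"):
            session = data.session(task, phase)
            patterns = prepare_patterns(session)
            pattern_sets[(task, phase)] = patterns
            for source in label_sources[task]:
                result: DecodingResult = leave_one_run_out(
                    patterns, label_source=source, cfg=clf, voxels=voxels
                )
                decoding_rows.append({
                    "task": task, "phase": phase, "label_source": source,
                    "accuracy": result.mean_accuracy, "n_folds": result.n_folds,
                    "n_test_per_fold": result.n_test_per_fold[0],
                    "n_train_per_fold": result.n_train_per_fold[0],
                })
    decoding = pd.DataFrame(decoding_rows)

    localizer_patterns = localizer_block_patterns(data.localizer_runs)
    gen_rows = []
    for task in ("prediction", "control"):
        source = "response" if task == "prediction" else "cued"
        for phase in ("pre", "post"):
            result = cross_decode(
                localizer_patterns, pattern_sets[(task, phase)], clf,
                voxel_set=voxels, test_label_source=source,
            )
            gen_rows.append({
                "task": task, "phase": phase, "test_label_source": source,
                "accuracy": result.mean_accuracy, "n_folds": result.n_folds,
            })
    generalization = pd.DataFrame(gen_rows)

    fit = fit_learning_curve(data.training["accuracy"].to_numpy())
    learning_fit = {"k": fit.k, "c": fit.c, "residual_ss": fit.residual_ss,
                    "n_runs": len(data.training)}

    permutation = None
    if n_permutation > 0:
        null = permutation_null(
            pattern_sets[("prediction", "post")], clf, n_iter=n_permutation,
            rng=rng, voxels=voxels,
        )
        observed = decoding.query(
            "task == 'prediction' and phase == 'post' and label_source == 'response'"
        )["accuracy"].iloc[0]
        permutation = pd.DataFrame([{
            "task": "prediction", "phase": "post", "n_iterations": null.n_iterations,
            "null_mean": null.mean, "null_sd": null.sd,
            "percentile_97_5": null.percentile(97.5),
            "observed": observed,
            "significant": null.is_significant(observed),
        }])

    report = ExperimentReport(
        decoding=decoding,
        generalization=generalization,
        behaviour=data.training,
        learning_fit=learning_fit,
        voxel_selection={
            "n_suprathreshold": int(stats.selected.sum()),
            "n_used": int(len(voxels)),
            "n_edge_excluded": int((~stats.eligible).sum()),
        },
        permutation=permutation,
        config=cfg.to_dict(),
        seed=seed,
        log=log,
    )
    if outdir is not None:
        report.save(outdir)
    return report


def simulate_cohort_accuracies(
    n_subjects: int,
    cfg: SimulationConfig | None = None,
    seed: int | None = None,
    *,
    task: str = "prediction",
    label_source: str = "response",
    n_voxels: int = 300,
) -> pd.DataFrame:
    """Pre/post decoding accuracies for a cohort of simulated participants.

    A utility for paired comparisons across simulated subjects; each subject
    gets an independent seed derived from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for subject, child in enumerate(ss.spawn(n_subjects)):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        data = simulate_experiment(cfg, seed=sub_seed)
        stats = activation_contrast(data.localizer_runs, exclude=data.population.edge_flag)
        voxels = select_top(stats, n=n_voxels)
        row = {"subject": subject}
        for phase in ("pre", "post"):
            patterns = prepare_patterns(data.session(task, phase))
            result = leave_one_run_out(patterns, label_source=label_source, voxels=voxels)
            row[phase] = result.mean_accuracy
        rows.append(row)
    return pd.DataFrame(rows)
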