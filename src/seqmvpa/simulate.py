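"""Synthetic voxel-level BOLD generation and behavioural responses.

The generator produces everything the decoding pipeline consumes, with the
statistical structure the analysis presumes:

* a voxel population with orientation preference (a fraction of voxels is
  tuned to leftward or rightward gratings), per-voxel stimulus-on activation
  gain, noise level, and an "edge" flag marking voxels at the stimulus edge
  that selection must reject;
* event-related runs in which grating events drive activation plus
  orientation-selective signal, and — in the prediction task only — the
  no-stimulation blank interval carries a weak reactivation signal toward
  the orientation the simulated participant predicts on that trial;
* a hemodynamic model (pure 3-volume lag shift by default, matching the
  shift used by the analysis; canonical double-gamma convolution available
  for stress-testing), i.i.d. Gaussian voxel noise, and motion traces with
  occasional spikes;
* behavioural responses whose accuracy follows the logarithmic learning law
  p(correct) = clamp(k*log(run) + c, 0.5, 1) across cumulative training runs.

Learning is a generator-controlled truth: the reactivation gain before vs
after training is configurable, so every downstream claim (decoding above
chance, pre/post differences, task specificity) can be tested against known
ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import (
    RunSchedule,
    TrialSchedule,
    builtin_sequences,
    make_localizer_run,
    make_scan_run,
    make_training_run,
    other_orientation,
)

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


@dataclass
class VoxelPopulation:
    """Per-voxel tuning, gain and noise parameters of the simulated ROI.

    ``preference`` holds orientation codes (1/2) for tuned voxels and 0 for
    untuned ones. ``reactivation_preference`` defaults to ``preference``
    (predictions reactivate the same population code as stimuli); setting it
    independently emulates a prediction signal carried by a different code,
    which cross-decoding should then fail to read.
    """

    preference: np.ndarray
    selectivity_amplitude: np.ndarray
    activation_gain: np.ndarray
    noise_sd: np.ndarray
    edge_flag: np.ndarray
    reactivation_preference: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_voxels < 1:
            raise ValueError("population needs at least one voxel")
        if np.any(self.selectivity_amplitude < 0) or np.any(self.activation_gain < 0):
            raise ValueError("amplitudes and gains must be non-negative")
        if np.any(self.noise_sd <= 0):
            raise ValueError("noise_sd must be positive")

    @property
    def n_voxels(self) -> int:
        return len(self.preference)

    def effective_reactivation_preference(self) -> np.ndarray:
        if self.reactivation_preference is None:
            return self.preference
        return self.reactivation_preference

    def with_independent_reactivation(self, rng: np.random.Generator) -> "VoxelPopulation":
        """Copy with reactivation tuning re-drawn independently of stimulus tuning.

        Any single redraw retains a chance-level overlap with the stimulus
        code (zero in expectation, fluctuating like 1/sqrt(n_tuned)).
        """
        pref = self.preference.copy()
        tuned = pref > 0
        new = np.zeros_like(pref)
        new[tuned] = rng.integers(1, 3, size=int(tuned.sum()))
        return dataclasses.replace(self, reactivation_preference=new)

    def with_orthogonal_reactivation(self, rng: np.random.Generator) -> "VoxelPopulation":
        """Copy whose reactivation code has zero net overlap with the stimulus code.

        Within each stimulus-preference group the reactivation preferences
        are split exactly half/half, so a stimulus-trained linear readout
        carries no expected reactivation signal (exact when amplitudes are
        homogeneous).
        """
        new = np.zeros_like(self.preference)
        for o in (1, 2):
            idx = rng.permutation(np.flatnonzero(self.preference == o))
            half = len(idx) // 2
            new[idx[:half]] = 1
            new[idx[half:]] = 2
        return dataclasses.replace(self, reactivation_preference=new)


def make_voxel_population(
    n_voxels: int,
    frac_selective: float,
    amplitude: float | np.ndarray = 1.0,
    noise_sd: float | np.ndarray = 1.0,
    rng: np.random.Generator | None = None,
    *,
    activation_gain: float | np.ndarray = 1.0,
    amplitude_jitter: float = 0.0,
    frac_edge: float = 0.0,
) -> VoxelPopulation:
    """Draw a voxel population.

    Each voxel is selective with probability ``frac_selective``; selective
    voxels prefer leftward or rightward orientations with equal probability.
    ``amplitude_jitter`` adds lognormal spread (sd of log) around the mean
    selectivity amplitude. Edge voxels (probability ``frac_edge``) respond
    to stimulation but carry no orientation tuning.
    """
    if n_voxels < 1:
        raise ValueError("n_voxels must be positive")
    if not 0.0 <= frac_selective <= 1.0:
        raise ValueError("frac_selective must lie in [0, 1]")
    if np.any(np.asarray(noise_sd) <= 0):
        raise ValueError("noise_sd must be positive")
    rng = rng or np.random.default_rng()
    selective = rng.random(n_voxels) < frac_selective
    preference = np.where(selective, rng.integers(1, 3, size=n_voxels), 0)
    edge = rng.random(n_voxels) < frac_edge
    preference[edge] = 0  # edge voxels are activated but untuned
    amp = np.broadcast_to(np.asarray(amplitude, dtype=float), (n_voxels,)).copy()
    if amplitude_jitter > 0:
        amp *= np.exp(rng.normal(0.0, amplitude_jitter, size=n_voxels))
    amp[preference == 0] = 0.0
    return VoxelPopulation(
        preference=preference,
        selectivity_amplitude=amp,
        activation_gain=np.broadcast_to(np.asarray(activation_gain, dtype=float), (n_voxels,)).copy(),
        noise_sd=np.broadcast_to(np.asarray(noise_sd, dtype=float), (n_voxels,)).copy(),
        edge_flag=edge,
    )


@dataclass
class SimulationConfig:
    """All tunable parameters of the simulated experiment.

    Gains are expressed in units of voxel noise SD (default noise_sd = 1).
    ``reactivation_gain_pre/post`` set the blank-interval signal strength
    toward the participant's per-trial prediction before/after training;
    ``cued_gain`` is the analogous (default zero) memory-trace signal in the
    control task, identical pre and post.
    """

    tr: float = 1.5
    # scan structure
    n_runs_per_session: int = 7
    n_trials_per_run: int = 12
    n_localizer_runs: int = 2
    # voxel population
    n_voxels: int = 400
    frac_selective: float = 0.5
    frac_edge: float = 0.1
    amplitude: float = 1.0
    amplitude_jitter: float = 0.25
    activation_gain: float = 1.0
    noise_sd: float = 1.0
    # signal gains
    stim_gain: float = 1.0
    reactivation_gain_pre: float = 0.02
    reactivation_gain_post: float = 0.15
    cued_gain: float = 0.0
    baseline: float = 0.0
    # hemodynamics
    hemodynamic: str = "lag"  # "lag" (pure shift) or "hrf" (double-gamma convolution)
    lag_volumes: int = 3
    # motion
    motion_sd: float = 0.03
    rotation_sd: float = 0.03
    motion_spike_prob: float = 0.01
    motion_spike_mm: float = 1.3
    # behaviour: p(correct) = clamp(k*log(run) + c, 0.5, 1)
    k: float = 0.1
    c: float = 0.55
    control_accuracy: float = 0.9
    n_training_sessions: int = 4
    runs_per_training_session: int = 4
    trials_per_training_run: int = 40
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("stim_gain", "reactivation_gain_pre", "reactivation_gain_post", "cued_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.reactivation_gain_post < self.reactivation_gain_pre:
            raise ValueError("reactivation_gain_post must be >= reactivation_gain_pre "
                             "when simulating learning")
        if self.hemodynamic not in ("lag", "hrf"):
            raise ValueError("hemodynamic model must be 'lag' or 'hrf'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)


@dataclass
class ParticipantState:
    """The simulated participant at one point in training.

    ``p_correct`` is the probability the internal prediction (or held cue)
    matches the true expected orientation; ``reactivation_gain`` scales the
    blank-interval signal toward that internal prediction.
    """

    p_correct: float = 0.5
    reactivation_gain: float = 0.0
    cued_gain: float = 0.0


@dataclass
class Run:
    """One simulated scan run: voxel x volume BOLD plus trial table and motion."""

    data: np.ndarray  # (n_voxels, n_volumes)
    tr: float
    task: str
    trial_table: pd.DataFrame
    motion: pd.DataFrame | None = None
    run_id: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "Run":
        return Run(self.data.copy(), self.tr, self.task, self.trial_table.copy(),
                   None if self.motion is None else self.motion.copy(),
                   self.run_id, dict(self.meta))

    def to_nifti(self, path) -> None:
        """Write as a 4-D NIfTI (voxels laid out along the first axis)."""
        import nibabel as nib

        img = nib.Nifti1Image(
            self.data.reshape(self.n_voxels, 1, 1, self.n_volumes).astype(np.float32),
            affine=np.eye(4),
        )
        img.header.set_zooms((1.0, 1.0, 1.0, self.tr))
        nib.save(img, str(path))

    def save(self, path) -> None:
        """Compact binary matrix + JSON-compatible sidecars (for tooling/tests)."""
        path = Path(path)
        motion = None if self.motion is None else self.motion.to_numpy()
        np.savez(
            path,
            data=self.data,
            tr=self.tr,
            task=self.task,
            run_id=self.run_id,
            trial_table=self.trial_table.to_json(orient="table"),
            motion=motion if motion is not None else np.zeros((0, 6)),
            has_motion=self.motion is not None,
            meta=json.dumps(self.meta),
        )

    @classmethod
    def load(cls, path) -> "Run":
        with np.load(path, allow_pickle=False) as z:
            import io
            table = pd.read_json(io.StringIO(str(z["trial_table"])), orient="table")
            motion = None
            if bool(z["has_motion"]):
                motion = pd.DataFrame(z["motion"], columns=MOTION_COLUMNS)
            return cls(
                data=z["data"],
                tr=float(z["tr"]),
                task=str(z["task"]),
                trial_table=table,
                motion=motion,
                run_id=int(z["run_id"]),
                meta=json.loads(str(z["meta"])),
            )


@dataclass
class Session:
    """A set of runs of one task acquired in one scan session (pre or post)."""

    task: str
    phase: str  # "pre" | "post"
    runs: list[Run]

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def copy(self) -> "Session":
        return Session(self.task, self.phase, [r.copy() for r in self.runs])


def double_gamma_hrf(tr: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at TR."""
    from scipy.stats import gamma as gamma_dist

    t = np.arange(0, duration, tr)
    peak = gamma_dist.pdf(t, 6)
    undershoot = gamma_dist.pdf(t, 16) / 6.0
    h = peak - undershoot
    return h / h.max()


def _occupancy(onset: float, duration: float, tr: float, n_volumes: int) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of each volume covered by [onset, onset+duration).

    Volume v (0-based) spans [v*TR, (v+1)*TR); an event contributes to a
    volume in proportion to their overlap.
    """
    v0 = max(int(np.floor(onset / tr)), 0)
    v1 = min(int(np.ceil((onset + duration) / tr)), n_volumes)
    vols = np.arange(v0, v1)
    starts = np.maximum(vols * tr, onset)
    ends = np.minimum((vols + 1) * tr, onset + duration)
    return vols, np.clip(ends - starts, 0.0, tr) / tr


def _simulate_behaviour_for_trials(
    labels: list[dict], p_correct: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw the internal prediction and the match/nonmatch response per trial.

    The internal prediction equals the true expected (or cued) orientation
    with probability ``p_correct``; the participant responds "match" iff the
    test grating matches their internal prediction, so the response-implied
    prediction (match -> test orientation, nonmatch -> the other one) always
    recovers the internal prediction.
    """
    rows = []
    for lab in labels:
        truth = lab["expected"] if lab["expected"] is not None else lab["cued"]
        internal = truth if rng.random() < p_correct else other_orientation(truth)
        response = "match" if lab["test"] == internal else "nonmatch"
        implied = lab["test"] if response == "match" else other_orientation(lab["test"])
        rows.append({
            "sequence_id": lab.get("sequence_id"),
            "expected": lab["expected"],
            "cued": lab["cued"],
            "test": lab["test"],
            "is_match": lab["is_match"],
            "response": response,
            "predicted": implied,
            "correct": internal == truth,
        })
    return pd.DataFrame(rows)


def simulate_run(
    schedule: RunSchedule,
    pop: VoxelPopulation,
    cfg: SimulationConfig,
    state: ParticipantState | None = None,
    rng: np.random.Generator | None = None,
    run_id: int = 0,
) -> Run:
    """Simulate one BOLD run from a schedule.

    Neural drive per volume is baseline plus, during grating/test events,
    ``stim_gain * (activation_gain + selectivity toward the on-screen
    orientation)`` and, during the blank interval, ``reactivation_gain *
    selectivity toward the trial's internally predicted orientation``
    (prediction task, structured sequences only; control blanks use
    ``cued_gain`` toward the held cue). Drive is mapped to BOLD by the
    configured hemodynamic model, then i.i.d. Gaussian noise is added.
    Events are binned to volumes by fractional occupancy.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    state = state or ParticipantState()
    n_vox = pop.n_voxels
    n_volumes = int(np.ceil(schedule.duration / cfg.tr))
    drive = np.full((n_vox, n_volumes), float(cfg.baseline))

    stim_tuning = {
        o: cfg.stim_gain * (pop.activation_gain + pop.selectivity_amplitude * (pop.preference == o))
        for o in (1, 2)
    }
    react_pref = pop.effective_reactivation_preference()
    react_tuning = {o: pop.selectivity_amplitude * (react_pref == o) for o in (1, 2)}

    is_localizer = schedule.task == "localizer"
    if is_localizer:
        trial_table = pd.DataFrame({
            "onset": schedule.trial_onsets,
            "duration": [t.duration for t in schedule.trials],
            "orientation": [t.labels["orientation"] for t in schedule.trials],
        })
    else:
        behaviour = _simulate_behaviour_for_trials(
            [t.labels for t in schedule.trials], state.p_correct, rng
        )
        trial_table = behaviour.assign(
            onset=schedule.trial_onsets,
            duration=[t.duration for t in schedule.trials],
        )

    for i, (trial, onset) in enumerate(zip(schedule.trials, schedule.trial_onsets)):
        for ev in trial.events:
            vols, frac = _occupancy(onset + ev.onset, ev.duration, cfg.tr, n_volumes)
            if len(vols) == 0:
                continue
            if ev.kind in ("grating", "test") and ev.orientation is not None:
                drive[:, vols] += np.outer(stim_tuning[ev.orientation], frac)
            elif ev.kind == "blank" and not is_localizer:
                if schedule.task == "prediction" and trial.labels.get("sequence_id") is not None:
                    target = int(trial_table.loc[i, "predicted"])
                    gain = state.reactivation_gain
                elif schedule.task == "control":
                    # held orientation = response-implied prediction for control trials
                    target = int(trial_table.loc[i, "predicted"])
                    gain = state.cued_gain
                else:
                    continue
                if gain > 0:
                    drive[:, vols] += gain * np.outer(react_tuning[target], frac)

    if cfg.hemodynamic == "lag":
        bold = np.zeros_like(drive)
        lag = int(cfg.lag_volumes)
        bold[:, lag:] = drive[:, : n_volumes - lag]
        bold[:, :lag] = cfg.baseline
    else:
        h = double_gamma_hrf(cfg.tr)
        bold = np.apply_along_axis(lambda x: np.convolve(x, h)[:n_volumes], 1, drive)

    bold = bold + rng.normal(0.0, 1.0, size=bold.shape) * pop.noise_sd[:, None]

    motion = _simulate_motion(schedule, cfg, rng, n_volumes)
    return Run(data=bold, tr=cfg.tr, task=schedule.task, trial_table=trial_table,
               motion=motion, run_id=run_id,
               meta={"hemodynamic": cfg.hemodynamic, "lag_volumes": cfg.lag_volumes})


def _simulate_motion(
    schedule: RunSchedule, cfg: SimulationConfig, rng: np.random.Generator, n_volumes: int
) -> pd.DataFrame:
    """Per-volume translation (mm) and rotation (deg) with occasional spikes."""
    trace = np.empty((n_volumes, 6))
    trace[:, :3] = rng.normal(0.0, cfg.motion_sd, size=(n_volumes, 3))
    trace[:, 3:] = rng.normal(0.0, cfg.rotation_sd, size=(n_volumes, 3))
    for onset, trial in zip(schedule.trial_onsets, schedule.trials):
        if rng.random() < cfg.motion_spike_prob:
            v0 = int(onset / cfg.tr)
            v1 = min(int((onset + trial.duration) / cfg.tr), n_volumes - 1)
            spike_at = int(rng.integers(v0, v1 + 1))
            axis = int(rng.integers(0, 3))
            trace[spike_at, axis] += cfg.motion_spike_mm * (1 if rng.random() < 0.5 else -1)
    return pd.DataFrame(trace, columns=MOTION_COLUMNS)


def learning_accuracy(run_index: int, cfg: SimulationConfig) -> float:
    """True p(correct) at cumulative training run ``run_index`` (1-based)."""
    if run_index < 1:
        raise ValueError("run_index is 1-based")
    return float(np.clip(cfg.k * np.log(run_index) + cfg.c, 0.5, 1.0))


def simulate_responses(
    schedule: list[TrialSchedule],
    run_index: int,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-trial responses for one training run at learning stage ``run_index``.

    Correctness is Bernoulli with p = clamp(k*log(run_index) + c, 0.5, 1);
    the response-implied prediction is derivable from (response, test
    orientation): a "match" response to test orientation o implies the
    participant predicted o, a "nonmatch" response implies the other one.
    """
    p = learning_accuracy(run_index, cfg)
    table = _simulate_behaviour_for_trials([t.labels for t in schedule], p, rng)
    table.insert(0, "run_index", run_index)
    table["p_true"] = p
    return table


def simulate_training(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """All behavioural training sessions; one row per run with observed accuracy."""
    sequences = builtin_sequences()
    rows = []
    run_global = 0
    for session in range(1, cfg.n_training_sessions + 1):
        for run in range(1, cfg.runs_per_training_session + 1):
            run_global += 1
            trials = make_training_run(sequences, cfg.trials_per_training_run, rng)
            responses = simulate_responses(trials, run_global, cfg, rng)
            rows.append({
                "session": session,
                "run": run,
                "run_global": run_global,
                "n_trials": len(trials),
                "accuracy": float(responses["correct"].mean()),
                "p_true": float(responses["p_true"].iloc[0]),
            })
    return pd.DataFrame(rows)


@dataclass
class ExperimentData:
    """Everything one simulated participant produces."""

    population: VoxelPopulation
    pre_prediction: Session
    post_prediction: Session
    pre_control: Session
    post_control: Session
    localizer_runs: list[Run]
    training: pd.DataFrame
    config: SimulationConfig

    def session(self, task: str, phase: str) -> Session:
        return getattr(self, f"{phase}_{task}")


def simulate_session(
    task: str,
    phase: str,
    pop: VoxelPopulation,
    cfg: SimulationConfig,
    state: ParticipantState,
    rng: np.random.Generator,
) -> Session:
    """Simulate all runs of one task in one scan session.

    Control runs are paired trial-by-trial to freshly drawn prediction-run
    schedules so that the cued orientation matches the expected orientation
    of the paired prediction trial.
    """
    runs = []
    for r in range(cfg.n_runs_per_session):
        if task == "prediction":
            schedule = make_scan_run("prediction", rng, n_trials=cfg.n_trials_per_run)
        elif task == "control":
            paired = make_scan_run("prediction", rng, n_trials=cfg.n_trials_per_run)
            schedule = make_scan_run("control", rng, n_trials=cfg.n_trials_per_run,
                                     paired_to=paired)
        else:
            raise ValueError(f"invalid task: {task!r}")
        runs.append(simulate_run(schedule, pop, cfg, state, rng, run_id=r))
    return Session(task=task, phase=phase, runs=runs)


def simulate_experiment(
    cfg: SimulationConfig | None = None,
    seed: int | None = None,
) -> ExperimentData:
    """Simulate one participant: training, pre/post scans of both tasks, localizer.

    Pre-training prediction accuracy is the learning curve at run 1 (= c);
    post-training accuracy is the curve at the last cumulative training run.
    Control-task accuracy is high and constant across sessions, and the
    control blank interval carries no structured-sequence reactivation
    (``cued_gain``, default 0, identical pre and post).
    """
    cfg = cfg or SimulationConfig()
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    pop = make_voxel_population(
        cfg.n_voxels, cfg.frac_selective, cfg.amplitude, cfg.noise_sd, rng,
        activation_gain=cfg.activation_gain, amplitude_jitter=cfg.amplitude_jitter,
        frac_edge=cfg.frac_edge,
    )
    training = simulate_training(cfg, rng)
    n_runs_total = cfg.n_training_sessions * cfg.runs_per_training_session
    p_pre = learning_accuracy(1, cfg)
    p_post = learning_accuracy(n_runs_total, cfg)

    pre_state = ParticipantState(p_pre, cfg.reactivation_gain_pre, cfg.cued_gain)
    post_state = ParticipantState(p_post, cfg.reactivation_gain_post, cfg.cued_gain)
    control_pre = ParticipantState(cfg.control_accuracy, 0.0, cfg.cued_gain)
    control_post = ParticipantState(cfg.control_accuracy, 0.0, cfg.cued_gain)

    data = ExperimentData(
        population=pop,
        pre_prediction=simulate_session("prediction", "pre", pop, cfg, pre_state, rng),
        post_prediction=simulate_session("prediction", "post", pop, cfg, post_state, rng),
        pre_control=simulate_session("control", "pre", pop, cfg, control_pre, rng),
        post_control=simulate_session("control", "post", pop, cfg, control_post, rng),
        localizer_runs=[
            simulate_run(make_localizer_run(rng), pop, cfg, None, rng, run_id=r)
            for r in range(cfg.n_localizer_runs)
        ],
        training=training,
        config=cfg,
    )
    return data
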