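"""Experimental design: orientation sequences, trial schedules, and design validation.

The experiment uses two grating orientations, coded ``1`` (leftward, 135°)
and ``2`` (rightward, 45°). Four deterministic 8-item sequences are used;
each sequence implicitly predicts the orientation of the item at the ninth
temporal position (the first item of a repeat). The four sequences are
counterbalanced so that decoding the predicted orientation cannot be driven
by the specific orientations at individual temporal positions:

* A and B share their last three items (so do A' and B');
* A'/B' are the orientation-swapped versions of A/B;
* A and A' share structure but predict opposite orientations;
* A and B' differ in structure but predict the same orientation.

Three timed designs are built here:

* event-related scan trials (28.5 s) for the prediction and control tasks,
* behavioural training trials (two sequence repeats, 16 gratings),
* a block-design orientation localizer (15 s blocks).

All schedules are expressed in seconds from run start and serialize to
BIDS-style events tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ORIENT_LEFT = 1  # 135 degrees
ORIENT_RIGHT = 2  # 45 degrees

#: durations (s) of the event-related scan trial components
GRATING_ON = 0.25
GRATING_ISI = 0.2
BLANK_PREDICTION = 11.6
CUE_LETTER = 0.25
BLANK_CONTROL = 11.35
CUE_TEST = 0.5
TEST_ON = 0.5
RESPONSE_WINDOW = 2.0
TRIAL_ITI = 10.5
SCAN_TRIAL_DURATION = 28.5
RUN_FIXATION_BLOCK = 15.0

#: behavioural training trial components
TRAIN_GRATING_ON = 0.3
TRAIN_GRATING_ISI = 0.3
TRAIN_PRECUE = 1.0
TRAIN_POSTTEST_FIX = 1.7  # with the 0.3 s test this spans the 2 s response window
TRAIN_END_CROSS = 1.0
TRAIN_TRIAL_DURATION = 13.0

#: localizer block structure
LOC_BLOCK_DURATION = 15.0
LOC_GRATINGS_PER_BLOCK = 30
LOC_BLOCKS_PER_ORIENTATION = 10


def other_orientation(code: int) -> int:
    """Return the complementary orientation code (1 <-> 2)."""
    if code not in (ORIENT_LEFT, ORIENT_RIGHT):
        raise ValueError(f"invalid orientation code: {code!r}")
    return 3 - code


@dataclass(frozen=True)
class SequenceSpec:
    """One 8-item orientation sequence and the orientation it predicts.

    ``predicted`` is the orientation expected at the ninth temporal
    position, i.e. the first item of a sequence repeat.
    """

    id: str
    items: tuple[int, ...]
    predicted: int

    def __post_init__(self) -> None:
        if len(self.items) != 8:
            raise ValueError("a sequence has exactly 8 items")
        if any(i not in (ORIENT_LEFT, ORIENT_RIGHT) for i in self.items):
            raise ValueError("items must be orientation codes 1 or 2")
        if self.predicted not in (ORIENT_LEFT, ORIENT_RIGHT):
            raise ValueError("predicted must be an orientation code")

    def swapped(self, new_id: str | None = None) -> "SequenceSpec":
        """The orientation-swapped version (same structure, opposite codes)."""
        return SequenceSpec(
            id=new_id or f"{self.id}_swapped",
            items=tuple(other_orientation(i) for i in self.items),
            predicted=other_orientation(self.predicted),
        )


def builtin_sequences() -> list[SequenceSpec]:
    """The four counterbalanced sequences used throughout the experiment."""
    a = SequenceSpec("A", (2, 1, 2, 1, 1, 2, 1, 2), predicted=ORIENT_RIGHT)
    b = SequenceSpec("B", (1, 1, 2, 1, 2, 2, 1, 2), predicted=ORIENT_LEFT)
    return [a, b, a.swapped("Aprime"), b.swapped("Bprime")]


@dataclass(frozen=True)
class Event:
    kind: str
    onset: float
    duration: float
    orientation: int | None = None

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass
class TrialSchedule:
    """Timed event list for a single trial (or localizer block).

    Onsets are in seconds relative to trial start. ``labels`` carries the
    per-trial decoding labels (expected/test/cued orientation, match flag,
    sequence identity).
    """

    task: str
    events: list[Event]
    labels: dict
    duration: float

    def __post_init__(self) -> None:
        onsets = [e.onset for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")
        for a, b in zip(self.events, self.events[1:]):
            if b.onset < a.offset - 1e-9:
                raise ValueError(f"events overlap: {a} / {b}")
        if self.events and self.events[-1].offset > self.duration + 1e-9:
            raise ValueError("events exceed declared trial duration")


@dataclass
class RunSchedule:
    """A full run: lead/trail fixation blocks around a list of trials."""

    task: str
    trials: list[TrialSchedule]
    lead_fixation: float = RUN_FIXATION_BLOCK
    trail_fixation: float = RUN_FIXATION_BLOCK

    @property
    def trial_onsets(self) -> np.ndarray:
        onsets = []
        t = self.lead_fixation
        for trial in self.trials:
            onsets.append(t)
            t += trial.duration
        return np.asarray(onsets)

    @property
    def duration(self) -> float:
        return self.lead_fixation + sum(t.duration for t in self.trials) + self.trail_fixation

    def events_table(self) -> pd.DataFrame:
        """Flatten to a BIDS-style events table with absolute onsets."""
        rows = [
            {"onset": 0.0, "duration": self.lead_fixation, "trial_type": "fixation_block",
             "orientation": None, "sequence_id": None, "trial": None, "is_match": None}
        ]
        for i, (trial, onset) in enumerate(zip(self.trials, self.trial_onsets)):
            for ev in trial.events:
                rows.append({
                    "onset": round(onset + ev.onset, 6),
                    "duration": ev.duration,
                    "trial_type": ev.kind,
                    "orientation": ev.orientation,
                    "sequence_id": trial.labels.get("sequence_id"),
                    "trial": i,
                    "is_match": trial.labels.get("is_match"),
                })
        rows.append({"onset": round(self.duration - self.trail_fixation, 6),
                     "duration": self.trail_fixation, "trial_type": "fixation_block",
                     "orientation": None, "sequence_id": None, "trial": None,
                     "is_match": None})
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.events_table().to_csv(path, sep="\t", index=False, na_rep="n/a")

    def to_json(self, path) -> None:
        table = self.events_table()
        payload = {
            "task": self.task,
            "duration": self.duration,
            "events": json.loads(table.to_json(orient="records")),
            "labels": [t.labels for t in self.trials],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {obj!r}")


def _sequence_part(items: Sequence[int]) -> list[Event]:
    """The 8-grating stream: 0.25 s on, 0.2 s off after each of the first 7.

    The fixation after the eighth grating is absorbed into the subsequent
    blank interval, which reconciles the per-component durations with the
    28.5 s trial length (8x0.25 + 7x0.2 = 3.4 s of stimulation).
    """
    return [
        Event("grating", i * (GRATING_ON + GRATING_ISI), GRATING_ON, orientation=o)
        for i, o in enumerate(items)
    ]


def make_scan_trial(
    task: str,
    seq: SequenceSpec | Sequence[int] | None,
    rng: np.random.Generator,
    is_match: bool,
    *,
    first_item: int | None = None,
    cued: int | None = None,
) -> TrialSchedule:
    """Build one 28.5 s event-related scan trial.

    Prediction task: ``seq`` is a :class:`SequenceSpec`; the first grating's
    orientation is randomized (pass ``first_item`` for exact run-level
    balance) while the remaining seven follow the sequence; the test grating
    matches the sequence-predicted orientation iff ``is_match``.

    Control task: ``seq`` is an explicit item list or ``None`` (a random
    order of four leftward and four rightward gratings is drawn); an "R"/"L"
    letter cue follows the sequence and the test grating matches the cued
    orientation iff ``is_match``. Pass ``cued`` to pair the cue with a
    prediction trial's expected orientation.
    """
    if task == "prediction":
        if not isinstance(seq, SequenceSpec):
            raise ValueError("prediction trials need a SequenceSpec")
        first = first_item if first_item is not None else int(rng.integers(1, 3))
        items = (first,) + tuple(seq.items[1:])
        expected = seq.predicted
        events = _sequence_part(items)
        t = events[-1].offset  # 3.4 s
        events.append(Event("blank", t, BLANK_PREDICTION))
        t += BLANK_PREDICTION
        labels = {
            "expected": expected,
            "cued": None,
            "sequence_id": seq.id,
            "first_item": first,
        }
    elif task == "control":
        if isinstance(seq, SequenceSpec):
            raise ValueError("control trials use a random item list, not a SequenceSpec")
        if seq is None:
            items = tuple(rng.permutation([ORIENT_LEFT] * 4 + [ORIENT_RIGHT] * 4).tolist())
        else:
            items = tuple(int(i) for i in seq)
        cue = cued if cued is not None else int(rng.integers(1, 3))
        expected = cue
        events = _sequence_part(items)
        t = events[-1].offset
        events.append(Event("letter_cue", t, CUE_LETTER, orientation=cue))
        t += CUE_LETTER
        events.append(Event("blank", t, BLANK_CONTROL))
        t += BLANK_CONTROL
        labels = {"expected": None, "cued": cue, "sequence_id": None, "first_item": items[0]}
    else:
        raise ValueError(f"invalid task: {task!r}")

    if expected is None:
        raise ValueError("match flag requested but no expected orientation defined")
    test = expected if is_match else other_orientation(expected)
    events.append(Event("cue", t, CUE_TEST))
    t += CUE_TEST
    events.append(Event("test", t, TEST_ON, orientation=test))
    t += TEST_ON
    events.append(Event("response", t, RESPONSE_WINDOW))
    t += RESPONSE_WINDOW
    events.append(Event("iti", t, TRIAL_ITI))
    labels.update({"test": test, "is_match": bool(is_match)})
    return TrialSchedule(task=task, events=events, labels=labels,
                         duration=SCAN_TRIAL_DURATION)


def _balanced_flags(n: int, rng: np.random.Generator) -> np.ndarray:
    """Exactly n/2 True flags in random order."""
    flags = np.zeros(n, dtype=bool)
    flags[: n // 2] = True
    return rng.permutation(flags)


def make_scan_run(
    task: str,
    rng: np.random.Generator,
    *,
    sequences: list[SequenceSpec] | None = None,
    n_trials: int = 12,
    paired_to: "RunSchedule | None" = None,
) -> RunSchedule:
    """Build a full event-related run: 15 s fixation + trials + 15 s fixation.

    Prediction runs allocate the four sequences equally across trials with a
    50% match rate and an exactly balanced randomized first item. Control
    runs draw random orientation-balanced sequences; when ``paired_to`` is a
    prediction run, each control trial's cue reproduces the paired trial's
    expected orientation.
    """
    if task == "prediction":
        sequences = sequences or builtin_sequences()
        if n_trials % len(sequences):
            raise ValueError("n_trials must divide evenly across sequences")
        order = rng.permutation(np.repeat(np.arange(len(sequences)), n_trials // len(sequences)))
        matches = _balanced_flags(n_trials, rng)
        firsts = np.where(_balanced_flags(n_trials, rng), ORIENT_LEFT, ORIENT_RIGHT)
        trials = [
            make_scan_trial("prediction", sequences[k], rng, bool(m), first_item=int(f))
            for k, m, f in zip(order, matches, firsts)
        ]
    elif task == "control":
        matches = _balanced_flags(n_trials, rng)
        if paired_to is not None:
            if len(paired_to.trials) != n_trials:
                raise ValueError("paired run must have the same number of trials")
            cues = [t.labels["expected"] for t in paired_to.trials]
        else:
            cues = np.where(_balanced_flags(n_trials, rng), ORIENT_LEFT, ORIENT_RIGHT).tolist()
        trials = [
            make_scan_trial("control", None, rng, bool(m), cued=int(c))
            for m, c in zip(matches, cues)
        ]
    else:
        raise ValueError(f"invalid task: {task!r}")
    return RunSchedule(task=task, trials=trials)


def make_training_trial(
    seq: SequenceSpec,
    test_position: int,
    is_match: bool,
) -> TrialSchedule:
    """One behavioural training trial: two sequence repeats (16 gratings).

    The test grating replaces the stimulus at ``test_position`` (1-based,
    within the second repeat, restricted to positions 1-5 because the last
    three items are shared across sequences). It is preceded by a 1 s red-dot
    cue and followed by a 1.7 s fixation, spanning the 2 s response window;
    the remaining gratings then complete the stream so every trial lasts
    exactly 13 s. The concurrent red circle around the test grating is not a
    separate timed event.
    """
    if not 1 <= test_position <= 5:
        raise ValueError("test position must lie in 1..5 (not the last three positions)")
    expected = seq.items[test_position - 1]
    test = expected if is_match else other_orientation(expected)
    test_index = 8 + test_position - 1  # 0-based among the 16 stimuli
    events: list[Event] = []
    t = 0.0
    for k in range(16):
        if k == test_index:
            events.append(Event("precue", t, TRAIN_PRECUE))
            t += TRAIN_PRECUE
            events.append(Event("test", t, TRAIN_GRATING_ON, orientation=test))
            t += TRAIN_GRATING_ON
            events.append(Event("response", t, TRAIN_POSTTEST_FIX))
            t += TRAIN_POSTTEST_FIX
        else:
            events.append(Event("grating", t, TRAIN_GRATING_ON, orientation=seq.items[k % 8]))
            t += TRAIN_GRATING_ON + TRAIN_GRATING_ISI
    events.append(Event("end_cross", t, TRAIN_END_CROSS))
    labels = {
        "sequence_id": seq.id,
        "test_position": test_position,
        "expected": expected,
        "test": test,
        "is_match": bool(is_match),
        "cued": None,
    }
    return TrialSchedule(task="training", events=events, labels=labels,
                         duration=TRAIN_TRIAL_DURATION)


def make_training_run(
    sequences: list[SequenceSpec],
    n_trials: int,
    rng: np.random.Generator,
) -> list[TrialSchedule]:
    """A training run: ``n_trials`` trials split equally across sequences.

    The match rate is exactly 50% within each sequence's trials (hence per
    run), and test positions are uniform over 1..5.
    """
    if n_trials % len(sequences):
        raise ValueError("n_trials must be divisible by the number of sequences")
    per_seq = n_trials // len(sequences)
    if per_seq % 2:
        raise ValueError("trials per sequence must be even for an exact 50% match rate")
    trials: list[TrialSchedule] = []
    for seq in sequences:
        matches = _balanced_flags(per_seq, rng)
        positions = rng.integers(1, 6, size=per_seq)
        trials.extend(
            make_training_trial(seq, int(p), bool(m)) for p, m in zip(positions, matches)
        )
    return [trials[i] for i in rng.permutation(len(trials))]


def make_localizer_block(orientation: int) -> TrialSchedule:
    """One 15 s localizer block: 30 gratings at 0.25 s on / 0.25 s off."""
    events = [
        Event("grating", 0.5 * j, GRATING_ON, orientation=orientation)
        for j in range(LOC_GRATINGS_PER_BLOCK)
    ]
    return TrialSchedule(task="localizer-block", events=events,
                         labels={"orientation": orientation, "sequence_id": None,
                                 "expected": None, "cued": None, "is_match": None,
                                 "test": None},
                         duration=LOC_BLOCK_DURATION)


def make_localizer_run(rng: np.random.Generator) -> RunSchedule:
    """Block-design orientation localizer run.

    20 stimulus blocks (10 per orientation, randomized order) flanked by one
    fixation block at the beginning and one at the end of the run.
    """
    orientations = rng.permutation(
        [ORIENT_LEFT] * LOC_BLOCKS_PER_ORIENTATION + [ORIENT_RIGHT] * LOC_BLOCKS_PER_ORIENTATION
    )
    blocks = [make_localizer_block(int(o)) for o in orientations]
    return RunSchedule(task="localizer", trials=blocks)


@dataclass
class CheckResult:
    passed: bool
    detail: str


@dataclass
class DesignReport:
    """Per-check outcome of :func:`validate_design`; failures are reported, not raised."""

    checks: dict[str, CheckResult] = field(default_factory=dict)

    def add(self, name: str, passed: bool, detail: str) -> None:
        self.checks[name] = CheckResult(bool(passed), detail)

    @property
    def all_passed(self) -> bool:
        return all(c.passed for c in self.checks.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"check": k, "passed": v.passed, "detail": v.detail} for k, v in self.checks.items()]
        )


def _structure(items: Iterable[int]) -> tuple[int, ...]:
    """Swap-invariant canonical form of a sequence (structure, not codes)."""
    items = tuple(items)
    first = items[0]
    return tuple(0 if i == first else 1 for i in items)


def validate_design(schedules: list) -> DesignReport:
    """Check design invariants over a heterogeneous list of schedule objects.

    Accepts :class:`SequenceSpec`, :class:`TrialSchedule` and
    :class:`RunSchedule` entries. Every check is enumerated in the report
    even when it passes vacuously.
    """
    if not schedules:
        raise ValueError("empty schedule list")
    report = DesignReport()
    seqs = [s for s in schedules if isinstance(s, SequenceSpec)]
    runs = [s for s in schedules if isinstance(s, RunSchedule)]
    trials = [s for s in schedules if isinstance(s, TrialSchedule)]
    for run in runs:
        trials = trials + list(run.trials)

    # per-sequence orientation frequency (four leftward, four rightward)
    bad = [s.id for s in seqs if sorted(np.bincount(s.items, minlength=3)[1:]) != [4, 4]]
    report.add("sequence_orientation_balance", not bad,
               f"unbalanced sequences: {bad}" if bad else f"{len(seqs)} sequences balanced 4/4")

    by_id = {s.id: s for s in seqs}
    pairs = [p for p in (("A", "B"), ("Aprime", "Bprime")) if set(p) <= by_id.keys()]
    bad_pairs = [p for p in pairs if by_id[p[0]].items[-3:] != by_id[p[1]].items[-3:]]
    report.add("sequence_pair_last_three", not bad_pairs,
               f"pairs with differing tails: {bad_pairs}" if bad_pairs
               else f"checked pairs: {pairs}")

    swaps = [(o, p) for o, p in (("A", "Aprime"), ("B", "Bprime")) if {o, p} <= by_id.keys()]
    bad_swaps = [
        (o, p) for o, p in swaps
        if by_id[p].items != by_id[o].swapped().items or
        by_id[p].predicted != other_orientation(by_id[o].predicted)
    ]
    report.add("sequence_code_swap", not bad_swaps,
               f"non-swapped versions: {bad_swaps}" if bad_swaps else f"checked: {swaps}")

    counter_ok, counter_detail = True, "not applicable (need all four sequences)"
    if {"A", "Aprime", "Bprime"} <= by_id.keys():
        a, ap, bp = by_id["A"], by_id["Aprime"], by_id["Bprime"]
        counter_ok = (
            _structure(a.items) == _structure(ap.items)
            and a.predicted != ap.predicted
            and _structure(a.items) != _structure(bp.items)
            and a.predicted == bp.predicted
        )
        counter_detail = "A/A' same structure, opposite prediction; A/B' opposite structure, same prediction"
    report.add("sequence_counterbalancing", counter_ok, counter_detail)

    expected_durations = {"prediction": SCAN_TRIAL_DURATION, "control": SCAN_TRIAL_DURATION,
                          "training": TRAIN_TRIAL_DURATION, "localizer-block": LOC_BLOCK_DURATION}
    bad_durs = [
        (t.task, t.duration) for t in trials
        if t.task in expected_durations and not np.isclose(t.duration, expected_durations[t.task])
    ]
    report.add("trial_durations", not bad_durs,
               f"wrong durations: {bad_durs[:5]}" if bad_durs
               else f"{len(trials)} trials at their specified lengths")

    bad_timing = []
    for t in trials:
        onsets = [e.onset for e in t.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            bad_timing.append(t.task)
        if any(b.onset < a.offset - 1e-9 for a, b in zip(t.events, t.events[1:])):
            bad_timing.append(t.task)
    report.add("event_timing", not bad_timing,
               f"schedules with overlap/non-increasing onsets: {len(bad_timing)}"
               if bad_timing else "onsets strictly increasing, no overlap")

    rates = []
    for run in runs:
        flags = [t.labels.get("is_match") for t in run.trials if t.labels.get("is_match") is not None]
        if flags:
            rates.append(float(np.mean(flags)))
    match_ok = all(np.isclose(r, 0.5) for r in rates)
    report.add("match_rate", match_ok, f"per-run match rates: {rates}" if rates
               else "not applicable (no match trials)")

    first_ok, first_detail = True, "not applicable (no prediction runs)"
    for run in runs:
        firsts = [t.labels.get("first_item") for t in run.trials if run.task == "prediction"]
        if firsts:
            counts = np.bincount(firsts, minlength=3)[1:]
            if counts[0] != counts[1]:
                first_ok = False
            first_detail = f"first-item counts per run (last): left={counts[0]}, right={counts[1]}"
    report.add("first_item_balance", first_ok, first_detail)

    positions = [t.labels["test_position"] for t in trials if "test_position" in t.labels]
    pos_ok = all(1 <= p <= 5 for p in positions)
    hist = np.bincount(positions, minlength=6)[1:].tolist() if positions else []
    report.add("test_position_range", pos_ok,
               f"test-position histogram (1..5): {hist}" if positions
               else "not applicable (no training trials)")

    freq_ok, freq_detail = True, "not applicable (no runs)"
    for run in runs:
        oris = [e.orientation for t in run.trials for e in t.events
                if e.kind == "grating" and e.orientation is not None]
        if oris:
            counts = np.bincount(oris, minlength=3)[1:]
            if counts[0] != counts[1]:
                freq_ok = False
            freq_detail = f"grating counts per run (last): left={counts[0]}, right={counts[1]}"
    report.add("run_orientation_frequency", freq_ok, freq_detail)

    return report
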