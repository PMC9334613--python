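"""Session schedules for the dyadic Rock-Paper-Scissors experiment.

A full session runs four conditions.  Free Play always comes first (to avoid
carry-over from the explicit instruction manipulations); the remaining three
conditions — Prediction-Different Action, Prediction-Same Action, Control —
appear in a seeded random order.  Each condition consists of two blocks of
30 trials with one-minute resting phases before, between and after the
blocks, so a full session carries 12 resting segments.

Trial structure:

* Free Play and Control trials last 8 s.  Control trials decompose into a
  3 s decision phase, 2 s button press, 3 s action; Free Play trials are
  uniform 8 s epochs (the verbal "one, two, three" cadence is not modeled).
* Prediction trials last 15 s: 3 s prediction, 2 s button press, 3 s action,
  3 s observation, plus a 4 s inter-trial interval so the printed 15 s trial
  duration is honored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_FS_HZ = 7.81

CONDITIONS = ("FreePlay", "PredictionDifferent", "PredictionSame", "Control")
#: Factor levels used in coherence tables: the four task conditions plus the
#: pooled resting-state pseudo-condition.
COHERENCE_CONDITIONS = CONDITIONS + ("Rest",)

TRIAL_PHASES = {
    "FreePlay": (("trial", 8.0),),
    "Control": (("decision", 3.0), ("button", 2.0), ("action", 3.0)),
    "PredictionDifferent": (
        ("prediction", 3.0),
        ("button", 2.0),
        ("action", 3.0),
        ("observation", 3.0),
        ("iti", 4.0),
    ),
    "PredictionSame": (
        ("prediction", 3.0),
        ("button", 2.0),
        ("action", 3.0),
        ("observation", 3.0),
        ("iti", 4.0),
    ),
}

TRIAL_DURATION_S = {c: sum(d for _, d in TRIAL_PHASES[c]) for c in CONDITIONS}


@dataclass(frozen=True)
class Trial:
    condition: str
    block: int          # 1 or 2
    index: int          # trial index within block, 0-based
    onset_s: float
    duration_s: float
    phases: tuple[tuple[str, float], ...]  # (name, onset within trial)


@dataclass(frozen=True)
class Segment:
    """A contiguous schedule segment: a resting phase or a task block."""

    kind: str           # "rest" | "task"
    condition: str      # owning condition ("Rest" segments keep their condition)
    block: int | None   # task block number, None for rest
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class SessionSchedule:
    """Ordered conditions, task blocks, rest segments and trials on one clock."""

    condition_order: list[str]
    segments: list[Segment]
    trials: list[Trial]
    fs_hz: float = DEFAULT_FS_HZ
    trials_per_block: int = 30
    rest_s: float = 60.0

    @property
    def duration_s(self) -> float:
        return self.segments[-1].end_s

    @property
    def n_samples(self) -> int:
        return int(np.ceil(self.duration_s * self.fs_hz))

    @property
    def rest_segments(self) -> list[Segment]:
        return [s for s in self.segments if s.kind == "rest"]

    def task_segments(self, condition: str) -> list[Segment]:
        return [s for s in self.segments if s.kind == "task" and s.condition == condition]

    def trials_in(self, condition: str) -> list[Trial]:
        return [t for t in self.trials if t.condition == condition]

    def validate(self) -> None:
        if self.condition_order[0] != "FreePlay":
            raise ValueError("FreePlay must be the first condition")
        if sorted(self.condition_order) != sorted(CONDITIONS):
            raise ValueError("condition_order must contain each condition once")
        prev_end = 0.0
        for seg in self.segments:
            if seg.start_s < prev_end - 1e-9:
                raise ValueError("segments overlap or are out of order")
            prev_end = seg.end_s
        for c in CONDITIONS:
            if len(self.trials_in(c)) != 2 * self.trials_per_block:
                raise ValueError(f"condition {c} does not have 2x{self.trials_per_block} trials")


def build_schedule(
    order_seed: int = 0,
    *,
    fs_hz: float = DEFAULT_FS_HZ,
    trials_per_block: int = 30,
    rest_s: float = 60.0,
) -> SessionSchedule:
    """Build a session schedule with a seeded random condition order.

    ``trials_per_block`` and ``rest_s`` default to the full design (30
    trials, 60 s rests); the test profile shrinks them for desk-scale runs.
    """
    rng = np.random.default_rng(order_seed)
    rest_order = [CONDITIONS[i] for i in rng.permutation(3) + 1]
    order = ["FreePlay"] + rest_order

    segments: list[Segment] = []
    trials: list[Trial] = []
    t = 0.0
    for cond in order:
        trial_d = TRIAL_DURATION_S[cond]
        block_d = trials_per_block * trial_d
        for block in (1, 2):
            segments.append(Segment("rest", cond, None, t, t + rest_s))
            t += rest_s
            seg_start = t
            for i in range(trials_per_block):
                onset = seg_start + i * trial_d
                phase_onsets = []
                p = 0.0
                for name, d in TRIAL_PHASES[cond]:
                    phase_onsets.append((name, p))
                    p += d
                trials.append(Trial(cond, block, i, onset, trial_d, tuple(phase_onsets)))
            segments.append(Segment("task", cond, block, t, t + block_d))
            t += block_d
        segments.append(Segment("rest", cond, None, t, t + rest_s))
        t += rest_s

    sched = SessionSchedule(order, segments, trials, fs_hz, trials_per_block, rest_s)
    sched.validate()
    return sched


def segment_slice(seg: Segment, fs_hz: float) -> slice:
    """Sample-index slice covering a segment at sampling rate ``fs_hz``."""
    return slice(int(round(seg.start_s * fs_hz)), int(round(seg.end_s * fs_hz)))
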