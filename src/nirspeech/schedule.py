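"""Block-design stimulus schedules.

Alternating forward/reverse speech blocks separated by silences of
randomised length, with a bound on how many consecutive blocks may share
a condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

CONDITIONS = ("forward", "reverse")


class ScheduleConstraintError(ValueError):
    """Raised when the requested schedule constraints are infeasible."""


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered stimulus blocks.

    onset_s, duration_s : float arrays, one entry per block
    condition : array of ``"forward"``/``"reverse"`` labels
    """

    onset_s: np.ndarray
    duration_s: np.ndarray
    condition: np.ndarray

    def __post_init__(self):
        if not (len(self.onset_s) == len(self.duration_s) == len(self.condition)):
            raise ValueError("schedule fields must have equal length")
        if np.any(np.diff(self.onset_s) <= 0):
            raise ValueError("block onsets must be strictly increasing")

    @property
    def n_blocks(self) -> int:
        return len(self.onset_s)

    def blocks(self, condition: str | None = None):
        """Iterate (onset, duration, condition) tuples, optionally filtered."""
        for o, d, c in zip(self.onset_s, self.duration_s, self.condition):
            if condition is None or c == condition:
                yield float(o), float(d), str(c)

    def end_s(self) -> float:
        return float(self.onset_s[-1] + self.duration_s[-1])


def _condition_sequence(counts: dict, max_run: int, rng: np.random.Generator) -> list:
    """Sample a condition order with run lengths <= max_run.

    Constructive sampling: at each position draw uniformly among
    conditions that (a) do not extend the current run past max_run and
    (b) leave a completable remainder.
    """
    names = list(counts)
    remaining = dict(counts)
    seq: list = []
    run_cond, run_len = None, 0
    total = sum(remaining.values())
    for _ in range(total):
        feasible = []
        for c in names:
            if remaining[c] == 0:
                continue
            if c == run_cond and run_len >= max_run:
                continue
            # after taking c the sequence must remain completable: every
            # condition k must fit its remaining blocks into runs of at
            # most max_run interleaved with the other conditions; the
            # current open run of c uses up part of its first slot group
            rem = dict(remaining)
            rem[c] -= 1
            carry = run_len + 1 if c == run_cond else 1
            ok = True
            for k, v in rem.items():
                others = sum(w for j, w in rem.items() if j != k)
                capacity = (others + 1) * max_run - (carry if k == c else 0)
                if v > capacity:
                    ok = False
                    break
            if ok:
                feasible.append(c)
        if not feasible:
            raise ScheduleConstraintError(
                "run-length constraint became unsatisfiable mid-sequence")
        c = feasible[int(rng.integers(len(feasible)))]
        seq.append(c)
        remaining[c] -= 1
        run_len = run_len + 1 if c == run_cond else 1
        run_cond = c
    return seq


def make_schedule(n_per_condition: int, block_dur: float = 15.0,
                  isi_range: tuple = (15.0, 30.0), max_run: int = 2,
                  seed: int | np.random.Generator = 0) -> StimulusSchedule:
    """Generate a pseudo-randomised forward/reverse block schedule.

    Each of the two conditions appears exactly ``n_per_condition`` times;
    silences (including the lead-in before the first block) are drawn
    uniformly from ``isi_range``; at most ``max_run`` consecutive blocks
    share a condition.
    """
    if n_per_condition < 1:
        raise ScheduleConstraintError("n_per_condition must be >= 1")
    if max_run < 1:
        raise ScheduleConstraintError("max_run must be >= 1")
    lo, hi = isi_range
    if lo > hi or lo < 0:
        raise ScheduleConstraintError("invalid ISI range")
    counts = {c: n_per_condition for c in CONDITIONS}
    if max(counts.values()) > (sum(counts.values()) - max(counts.values()) + 1) * max_run:
        raise ScheduleConstraintError(
            f"cannot place {counts} blocks with max_run={max_run}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seq = _condition_sequence(counts, max_run, rng)
    n = len(seq)
    gaps = rng.uniform(lo, hi, size=n)
    onsets = np.empty(n)
    t = 0.0
    for i in range(n):
        t += gaps[i]
        onsets[i] = t
        t += block_dur
    return StimulusSchedule(onset_s=onsets,
                            duration_s=np.full(n, float(block_dur)),
                            condition=np.array(seq))


def validate_schedule(sched: StimulusSchedule, isi_range: tuple, max_run: int) -> None:
    """Raise if a schedule violates ISI bounds or the run-length cap."""
    lo, hi = isi_range
    ends = sched.onset_s[:-1] + sched.duration_s[:-1]
    gaps = sched.onset_s[1:] - ends
    eps = 1e-9
    if np.any(gaps < lo - eps) or np.any(gaps > hi + eps):
        raise ValueError("inter-block gap outside ISI range")
    run = 0
    prev = None
    for c in sched.condition:
        run = run + 1 if c == prev else 1
        prev = c
        if run > max_run:
            raise ValueError("run-length constraint violated")
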