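"""Trial schedules for the probabilistic decision-making under volatility task.

Each task run is 180 trials: a *stable* block of 90 trials in which one shape
delivers the outcome event with probability 0.75, and a *volatile* block of 90
trials in which the high-probability shape (0.80) reverses every 20 trials.
Three task versions share this structure and differ only in what the outcome
event is: ``gain`` (reward delivered), ``aversive`` (shock delivered) and
``loss`` (points subtracted).  Outcome magnitudes for the two shapes are
integers drawn uniformly from 1..99 independently on every trial.

Magnitude and event sequences are deterministic functions of
``(task_version, block_order, seed)``, so one seed per cohort condition yokes
the sequences across subjects who share a block order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TASK_VERSIONS = ("gain", "aversive", "loss")
BLOCK_ORDERS = ("stable_first", "volatile_first")

N_TRIALS = 180
BLOCK_LENGTH = 90
RUN_LENGTH = 20          # reversal interval in the volatile block
P_STABLE = 0.75
P_VOLATILE = 0.80

#: Whether the outcome event is the *good* outcome for the chooser.
#: Receiving a reward is good; receiving a shock or losing points is bad.
EVENT_IS_GOOD = {"gain": True, "aversive": False, "loss": False}

_VERSION_CODE = {v: i for i, v in enumerate(TASK_VERSIONS)}
_ORDER_CODE = {o: i for i, o in enumerate(BLOCK_ORDERS)}


@dataclass
class TrialSchedule:
    """Per-trial contingency and magnitude structure of one 180-trial run."""

    task_version: str
    block_order: str
    seed: int
    trials: pd.DataFrame = field(repr=False)
    # trials columns: trial (1-based), block_type, p_shape1_event, M1, M2,
    # event_shape

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def block_type(self) -> np.ndarray:
        return self.trials["block_type"].to_numpy()

    @property
    def event_shape(self) -> np.ndarray:
        return self.trials["event_shape"].to_numpy()

    @property
    def magnitudes(self) -> tuple[np.ndarray, np.ndarray]:
        return self.trials["M1"].to_numpy(), self.trials["M2"].to_numpy()

    def to_csv(self, path) -> None:
        self.trials.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, task_version: str, block_order: str,
                 seed: int = -1) -> "TrialSchedule":
        return cls(task_version, block_order, seed, pd.read_csv(path))


def _schedule_rng(task_version: str, block_order: str, seed: int):
    return np.random.default_rng(
        [int(seed) & 0x7FFFFFFF, _VERSION_CODE[task_version],
         _ORDER_CODE[block_order], 0x5EED]
    )


def make_schedule(task_version: str, block_order: str, seed: int) -> TrialSchedule:
    """Generate one task run.

    The shape that starts as the high-probability shape is a fair coin flip
    from the seed (independently for the two blocks).  ``event_shape`` is
    realized per trial by a Bernoulli draw from ``p_shape1_event``.
    """
    if task_version not in TASK_VERSIONS:
        raise ValueError(f"unknown task_version {task_version!r}")
    if block_order not in BLOCK_ORDERS:
        raise ValueError(f"unknown block_order {block_order!r}")

    rng = _schedule_rng(task_version, block_order, seed)

    # stable block: constant contingency
    stable_shape1_high = bool(rng.integers(2))
    p_stable = np.full(BLOCK_LENGTH, P_STABLE if stable_shape1_high else 1 - P_STABLE)

    # volatile block: reversal every RUN_LENGTH trials
    volatile_shape1_high_first = bool(rng.integers(2))
    runs = BLOCK_LENGTH // RUN_LENGTH + (BLOCK_LENGTH % RUN_LENGTH > 0)
    p_volatile = np.empty(BLOCK_LENGTH)
    for r in range(runs):
        high = volatile_shape1_high_first if r % 2 == 0 else not volatile_shape1_high_first
        lo, hi = r * RUN_LENGTH, min((r + 1) * RUN_LENGTH, BLOCK_LENGTH)
        p_volatile[lo:hi] = P_VOLATILE if high else 1 - P_VOLATILE

    if block_order == "stable_first":
        p = np.concatenate([p_stable, p_volatile])
        block = np.array(["stable"] * BLOCK_LENGTH + ["volatile"] * BLOCK_LENGTH)
    else:
        p = np.concatenate([p_volatile, p_stable])
        block = np.array(["volatile"] * BLOCK_LENGTH + ["stable"] * BLOCK_LENGTH)

    event_shape = np.where(rng.random(N_TRIALS) < p, 1, 2)
    m1 = rng.integers(1, 100, size=N_TRIALS)
    m2 = rng.integers(1, 100, size=N_TRIALS)

    trials = pd.DataFrame(
        {
            "trial": np.arange(1, N_TRIALS + 1),
            "block_type": block,
            "p_shape1_event": p,
            "M1": m1,
            "M2": m2,
            "event_shape": event_shape,
        }
    )
    return TrialSchedule(task_version, block_order, int(seed), trials)


def validate_schedule(schedule: TrialSchedule) -> list[str]:
    """Check the schedule invariants; return a description of each violation.

    An empty list means the schedule is valid.  Violations are returned
    rather than raised so malformed external files can be reported in full.
    """
    violations: list[str] = []
    t = schedule.trials

    if len(t) != N_TRIALS:
        violations.append(f"schedule has {len(t)} trials, expected {N_TRIALS}")

    for block_name in ("stable", "volatile"):
        n = int((t["block_type"] == block_name).sum())
        if n != BLOCK_LENGTH:
            violations.append(
                f"{block_name} block has {n} trials, expected {BLOCK_LENGTH}"
            )

    for _, row in t.iterrows():
        idx = int(row["trial"])
        for col in ("M1", "M2"):
            m = row[col]
            if not (1 <= m <= 99) or int(m) != m:
                violations.append(
                    f"trial {idx}: {col}={m} outside integer range [1, 99]"
                )
        if row["event_shape"] not in (1, 2):
            violations.append(f"trial {idx}: event_shape={row['event_shape']}")
        p = row["p_shape1_event"]
        expected = {P_STABLE, 1 - P_STABLE} if row["block_type"] == "stable" \
            else {P_VOLATILE, 1 - P_VOLATILE}
        if not any(np.isclose(p, e) for e in expected):
            violations.append(
                f"trial {idx}: p_shape1_event={p} not in {sorted(expected)} "
                f"for {row['block_type']} block"
            )

    # constant contingency in the stable block
    stable_p = t.loc[t["block_type"] == "stable", "p_shape1_event"].to_numpy()
    if len(stable_p) and not np.allclose(stable_p, stable_p[0]):
        violations.append("stable block contingency is not constant")

    # reversal exactly at every 20th trial of the volatile block; with a
    # 90-trial block the switches fall at within-block trials 21, 41, 61, 81
    # and the final run is truncated to 10 trials
    vol_p = t.loc[t["block_type"] == "volatile", "p_shape1_event"].to_numpy()
    if len(vol_p):
        change = (np.flatnonzero(np.diff(vol_p) != 0) + 1).tolist()
        expected_switches = list(range(RUN_LENGTH, len(vol_p), RUN_LENGTH))
        if change != expected_switches:
            violations.append(
                "volatile block reverses at within-block trials "
                f"{[c + 1 for c in change]} (1-based), expected "
                f"{[c + 1 for c in expected_switches]} "
                "(a reversal every 20th trial)"
            )

    return violations
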