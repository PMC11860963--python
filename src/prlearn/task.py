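"""Trial structure of the prosocial reversal-learning bandit task.

The task interleaves two independent two-armed bandit problems — one whose
points go to the participant ("self"), one whose points go to another person
("other") — within each block. Each bandit has one arm rewarding at a high
probability (default 70%) and one at a low probability (default 30%), and
the identity of the high arm swaps at fixed intervals (reversals). The
schedule itself is deterministic; only choices and reward draws are random.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

CONDITIONS = ("self", "other")
ARMS = ("a", "b")


@dataclass(frozen=True)
class TaskConfig:
    """Structural parameters of the task.

    Parameters
    ----------
    n_blocks : number of consecutive blocks (default 3).
    trials_per_condition : trials per condition within a block (default 30,
        i.e. 60 trials per block with two conditions).
    p_high, p_low : reward probabilities of the currently better / worse arm.
    reversal_period : number of within-condition trials between swaps of
        which arm carries ``p_high``.
    response_window_s : response deadline in seconds (metadata only; the
        simulator never times out).
    first_condition : condition shown on the first trial of every block.
    """

    n_blocks: int = 3
    trials_per_condition: int = 30
    p_high: float = 0.70
    p_low: float = 0.30
    reversal_period: int = 10
    response_window_s: float = 4.0
    first_condition: str = "self"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_low < self.p_high <= 1.0):
            raise ValueError(
                f"require 0 <= p_low < p_high <= 1, got p_low={self.p_low}, "
                f"p_high={self.p_high}"
            )
        if self.n_blocks < 1:
            raise ValueError(f"n_blocks must be >= 1, got {self.n_blocks}")
        if self.trials_per_condition < 1:
            raise ValueError(
                f"trials_per_condition must be >= 1, got {self.trials_per_condition}"
            )
        if self.reversal_period < 1:
            raise ValueError(
                f"reversal_period must be >= 1, got {self.reversal_period}"
            )
        if self.first_condition not in CONDITIONS:
            raise ValueError(
                f"first_condition must be one of {CONDITIONS}, got "
                f"{self.first_condition!r}"
            )

    @property
    def trials_per_block(self) -> int:
        return 2 * self.trials_per_condition

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


@dataclass(frozen=True)
class TrialSpec:
    """One presentation: which bandit, and which arm is currently better.

    ``block`` and ``trial_in_block`` are 1-based (matching the trial-table
    CSV); ``within_condition_index`` is 0-based so that the high arm flips
    exactly when ``within_condition_index`` reaches a multiple of the
    reversal period.
    """

    block: int
    trial_in_block: int
    condition: str
    within_condition_index: int
    p_arm_a: float
    p_arm_b: float
    high_arm: str

    @property
    def p_high_arm(self) -> float:
        return self.p_arm_a if self.high_arm == "a" else self.p_arm_b


@dataclass(frozen=True)
class Schedule:
    """Ordered trial list for one subject's session."""

    config: TaskConfig
    trials: tuple[TrialSpec, ...] = field(repr=False)

    def __len__(self) -> int:
        return len(self.trials)

    def block_trials(self, block: int) -> list[TrialSpec]:
        return [t for t in self.trials if t.block == block]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "block": [t.block for t in self.trials],
                "trial": [t.trial_in_block for t in self.trials],
                "condition": [t.condition for t in self.trials],
                "within_condition_index": [
                    t.within_condition_index for t in self.trials
                ],
                "p_arm_a": [t.p_arm_a for t in self.trials],
                "p_arm_b": [t.p_arm_b for t in self.trials],
                "high_arm": [t.high_arm for t in self.trials],
            }
        )


def build_schedule(config: TaskConfig) -> Schedule:
    """Construct the deterministic trial schedule for ``config``.

    Conditions strictly alternate within a block, starting with
    ``config.first_condition``. Within each condition, arm "a" carries the
    high probability initially and the assignment swaps after every
    ``reversal_period`` presentations of that condition. Reversal phase
    resets at each block boundary.
    """
    second = "other" if config.first_condition == "self" else "self"
    order = (config.first_condition, second)
    trials: list[TrialSpec] = []
    for block in range(1, config.n_blocks + 1):
        for i in range(config.trials_per_condition):
            for j, condition in enumerate(order):
                high_arm = ARMS[(i // config.reversal_period) % 2]
                p_a = config.p_high if high_arm == "a" else config.p_low
                p_b = config.p_high if high_arm == "b" else config.p_low
                trials.append(
                    TrialSpec(
                        block=block,
                        trial_in_block=2 * i + j + 1,
                        condition=condition,
                        within_condition_index=i,
                        p_arm_a=p_a,
                        p_arm_b=p_b,
                        high_arm=high_arm,
                    )
                )
    return Schedule(config=config, trials=tuple(trials))


def schedule_from_frame(df: pd.DataFrame, config: TaskConfig) -> Schedule:
    """Rebuild a Schedule from its ``to_frame`` representation."""
    trials = tuple(
        TrialSpec(
            block=int(r.block),
            trial_in_block=int(r.trial),
            condition=str(r.condition),
            within_condition_index=int(r.within_condition_index),
            p_arm_a=float(r.p_arm_a),
            p_arm_b=float(r.p_arm_b),
            high_arm=str(r.high_arm),
        )
        for r in df.itertuples(index=False)
    )
    return Schedule(config=config, trials=trials)
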