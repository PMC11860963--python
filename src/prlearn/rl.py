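"""Rescorla–Wagner valuation with softmax choice, for the two-bandit task.

Three models of trial-by-trial choice:

* ``M0`` — null: every choice is a fair coin, P(a) = 0.5.
* ``M1`` — one learning rate α and one inverse temperature τ shared across
  the "self" and "other" conditions.
* ``M2`` — separate (α, τ) per condition; the likelihood decouples across
  conditions because each condition has its own stimulus pair and value
  estimates.

Values are tracked per condition in all learning models (each condition has
its own pair of options); only the parameters are tied in M1. Rewards are
binary, values are initialised at ``v0`` (default 0.5, the midpoint of the
reward scale), and only the chosen option's value moves, by α times the
reward prediction error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit

from .task import CONDITIONS, Schedule, TrialSpec

MODELS = ("M0", "M1", "M2")

#: free-parameter count per model
MODEL_K = {"M0": 0, "M1": 2, "M2": 4}

DEFAULT_V0 = 0.5
TAU_MAX = 20.0


def _check_alpha(alpha: float, name: str = "alpha") -> None:
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {alpha}")


def _check_tau(tau: float, name: str = "tau") -> None:
    if tau < 0.0:
        raise ValueError(f"{name} must be >= 0, got {tau}")


@dataclass(frozen=True)
class ParamSetShared:
    """M1 parameters: one (α, τ) for both reward conditions."""

    alpha: float
    tau: float

    def __post_init__(self) -> None:
        _check_alpha(self.alpha)
        _check_tau(self.tau)

    def for_condition(self, condition: str) -> tuple[float, float]:
        return self.alpha, self.tau


@dataclass(frozen=True)
class ParamSetSeparate:
    """M2 parameters: condition-specific learning rates and temperatures."""

    alpha_self: float
    alpha_other: float
    tau_self: float
    tau_other: float

    def __post_init__(self) -> None:
        _check_alpha(self.alpha_self, "alpha_self")
        _check_alpha(self.alpha_other, "alpha_other")
        _check_tau(self.tau_self, "tau_self")
        _check_tau(self.tau_other, "tau_other")

    def for_condition(self, condition: str) -> tuple[float, float]:
        if condition == "self":
            return self.alpha_self, self.tau_self
        return self.alpha_other, self.tau_other

    @property
    def pls(self) -> float:
        """Prosocial learning sensitivity, α_other − α_self."""
        return self.alpha_other - self.alpha_self


ParamSet = ParamSetShared | ParamSetSeparate


@dataclass
class ChoiceRecord:
    """Observed or simulated behavior on one trial.

    ``chosen`` is ``None`` for a missed response; then ``reward`` and
    ``rt_ms`` are ``None`` too and the trial contributes nothing to the
    likelihood or to value updates.
    """

    trial: TrialSpec
    chosen: str | None
    reward: int | None
    rt_ms: float | None = None

    def __post_init__(self) -> None:
        if (self.chosen is None) != (self.reward is None):
            raise ValueError("reward must be present exactly when a choice was made")
        if self.chosen is not None and self.chosen not in ("a", "b"):
            raise ValueError(f"chosen must be 'a', 'b' or None, got {self.chosen!r}")
        if self.reward is not None and self.reward not in (0, 1):
            raise ValueError(f"reward must be 0 or 1, got {self.reward!r}")

    @property
    def missing(self) -> bool:
        return self.chosen is None

    @property
    def chose_high(self) -> int | None:
        if self.chosen is None:
            return None
        return int(self.chosen == self.trial.high_arm)


@dataclass
class SubjectDataset:
    """All trials of one subject, in presentation order."""

    subject_id: str
    group: str
    records: list[ChoiceRecord]

    def block_records(self, block: int) -> list[ChoiceRecord]:
        return [r for r in self.records if r.trial.block == block]

    def blocks(self) -> list[int]:
        return sorted({r.trial.block for r in self.records})

    def missing_fraction(self, block: int) -> float:
        recs = self.block_records(block)
        return sum(r.missing for r in recs) / len(recs)

    def hrp(self, condition: str, block: int | None = None) -> float:
        """Proportion of non-missing trials on which the currently
        high-probability arm was chosen."""
        recs = [
            r
            for r in self.records
            if r.trial.condition == condition
            and not r.missing
            and (block is None or r.trial.block == block)
        ]
        if not recs:
            return float("nan")
        return float(np.mean([r.chose_high for r in recs]))


def choice_prob(v_a: float, v_b: float, tau: float) -> float:
    """P(choose a) = logistic(τ·(V_a − V_b)).

    Implemented through the shift-invariant logistic, so it is finite for
    any |τ·ΔV| the float format can represent.
    """
    _check_tau(tau)
    if not (np.isfinite(v_a) and np.isfinite(v_b)):
        raise ValueError("values must be finite")
    return float(expit(tau * (v_a - v_b)))


def update_values(
    values: tuple[float, float], chosen: str, reward: int, alpha: float
) -> tuple[float, float]:
    """Delta-rule update: move the chosen arm's value toward the reward."""
    _check_alpha(alpha)
    v_a, v_b = values
    if chosen == "a":
        return (v_a + alpha * (reward - v_a), v_b)
    if chosen == "b":
        return (v_a, v_b + alpha * (reward - v_b))
    raise ValueError(f"chosen must be 'a' or 'b', got {chosen!r}")


def _log_sigmoid(x: float) -> float:
    # log(1/(1+exp(-x))) without overflow
    if x >= 0:
        return -np.log1p(np.exp(-x))
    return x - np.log1p(np.exp(x))


def sequence_nll(
    params: ParamSet | None,
    model: str,
    records: Sequence[ChoiceRecord],
    v0: float = DEFAULT_V0,
) -> float:
    """Negative log-likelihood of an observed choice sequence.

    Missing trials are skipped entirely: no likelihood contribution and no
    value update. Raises if the sequence contains no scored trial.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    n_scored = sum(not r.missing for r in records)
    if n_scored == 0:
        raise ValueError("no non-missing trials: likelihood undefined")
    if model == "M0":
        return n_scored * np.log(2.0)

    values = {c: (v0, v0) for c in CONDITIONS}
    nll = 0.0
    for rec in records:
        if rec.missing:
            continue
        cond = rec.trial.condition
        alpha, tau = params.for_condition(cond)
        v_a, v_b = values[cond]
        x = tau * (v_a - v_b)
        # log P(observed choice)
        logp = _log_sigmoid(x) if rec.chosen == "a" else _log_sigmoid(-x)
        nll -= logp
        values[cond] = update_values((v_a, v_b), rec.chosen, rec.reward, alpha)
    return float(nll)


def sequence_nll_batch(
    alphas: np.ndarray,
    taus: np.ndarray,
    records: Sequence[ChoiceRecord],
    v0: float = DEFAULT_V0,
) -> np.ndarray:
    """NLL of one choice sequence under many (α, τ) pairs at once.

    Used by the fitting start-grid: the same shared-parameter likelihood as
    ``sequence_nll`` with model M1, vectorised over candidate parameter
    sets. For per-condition (M2) fitting, pass the records of a single
    condition.
    """
    alphas = np.asarray(alphas, dtype=float)
    taus = np.asarray(taus, dtype=float)
    k = alphas.shape[0]
    va = {c: np.full(k, v0) for c in CONDITIONS}
    vb = {c: np.full(k, v0) for c in CONDITIONS}
    nll = np.zeros(k)
    for rec in records:
        if rec.missing:
            continue
        cond = rec.trial.condition
        x = taus * (va[cond] - vb[cond])
        if rec.chosen == "a":
            nll += np.logaddexp(0.0, -x)
            va[cond] = va[cond] + alphas * (rec.reward - va[cond])
        else:
            nll += np.logaddexp(0.0, x)
            vb[cond] = vb[cond] + alphas * (rec.reward - vb[cond])
    return nll


def simulate_agent(
    params: ParamSet | None,
    model: str,
    schedule: Schedule,
    seed: int | np.random.Generator,
) -> SubjectDataset:
    """Forward-simulate one agent through ``schedule``.

    Choices are drawn from the softmax policy, rewards from the chosen
    arm's current probability, and values follow the delta rule. Value
    estimates (and hence the policy) reset at each block boundary. Returns
    a complete dataset (no missing responses; RTs absent).
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    records: list[ChoiceRecord] = []
    current_block = None
    values: dict[str, tuple[float, float]] = {}
    for trial in schedule.trials:
        if trial.block != current_block:
            current_block = trial.block
            values = {c: (DEFAULT_V0, DEFAULT_V0) for c in CONDITIONS}
        cond = trial.condition
        if model == "M0":
            p_a = 0.5
        else:
            _, tau = params.for_condition(cond)
            p_a = choice_prob(*values[cond], tau)
        chosen = "a" if rng.random() < p_a else "b"
        p_reward = trial.p_arm_a if chosen == "a" else trial.p_arm_b
        reward = int(rng.random() < p_reward)
        if model != "M0":
            alpha, _ = params.for_condition(cond)
            values[cond] = update_values(values[cond], chosen, reward, alpha)
        records.append(ChoiceRecord(trial=trial, chosen=chosen, reward=reward))
    return SubjectDataset(subject_id="sim", group="NA", records=records)


def simulate_hrp_population(
    alpha_self: float,
    alpha_other: float,
    tau_self: float,
    tau_other: float,
    schedule: Schedule,
    n_agents: int,
    seed: int | np.random.SeedSequence | np.random.Generator,
    v0: float = DEFAULT_V0,
) -> dict[str, np.ndarray]:
    """High-reward-probability choice rates for many agents, vectorised.

    Simulates ``n_agents`` independent M2 agents through the same schedule
    in one pass (arrays over agents) and returns, per condition and
    overall, each agent's proportion of trials on which it picked the arm
    currently carrying the high reward probability.
    """
    if n_agents < 1:
        raise ValueError("n_agents must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    alpha = {"self": alpha_self, "other": alpha_other}
    tau = {"self": tau_self, "other": tau_other}
    for c in CONDITIONS:
        _check_alpha(alpha[c], f"alpha_{c}")
        _check_tau(tau[c], f"tau_{c}")

    hits = {c: np.zeros(n_agents) for c in CONDITIONS}
    counts = {c: 0 for c in CONDITIONS}
    current_block = None
    va: dict[str, np.ndarray] = {}
    vb: dict[str, np.ndarray] = {}
    for trial in schedule.trials:
        if trial.block != current_block:
            current_block = trial.block
            va = {c: np.full(n_agents, v0) for c in CONDITIONS}
            vb = {c: np.full(n_agents, v0) for c in CONDITIONS}
        c = trial.condition
        p_a = expit(tau[c] * (va[c] - vb[c]))
        chose_a = rng.random(n_agents) < p_a
        p_reward = np.where(chose_a, trial.p_arm_a, trial.p_arm_b)
        reward = (rng.random(n_agents) < p_reward).astype(float)
        va[c] = np.where(chose_a, va[c] + alpha[c] * (reward - va[c]), va[c])
        vb[c] = np.where(~chose_a, vb[c] + alpha[c] * (reward - vb[c]), vb[c])
        chose_high = chose_a if trial.high_arm == "a" else ~chose_a
        hits[c] += chose_high
        counts[c] += 1
    out = {c: hits[c] / counts[c] for c in CONDITIONS}
    total = sum(counts.values())
    out["overall"] = (hits["self"] + hits["other"]) / total
    return out
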