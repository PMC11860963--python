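"""Posterior predictive checks and the α/τ grid simulation.

Two validation devices for the winning condition-separate model:

* a posterior predictive check — re-simulate each fitted subject many
  times with their own parameters and compare the predicted proportion of
  high-reward-probability (HRP) choices with the observed one;
* a grid simulation over the (α, τ) plane showing that the learning rate,
  not the inverse temperature, drives predicted HRP under a rapidly
  reversing schedule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .fitting import FitResult
from .rl import ChoiceRecord, SubjectDataset, simulate_hrp_population
from .task import Schedule

DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.1, 1.0001, 0.1), 10))
DEFAULT_TAU_GRID = tuple(np.round(np.arange(0.5, 10.0001, 0.5), 10))


@dataclass
class PpcResult:
    subject: str
    block: int
    predicted_hrp: dict[str, float]
    actual_hrp: dict[str, float]
    n_sims: int


def posterior_predictive(
    fit: FitResult,
    schedule: Schedule,
    records: list[ChoiceRecord] | None = None,
    n_sims: int = 1000,
    seed: int | np.random.SeedSequence = 0,
) -> PpcResult:
    """Simulate ``n_sims`` agents with the fitted M2 parameters and average
    their HRP per condition; attach the subject's observed HRP if records
    are given."""
    if fit.model != "M2":
        raise ValueError("posterior predictive check requires an M2 fit")
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    p = fit.params
    hrp = simulate_hrp_population(
        p.alpha_self, p.alpha_other, p.tau_self, p.tau_other,
        schedule, n_sims, seed,
    )
    predicted = {c: float(np.mean(hrp[c])) for c in ("self", "other")}
    actual = {"self": float("nan"), "other": float("nan")}
    if records is not None:
        ds = SubjectDataset(subject_id=fit.subject, group="NA", records=list(records))
        actual = {c: ds.hrp(c) for c in ("self", "other")}
    return PpcResult(
        subject=fit.subject, block=fit.block,
        predicted_hrp=predicted, actual_hrp=actual, n_sims=n_sims,
    )


def grid_predictiveness(
    schedule: Schedule,
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID,
    tau_grid: tuple[float, ...] = DEFAULT_TAU_GRID,
    n_sims: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, float, float]:
    """Mean simulated HRP for every (α, τ) cell, and how well each
    parameter predicts it.

    Every cell simulates ``n_sims`` agents that use the same (α, τ) in
    both conditions on the deterministic ``schedule`` (each cell gets an
    independent substream of ``seed``). Returns the cell table and the
    Pearson correlations of cell α and cell τ with cell mean HRP across
    all cells.
    """
    if len(alpha_grid) == 0 or len(tau_grid) == 0:
        raise ValueError("grids must be non-empty")
    if len(alpha_grid) * len(tau_grid) < 2:
        raise ValueError("correlations undefined on a single-cell grid")
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(alpha_grid) * len(tau_grid))
    rows = []
    i = 0
    for alpha in alpha_grid:
        for tau in tau_grid:
            hrp = simulate_hrp_population(
                alpha, alpha, tau, tau, schedule, n_sims, children[i]
            )
            rows.append(
                {
                    "alpha": alpha,
                    "tau": tau,
                    "mean_hrp": float(np.mean(hrp["overall"])),
                    "n_sims": n_sims,
                }
            )
            i += 1
    cells = pd.DataFrame(rows)
    r_alpha = _margin_corr(cells, "alpha")
    r_tau = _margin_corr(cells, "tau")
    return cells, r_alpha, r_tau


def _margin_corr(cells: pd.DataFrame, param: str) -> float:
    if cells[param].nunique() < 2:
        raise ValueError(
            f"correlation with {param} undefined: grid is constant in {param}"
        )
    r, _ = pearsonr(cells[param], cells["mean_hrp"])
    return float(r)
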