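"""Per-subject, per-block maximum-likelihood fitting and BIC comparison.

Each subject's choices in each block are fitted with the null model M0
(no free parameters), the shared-parameter model M1 (α, τ) and the
condition-separate model M2 (α_self, α_other, τ_self, τ_other). Fits are
deterministic: the negative log-likelihood is evaluated on a fixed start
grid, the best starts are refined by a nested local grid search, and the
winner is optionally polished with bounded L-BFGS-B, all inside
α ∈ [0, 1], τ ∈ [0, tau_max]. Models are compared by BIC summed over
subjects within a block (fixed-effects aggregation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize

from .rl import (
    DEFAULT_V0,
    ChoiceRecord,
    ParamSetSeparate,
    ParamSetShared,
    SubjectDataset,
    sequence_nll_batch,
)

#: subjects whose fitted block-1 alpha_self falls at or below this value are
#: treated as "estimated to be zero" (no evidence of self-regarding learning)
ALPHA_ZERO_TOL = 1e-6


@dataclass(frozen=True)
class FitSettings:
    """Controls for the deterministic multi-start MLE.

    The likelihood is evaluated on the fixed start grid (vectorised over
    starts), the best ``n_refine`` starts are refined by a nested local
    grid search (``zoom_levels`` rounds of a 9×9 box shrinking 4× per
    round), and the winner is optionally polished with bounded L-BFGS-B.
    Everything is deterministic given the data and these settings.
    """

    tau_max: float = 20.0
    v0: float = DEFAULT_V0
    alpha_starts: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
    tau_starts: tuple[float, ...] = (0.5, 1.0, 3.0, 5.0, 10.0)
    n_refine: int = 3
    zoom_levels: int = 2
    polish: bool = True  # final L-BFGS-B polish of the best candidate


#: reduced-accuracy profile for replicated simulation studies
FAST_FIT_SETTINGS = FitSettings(
    alpha_starts=(0.2, 0.5, 0.8),
    tau_starts=(1.0, 3.0, 8.0),
    n_refine=1,
    zoom_levels=2,
    polish=False,
)


@dataclass
class FitResult:
    subject: str
    block: int
    model: str
    params: ParamSetShared | ParamSetSeparate | None
    nll: float
    n_trials: int
    k: int
    bic: float
    n_starts: int
    converged: bool


def bic(nll: float, k: int, n: int) -> float:
    """Bayesian information criterion, k·ln(n) + 2·NLL (lower is better)."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return k * np.log(n) + 2.0 * nll


def _fit_two_param(
    records: Sequence[ChoiceRecord], settings: FitSettings
) -> tuple[float, float, float, bool]:
    """MLE of a shared (α, τ) on ``records``.

    Returns (alpha, tau, nll, converged). Grid evaluation is vectorised
    over starts; the best ``n_refine`` starts are refined by a shrinking
    local grid and the overall winner is optionally polished with
    L-BFGS-B. Deterministic.
    """
    grid = [(a, t) for a in settings.alpha_starts for t in settings.tau_starts]
    alphas = np.array([g[0] for g in grid])
    taus = np.array([g[1] for g in grid])
    grid_nll = sequence_nll_batch(alphas, taus, records, v0=settings.v0)
    order = np.argsort(grid_nll, kind="stable")[: max(1, settings.n_refine)]

    best = (float(alphas[order[0]]), float(taus[order[0]]), float(grid_nll[order[0]]))
    # nested local grid search around each retained start
    span_a0 = max(np.diff(np.sort(settings.alpha_starts)).max(), 0.05)
    span_t0 = max(np.diff(np.sort(settings.tau_starts)).max(), 0.5)
    offsets = np.linspace(-1.0, 1.0, 9)
    for idx in order:
        ca, ct = float(alphas[idx]), float(taus[idx])
        span_a, span_t = span_a0, span_t0
        local_best = (ca, ct, float(grid_nll[idx]))
        for _ in range(max(0, settings.zoom_levels)):
            aa = np.clip(ca + span_a * offsets, 0.0, 1.0)
            tt = np.clip(ct + span_t * offsets, 0.0, settings.tau_max)
            A, T = np.meshgrid(aa, tt, indexing="ij")
            nll = sequence_nll_batch(A.ravel(), T.ravel(), records, v0=settings.v0)
            j = int(np.argmin(nll))
            ca, ct = float(A.ravel()[j]), float(T.ravel()[j])
            if nll[j] < local_best[2]:
                local_best = (ca, ct, float(nll[j]))
            span_a /= 4.0
            span_t /= 4.0
        if local_best[2] < best[2]:
            best = local_best

    converged = True
    if settings.polish:
        def objective(x: np.ndarray) -> float:
            return float(
                sequence_nll_batch(
                    np.array([x[0]]), np.array([x[1]]), records, v0=settings.v0
                )[0]
            )

        res = minimize(
            objective,
            x0=np.array([best[0], best[1]]),
            method="L-BFGS-B",
            bounds=[(0.0, 1.0), (0.0, settings.tau_max)],
        )
        if res.fun < best[2]:
            best = (float(res.x[0]), float(res.x[1]), float(res.fun))
        converged = bool(res.success)
    return best[0], best[1], best[2], converged


def _is_degenerate(records: Sequence[ChoiceRecord]) -> bool:
    # all responses identical with fewer than 2 scored trials: the
    # likelihood surface has no interior information about tau
    choices = [r.chosen for r in records if not r.missing]
    return len(set(choices)) < 2 and len(choices) < 2


def fit_subject_block(
    records: Sequence[ChoiceRecord],
    model: str,
    settings: FitSettings = FitSettings(),
    subject: str = "NA",
    block: int = 0,
) -> FitResult:
    """Fit one model to one subject-block by maximum likelihood."""
    scored = [r for r in records if not r.missing]
    if not scored:
        raise ValueError("no non-missing trials to fit")
    n = len(scored)
    n_starts = len(settings.alpha_starts) * len(settings.tau_starts)

    if model == "M0":
        nll = n * np.log(2.0)
        return FitResult(
            subject=subject, block=block, model="M0", params=None,
            nll=float(nll), n_trials=n, k=0, bic=bic(nll, 0, n),
            n_starts=0, converged=True,
        )

    if model == "M1":
        a, t, nll, ok = _fit_two_param(records, settings)
        params = ParamSetShared(alpha=a, tau=t)
        return FitResult(
            subject=subject, block=block, model="M1", params=params,
            nll=nll, n_trials=n, k=2, bic=bic(nll, 2, n),
            n_starts=n_starts, converged=ok and not _is_degenerate(records),
        )

    if model == "M2":
        by_cond = {}
        nll_total = 0.0
        ok = True
        for cond in ("self", "other"):
            cond_recs = [r for r in records if r.trial.condition == cond]
            if not any(not r.missing for r in cond_recs):
                raise ValueError(f"no non-missing {cond!r}-condition trials")
            a, t, nll, c_ok = _fit_two_param(cond_recs, settings)
            by_cond[cond] = (a, t)
            nll_total += nll
            ok = ok and c_ok and not _is_degenerate(cond_recs)
        params = ParamSetSeparate(
            alpha_self=by_cond["self"][0], alpha_other=by_cond["other"][0],
            tau_self=by_cond["self"][1], tau_other=by_cond["other"][1],
        )
        return FitResult(
            subject=subject, block=block, model="M2", params=params,
            nll=float(nll_total), n_trials=n, k=4, bic=bic(nll_total, 4, n),
            n_starts=n_starts, converged=ok,
        )

    raise ValueError(f"unknown model {model!r}")


def fit_dataset(
    dataset: SubjectDataset,
    models: Sequence[str] = ("M0", "M1", "M2"),
    settings: FitSettings = FitSettings(),
) -> list[FitResult]:
    """Fit every requested model to every block of one subject."""
    out = []
    for block in dataset.blocks():
        recs = dataset.block_records(block)
        for model in models:
            out.append(
                fit_subject_block(
                    recs, model, settings, subject=dataset.subject_id, block=block
                )
            )
    return out


@dataclass
class ModelComparison:
    block: int
    summed_bic: dict[str, float]
    delta_bic: dict[str, float]
    n_subjects: int


def compare_models(
    fits: Iterable[FitResult], block: int, models: Sequence[str] = ("M0", "M1", "M2")
) -> ModelComparison:
    """Sum BIC across subjects per model within a block; report ΔBIC
    (alternative minus winner) for every model pair."""
    per_model: dict[str, dict[str, float]] = {m: {} for m in models}
    for f in fits:
        if f.block == block and f.model in per_model:
            per_model[f.model][f.subject] = f.bic
    subjects = None
    for m in models:
        have = set(per_model[m])
        if subjects is None:
            subjects = have
        elif have != subjects:
            diff = sorted(subjects.symmetric_difference(have))
            raise ValueError(
                f"block {block}: subjects without fits for all models: {diff}"
            )
    if not subjects:
        raise ValueError(f"no fits found for block {block}")
    summed = {m: float(sum(per_model[m].values())) for m in models}
    winner = min(summed, key=summed.get)
    delta = {
        f"{m}-{winner}": summed[m] - summed[winner] for m in models if m != winner
    }
    return ModelComparison(
        block=block, summed_bic=summed, delta_bic=delta, n_subjects=len(subjects)
    )


@dataclass
class ExclusionReport:
    included: list[str]
    excluded: dict[str, list[str]]  # subject -> reasons


def apply_exclusions(
    datasets: Sequence[SubjectDataset],
    fits: Iterable[FitResult],
    alpha_zero_tol: float = ALPHA_ZERO_TOL,
) -> ExclusionReport:
    """Exclude subjects missing more than half the responses in any block,
    and subjects whose fitted block-1 α_self is (numerically) zero — i.e.
    no evidence of learning even for their own reward."""
    block1_m2 = {
        f.subject: f for f in fits if f.block == 1 and f.model == "M2"
    }
    included: list[str] = []
    excluded: dict[str, list[str]] = {}
    for ds in datasets:
        reasons = []
        for block in ds.blocks():
            if ds.missing_fraction(block) > 0.5:
                reasons.append(f"missing more than half of responses in block {block}")
                break
        fit = block1_m2.get(ds.subject_id)
        if fit is None:
            raise ValueError(f"no block-1 M2 fit for subject {ds.subject_id}")
        if fit.params.alpha_self <= alpha_zero_tol:
            reasons.append("no self-learning (block-1 alpha_self estimated as zero)")
        if reasons:
            excluded[ds.subject_id] = reasons
        else:
            included.append(ds.subject_id)
    return ExclusionReport(included=included, excluded=excluded)
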