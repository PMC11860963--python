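"""Trial-table and results I/O, configuration, and seed management.

The trial table is a plain CSV, one row per presentation:

    subject_id, group, block, trial, condition, chosen, chose_high,
    reward, rt_ms

``block`` and ``trial`` are 1-based; ``chosen`` is ``a``/``b`` or ``NA``
for a missed response, in which case ``chose_high``, ``reward`` and
``rt_ms`` must be ``NA`` too. Every writer output is loadable by the
matching reader (round-trip closure).
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortSpec, EffectSpec, GROUPS
from .fitting import FitResult, FitSettings
from .rl import ChoiceRecord, ParamSetSeparate, ParamSetShared, SubjectDataset
from .task import CONDITIONS, TaskConfig, build_schedule

NA = "NA"

TRIAL_COLUMNS = [
    "subject_id", "group", "block", "trial", "condition",
    "chosen", "chose_high", "reward", "rt_ms",
]


def spawn_seed(global_seed: int, stage: str) -> np.random.SeedSequence:
    """Deterministic per-stage substream: the stage name is hashed with
    CRC-32 and combined with the global seed as SeedSequence entropy."""
    return np.random.SeedSequence([int(global_seed), zlib.crc32(stage.encode())])


def datasets_to_frame(datasets: list[SubjectDataset]) -> pd.DataFrame:
    rows = []
    for ds in datasets:
        for rec in ds.records:
            t = rec.trial
            rows.append(
                {
                    "subject_id": ds.subject_id,
                    "group": ds.group,
                    "block": t.block,
                    "trial": t.trial_in_block,
                    "condition": t.condition,
                    "chosen": rec.chosen if rec.chosen is not None else NA,
                    "chose_high": rec.chose_high if rec.chose_high is not None else NA,
                    "reward": rec.reward if rec.reward is not None else NA,
                    "rt_ms": rec.rt_ms if rec.rt_ms is not None else NA,
                }
            )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def write_trials(datasets: list[SubjectDataset], path: str | Path) -> None:
    # %.17g keeps float round-trips exact
    datasets_to_frame(datasets).to_csv(path, index=False, float_format="%.17g")


def read_trials(
    path: str | Path, config: TaskConfig = TaskConfig()
) -> list[SubjectDataset]:
    """Read and validate a trial-table CSV.

    The task config reconstructs each trial's arm probabilities and
    current high arm (the table stores behavior, not the schedule).
    Schema violations are reported with 1-based data row numbers.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"trial table missing columns: {missing_cols}")
    if df.empty:
        import warnings

        warnings.warn(f"{path}: trial table is empty", stacklevel=2)
        return []

    schedule = build_schedule(config)
    by_key = {
        (t.block, t.trial_in_block): t for t in schedule.trials
    }
    datasets: dict[str, SubjectDataset] = {}
    seen: set[tuple[str, int, int]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = row 1
        if row.group not in GROUPS and row.group != "NA":
            raise ValueError(f"row {i}: unknown group {row.group!r}")
        if row.condition not in CONDITIONS:
            raise ValueError(f"row {i}: unknown condition {row.condition!r}")
        block, trial = int(row.block), int(row.trial)
        key = (row.subject_id, block, trial)
        if key in seen:
            raise ValueError(f"row {i}: duplicate (subject, block, trial) {key}")
        seen.add(key)
        spec = by_key.get((block, trial))
        if spec is None:
            raise ValueError(f"row {i}: (block={block}, trial={trial}) not in schedule")
        if spec.condition != row.condition:
            raise ValueError(
                f"row {i}: condition {row.condition!r} does not match the "
                f"schedule ({spec.condition!r})"
            )
        if row.chosen == NA:
            if row.reward != NA or row.chose_high != NA or row.rt_ms != NA:
                raise ValueError(
                    f"row {i}: chose_high/reward/rt_ms must be NA when chosen is NA"
                )
            rec = ChoiceRecord(trial=spec, chosen=None, reward=None)
        else:
            if row.chosen not in ("a", "b"):
                raise ValueError(f"row {i}: chosen must be a, b or NA, got {row.chosen!r}")
            if row.reward == NA:
                raise ValueError(f"row {i}: reward present iff chosen present")
            rec = ChoiceRecord(
                trial=spec,
                chosen=row.chosen,
                reward=int(row.reward),
                rt_ms=float(row.rt_ms) if row.rt_ms != NA else None,
            )
            if row.chose_high != NA and int(row.chose_high) != rec.chose_high:
                raise ValueError(f"row {i}: chose_high inconsistent with schedule")
        ds = datasets.setdefault(
            row.subject_id,
            SubjectDataset(subject_id=row.subject_id, group=row.group, records=[]),
        )
        ds.records.append(rec)
    return list(datasets.values())


# ---------------------------------------------------------------------------
# fit results

def fits_to_frame(fits: list[FitResult]) -> pd.DataFrame:
    rows = []
    for f in fits:
        row = {
            "subject": f.subject, "block": f.block, "model": f.model,
            "alpha": NA, "tau": NA, "alpha_self": NA, "alpha_other": NA,
            "tau_self": NA, "tau_other": NA,
            "nll": f.nll, "k": f.k, "n": f.n_trials, "bic": f.bic,
            "converged": f.converged,
        }
        if f.model == "M1":
            row.update(alpha=f.params.alpha, tau=f.params.tau)
        elif f.model == "M2":
            row.update(
                alpha_self=f.params.alpha_self, alpha_other=f.params.alpha_other,
                tau_self=f.params.tau_self, tau_other=f.params.tau_other,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def write_fits(fits: list[FitResult], path: str | Path) -> None:
    fits_to_frame(fits).to_csv(path, index=False, float_format="%.17g")


def read_fits(path: str | Path) -> list[FitResult]:
    df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
    out = []
    for row in df.itertuples(index=False):
        model = row.model
        if model == "M0":
            params = None
        elif model == "M1":
            params = ParamSetShared(alpha=float(row.alpha), tau=float(row.tau))
        else:
            params = ParamSetSeparate(
                alpha_self=float(row.alpha_self), alpha_other=float(row.alpha_other),
                tau_self=float(row.tau_self), tau_other=float(row.tau_other),
            )
        out.append(
            FitResult(
                subject=row.subject, block=int(row.block), model=model,
                params=params, nll=float(row.nll), n_trials=int(row.n),
                k=int(row.k), bic=float(row.bic), n_starts=0,
                converged=bool(row.converged),
            )
        )
    return out


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Everything one end-to-end pipeline run needs."""

    seed: int = 0
    out_dir: str = "results/pipeline"
    task: TaskConfig = field(default_factory=TaskConfig)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    fit: FitSettings = field(default_factory=FitSettings)
    grid_n_sims: int = 1000
    ppc_n_sims: int = 1000
    n_boot: int = 1000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        task = TaskConfig(**raw.get("task", {}))
        cohort_raw = dict(raw.get("cohort", {}))
        effects_raw = cohort_raw.pop("effects", None)
        if effects_raw is not None:
            effects = {
                (e["group"], e["subtype"]): EffectSpec(**e) for e in effects_raw
            }
            cohort_raw["effects"] = effects
        cohort = CohortSpec(task=task, **cohort_raw)
        fit = FitSettings(**raw.get("fit", {}))
        return cls(
            seed=raw.get("seed", 0),
            out_dir=raw.get("out_dir", "results/pipeline"),
            task=task, cohort=cohort, fit=fit,
            grid_n_sims=raw.get("grid_n_sims", 1000),
            ppc_n_sims=raw.get("ppc_n_sims", 1000),
            n_boot=raw.get("n_boot", 1000),
        )

    def describe(self) -> dict:
        """JSON/YAML-serialisable provenance record of this configuration."""
        d = {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "task": asdict(self.task),
            "fit": asdict(self.fit),
            "cohort": {
                k: v
                for k, v in asdict(self.cohort).items()
                if k not in ("effects", "task")
            },
            "grid_n_sims": self.grid_n_sims,
            "ppc_n_sims": self.ppc_n_sims,
            "n_boot": self.n_boot,
        }
        d["cohort"]["effects"] = [
            asdict(e) for e in self.cohort.effects.values()
        ]
        return d
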