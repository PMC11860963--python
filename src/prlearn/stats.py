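"""Subject-level summaries and the group-level inferential pipeline.

Covers: prosocial learning sensitivity (PLS = α_other − α_self) and the
Selfish/Prosocial categorization from block-1 PLS; high-reward-probability
choice rates and z-scored reaction times; mixed repeated-measures ANOVA
with arbitrary between- and within-subject factors; Benjamini–Hochberg
FDR-corrected paired post-hocs; the basic t-test/correlation battery; and
a percentile bootstrap for between-group differences.

The mixed ANOVA is the univariate (sphericity-assumed) mixed-model
analysis: the repeated measures are transformed by orthonormal
within-subject contrasts and each within-effect is tested by Type III
sums of squares of the between-subjects design on the transformed
variables (summed across contrast columns). With effects coding this
reproduces the SPSS-style tests, including integer error degrees of
freedom such as F(2, 196) for a 2×2 between × 3×2 within layout with 102
subjects.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .fitting import FitResult
from .rl import SubjectDataset

LABELS = ("Selfish", "Prosocial")


# ---------------------------------------------------------------------------
# subject summaries and categorization

@dataclass
class SubjectSummary:
    subject: str
    group: str
    hrp: dict  # (block, condition) -> proportion
    z_rt: dict  # (block, condition) -> mean z-scored RT
    alpha: dict  # (block, condition) -> fitted learning rate
    tau: dict  # (block, condition) -> fitted inverse temperature
    pls: dict  # block -> alpha_other - alpha_self
    label: str  # Selfish iff block-1 PLS < 0
    included: bool = True
    rt_zero_variance: bool = False


def categorize(pls_block1: float) -> str:
    """Selfish if block-1 PLS is negative, Prosocial if zero or positive."""
    return "Selfish" if pls_block1 < 0 else "Prosocial"


def summarize_subject(
    fits: list[FitResult], dataset: SubjectDataset, included: bool = True
) -> SubjectSummary:
    """Build one subject's summary from their M2 fits and trial data.

    Reaction times are z-scored within subject within block across all
    non-missing trials (both conditions pooled), then averaged per
    condition; a block with zero RT variance contributes zeros and sets a
    flag.
    """
    m2 = {f.block: f for f in fits if f.model == "M2" and f.subject == dataset.subject_id}
    blocks = dataset.blocks()
    missing_fits = [b for b in blocks if b not in m2]
    if missing_fits:
        raise ValueError(
            f"subject {dataset.subject_id}: missing M2 fits for blocks {missing_fits}"
        )
    hrp, z_rt, alpha, tau, pls = {}, {}, {}, {}, {}
    zero_var = False
    for b in blocks:
        recs = dataset.block_records(b)
        rts = np.array([r.rt_ms for r in recs if not r.missing and r.rt_ms is not None])
        mu = rts.mean() if rts.size else np.nan
        sd = rts.std(ddof=1) if rts.size > 1 else 0.0
        if rts.size and sd == 0.0:
            zero_var = True
        p = m2[b].params
        for cond in ("self", "other"):
            hrp[(b, cond)] = dataset.hrp(cond, b)
            cond_rts = [
                r.rt_ms
                for r in recs
                if not r.missing and r.rt_ms is not None and r.trial.condition == cond
            ]
            if cond_rts:
                z = (np.array(cond_rts) - mu) / sd if sd > 0 else np.zeros(len(cond_rts))
                z_rt[(b, cond)] = float(np.mean(z))
            else:
                z_rt[(b, cond)] = float("nan")
            a, t = p.for_condition(cond)
            alpha[(b, cond)] = a
            tau[(b, cond)] = t
        pls[b] = p.pls
    return SubjectSummary(
        subject=dataset.subject_id, group=dataset.group,
        hrp=hrp, z_rt=z_rt, alpha=alpha, tau=tau, pls=pls,
        label=categorize(pls[min(blocks)]), included=included,
        rt_zero_variance=zero_var,
    )


def summaries_to_long(
    summaries: list[SubjectSummary], measure: str = "alpha"
) -> pd.DataFrame:
    """Tidy long table (subject × block × reward) of one measure, with the
    between-subject factors attached — the input layout for the ANOVA."""
    rows = []
    for s in summaries:
        if not s.included:
            continue
        values = getattr(s, measure)
        for (block, cond), v in values.items():
            rows.append(
                {
                    "subject": s.subject, "group": s.group, "pls_group": s.label,
                    "block": block, "reward": cond, measure: v,
                }
            )
    return pd.DataFrame(rows)


def summaries_to_frame(summaries: list[SubjectSummary]) -> pd.DataFrame:
    """One row per subject: label, per-block PLS, per-cell α/τ/HRP/z-RT."""
    rows = []
    for s in summaries:
        row = {"subject": s.subject, "group": s.group, "label": s.label,
               "included": s.included}
        for b, v in s.pls.items():
            row[f"pls_b{b}"] = v
        for (b, c), v in s.alpha.items():
            row[f"alpha_{c}_b{b}"] = v
        for (b, c), v in s.tau.items():
            row[f"tau_{c}_b{b}"] = v
        for (b, c), v in s.hrp.items():
            row[f"hrp_{c}_b{b}"] = v
        for (b, c), v in s.z_rt.items():
            row[f"zrt_{c}_b{b}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mixed repeated-measures ANOVA

def _orthonormal_contrasts(n_levels: int) -> np.ndarray:
    """(n_levels × n_levels−1) matrix, columns orthonormal and orthogonal
    to the unit vector."""
    q, _ = np.linalg.qr(
        np.column_stack([np.ones(n_levels) / np.sqrt(n_levels), np.eye(n_levels)])
    )
    return q[:, 1:n_levels]


def _sum_coded_design(
    data: pd.DataFrame, between: list[str]
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Full-factorial effects-coded (deviation) design for the between
    factors. Returns the design matrix (intercept first) and, per term,
    the column indices belonging to that term."""
    pieces = {}
    for f in between:
        levels = sorted(data[f].unique())
        L = len(levels)
        # deviation coding: L-1 columns, last level coded -1
        cols = np.zeros((len(data), L - 1))
        for j, lev in enumerate(levels[:-1]):
            cols[:, j] = np.where(
                data[f] == lev, 1.0, np.where(data[f] == levels[-1], -1.0, 0.0)
            )
        pieces[f] = cols
    X_parts = [np.ones((len(data), 1))]
    term_cols: dict[str, np.ndarray] = {"Intercept": np.array([0])}
    start = 1
    for r in range(1, len(between) + 1):
        for combo in itertools.combinations(between, r):
            block = pieces[combo[0]]
            for f in combo[1:]:
                # interaction columns: all pairwise products
                block = np.concatenate(
                    [block[:, [i]] * pieces[f] for i in range(block.shape[1])], axis=1
                )
            X_parts.append(block)
            idx = np.arange(start, start + block.shape[1])
            term_cols[" x ".join(combo)] = idx
            start += block.shape[1]
    return np.concatenate(X_parts, axis=1), term_cols


def _type3_ss(X: np.ndarray, term_cols: dict[str, np.ndarray],
              Y: np.ndarray) -> tuple[dict[str, float], float]:
    """Type III sums of squares (summed over the columns of Y) for every
    term of the effects-coded design, plus the pooled residual SS."""
    def rss(A: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(A, Y, rcond=None)
        resid = Y - A @ beta
        return float(np.sum(resid ** 2))

    rss_full = rss(X)
    ss = {}
    for term, idx in term_cols.items():
        keep = np.setdiff1d(np.arange(X.shape[1]), idx)
        ss[term] = rss(X[:, keep]) - rss_full
    return ss, rss_full


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str = "subject",
    between: list[str] | tuple[str, ...] = (),
    within: list[str] | tuple[str, ...] = (),
) -> pd.DataFrame:
    """Mixed-design repeated-measures ANOVA (sphericity-assumed).

    ``data`` is long: one row per subject × within-cell. Every subject
    must have exactly one observation in every within-cell (balanced
    within); between-cells may be unbalanced (Type III tests). Returns a
    table with one row per effect: F, numerator/denominator df, p and
    partial eta squared.
    """
    between = list(between)
    within = list(within)
    if not within:
        raise ValueError("at least one within-subject factor is required")
    w_levels = {f: sorted(data[f].unique()) for f in within}
    n_cells_w = int(np.prod([len(w_levels[f]) for f in within]))

    # balance check: each subject has each within-cell exactly once
    counts = data.groupby([subject] + within, sort=True).size()
    bad = sorted(
        {
            s
            for s, c in counts.groupby(level=0).size().items()
            if c != n_cells_w
        }
        | {s for (s, *_), c in counts.items() if c != 1}
    )
    if bad:
        raise ValueError(f"unbalanced within-subject cells for subjects: {bad}")

    # subject-level between info and wide response matrix
    cell_order = list(itertools.product(*[w_levels[f] for f in within]))
    wide = data.pivot_table(
        index=subject, columns=within, values=dv, sort=True
    )
    wide = wide.reindex(
        columns=cell_order if len(within) > 1 else [c[0] for c in cell_order]
    )
    if between:
        dup = data[[subject] + between].drop_duplicates()
        if dup[subject].duplicated().any():
            raise ValueError("a subject appears in more than one between-cell")
        subj_info = dup.set_index(subject).loc[wide.index]
        cell_sizes = subj_info.groupby(between).size()
        if (cell_sizes < 2).any():
            raise ValueError(
                f"between-cells with fewer than 2 subjects: "
                f"{cell_sizes[cell_sizes < 2].index.tolist()}"
            )
    else:
        subj_info = pd.DataFrame(index=wide.index)
    n_subj = wide.shape[0]
    Y = wide.to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise ValueError("missing cells in the response matrix")

    if between:
        X, term_cols = _sum_coded_design(subj_info.reset_index(), between)
    else:
        X = np.ones((n_subj, 1))
        term_cols = {"Intercept": np.array([0])}
    p_between = X.shape[1]
    df_err_between = n_subj - p_between

    contrasts = {f: _orthonormal_contrasts(len(w_levels[f])) for f in within}
    unit = {f: np.ones((len(w_levels[f]), 1)) / np.sqrt(len(w_levels[f])) for f in within}

    rows = []

    def add_row(name, ss_h, df_h, ss_e, df_e):
        flag = ""
        if ss_e <= 1e-12:
            flag = "zero error variance"
            f_stat = 0.0 if ss_h <= 1e-12 else np.inf
            p = np.nan
        else:
            f_stat = (ss_h / df_h) / (ss_e / df_e)
            f_stat = max(f_stat, 0.0)
            p = float(sps.f.sf(f_stat, df_h, df_e))
        pes = ss_h / (ss_h + ss_e) if (ss_h + ss_e) > 0 else 0.0
        rows.append(
            {
                "effect": name, "df_num": df_h, "df_den": df_e,
                "F": float(f_stat), "p": p, "partial_eta_sq": float(pes),
                "flag": flag,
            }
        )

    # between-subjects effects: responses averaged over within-cells
    m = Y.shape[1]
    y0 = Y @ (np.ones((m, 1)) / np.sqrt(m))
    ss0, rss0 = _type3_ss(X, term_cols, y0)
    for term, idx in term_cols.items():
        if term == "Intercept":
            continue
        add_row(term, ss0[term], len(idx), rss0, df_err_between)

    # within effects and their interactions with between terms
    for r in range(1, len(within) + 1):
        for combo in itertools.combinations(within, r):
            mats = [contrasts[f] if f in combo else unit[f] for f in within]
            C = mats[0]
            for mmat in mats[1:]:
                C = np.kron(C, mmat)
            q = C.shape[1]
            Yc = Y @ C
            ss, rss_w = _type3_ss(X, term_cols, Yc)
            w_name = " x ".join(combo)
            df_e = df_err_between * q
            add_row(w_name, ss["Intercept"], q, rss_w, df_e)
            for term, idx in term_cols.items():
                if term == "Intercept":
                    continue
                add_row(f"{term} x {w_name}", ss[term], len(idx) * q, rss_w, df_e)

    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# post-hocs, basic tests, bootstrap

def posthoc_paired(
    contrasts: list[tuple[str, np.ndarray, np.ndarray]]
) -> pd.DataFrame:
    """Paired t-tests with Benjamini–Hochberg step-up adjustment across
    the contrast family. Each contrast is (label, x, y) with x, y paired."""
    if not contrasts:
        raise ValueError("empty contrast family")
    rows = []
    for label, x, y in contrasts:
        x, y = np.asarray(x, float), np.asarray(y, float)
        if x.shape != y.shape or x.size < 2:
            raise ValueError(f"contrast {label!r}: need >= 2 pairs")
        t, p = sps.ttest_rel(x, y)
        rows.append({"contrast": label, "t": float(t), "df": x.size - 1,
                     "p_raw": float(p)})
    df = pd.DataFrame(rows)
    df["p_fdr"] = multipletests(df["p_raw"], method="fdr_bh")[1]
    return df


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(p_values, float), method="fdr_bh")[1]


@dataclass
class TestRecord:
    name: str
    statistic: float
    df: float
    p: float
    flag: str = ""


def one_sample_t(x, popmean: float, name: str = "one-sample t") -> TestRecord:
    x = np.asarray(x, float)
    if np.std(x, ddof=1) == 0:
        return TestRecord(name, 0.0 if x.mean() == popmean else np.inf,
                          x.size - 1, np.nan, "zero variance")
    t, p = sps.ttest_1samp(x, popmean)
    return TestRecord(name, float(t), x.size - 1, float(p))


def paired_t(x, y, name: str = "paired t") -> TestRecord:
    d = np.asarray(x, float) - np.asarray(y, float)
    return one_sample_t(d, 0.0, name)


def independent_t(x, y, name: str = "independent t") -> TestRecord:
    x, y = np.asarray(x, float), np.asarray(y, float)
    if np.std(x, ddof=1) == 0 and np.std(y, ddof=1) == 0:
        return TestRecord(name, 0.0 if x.mean() == y.mean() else np.inf,
                          x.size + y.size - 2, np.nan, "zero variance")
    t, p = sps.ttest_ind(x, y)
    return TestRecord(name, float(t), x.size + y.size - 2, float(p))


def pearson_corr(x, y, name: str = "pearson r") -> TestRecord:
    x, y = np.asarray(x, float), np.asarray(y, float)
    if np.std(x) == 0 or np.std(y) == 0:
        return TestRecord(name, np.nan, x.size - 2, np.nan, "zero variance")
    r, p = sps.pearsonr(x, y)
    return TestRecord(name, float(r), x.size - 2, float(p))


def bootstrap_diff(
    sample_a,
    sample_b,
    n_boot: int = 1000,
    seed: int | np.random.SeedSequence = 0,
) -> dict:
    """Percentile bootstrap of the difference in means (a − b).

    Resamples each group with replacement ``n_boot`` times; reports the
    observed difference, the 95% percentile interval, and a two-sided
    bootstrap p (twice the smaller tail fraction of the bootstrap
    distribution relative to zero). Deterministic given ``seed``.
    """
    a, b = np.asarray(sample_a, float), np.asarray(sample_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    flag = "n_boot below 100: unstable" if n_boot < 100 else ""
    rng = np.random.default_rng(seed)
    idx_a = rng.integers(0, a.size, size=(n_boot, a.size))
    idx_b = rng.integers(0, b.size, size=(n_boot, b.size))
    boots = a[idx_a].mean(axis=1) - b[idx_b].mean(axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    p = 2.0 * min(np.mean(boots <= 0.0), np.mean(boots >= 0.0))
    return {
        "diff": float(a.mean() - b.mean()),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "p_boot": float(min(p, 1.0)),
        "n_boot": n_boot,
        "flag": flag,
    }


def default_posthoc_family(
    long_alpha: pd.DataFrame, arm: str = "OBS"
) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """The block-1 → block-2 learning-rate contrasts tested together:
    {self, other} × {Selfish, Prosocial} within one observation arm."""
    fam = []
    for label in LABELS:
        for cond in ("self", "other"):
            sub = long_alpha[
                (long_alpha.group == arm)
                & (long_alpha.pls_group == label)
                & (long_alpha.reward == cond)
            ]
            wide = sub.pivot(index="subject", columns="block", values="alpha")
            if wide.shape[0] >= 2 and {1, 2} <= set(wide.columns):
                fam.append(
                    (
                        f"{arm}-{label} {cond}: block1 vs block2",
                        wide[1].to_numpy(),
                        wide[2].to_numpy(),
                    )
                )
    return fam
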