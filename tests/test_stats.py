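"""Subject summaries, mixed ANOVA, FDR post-hocs, basic tests, bootstrap."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from prlearn.fitting import FitResult, bic
from prlearn.rl import ChoiceRecord, ParamSetSeparate, SubjectDataset
from prlearn.stats import (
    bh_adjust,
    bootstrap_diff,
    categorize,
    independent_t,
    mixed_anova,
    one_sample_t,
    paired_t,
    pearson_corr,
    posthoc_paired,
    summarize_subject,
)
from prlearn.task import TaskConfig, build_schedule


# ---------------------------------------------------------------------------
# categorization and summaries

def test_categorization_rule_and_boundary():
    assert categorize(-0.2) == "Selfish"
    assert categorize(0.0) == "Prosocial"  # tie goes to Prosocial
    assert categorize(0.4) == "Prosocial"


def _subject_with_fits(alpha_self=0.5, alpha_other=0.3, rt_constant=None):
    sched = build_schedule(TaskConfig(n_blocks=3, trials_per_condition=4))
    records = []
    rng = np.random.default_rng(1)
    for t in sched.trials:
        rt = rt_constant if rt_constant is not None else float(rng.uniform(400, 900))
        records.append(ChoiceRecord(trial=t, chosen="a", reward=1, rt_ms=rt))
    ds = SubjectDataset(subject_id="S1", group="OBS", records=records)
    fits = [
        FitResult(
            subject="S1", block=b, model="M2",
            params=ParamSetSeparate(alpha_self, alpha_other, 3.0, 3.0),
            nll=5.0, n_trials=8, k=4, bic=bic(5.0, 4, 8), n_starts=0,
            converged=True,
        )
        for b in (1, 2, 3)
    ]
    return ds, fits


def test_summary_pls_arithmetic_and_label():
    ds, fits = _subject_with_fits(alpha_self=0.5, alpha_other=0.3)
    s = summarize_subject(fits, ds)
    assert s.pls[1] == pytest.approx(-0.2)
    assert s.label == "Selfish"


def test_constant_rts_zscore_to_zero_with_flag():
    ds, fits = _subject_with_fits(rt_constant=650.0)
    s = summarize_subject(fits, ds)
    assert s.rt_zero_variance
    assert all(v == 0.0 for v in s.z_rt.values())


def test_missing_block_fits_rejected():
    ds, fits = _subject_with_fits()
    with pytest.raises(ValueError, match="blocks \\[3\\]"):
        summarize_subject(fits[:2], ds)


# ---------------------------------------------------------------------------
# mixed ANOVA

def _balanced_2b2w(n_per_cell=3, effect=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for b1 in ("p", "q"):
        for b2 in ("u", "v"):
            for i in range(n_per_cell):
                s = f"{b1}{b2}{i}"
                base = rng.normal(0, 1)
                for w1 in ("l", "r"):
                    for w2 in ("x", "z"):
                        y = base + rng.normal(0, 1)
                        if b1 == "p" and w1 == "l":
                            y += effect
                        rows.append(
                            {"subject": s, "b1": b1, "b2": b2,
                             "w1": w1, "w2": w2, "y": y}
                        )
    return pd.DataFrame(rows)


def _brute_force_2b2w(df):
    """Independent sums-of-squares oracle for the balanced all-2-level
    mixed design, via +/-1 contrast scores per subject."""
    wide = df.pivot_table(index=["subject", "b1", "b2"], columns=["w1", "w2"],
                          values="y").reset_index()
    y = wide[[("l", "x"), ("l", "z"), ("r", "x"), ("r", "z")]].to_numpy()
    scores = {
        (): y.mean(axis=1),
        ("w1",): (y[:, 0] + y[:, 1] - y[:, 2] - y[:, 3]) / 4,
        ("w2",): (y[:, 0] - y[:, 1] + y[:, 2] - y[:, 3]) / 4,
        ("w1", "w2"): (y[:, 0] - y[:, 1] - y[:, 2] + y[:, 3]) / 4,
    }
    c1 = np.where(wide["b1"] == "p", 1.0, -1.0)
    c2 = np.where(wide["b2"] == "u", 1.0, -1.0)
    codes = {(): np.ones(len(wide)), ("b1",): c1, ("b2",): c2, ("b1", "b2"): c1 * c2}
    n = len(wide)
    out = {}
    for w_key, z in scores.items():
        # between-cell means of z for the error term
        cell_mean = (
            pd.DataFrame({"b1": wide["b1"], "b2": wide["b2"], "z": z})
            .groupby(["b1", "b2"])["z"].transform("mean").to_numpy()
        )
        ss_err = float(np.sum((z - cell_mean) ** 2))
        df_err = n - 4
        for b_key, c in codes.items():
            ss = float(np.sum(c * z) ** 2 / n)
            name = tuple(b_key) + tuple(w_key)
            if name == ():
                continue  # grand mean
            f = (ss / 1.0) / (ss_err / df_err)
            out[name] = (f, ss, ss_err, df_err)
    return out


def test_mixed_anova_matches_brute_force_on_balanced_design():
    df = _balanced_2b2w(n_per_cell=3, effect=1.2, seed=5)
    ours = mixed_anova(df, dv="y", between=["b1", "b2"], within=["w1", "w2"])
    oracle = _brute_force_2b2w(df)
    name_map = {
        ("b1",): "b1", ("b2",): "b2", ("b1", "b2"): "b1 x b2",
        ("w1",): "w1", ("w2",): "w2", ("w1", "w2"): "w1 x w2",
        ("b1", "w1"): "b1 x w1", ("b1", "w2"): "b1 x w2",
        ("b2", "w1"): "b2 x w1", ("b2", "w2"): "b2 x w2",
        ("b1", "b2", "w1"): "b1 x b2 x w1",
        ("b1", "b2", "w2"): "b1 x b2 x w2",
        ("b1", "w1", "w2"): "b1 x w1 x w2",
        ("b2", "w1", "w2"): "b2 x w1 x w2",
        ("b1", "b2", "w1", "w2"): "b1 x b2 x w1 x w2",
    }
    for key, label in name_map.items():
        f_oracle = oracle[key][0]
        f_ours = float(ours.loc[ours.effect == label, "F"].iloc[0])
        assert f_ours == pytest.approx(f_oracle, abs=1e-8), label


def test_mixed_anova_matches_pingouin_on_unbalanced_groups():
    import pingouin as pg

    rng = np.random.default_rng(99)
    rows = []
    for g, n in (("A", 12), ("B", 15)):
        for i in range(n):
            s = f"{g}{i}"
            base = rng.normal(0, 1)
            for w, lev in enumerate(("w1", "w2", "w3")):
                rows.append(
                    {"subject": s, "grp": g, "w": lev,
                     "y": base + 0.4 * w + (0.5 if g == "A" else 0) * w
                     + rng.normal(0, 1)}
                )
    df = pd.DataFrame(rows)
    ours = mixed_anova(df, dv="y", between=["grp"], within=["w"])
    theirs = pg.mixed_anova(df, dv="y", within="w", subject="subject", between="grp")
    # between main effect and the interaction are coding-invariant and
    # must agree exactly; pingouin's within main effect uses weighted
    # (unbalanced) means rather than Type III, so it is not compared
    f_between = float(theirs.loc[theirs.Source == "grp", "F"].iloc[0])
    f_inter = float(theirs.loc[theirs.Source == "Interaction", "F"].iloc[0])
    assert float(ours.loc[ours.effect == "grp", "F"].iloc[0]) == pytest.approx(
        f_between, abs=1e-8
    )
    assert float(ours.loc[ours.effect == "grp x w", "F"].iloc[0]) == pytest.approx(
        f_inter, abs=1e-8
    )


R_ORACLE = """
suppressMessages(library(car))
w <- read.csv(commandArgs(TRUE)[1])
Y <- as.matrix(w[, 3:8])
idata <- data.frame(block = factor(rep(1:3, each = 2)),
                    rew = factor(rep(c("x", "z"), 3)))
options(contrasts = c("contr.sum", "contr.poly"))
mod <- lm(Y ~ g1 * g2, data = w)
a <- Anova(mod, idata = idata, idesign = ~ block * rew, type = 3)
u <- summary(a, multivariate = FALSE)$univariate.tests
write.csv(as.data.frame(unclass(u)), commandArgs(TRUE)[2])
"""


def test_mixed_anova_matches_r_car_type3(tmp_path):
    """Full 2x2 between x 3x2 within cross-check against car::Anova
    (the SPSS-equivalent Type III univariate mixed ANOVA)."""
    rng = np.random.default_rng(4)
    rows = []
    for g1 in ("O", "C"):
        for g2 in ("S", "P"):
            n = {"OS": 7, "OP": 4, "CS": 8, "CP": 5}[g1 + g2]
            for i in range(n):
                s = f"{g1}{g2}{i}"
                base = rng.normal(0, 1)
                for b in (1, 2, 3):
                    for r_ in ("x", "z"):
                        eff = 0.9 if (g1 == "O" and g2 == "S" and b == 2
                                      and r_ == "z") else 0.0
                        rows.append({"subject": s, "g1": g1, "g2": g2,
                                     "block": b, "rew": r_,
                                     "y": base + 0.2 * b + eff + rng.normal(0, 0.8)})
    df = pd.DataFrame(rows)
    ours = mixed_anova(df, dv="y", between=["g1", "g2"], within=["block", "rew"])

    wide = df.pivot_table(index=["subject", "g1", "g2"], columns=["block", "rew"],
                          values="y")
    wide = wide.reindex(columns=[(b, r_) for b in (1, 2, 3) for r_ in ("x", "z")])
    wide.columns = [f"y{b}{r_}" for b, r_ in wide.columns]
    csv_in = tmp_path / "wide.csv"
    csv_out = tmp_path / "anova.csv"
    wide.reset_index().drop(columns="subject").to_csv(csv_in, index=False)
    script = tmp_path / "oracle.R"
    script.write_text(R_ORACLE)
    subprocess.run(
        ["Rscript", str(script), str(csv_in), str(csv_out)],
        check=True, capture_output=True,
    )
    r_table = pd.read_csv(csv_out, index_col=0)
    name_map = {
        "g1": "g1", "g2": "g2", "g1:g2": "g1 x g2",
        "block": "block", "g1:block": "g1 x block", "g2:block": "g2 x block",
        "g1:g2:block": "g1 x g2 x block",
        "rew": "rew", "g1:rew": "g1 x rew", "g2:rew": "g2 x rew",
        "g1:g2:rew": "g1 x g2 x rew",
        "block:rew": "block x rew", "g1:block:rew": "g1 x block x rew",
        "g2:block:rew": "g2 x block x rew",
        "g1:g2:block:rew": "g1 x g2 x block x rew",
    }
    for r_name, our_name in name_map.items():
        f_r = float(r_table.loc[r_name, "F value"])
        f_ours = float(ours.loc[ours.effect == our_name, "F"].iloc[0])
        assert f_ours == pytest.approx(f_r, rel=1e-6), our_name


def test_constant_responses_flagged_zero_variance():
    rows = [
        {"subject": f"{g}{i}", "b1": g, "w1": w, "y": 5.0}
        for g in ("p", "q") for i in range(3) for w in ("l", "r")
    ]
    res = mixed_anova(pd.DataFrame(rows), dv="y", between=["b1"], within=["w1"])
    assert (res.flag == "zero error variance").all()
    assert (res.F == 0).all()


def test_duplicated_groups_give_zero_between_f():
    rng = np.random.default_rng(2)
    rows = []
    for i in range(6):
        base = rng.normal(0, 1)
        vals = {w: base + rng.normal(0, 1) for w in ("x", "z")}
        for g in ("A", "B"):  # same data duplicated under both labels
            for w, y in vals.items():
                rows.append({"subject": f"{g}{i}", "grp": g, "w": w, "y": y})
    res = mixed_anova(pd.DataFrame(rows), dv="y", between=["grp"], within=["w"])
    assert float(res.loc[res.effect == "grp", "F"].iloc[0]) == pytest.approx(0, abs=1e-18)


def test_unbalanced_within_cells_rejected_with_subjects():
    df = _balanced_2b2w(n_per_cell=2, seed=3)
    df = df[~((df.subject == "pu0") & (df.w1 == "l") & (df.w2 == "x"))]
    with pytest.raises(ValueError, match="pu0"):
        mixed_anova(df, dv="y", between=["b1", "b2"], within=["w1", "w2"])


# ---------------------------------------------------------------------------
# BH-FDR post-hocs

def test_bh_step_up_on_worked_p_set():
    adj = bh_adjust([0.01, 0.02, 0.04, 0.60])
    assert adj == pytest.approx([0.04, 0.04, 0.04 * 4 / 3, 0.60])


def test_bh_ties_and_single_contrast():
    assert bh_adjust([0.3, 0.3, 0.3]) == pytest.approx([0.3, 0.3, 0.3])
    assert bh_adjust([0.123]) == pytest.approx([0.123])


def test_bh_adjusted_p_bounded_by_raw_and_one(rng):
    p = rng.uniform(0, 1, size=20)
    adj = bh_adjust(p)
    order = np.argsort(p)
    assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)
    assert np.all(np.diff(adj[order]) >= -1e-15)  # monotone under step-up order


def test_posthoc_paired_family():
    rng = np.random.default_rng(6)
    x = rng.normal(0, 1, 20)
    fam = [
        ("shifted", x + 0.9, x),
        ("null", x, x + rng.normal(0, 0.1, 20)),
    ]
    res = posthoc_paired(fam)
    assert set(res.columns) >= {"contrast", "t", "df", "p_raw", "p_fdr"}
    assert (res.p_fdr >= res.p_raw - 1e-15).all()
    assert res.loc[res.contrast == "shifted", "p_fdr"].iloc[0] < 0.01

    with pytest.raises(ValueError):
        posthoc_paired([])
    with pytest.raises(ValueError, match="pairs"):
        posthoc_paired([("tiny", np.array([1.0]), np.array([2.0]))])


# ---------------------------------------------------------------------------
# basic tests and bootstrap

def test_basic_test_battery_degenerate_and_trivial_cases():
    r = one_sample_t([0.5, 0.5, 0.5], 0.5)
    assert r.flag == "zero variance" and r.statistic == 0.0

    x = np.array([1.0, 2.0, 3.0, 4.0])
    assert pearson_corr(x, x).statistic == pytest.approx(1.0)

    d = paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])  # constant difference
    assert d.flag == "zero variance" and np.isinf(d.statistic)

    t = independent_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t.statistic == pytest.approx(0.0)


class TestBootstrap:
    def test_identical_samples_cover_zero(self):
        x = np.arange(10.0)
        res = bootstrap_diff(x, x, n_boot=1000, seed=1)
        assert res["ci_low"] <= 0.0 <= res["ci_high"]
        assert res["p_boot"] > 0.5

    def test_separated_samples_reject(self):
        rng = np.random.default_rng(3)
        a = rng.normal(10, 0.1, 15)
        b = rng.normal(0, 0.1, 15)
        res = bootstrap_diff(a, b, n_boot=1000, seed=1)
        assert res["p_boot"] < 0.01
        assert res["ci_low"] > 0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 12)
        r1 = bootstrap_diff(a, b, n_boot=500, seed=77)
        r2 = bootstrap_diff(a, b, n_boot=500, seed=77)
        assert r1 == r2

    def test_small_n_boot_flagged(self):
        res = bootstrap_diff([1.0, 2.0], [1.5, 2.5], n_boot=50, seed=0)
        assert "unstable" in res["flag"]

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_diff([], [1.0], seed=0)
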