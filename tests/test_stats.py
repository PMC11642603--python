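"""Behavioural statistics: Wilcoxon, t-tests, congruency effect, LMM, GLM."""

import subprocess
import sys

import numpy as np
import pandas as pd
import pytest

from dyaddraw.stats import (
    LMMConvergenceError,
    ModelSpec,
    StatResult,
    ZeroVarianceError,
    congruency_effect,
    fit_count_glm,
    fit_lmm,
    one_sample_t,
    paired_t,
    wilcoxon_signed_rank,
)


class TestWilcoxon:
    def test_all_zero_differences_error(self):
        a = np.arange(5.0) + 1
        with pytest.raises(ZeroVarianceError):
            wilcoxon_signed_rank(a, a)

    def test_exact_one_sided_p_for_six_positive_differences(self):
        """All 6 differences positive: one-sided exact p = 1/2^6 = 1/64."""
        b = np.zeros(6)
        a = np.array([1.0, 2, 3, 4, 5, 6])
        res = wilcoxon_signed_rank(a, b, alternative="greater")
        assert res.p == pytest.approx(1 / 64)
        assert res.effect_size == 1.0  # CLES: every a_i > b_i

    def test_symmetric_differences_near_null(self, rng):
        b = np.zeros(60)
        a = np.tile([1.0, -1.0], 30)
        res = wilcoxon_signed_rank(a, b)
        assert res.p > 0.5
        assert res.effect_size == pytest.approx(0.5)


class TestOneSampleT:
    def test_mean_equal_to_mu0_gives_t_zero(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0]) - 3.0
        res = one_sample_t(vals, 0.0, bayes=False)
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_t(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = one_sample_t(vals, 0.0, bayes=True)
        sd = np.std(vals, ddof=1)
        assert res.statistic == pytest.approx(vals.mean() / (sd / np.sqrt(5)))
        assert res.effect_size == pytest.approx(vals.mean() / sd)
        assert res.df == 4
        assert res.bf10 > 1  # clear effect

    def test_zero_variance_error(self):
        with pytest.raises(ZeroVarianceError):
            one_sample_t(np.full(10, 3.0), 0.0)

    def test_one_tailed_is_half_two_tailed_in_hypothesized_direction(self, rng):
        for _ in range(20):
            vals = rng.normal(0.3, 1.0, 15)
            if vals.mean() <= 0:
                continue
            two = one_sample_t(vals, 0.0, "two-sided", bayes=False).p
            one = one_sample_t(vals, 0.0, "greater", bayes=False).p
            assert one == pytest.approx(two / 2)

    def test_jzs_bayes_factor_matches_pingouin(self):
        import pingouin as pg

        vals = np.array([0.3, 0.5, -0.1, 0.8, 0.2, 0.4, 0.6, 0.1, 0.35, 0.55])
        res = one_sample_t(vals, 0.0)
        ref = float(pg.bayesfactor_ttest(res.statistic, len(vals), paired=False, r=0.707))
        assert res.bf10 == pytest.approx(ref, rel=1e-3)


class TestCongruencyEffect:
    @staticmethod
    def _records(rng, n_sub=12, shift_parallel=0.0, n=20):
        rows = []
        for s in range(n_sub):
            base = rng.normal(0, 0.3)
            for cx in ("Joint", "Parallel"):
                for cg in ("congruent", "incongruent"):
                    mu = base + (
                        shift_parallel if (cx, cg) == ("Parallel", "incongruent") else 0.0
                    )
                    for _ in range(n):
                        rows.append(
                            dict(subject=s, context=cx, congruency=cg,
                                 area_boxcox=mu + rng.normal(0, 1))
                        )
        return pd.DataFrame(rows)

    def test_null_effects_near_zero(self, rng):
        eff, res = congruency_effect(self._records(rng))
        assert abs(eff["effect"].mean()) < 0.2
        assert res.p > 0.01

    def test_planted_parallel_incongruent_shift_detected(self, rng):
        eff, res = congruency_effect(self._records(rng, n_sub=20, shift_parallel=1.0))
        par = eff.loc[eff.context == "Parallel", "effect"].mean()
        joi = eff.loc[eff.context == "Joint", "effect"].mean()
        assert par > joi
        assert res.p < 0.05

    def test_single_subject_errors(self, rng):
        df = self._records(rng, n_sub=1)
        with pytest.raises(ValueError):
            congruency_effect(df)


def _simulate_lmm(rng, n_sub=12, n_per_cell=8, b_ctx=0.0, b_cong=0.0, b_int=0.0,
                  tau=0.5, sigma=1.0):
    rows = []
    for s in range(n_sub):
        u = rng.normal(0, tau)
        for cx, xc in (("Joint", -1), ("Parallel", 1)):
            for cg, xg in (("congruent", -1), ("incongruent", 1)):
                mu = 1.0 + b_ctx * xc + b_cong * xg + b_int * xc * xg + u
                for _ in range(n_per_cell):
                    rows.append(dict(subject=s, context=cx, congruency=cg,
                                     y=mu + rng.normal(0, sigma)))
    return pd.DataFrame(rows)


SPEC = ModelSpec(response="y", fixed=["context", "congruency"], random="subject")


class TestLMM:
    def test_matches_lmerTest_oracle(self, rng, tmp_path):
        """beta, SE, Satterthwaite df and p agree with lmerTest (R)."""
        df = _simulate_lmm(rng, b_ctx=0.3, b_cong=-0.2, b_int=0.1)
        res = fit_lmm(df, SPEC)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        rscript = f"""
        suppressMessages(library(lmerTest))
        d <- read.csv("{csv}")
        d$context <- factor(d$context); d$congruency <- factor(d$congruency)
        contrasts(d$context) <- c(-1, 1); contrasts(d$congruency) <- c(-1, 1)
        m <- lmer(y ~ context * congruency + (1|subject), data=d, REML=TRUE)
        write.csv(summary(m)$coefficients, "{tmp_path}/out.csv")
        """
        r = subprocess.run(["Rscript", "-e", rscript], capture_output=True, text=True)
        assert r.returncode == 0, r.stderr
        ref = pd.read_csv(tmp_path / "out.csv", index_col=0)
        pairs = {
            "Intercept": "(Intercept)", "context": "context1",
            "congruency": "congruency1", "context:congruency": "context1:congruency1",
        }
        for mine, theirs in pairs.items():
            row = ref.loc[theirs]
            assert res[mine].extra["beta"] == pytest.approx(row["Estimate"], abs=1e-5)
            assert res[mine].extra["se"] == pytest.approx(row["Std. Error"], abs=1e-5)
            assert res[mine].df == pytest.approx(row["df"], rel=0.02)
            assert res[mine].p == pytest.approx(row["Pr(>|t|)"], rel=0.02, abs=1e-6)

    def test_null_coefficient_coverage(self):
        """95% CIs cover zero in >= 93% of null simulations per coefficient.

        Simulated at 12 subjects x 8 observations per cell, where the
        Satterthwaite approximation is accurate; rare non-convergent
        replicates are excluded (the fit refuses rather than degrades).
        """
        cover = {"context": 0, "congruency": 0, "context:congruency": 0}
        ok = 0
        for i in range(100):
            rng = np.random.default_rng(5000 + i)
            df = _simulate_lmm(rng, n_sub=12, n_per_cell=8)
            try:
                res = fit_lmm(df, SPEC)
            except LMMConvergenceError:
                continue
            ok += 1
            for name in cover:
                lo, hi = res[name].ci95
                cover[name] += lo <= 0.0 <= hi
        assert ok >= 90
        for name, c in cover.items():
            assert c / ok >= 0.93, f"{name}: coverage {c}/{ok}"

    def test_planted_context_effect_recovered(self):
        """beta = -0.5 planted: CI covers it in >= 93% of simulations."""
        hits = 0
        ok = 0
        for i in range(100):
            rng = np.random.default_rng(7000 + i)
            df = _simulate_lmm(rng, n_sub=12, n_per_cell=8, b_ctx=-0.5)
            try:
                res = fit_lmm(df, SPEC)
            except LMMConvergenceError:
                continue
            ok += 1
            lo, hi = res["context"].ci95
            hits += lo <= -0.5 <= hi
        assert ok >= 90
        assert hits / ok >= 0.93

    def test_zero_random_intercept_variance_boundary(self, rng):
        df = _simulate_lmm(rng, n_sub=10, n_per_cell=10, tau=0.0)
        res = fit_lmm(df, SPEC)
        assert res["_variance"].extra["tau2"] < 0.05

    def test_sum_coding_sign_invariance_under_relabeling(self, rng):
        df = _simulate_lmm(rng, b_ctx=0.4)
        res1 = fit_lmm(df, SPEC)
        flipped = df.replace({"context": {"Joint": "zJoint"}})  # reverses sort order
        res2 = fit_lmm(flipped, SPEC)
        assert abs(res1["context"].extra["beta"]) == pytest.approx(
            abs(res2["context"].extra["beta"]), abs=1e-8
        )
        assert res1["context"].p == pytest.approx(res2["context"].p, abs=1e-8)


class TestCountGLM:
    SPECP = ModelSpec(response="count", fixed=["context", "congruency"],
                      random="subject", family="poisson")

    @staticmethod
    def _counts(rng, n_sub=36, rate=2.0, ctx_ratio=1.0):
        rows = []
        for s in range(n_sub):
            for cx, xc in (("Joint", -1), ("Parallel", 1)):
                lam = rate * ctx_ratio ** (xc / 2)
                for cg in ("congruent", "incongruent"):
                    rows.append(dict(subject=s, context=cx, congruency=cg,
                                     count=rng.poisson(lam)))
        return pd.DataFrame(rows)

    def test_type_I_error_near_nominal(self):
        rej = 0
        n_sim = 500
        for i in range(n_sim):
            rng = np.random.default_rng(9000 + i)
            res = fit_count_glm(self._counts(rng), self.SPECP)
            rej += res["context"].p < 0.05
        assert abs(rej / n_sim - 0.05) < 0.025

    def test_power_for_rate_ratio_two(self):
        hits = 0
        for i in range(50):
            rng = np.random.default_rng(11000 + i)
            res = fit_count_glm(self._counts(rng, ctx_ratio=2.0), self.SPECP)
            hits += res["context"].p < 0.05
        assert hits >= 40  # >= 80%

    def test_degenerate_single_nonzero_cell_flagged_unstable(self):
        df = pd.DataFrame(
            dict(subject=list(range(4)) * 4,
                 context=["Joint"] * 8 + ["Parallel"] * 8,
                 congruency=(["congruent"] * 4 + ["incongruent"] * 4) * 2,
                 count=[5, 4, 6, 5] + [0] * 12)
        )
        res = fit_count_glm(df, self.SPECP)
        assert res["context"].extra["unstable"]

    def test_all_zero_counts_error(self):
        df = pd.DataFrame(dict(subject=[0, 0, 1, 1],
                               context=["Joint", "Parallel"] * 2,
                               congruency=["congruent"] * 4, count=[0, 0, 0, 0]))
        with pytest.raises(ZeroVarianceError):
            fit_count_glm(df, self.SPECP)
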