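"""Permutation engines, r_equivalent, GLMM, LRT, and the correlation rule."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from toj import inference
from toj.inference import (
    bias_accuracy_correlation,
    fit_binomial_glmm,
    lrt,
    perm_anova_oneway,
    perm_pearson,
    perm_t_one_sample,
    perm_t_two_sample,
    r_equivalent,
    wald_contrast,
)


class TestPermTOneSample:
    def test_exhaustive_worked_example(self):
        """[1,2,3,4] vs 0, one-tailed: the observed all-positive sign
        pattern is the most extreme of the 16, so p = 1/16."""
        res = perm_t_one_sample([1, 2, 3, 4], 0.0, tails="one")
        assert res.exhaustive and res.n_perm == 16
        assert res.p_perm == pytest.approx(1 / 16)
        assert res.df == 3

    def test_symmetric_values_give_p_one(self):
        res = perm_t_one_sample([-2, -1, 1, 2], 0.0, tails="two")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_perm == 1.0

    def test_shift_invariance(self):
        x = np.array([0.3, -1.2, 2.5, 0.9, 1.1])
        a = perm_t_one_sample(x, 0.5, tails="two", seed=1)
        b = perm_t_one_sample(x + 10, 10.5, tails="two", seed=1)
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_perm == b.p_perm

    def test_zero_variance_flagged(self):
        res = perm_t_one_sample([2.0, 2.0, 2.0, 2.0], 2.0)
        assert np.isnan(res.statistic)
        assert res.p_perm == 1.0
        assert "undefined" in res.note

    def test_monte_carlo_matches_exhaustive(self):
        """MC and exhaustive p agree within 3*sqrt(p(1-p)/n) on one dataset."""
        rng = np.random.default_rng(5)
        x = rng.normal(0.6, 1.0, 12)
        exact = perm_t_one_sample(x, 0.0, tails="two")
        assert exact.exhaustive
        # force the MC path by a larger synthetic sample of the same values
        t_obs = exact.statistic
        n_mc = 20_000
        signs = rng.integers(0, 2, size=(n_mc, len(x))) * 2 - 1
        flipped = signs * x
        t_null = flipped.mean(axis=1) / (flipped.std(axis=1, ddof=1) / np.sqrt(len(x)))
        p_mc = (np.sum(np.abs(t_null) >= abs(t_obs) - 1e-12) + 1) / (n_mc + 1)
        se = 3 * np.sqrt(exact.p_perm * (1 - exact.p_perm) / n_mc)
        assert abs(p_mc - exact.p_perm) < se + 1e-4


class TestPermTTwoSample:
    def test_identical_groups_give_p_one(self):
        res = perm_t_two_sample([1, 2, 3], [1, 2, 3], tails="two")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_perm == 1.0

    def test_exhaustive_worked_example(self):
        """[1,2] vs [10,11]: 2 of the 6 assignments give |t| as extreme."""
        res = perm_t_two_sample([1, 2], [10, 11], tails="two")
        assert res.exhaustive and res.n_perm == 6
        assert res.p_perm == pytest.approx(2 / 6)
        assert res.df == 2

    def test_swapping_groups_negates_t(self):
        a, b = [1.0, 2.0, 4.0], [3.0, 5.0, 6.0]
        r1 = perm_t_two_sample(a, b, tails="two", seed=3)
        r2 = perm_t_two_sample(b, a, tails="two", seed=3)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_perm == r2.p_perm

    def test_degenerate_identical_values_flagged(self):
        res = perm_t_two_sample([5, 5, 5], [5, 5, 5])
        assert "degenerate" in res.note


class TestPermAnova:
    def test_identical_groups_give_f_zero(self):
        res = perm_anova_oneway([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_perm == 1.0

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 8)
        f = perm_anova_oneway([a, b], n_perm=4000, seed=11)
        t = perm_t_two_sample(a, b, tails="two", n_perm=4000, seed=11)
        assert f.statistic == pytest.approx(t.statistic**2, rel=1e-9)
        # same permutation scheme: p-values agree to Monte-Carlo error
        assert abs(f.p_perm - t.p_perm) < 3 * np.sqrt(0.05 * 0.95 / 4000) + 1e-3

    def test_matches_scipy_f_statistic(self):
        rng = np.random.default_rng(9)
        groups = [rng.normal(m, 1, 7) for m in (0.0, 0.4, 1.0)]
        res = perm_anova_oneway(groups, n_perm=100, seed=1)
        f_ref = stats.f_oneway(*groups).statistic
        assert res.statistic == pytest.approx(f_ref, rel=1e-9)


class TestREquivalent:
    @pytest.mark.parametrize(
        "p,df,expected",
        [
            (0.009, 9, 0.69),  # one-sample, n = 10
            (0.033, 9, 0.57),
            (0.038, 9, 0.55),  # chi-square contrast, participants-based df
            (0.005, 18, 0.56),  # two-sample, 10 + 10
        ],
    )
    def test_reported_reconstructions(self, p, df, expected):
        assert r_equivalent(p, df) == pytest.approx(expected, abs=0.01)

    def test_p_half_gives_zero(self):
        assert r_equivalent(0.5, 9) == 0.0
        assert r_equivalent(0.7, 9) == 0.0

    def test_strictly_decreasing_in_p(self):
        ps = np.linspace(0.001, 0.49, 50)
        rs = [r_equivalent(p, 12) for p in ps]
        assert all(a > b for a, b in zip(rs, rs[1:]))
        assert all(0 <= r < 1 for r in rs)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            r_equivalent(0.0, 9)
        with pytest.raises(ValueError):
            r_equivalent(0.05, 0)


def simulate_glmm(rng, n_participants=12, n_trials=60, beta_group=0.0,
                  tau=0.5, intercept=0.2):
    rows = []
    for pid in range(n_participants):
        grp = "ctrl" if pid < n_participants // 2 else "clin"
        b = rng.normal(0, tau)
        eta = intercept + (beta_group if grp == "clin" else 0.0) + b
        y = rng.random(n_trials) < 1 / (1 + np.exp(-eta))
        rows += [
            {"participant_id": f"P{pid:02d}", "group": grp, "y": int(v)} for v in y
        ]
    return pd.DataFrame(rows)


class TestGLMM:
    def test_zero_variance_matches_plain_glm(self):
        """With no participant heterogeneity the AGQ fit collapses to an
        ordinary binomial GLM (independent statsmodels oracle)."""
        import statsmodels.api as sm

        df = simulate_glmm(np.random.default_rng(2), tau=0.0, beta_group=0.7)
        fit = fit_binomial_glmm(df, "y", ["group"])
        X = pd.DataFrame({
            "Intercept": 1.0,
            "group[ctrl]": (df["group"] == "ctrl").astype(float),
        })
        glm = sm.GLM(df["y"], X, family=sm.families.Binomial()).fit()
        assert fit.random_intercept_variance < 1e-4
        assert np.allclose(
            fit.fixed_effects.to_numpy(), glm.params.to_numpy(), atol=1e-4
        )

    def test_intercept_only_balanced_is_zero(self):
        rng = np.random.default_rng(4)
        rows = []
        for pid in range(10):
            y = np.concatenate([np.ones(30), np.zeros(30)])
            rows += [{"participant_id": f"P{pid}", "y": int(v)} for v in y]
        fit = fit_binomial_glmm(pd.DataFrame(rows), "y", [])
        assert fit.fixed_effects["Intercept"] == pytest.approx(0.0, abs=1e-6)

    def test_loglik_invariant_to_relabelling(self):
        rng = np.random.default_rng(6)
        df = simulate_glmm(rng, tau=0.6, beta_group=0.5)
        fit1 = fit_binomial_glmm(df, "y", ["group"])
        relabel = {p: f"Q{i:02d}" for i, p in
                   enumerate(reversed(sorted(df["participant_id"].unique())))}
        df2 = df.assign(participant_id=df["participant_id"].map(relabel))
        fit2 = fit_binomial_glmm(df2, "y", ["group"])
        assert fit1.log_marginal_likelihood == pytest.approx(
            fit2.log_marginal_likelihood, abs=1e-6
        )

    def test_loglik_stabilizes_with_quadrature_nodes(self):
        df = simulate_glmm(np.random.default_rng(7), tau=0.8, beta_group=0.4)
        lls = {}
        for q in (3, 7, 15, 25):
            lls[q] = fit_binomial_glmm(df, "y", ["group"], n_quad=q
                                       ).log_marginal_likelihood
        assert abs(lls[25] - lls[15]) < 1e-5
        assert abs(lls[25] - lls[15]) <= abs(lls[25] - lls[3]) + 1e-9

    def test_matches_lme4_glmer(self):
        """Independent oracle: lme4::glmer with AGQ on the same counts."""
        df = simulate_glmm(np.random.default_rng(12), tau=0.7, beta_group=0.9)
        agg = df.groupby(["participant_id", "group"])["y"].agg(["sum", "count"])
        agg = agg.reset_index()
        csv = agg.to_csv(index=False)
        script = textwrap.dedent("""
            suppressMessages(library(lme4))
            d <- read.csv("stdin")
            d$fail <- d$count - d$sum
            m <- glmer(cbind(sum, fail) ~ group + (1|participant_id),
                       family=binomial, data=d, nAGQ=15)
            cat(fixef(m), as.numeric(VarCorr(m)$participant_id), logLik(m), sep=",")
        """)
        try:
            out = subprocess.run(
                ["Rscript", "-e", script.replace('"stdin"', '"/dev/stdin"')],
                input=csv, capture_output=True, text=True, timeout=300, check=True,
            )
        except (FileNotFoundError, subprocess.SubprocessError):
            pytest.skip("Rscript/lme4 unavailable")
        b0, b1, tau2, _ll = map(float, out.stdout.strip().split(","))
        fit = fit_binomial_glmm(df, "y", ["group"])
        # glmer codes group by its own contrast; compare on the same scale
        assert fit.fixed_effects["Intercept"] == pytest.approx(b0, abs=2e-2)
        assert fit.fixed_effects["group[ctrl]"] == pytest.approx(b1, abs=2e-2)
        assert fit.random_intercept_variance == pytest.approx(tau2, abs=5e-2)

    def test_parameter_recovery_with_heterogeneity(self):
        """Group effect 0.8, tau^2 = 0.25: the estimate covers the truth."""
        rng = np.random.default_rng(13)
        hits = 0
        n_rep = 20
        for _ in range(n_rep):
            df = simulate_glmm(rng, n_participants=20, n_trials=160,
                               beta_group=0.8, tau=0.5)
            fit = fit_binomial_glmm(df, "y", ["group"])
            est = -fit.fixed_effects["group[ctrl]"]  # clin - ctrl on logit scale
            se = fit.se["group[ctrl]"]
            hits += abs(est - 0.8) <= 1.96 * se
        assert hits >= int(0.7 * n_rep)  # 95% CI coverage, small-replicate bound

    def test_log_link_supported(self):
        rng = np.random.default_rng(14)
        rows = []
        for pid in range(8):
            y = rng.random(50) < 0.3
            rows += [{"participant_id": f"P{pid}", "y": int(v)} for v in y]
        fit = fit_binomial_glmm(pd.DataFrame(rows), "y", [], link="log")
        assert fit.converged
        assert fit.fixed_effects["Intercept"] == pytest.approx(np.log(0.3), abs=0.15)


class TestLRTAndContrasts:
    def test_identical_models_give_zero(self):
        df = simulate_glmm(np.random.default_rng(3), beta_group=0.0, tau=0.4)
        full = fit_binomial_glmm(df, "y", ["group"])
        reduced = fit_binomial_glmm(df, "y", [])
        res = lrt(full, reduced, r_equiv_df=10)
        assert res.statistic >= 0
        assert 0 < res.p_perm <= 1

    def test_reported_chi_square_effect_size(self):
        """chi2(1) p = 0.038 with 10 participants -> r_equiv ~ 0.55."""
        df = simulate_glmm(np.random.default_rng(3), beta_group=0.0, tau=0.4)
        full = fit_binomial_glmm(df, "y", ["group"])
        reduced = fit_binomial_glmm(df, "y", [])
        res = lrt(full, reduced, r_equiv_df=9)
        assert res.df == 1
        assert r_equivalent(0.038, 9) == pytest.approx(0.55, abs=0.01)

    def test_wald_contrast_against_chance(self):
        rng = np.random.default_rng(15)
        rows = []
        for pid in range(10):
            y = rng.random(100) < 0.7
            rows += [{"participant_id": f"P{pid}", "y": int(v)} for v in y]
        fit = fit_binomial_glmm(pd.DataFrame(rows), "y", [])
        res = wald_contrast(fit, {"Intercept": 1.0}, value=0.0, r_equiv_df=9)
        assert res.p_perm < 0.01  # 0.7 is far from chance on the logit scale
        assert res.r_equiv > 0.5


class TestCorrelation:
    def test_perfect_decreasing_line(self):
        x = np.arange(10, dtype=float)
        res = perm_pearson(x, -2 * x + 3, tails="two", seed=1)
        assert res.statistic == pytest.approx(-1.0)
        assert res.p_perm < 0.01

    def test_group_exclusion_arithmetic(self):
        """{0.1,0.1,0.1,0.9}: the 0.9 sits 1.5 SDs out, so nothing is
        excluded at the 2.5 SD rule; a true outlier is."""
        df = pd.DataFrame({
            "group": ["A"] * 4,
            "bias": [0.1, 0.1, 0.1, 0.9],
            "accuracy": [0.8, 0.7, 0.75, 0.72],
        })
        v = np.array([0.1, 0.1, 0.1, 0.9])
        assert (0.9 - v.mean()) / v.std(ddof=1) == pytest.approx(1.5)
        _, pts = bias_accuracy_correlation(df, n_perm=200, seed=1)
        assert not pts["excluded"].any()

        bias2 = [0.10, 0.11, 0.09, 0.10, 0.12, 0.08, 0.11, 0.10, 0.09, 0.11, 0.10,
                 0.60]
        df2 = pd.DataFrame({
            "group": ["A"] * 12,
            "bias": bias2,
            "accuracy": np.linspace(0.7, 0.8, 12),
        })
        z = (0.60 - df2["bias"].mean()) / df2["bias"].std(ddof=1)
        assert z > 2.5  # the outlier survives its own inflation of the SD
        _, pts2 = bias_accuracy_correlation(df2, n_perm=200, seed=1)
        assert pts2["excluded"].sum() == 1
        assert pts2.loc[pts2["excluded"], "bias"].iloc[0] == 0.60

    def test_zero_variance_flagged(self):
        df = pd.DataFrame({
            "group": ["A"] * 5,
            "bias": [0.2] * 5,
            "accuracy": [0.6, 0.7, 0.8, 0.9, 0.5],
        })
        res, _ = bias_accuracy_correlation(df, n_perm=100, seed=2)
        assert np.isnan(res.statistic)
        assert res.p_perm == 1.0


class TestNullCalibration:
    """p-values are valid under the null (small-scale spot checks; the
    full-scale rejection-rate bands run in the acceptance suite)."""

    def test_one_sample_p_uniformity(self):
        rng = np.random.default_rng(20)
        ps = [
            perm_t_one_sample(rng.normal(0, 1, 10), 0.0, tails="two").p_perm
            for _ in range(300)
        ]
        d, p_ks = stats.kstest(ps, "uniform")
        assert p_ks > 0.01

    def test_pearson_null_rejection_rate(self):
        rng = np.random.default_rng(21)
        rej = 0
        n_rep = 300
        for i in range(n_rep):
            x, y = rng.normal(0, 1, 12), rng.normal(0, 1, 12)
            res = perm_pearson(x, y, tails="two", n_perm=500, seed=int(i))
            rej += res.p_perm <= 0.05
        assert 0.02 <= rej / n_rep <= 0.09
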