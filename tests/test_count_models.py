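"""Mixed count regressions, overdispersion diagnostics, model selection,
mixture clustering and rank-based regression."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from habitsim import count_models as cm

GROUPS = ("short", "extensive", "extensive_parallel")
MANIPS = ("control_pre", "devaluation", "control_post")


def simulate_counts(n_per_group, beta, sigma_b, seed, family="poisson",
                    disp=None):
    """Direct generative oracle for the mixed count model (independent of
    the agent simulator): eta = X beta + b_i, counts from the family."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in GROUPS:
        for i in range(n_per_group):
            b = rng.normal(0, sigma_b)
            for m in MANIPS:
                eta = (beta["Intercept"]
                       + beta.get(f"m:{m}", 0.0) + beta.get(f"g:{g}", 0.0)
                       + beta.get(f"i:{m}:{g}", 0.0))
                mu = np.exp(eta + b)
                if family == "poisson":
                    y = rng.poisson(mu)
                elif family == "nb1":
                    y = rng.negative_binomial(mu / disp, 1 / (1 + disp))
                elif family == "nb2":
                    y = rng.negative_binomial(disp, disp / (disp + mu))
                rows.append({"participant_id": f"{g}_{i:03d}", "group": g,
                             "manipulation": m, "entries": int(y)})
    return pd.DataFrame(rows)


TRUE_BETA = {"Intercept": 3.2, "m:devaluation": -1.5, "m:control_post": -0.2,
             "g:extensive": -0.3, "g:extensive_parallel": -0.5,
             "i:devaluation:extensive": 0.6,
             "i:devaluation:extensive_parallel": 0.8,
             "i:control_post:extensive": 0.1,
             "i:control_post:extensive_parallel": 0.0}


def beta_vector(fit):
    """True coefficients in the fit's column order."""
    out = []
    for name in fit.coef.index:
        key = (name.replace("Manipulation[Devaluation]", "m:devaluation")
               .replace("Manipulation[ControlPost]", "m:control_post")
               .replace("Group[ExtensiveParallel]", "g:extensive_parallel")
               .replace("Group[Extensive]", "g:extensive"))
        if ":Group" in name or (name.count("[") == 2):
            m = "devaluation" if "Devaluation" in name else "control_post"
            g = ("extensive_parallel" if "ExtensiveParallel" in name
                 else "extensive")
            out.append(TRUE_BETA[f"i:{m}:{g}"])
        elif key == "Intercept":
            out.append(TRUE_BETA["Intercept"])
        else:
            out.append(TRUE_BETA[key])
    return np.array(out)


class TestVarianceFunctions:
    def test_nb_variance_parameterizations(self):
        assert cm.nb2_variance(10.0, 5.0) == pytest.approx(30.0)
        assert cm.nb1_variance(10.0, 2.0) == pytest.approx(30.0)


class TestMixedCountFit:
    def test_poisson_recovery_within_three_se(self):
        data = simulate_counts(67, TRUE_BETA, 0.6, seed=5)
        fit = cm.fit_mixed_count(data, "poisson")
        z = np.abs(fit.coef.to_numpy() - beta_vector(fit)) / fit.se.to_numpy()
        assert np.all(z < 3.0)
        assert fit.sigma_b == pytest.approx(0.6, abs=0.15)

    def test_nb1_limit_matches_poisson(self):
        """As the NB1 dispersion vanishes the likelihood nests Poisson."""
        data = simulate_counts(15, TRUE_BETA, 0.5, seed=2)
        pois = cm.fit_mixed_count(data, "poisson", compute_se=False)
        X, _, y, pidx, ids = cm.build_design(data)
        beta = pois.coef.to_numpy()
        ll_pois = cm._marginal_loglik(y, X, pidx, len(ids), beta,
                                      pois.sigma_b, "poisson", None)
        ll_nb1 = cm._marginal_loglik(y, X, pidx, len(ids), beta,
                                     pois.sigma_b, "nb1", 1e-6)
        assert ll_nb1 == pytest.approx(ll_pois, abs=0.05)

    def test_matches_glmmTMB_reference(self, tmp_path):
        """NB1 fixed effects, SEs and dispersion agree with glmmTMB."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable for the reference comparison")
        data = simulate_counts(12, TRUE_BETA, 0.6, seed=7, family="nb1",
                               disp=4.0)
        csv = tmp_path / "d.csv"
        data.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(glmmTMB))
            d <- read.csv('{csv}')
            d$manipulation <- factor(d$manipulation,
                levels=c('control_pre','devaluation','control_post'))
            d$group <- factor(d$group,
                levels=c('short','extensive','extensive_parallel'))
            m <- glmmTMB(entries ~ manipulation*group + (1|participant_id),
                         data=d, family=nbinom1)
            co <- summary(m)$coefficients$cond
            write.csv(data.frame(est=co[,1], se=co[,2]),
                      '{tmp_path}/ref.csv', row.names=FALSE)
            cat(sigma(m), sqrt(VarCorr(m)$cond$participant_id[1,1]))
        """))
        res = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=300)
        assert res.returncode == 0, res.stderr
        ref = pd.read_csv(tmp_path / "ref.csv")
        alpha_ref, sigma_ref = map(float, res.stdout.split()[-2:])
        # glmmTMB orders interactions dev:ext, post:ext, dev:extp, post:extp
        order = [0, 1, 2, 3, 4, 5, 7, 6, 8]
        fit = cm.fit_mixed_count(data, "nb1")
        np.testing.assert_allclose(fit.coef.to_numpy(),
                                   ref["est"].to_numpy()[order], atol=0.02)
        np.testing.assert_allclose(fit.se.to_numpy(),
                                   ref["se"].to_numpy()[order], rtol=0.1)
        assert fit.dispersion == pytest.approx(alpha_ref, rel=0.05)
        assert fit.sigma_b == pytest.approx(sigma_ref, rel=0.1)

    def test_invalid_inputs_rejected(self):
        data = simulate_counts(5, TRUE_BETA, 0.5, seed=1)
        with pytest.raises(ValueError):
            cm.fit_mixed_count(data, "lognormal")
        dup = pd.concat([data, data.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate"):
            cm.fit_mixed_count(dup, "poisson")


class TestDispersionRatio:
    def test_published_worked_example(self):
        """chi-square 4545 on 389 df reproduces the reported ratio 11.683."""
        out = cm.dispersion_ratio_from_chi2(4545.0, 389)
        assert out["ratio"] == pytest.approx(11.683, abs=1e-3)
        assert out["p"] < 0.001

    def test_zero_residuals_zero_ratio(self):
        assert cm.dispersion_ratio_from_chi2(0.0, 100)["ratio"] == 0.0

    def test_nonpositive_df_rejected(self):
        with pytest.raises(ValueError):
            cm.dispersion_ratio_from_chi2(10.0, 0)

    def test_equidispersed_poisson_not_flagged(self):
        """On equidispersed Poisson data the conditional-residual ratio
        sits below 1 (clusters of size 3 absorb fitting freedom); 0.7237
        is frozen from lme4's pearson residuals on this exact dataset."""
        data = simulate_counts(45, TRUE_BETA, 0.6, seed=3)
        fit = cm.fit_mixed_count(data, "poisson", compute_se=False)
        out = cm.dispersion_ratio(fit)
        assert out["ratio"] == pytest.approx(0.7237, abs=0.01)
        assert out["p"] > 0.05

    def test_overdispersed_data_flagged(self):
        data = simulate_counts(45, TRUE_BETA, 0.6, seed=3, family="nb1",
                               disp=10.0)
        fit = cm.fit_mixed_count(data, "poisson", compute_se=False)
        out = cm.dispersion_ratio(fit)
        assert out["ratio"] > 5.0
        assert out["p"] < 0.001


class TestLOOCV:
    def test_single_family_returned(self):
        data = simulate_counts(8, TRUE_BETA, 0.5, seed=4)
        sel = cm.loocv_select(data, families=("nb2",))
        assert sel["winner"] == "nb2"

    def test_leave_participant_out_option(self):
        data = simulate_counts(8, TRUE_BETA, 0.5, seed=4)
        sel = cm.loocv_select(data, families=("nb2",),
                              granularity="participant")
        assert sel["winner"] == "nb2"
        assert np.isfinite(sel["per_family"]["nb2"]["mse"])

    def test_unknown_granularity_rejected(self):
        data = simulate_counts(8, TRUE_BETA, 0.5, seed=4)
        with pytest.raises(ValueError):
            cm.loocv_select(data, granularity="fold")


class TestInteractionTests:
    def test_zeroed_interaction_block_gives_zero_chisquare(self):
        data = simulate_counts(20, TRUE_BETA, 0.5, seed=6)
        fit = cm.fit_mixed_count(data, "poisson")
        for name in fit.coef.index:
            if ":" in name:
                fit.coef[name] = 0.0
        out = cm.interaction_tests(fit)
        assert out["interaction_chi2"] == pytest.approx(0.0)
        assert out["interaction_df"] == 4

    def test_built_in_interaction_detected(self):
        data = simulate_counts(45, TRUE_BETA, 0.5, seed=8)
        fit = cm.fit_mixed_count(data, "poisson")
        out = cm.interaction_tests(fit)
        assert out["interaction_p"] < 0.05
        key = "Manipulation[Devaluation]:Group[Extensive]"
        assert out["simple_interactions"][key]["estimate"] > 0

    def test_simple_group_effects_reported(self):
        data = simulate_counts(20, TRUE_BETA, 0.5, seed=9)
        fit = cm.fit_mixed_count(data, "poisson")
        out = cm.interaction_tests(fit)
        assert set(out["simple_group_effects"]) == {
            "Group[Extensive]", "Group[ExtensiveParallel]"}


class TestMixture:
    def test_unimodal_selects_one_cluster(self):
        rng = np.random.default_rng(0)
        k, _ = cm.select_k(rng.normal(0.5, 0.1, 200))
        assert k == 1

    def test_bimodal_selects_two_clusters(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0.05, 0.05, 100),
                            rng.normal(0.9, 0.05, 100)])
        k, fits = cm.select_k(x)
        assert k == 2
        assert fits[2].means == pytest.approx([0.05, 0.9], abs=0.03)

    def test_bic_formula_for_single_component(self):
        """k = 1 has two free parameters, so BIC = -2 l + 2 log n with the
        closed-form Gaussian maximum likelihood."""
        rng = np.random.default_rng(1)
        x = rng.normal(0.0, 1.0, 64)
        fit = cm.fit_mixture(x, k=1)
        var = x.var() + 1e-4  # EM variance includes the floor
        ll = -0.5 * len(x) * (np.log(2 * np.pi * var) + x.var() / var)
        assert fit.bic == pytest.approx(-2 * ll + 2 * np.log(len(x)), rel=1e-6)

    def test_degenerate_atom_does_not_fake_a_cluster(self):
        """A point mass cannot win model selection through a collapsed
        (variance-floor) component."""
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0.5, 0.12, 60), np.ones(4)])
        k, fits = cm.select_k(x)
        assert fits[2].degenerate
        assert k == 1

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            cm.fit_mixture(np.ones(5), 1)


class TestRankRegression:
    def test_slope_recovery_under_heavy_tails(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        y = 2.0 * x + rng.standard_t(3, 200)
        fit = cm.rank_regression(y, pd.DataFrame({"x": x}), normalize=False)
        assert fit.coef["x"] == pytest.approx(2.0, abs=0.2)
        assert fit.term_tests["x"]["p"] < 1e-6

    def test_noiseless_monotone_has_positive_slope_and_tiny_dispersion(self):
        x = np.linspace(0, 1, 40)
        y = 3.0 * x
        fit = cm.rank_regression(y, pd.DataFrame({"x": x}), normalize=False)
        assert fit.coef["x"] > 0
        assert fit.dispersion == pytest.approx(0.0, abs=1e-6)

    def test_null_term_p_values_roughly_uniform(self):
        """Under pure noise the drop-in-dispersion p-values should be
        near-uniform (coarse Kolmogorov-Smirnov check)."""
        from scipy import stats
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(120):
            x = rng.normal(size=40)
            y = rng.normal(size=40)
            fit = cm.rank_regression(y, pd.DataFrame({"x": x}),
                                     normalize=False)
            ps.append(fit.term_tests["x"]["p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_effect_coded_columns_not_standardized(self):
        rng = np.random.default_rng(4)
        g = np.repeat([-1.0, 1.0], 30)
        x = rng.normal(size=60)
        y = 0.5 * g + x + rng.normal(size=60)
        fit = cm.rank_regression(y, pd.DataFrame({"group": g, "x": x}))
        assert fit.normalized
        # the group column keeps its +-1 coding; a unit change in the
        # estimate corresponds to the half-difference between groups
        assert fit.coef["group"] == pytest.approx(0.5, abs=0.25)

    def test_rank_deficient_design_rejected(self):
        x = np.ones(30)
        with pytest.raises(ValueError):
            cm.rank_regression(np.arange(30.0),
                               pd.DataFrame({"a": x, "b": x}),
                               normalize=False)
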