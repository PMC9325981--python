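"""Random-intercept LMM fitting, model selection and marginal effects."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from leachdom import mixed_model as mm
from leachdom.synthetic import StudyDesign, make_lake_covariates, make_response_data


def simulate(rng, n_lakes=12, n_rep=3, treatment_effect=0.8, fd_effect=0.0,
             interaction=0.0, lake_sd=0.4, resid_sd=0.3):
    rows = []
    for li in range(n_lakes):
        fd = rng.normal()
        u = rng.normal(0.0, lake_sd)
        for treatment, t in (("control", 0.0), ("plastic", 1.0)):
            for rep in range(n_rep):
                log_y = 0.5 + treatment_effect * t + fd_effect * fd \
                    + interaction * t * fd + u + rng.normal(0.0, resid_sd)
                rows.append({"lake_id": f"L{li}", "treatment": treatment,
                             "fd": fd, "response": float(np.exp(log_y))})
    return pd.DataFrame(rows)


class TestFitLmm:
    def test_zero_lake_variance_matches_ols(self, rng):
        df = simulate(rng, lake_sd=0.0)
        fit = mm.fit_lmm(df, ["treatment", "fd"], objective="ML")
        y = np.log(df.response.to_numpy())
        z = (df.fd - df.fd.mean()) / df.fd.std(ddof=1)
        x = np.column_stack([np.ones(len(df)), (df.treatment == "plastic").astype(float), z])
        beta_ols = np.linalg.lstsq(x, y, rcond=None)[0]
        assert fit.params.to_numpy() == pytest.approx(beta_ols, abs=1e-6)
        assert fit.group_var <= 1e-4

    def test_balanced_two_group_closed_form(self, rng):
        df = simulate(rng, n_rep=1)
        fit = mm.fit_lmm(df, ["treatment"])
        logs = np.log(df.response)
        expected = logs[df.treatment == "plastic"].mean() - logs[df.treatment == "control"].mean()
        assert fit.params["treatment"] == pytest.approx(expected, abs=1e-8)

    def test_response_scaling_shifts_only_intercept(self, rng):
        df = simulate(rng)
        fit1 = mm.fit_lmm(df, ["treatment", "fd"])
        df2 = df.assign(response=df.response * 7.0)
        fit2 = mm.fit_lmm(df2, ["treatment", "fd"])
        assert fit2.params["Intercept"] - fit1.params["Intercept"] == pytest.approx(np.log(7.0), abs=1e-8)
        assert fit2.params["treatment"] == pytest.approx(fit1.params["treatment"], abs=1e-8)

    @pytest.mark.parametrize("objective", ["ML", "REML"])
    def test_matches_statsmodels_mixedlm(self, rng, objective):
        """Independent oracle: statsmodels MixedLM on the same design."""
        df = simulate(rng, interaction=0.3, fd_effect=0.2)
        fit = mm.fit_lmm(df, ["treatment", "fd", "treatment:fd"], objective=objective)
        d = df.assign(
            logy=np.log(df.response),
            treat=(df.treatment == "plastic").astype(float),
            z_fd=(df.fd - df.fd.mean()) / df.fd.std(ddof=1),
        )
        oracle = smf.mixedlm("logy ~ treat + z_fd + treat:z_fd", d,
                             groups=d["lake_id"]).fit(reml=(objective == "REML"))
        assert fit.params.to_numpy() == pytest.approx(oracle.fe_params.values, abs=1e-6)
        assert fit.llf == pytest.approx(oracle.llf, abs=1e-5)
        assert fit.group_var == pytest.approx(float(np.asarray(oracle.cov_re)[0, 0]), abs=1e-4)

    def test_singular_design_names_columns(self, rng):
        df = simulate(rng)
        df["fd2"] = df["fd"]
        with pytest.raises(ValueError, match="collinear"):
            mm.fit_lmm(df, ["treatment", "fd", "fd2"])

    def test_refit_reproduces_aic(self, rng):
        df = simulate(rng)
        fit1 = mm.fit_lmm(df, ["treatment", "fd"], objective="ML")
        fit2 = mm.fit_lmm(df, ["treatment", "fd"], objective="ML",
                          covariate_stats=fit1.covariate_stats)
        assert fit1.aic == pytest.approx(fit2.aic, abs=1e-8)


class TestCollinearityScreen:
    def test_duplicate_covariate_dropped(self, rng):
        df = pd.DataFrame({"fd": rng.normal(size=30)})
        df["doc"] = df["fd"]
        retained, dropped = mm.collinearity_screen(df, ["fd", "doc"])
        assert retained == ["fd"]
        assert dropped[0][:2] == ("fd", "doc")

    def test_strict_inequality_at_boundary(self, rng):
        x = rng.normal(size=200)
        y = 0.9 * x + np.sqrt(1 - 0.81) * rng.normal(size=200)
        r = abs(float(np.corrcoef(x, y)[0, 1]))
        df = pd.DataFrame({"fd": x, "doc": y})
        both, _ = mm.collinearity_screen(df, ["fd", "doc"], threshold=r)
        assert both == ["fd", "doc"]          # exactly r is not > r
        one, _ = mm.collinearity_screen(df, ["fd", "doc"], threshold=r - 1e-9)
        assert one == ["fd"]

    def test_independent_covariates_all_kept(self, rng):
        df = pd.DataFrame(rng.normal(size=(100, 4)), columns=["fd", "doc", "tn", "ph"])
        retained, dropped = mm.collinearity_screen(df, ["fd", "doc", "tn", "ph"])
        assert retained == ["fd", "doc", "tn", "ph"]
        assert dropped == []

    def test_priority_decides_which_member_drops(self, rng):
        df = pd.DataFrame({"shannon": rng.normal(size=30)})
        df["fd"] = df["shannon"] * 1.0000001
        retained, _ = mm.collinearity_screen(df, ["shannon", "fd"])
        assert retained == ["fd"]  # fd outranks shannon in the default priority


class TestBackwardElimination:
    def test_null_covariate_usually_eliminated(self):
        rng = np.random.default_rng(42)
        eliminated = 0
        n_sets = 60
        for _ in range(n_sets):
            df = simulate(rng, n_lakes=29, fd_effect=0.0)
            res = mm.backward_eliminate(df, ["treatment", "fd"])
            eliminated += "fd" not in res.final.terms
        assert eliminated / n_sets >= 0.9

    def test_strong_interaction_usually_retained(self):
        rng = np.random.default_rng(43)
        retained = 0
        n_sets = 60
        for _ in range(n_sets):
            df = simulate(rng, n_lakes=29, fd_effect=0.3, interaction=1.0)
            res = mm.backward_eliminate(df, ["treatment", "fd", "treatment:fd"])
            retained += "treatment:fd" in res.final.terms
        assert retained / n_sets >= 0.9

    def test_treatment_never_dropped(self, rng):
        # response unrelated to treatment; the design term must still survive
        df = simulate(rng, treatment_effect=0.0)
        res = mm.backward_eliminate(df, ["treatment", "fd"])
        assert "treatment" in res.final.terms

    def test_marginality_respected(self, rng):
        df = simulate(rng, fd_effect=0.0, interaction=1.5)
        res = mm.backward_eliminate(df, ["treatment", "fd", "treatment:fd"])
        if "treatment:fd" in res.final.terms:
            assert "fd" in res.final.terms

    def test_drop_decision_boundary(self, rng):
        """A removal raising AIC by exactly the threshold still drops."""
        df = simulate(rng, fd_effect=0.35)
        full = mm.fit_lmm(df, ["treatment", "fd"], objective="ML")
        reduced = mm.fit_lmm(df, ["treatment"], objective="ML",
                             covariate_stats=full.covariate_stats)
        delta = reduced.aic - full.aic
        assert delta > 0  # fd is informative here; removing it costs AIC
        at = mm.backward_eliminate(df, ["treatment", "fd"], aic_threshold=delta)
        assert "fd" not in at.final.terms
        below = mm.backward_eliminate(df, ["treatment", "fd"], aic_threshold=delta - 1e-6)
        assert "fd" in below.final.terms

    def test_invariant_to_term_ordering(self, rng):
        df = simulate(rng, n_lakes=20, fd_effect=0.4, interaction=0.0)
        df["doc"] = rng.normal(size=len(df))
        a = mm.backward_eliminate(df, ["treatment", "fd", "doc", "treatment:fd"])
        b = mm.backward_eliminate(df, ["treatment", "doc", "treatment:fd", "fd"])
        assert set(a.final.terms) == set(b.final.terms)

    def test_final_fit_is_reml(self, rng):
        df = simulate(rng)
        res = mm.backward_eliminate(df, ["treatment", "fd"])
        assert res.final.objective == "REML"
        assert res.ml_fit.objective == "ML"


class TestMarginalEffects:
    def test_null_effect_fold_ci_covers_one(self, rng):
        df = simulate(rng, treatment_effect=0.0)
        fit = mm.fit_lmm(df, ["treatment"], objective="REML")
        eff = mm.marginal_effects(fit)[0]
        assert eff.fold_ci[0] < 1.0 < eff.fold_ci[1]

    def test_planted_contrast_recovered_exactly_without_noise(self, design):
        rng = np.random.default_rng(0)
        df, truth = make_response_data(design, rng, "bpp", lake_sd=0.0, resid_sd=0.0)
        fit = mm.fit_lmm(df, ["treatment"], objective="REML")
        eff = mm.marginal_effects(fit)[0]
        assert eff.fold_change == pytest.approx(truth["fold"], abs=1e-6)  # 2.29

    def test_fold_equals_ratio_of_means(self, rng):
        df = simulate(rng, fd_effect=0.3, interaction=0.4)
        fit = mm.fit_lmm(df, ["treatment", "fd", "treatment:fd"], objective="REML")
        for eff in mm.marginal_effects(fit, moderator="fd"):
            assert eff.fold_change == pytest.approx(eff.plastic_mean / eff.control_mean, rel=1e-12)

    def test_unknown_moderator_rejected(self, rng):
        df = simulate(rng)
        fit = mm.fit_lmm(df, ["treatment"], objective="REML")
        with pytest.raises(ValueError, match="moderator"):
            mm.marginal_effects(fit, moderator="doc")

    def test_interaction_probe_orders_fold_changes(self, rng):
        df = simulate(rng, n_lakes=40, interaction=0.6, resid_sd=0.1)
        fit = mm.fit_lmm(df, ["treatment", "fd", "treatment:fd"], objective="REML")
        lo, mid, hi = mm.marginal_effects(fit, moderator="fd")
        assert lo.level_sd == -1.0 and hi.level_sd == 1.0
        assert lo.fold_change < mid.fold_change < hi.fold_change


def test_wald_ci_coverage_spot_check(design):
    """CIs at the two study designs hit near-nominal coverage (fuller check
    in the acceptance suite)."""
    rng = np.random.default_rng(7)
    cover = 0
    n_sims = 100
    for _ in range(n_sims):
        df, truth = make_response_data(design, rng, "bge", interactions={})
        fit = mm.fit_lmm(df, ["treatment"], objective="REML")
        from scipy import stats as sps
        b = fit.params["treatment"]
        se = np.sqrt(fit.cov_params.loc["treatment", "treatment"])
        t = sps.t.ppf(0.975, fit.df_resid)
        cover += (b - t * se <= truth["log_treatment_effect"] <= b + t * se)
    assert 0.88 <= cover / n_sims <= 1.0
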