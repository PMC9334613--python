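import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from nirsync.inference import (
    ModelSpec,
    _formula_without_factor,
    _formula_without_term,
    control_spec,
    covariate_models,
    emmeans_contrasts,
    fit_beta_glmm,
    lr_effect,
    main_spec,
    wald_effect,
)

CONDS = ["FreePlay", "PredictionDifferent", "PredictionSame", "Control", "Rest"]
REGIONS = ["lDLPFC", "rDLPFC", "lTPJ", "rTPJ"]


def make_table(rng, n_dyads=8, cond_eff=None, pairing_eff=None, phi=60.0,
               sd=0.2, covariate_slope=None):
    cond_eff = cond_eff or {c: 0.0 for c in CONDS}
    rows = []
    for d in range(n_dyads):
        b = rng.normal(0, sd)
        rt = rng.normal(0, 1.0)
        for pairing in ("original", "random"):
            for cond in CONDS:
                for reg in REGIONS:
                    eta = -0.3 + b + cond_eff[cond]
                    if pairing_eff and pairing == "original":
                        eta += pairing_eff.get(cond, 0.0)
                    if covariate_slope is not None:
                        eta += covariate_slope * rt
                    mu = expit(eta)
                    y = rng.beta(mu * phi, (1 - mu) * phi)
                    rows.append((f"d{d}", pairing, cond, reg, y, rt))
    return pd.DataFrame(
        rows, columns=["dyad", "pairing", "condition", "region", "wtc_value", "rt_diff"]
    )


@pytest.fixture(scope="module")
def table_with_effects():
    rng = np.random.default_rng(21)
    return make_table(
        rng,
        cond_eff={"FreePlay": 0.3, "PredictionDifferent": 0.15,
                  "PredictionSame": 0.15, "Control": 0.0, "Rest": -0.1},
        pairing_eff={"FreePlay": 0.5, "PredictionDifferent": 0.3,
                     "PredictionSame": 0.3, "Control": 0.0, "Rest": 0.15},
    )


@pytest.fixture(scope="module")
def control_fit(table_with_effects):
    return fit_beta_glmm(table_with_effects, control_spec())


class TestFormulaSurgery:
    def test_drop_factor_removes_all_terms(self):
        f = _formula_without_factor("y ~ a * b * c", "a")
        assert "a" not in f.split("~")[1]
        assert "b" in f and "c" in f and "b:c" in f.replace(" ", "")

    def test_drop_interaction_keeps_main_effects(self):
        f = _formula_without_term("y ~ a * b * c", "a:b")
        rhs = f.split("~")[1].replace(" ", "")
        assert "a:b" not in rhs.replace("a:b:c", "")
        assert "a:b:c" not in rhs
        assert "a" in rhs and "b" in rhs and "a:c" in rhs


class TestFitBetaGlmm:
    def test_control_fit_converges_with_trail(self, control_fit):
        assert control_fit.converged
        assert control_fit.reduction_trail == ["1"]
        assert control_fit.phi > 0
        assert np.isfinite(control_fit.llf)

    def test_slope_trail_reduces_on_failure(self, table_with_effects):
        # 8 dyads cannot support a full slope structure; the trail must
        # fall back to the intercept-only model
        spec = ModelSpec(
            "wtc_value ~ pairing * condition",
            ["1 + pairing * condition", "1"],
        )
        res = fit_beta_glmm(table_with_effects.iloc[:400], spec, maxiter=40)
        assert res.reduction_trail[-1] == "1" or res.converged

    def test_summary_mentions_key_quantities(self, control_fit):
        s = control_fit.summary()
        assert "logLik" in s and "phi" in s and "pairing" in s

    def test_quantile_residuals_near_normal(self, control_fit):
        r = control_fit.resid_quantile
        assert abs(np.mean(r)) < 0.15
        assert 0.8 < np.std(r) < 1.2


class TestLrEffects:
    def test_pairing_effect_detected(self, table_with_effects, control_fit):
        out = lr_effect(table_with_effects, control_spec(), "pairing",
                        full_fit=control_fit)
        assert out["p"] < 0.01
        assert out["df"] >= 1

    def test_null_region_effect_not_detected(self, table_with_effects, control_fit):
        out = lr_effect(table_with_effects, control_spec(), "region",
                        full_fit=control_fit)
        assert out["p"] > 0.01  # no region effect simulated

    def test_wald_and_lr_agree_without_higher_order_terms(self, table_with_effects):
        # without a 3-way term the 2-way coefficients span the whole
        # interaction, so Wald and LR must both flag the simulated effect
        spec = ModelSpec("wtc_value ~ pairing * condition")
        fit = fit_beta_glmm(table_with_effects, spec)
        w = wald_effect(fit, "pairing:condition")
        l = lr_effect(table_with_effects, spec, "pairing:condition", full_fit=fit)
        assert w["df"] == 4
        assert w["p"] < 0.05 and l["p"] < 0.05


class TestEmmeans:
    def test_pairwise_count_for_five_levels(self, control_fit):
        con = emmeans_contrasts(control_fit, "condition")
        assert len(con) == 10  # C(5,2)

    def test_adjusted_p_not_smaller_than_raw(self, control_fit):
        con = emmeans_contrasts(control_fit, "condition")
        assert (con["p_adj"] >= con["p_unadj"] - 1e-12).all()

    def test_two_level_factor_reduces_to_unadjusted(self, control_fit):
        con = emmeans_contrasts(control_fit, "pairing")
        assert np.allclose(con["p_adj"], con["p_unadj"], atol=1e-10)

    def test_by_conditioning_detects_pattern(self, control_fit):
        con = emmeans_contrasts(control_fit, "pairing", by="condition")
        con = con.set_index("by")
        # simulated: strong original>random in FreePlay, none in Control
        assert con.loc["FreePlay", "p_adj"] < 0.01
        assert con.loc["FreePlay", "estimate"] > 0
        assert con.loc["Control", "p_adj"] > 0.05

    def test_unknown_factor_rejected(self, control_fit):
        with pytest.raises(ValueError):
            emmeans_contrasts(control_fit, "nonexistent")


class TestCovariateModels:
    def _light(self, rng, n_dyads, slope=0.0):
        rows = []
        for d in range(n_dyads):
            b = rng.normal(0, 0.2)
            rt = rng.normal()
            for cond in CONDS:
                for _ in range(4):
                    mu = expit(-0.3 + b + slope * rt)
                    rows.append((f"d{d}", cond, rng.beta(mu * 60, (1 - mu) * 60), rt))
        return pd.DataFrame(rows, columns=["dyad", "condition", "wtc_value", "rt_diff"])

    def test_null_covariate_ci_covers_zero(self):
        """A dyad-level covariate unrelated to coherence should have a CI
        covering zero in the large majority of replicates."""
        rng = np.random.default_rng(31)
        hits = 0
        reps = 20
        for _ in range(reps):
            tab = self._light(rng, 14)
            cov = tab[["dyad", "rt_diff"]].drop_duplicates()
            res = covariate_models(
                tab.drop(columns="rt_diff"), cov, ["rt_diff"],
                base_formula="wtc_value ~ condition",
            )
            ci = res.conf_int().loc["rt_diff"]
            hits += int(ci["lower"] <= 0 <= ci["upper"])
        assert hits >= int(0.9 * reps) - 1

    def test_known_slope_sign_recovered(self):
        rng = np.random.default_rng(32)
        tab = self._light(rng, 12, slope=0.3)
        cov = tab[["dyad", "rt_diff"]].drop_duplicates()
        res = covariate_models(
            tab.drop(columns="rt_diff"), cov, ["rt_diff"],
            base_formula="wtc_value ~ condition",
        )
        assert res.params["rt_diff"] > 0
        assert res.params["rt_diff"] / res.bse["rt_diff"] > 2

    def test_zero_variance_covariate_rejected(self):
        rng = np.random.default_rng(33)
        tab = self._light(rng, 4)
        cov = tab[["dyad"]].drop_duplicates()
        cov["flat"] = 1.0
        with pytest.raises(np.linalg.LinAlgError):
            covariate_models(tab, cov, ["flat"],
                             base_formula="wtc_value ~ condition")

    def test_unmatched_dyads_rejected(self):
        rng = np.random.default_rng(34)
        tab = self._light(rng, 4)
        cov = pd.DataFrame({"dyad": ["d0", "d1"], "rt_diff": [0.1, -0.2]})
        with pytest.raises(ValueError, match="missing"):
            covariate_models(tab.drop(columns="rt_diff"), cov, ["rt_diff"],
                             base_formula="wtc_value ~ condition")


def test_main_spec_formula():
    assert main_spec().formula == "wtc_value ~ condition * region"
    assert control_spec(random_slopes=True).re_trail[-1] == "1"
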