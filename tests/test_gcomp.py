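import numpy as np
import pandas as pd
import pytest

import gmediate as gm
from gmediate import glm
from gmediate.gcomp import (
    CounterfactualMeans,
    EstimationError,
    MediationConfig,
    counterfactual_means,
    decompose,
    estimate,
    simulate_mediator,
)
from gmediate.simulate import recovery_config


def _toy_models(n=50, seed=0, m_x_coef=2.0, y_m_coef=0.3):
    """Small fitted M and Y models on synthetic columns."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "x_helpful": rng.integers(0, 2, n).astype(float),
        "c": rng.standard_normal(n),
    })
    df["m"] = 1.0 + m_x_coef * df["x_helpful"] + 0.5 * df["c"] \
        + rng.standard_normal(n)
    lp = -0.2 + 0.8 * df["x_helpful"] + y_m_coef * df["m"] + 0.3 * df["c"]
    df["y"] = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
    model_m = glm.fit(glm.DesignSpec("m", ("x_helpful", "c")), df)
    model_y = glm.fit(glm.DesignSpec("y", ("x_helpful", "m", "c"),
                                     family="binomial"), df)
    return df, model_m, model_y


def test_zero_residual_sd_gives_degenerate_draws():
    df = pd.DataFrame({"x_helpful": [0.0, 1.0, 0.0, 1.0],
                       "c": [1.0, 2.0, 3.0, 4.0]})
    df["m"] = 2.0 + 1.0 * df["x_helpful"] + 0.5 * df["c"]  # exact line
    model = glm.fit(glm.DesignSpec("m", ("x_helpful", "c")), df)
    draws, clipped = simulate_mediator(model, df, x_set=1, draws=7,
                                       rng=np.random.default_rng(0))
    assert draws.shape == (4, 7)
    expected = 3.0 + 0.5 * df["c"].to_numpy()
    np.testing.assert_allclose(
        draws, np.broadcast_to(expected[:, None], (4, 7)), atol=1e-10)
    assert clipped == 0


def test_null_exposure_mediator_path_gives_identical_draw_distributions():
    df, model_m, _ = _toy_models(n=400, seed=1, m_x_coef=0.0)
    rng = np.random.default_rng(5)
    d0, _ = simulate_mediator(model_m, df, 0, 200, rng)
    d1, _ = simulate_mediator(model_m, df, 1, 200, rng)
    # exposure coefficient is an estimate near 0, not exactly 0
    fitted_gap = abs(model_m.coefficients["x_helpful"])
    assert abs(d1.mean() - d0.mean()) < fitted_gap + 3 * df["m"].std() / np.sqrt(200 * len(df))


def test_mediator_draw_mean_obeys_clt_bound():
    df, model_m, _ = _toy_models(n=30, seed=2)
    rng = np.random.default_rng(9)
    draws, _ = simulate_mediator(model_m, df, 1, 100_000, rng)
    frame = df.copy()
    frame["x_helpful"] = 1.0
    lp = glm.predict_linear(model_m, frame)
    for i in (0, 7, 29):
        tol = 3 * model_m.residual_sd / np.sqrt(100_000)
        assert abs(draws[i].mean() - lp[i]) < tol


def test_binary_mediator_modes():
    rng = np.random.default_rng(3)
    n = 300
    df = pd.DataFrame({"x_helpful": rng.integers(0, 2, n).astype(float),
                       "c": rng.standard_normal(n)})
    df["m"] = (rng.random(n) < 0.3 + 0.3 * df["x_helpful"]).astype(float)
    lpm = glm.fit(glm.DesignSpec("m", ("x_helpful", "c")), df)
    draws, _ = simulate_mediator(lpm, df, 1, 50, rng, kind="binary_lpm")
    assert set(np.unique(draws)) <= {0.0, 1.0}
    logit = glm.fit(glm.DesignSpec("m", ("x_helpful", "c"),
                                   family="binomial"), df)
    draws, clipped = simulate_mediator(logit, df, 0, 50, rng,
                                       kind="binary_logit")
    assert set(np.unique(draws)) <= {0.0, 1.0}
    assert clipped == 0


def test_intercept_only_outcome_gives_half_everywhere():
    df, model_m, _ = _toy_models(n=60, seed=4)
    # outcome model with all coefficients zero: expit(0) = 0.5
    spec_y = glm.DesignSpec("y", ("x_helpful", "m", "c"), family="binomial")
    model_y = glm.fit(spec_y, df)
    model_y.params = np.zeros_like(model_y.params)
    means, _ = counterfactual_means(model_y, model_m, df, draws=20,
                                    rng=np.random.default_rng(0),
                                    mediator="m")
    assert means.mu_11 == means.mu_00 == means.mu_10 == pytest.approx(0.5)


def test_mediator_irrelevant_outcome_collapses_nde_gap():
    df, model_m, model_y = _toy_models(n=200, seed=6)
    model_y.params[model_y.spec.param_names.index("m")] = 0.0
    means, _ = counterfactual_means(model_y, model_m, df, draws=500,
                                    rng=np.random.default_rng(1),
                                    mediator="m")
    assert means.mu_11 == pytest.approx(means.mu_10, abs=1e-12)


def test_counterfactual_means_match_direct_dgp_oracle(recovery_dgp,
                                                      recovery_mediation_config):
    """Plug-in means on one large cohort agree with the true-model oracle."""
    cfg = recovery_config(20_000)
    df = gm.generate(cfg, seed=99)
    res = estimate(df, None, recovery_mediation_config, rng=7)
    truth = gm.true_effects(cfg, oracle_n=400_000, seed=17)
    assert res.estimates.tce == pytest.approx(truth.true_tce, abs=0.01)
    assert res.estimates.nde == pytest.approx(truth.true_nde, abs=0.01)
    assert res.estimates.nie == pytest.approx(truth.true_nie, abs=0.01)


def test_decompose_zero_effect_has_undefined_proportion():
    est = decompose(CounterfactualMeans(0.5, 0.5, 0.5))
    assert est.tce == est.nde == est.nie == 0.0
    assert est.prop_mediated is None


def test_decompose_reports_risk_differences():
    est = decompose(CounterfactualMeans(mu_11=0.74, mu_00=0.60, mu_10=0.73))
    assert est.tce == pytest.approx(0.14)
    assert est.nde == pytest.approx(0.13)
    assert est.nie == est.tce - est.nde  # identity, bit-exact
    assert est.prop_mediated == pytest.approx(est.nie / est.tce)


def test_estimate_is_deterministic_under_seed(recovery_dgp,
                                              recovery_mediation_config):
    df = gm.generate(recovery_config(400), seed=21)
    a = estimate(df, None, recovery_mediation_config, rng=123)
    b = estimate(df, None, recovery_mediation_config, rng=123)
    assert a.estimates == b.estimates
    assert a.means == b.means


def test_estimate_requires_dag_or_explicit_sets():
    df = gm.generate(recovery_config(200), seed=2)
    with pytest.raises(EstimationError, match="DAG"):
        estimate(df, None, MediationConfig(), rng=0)


def test_interaction_term_is_supported(recovery_mediation_config):
    df = gm.generate(recovery_config(1000), seed=31)
    cfg = MediationConfig(
        interaction=True,
        adjustment_outcome=recovery_mediation_config.adjustment_outcome,
        adjustment_mediator=recovery_mediation_config.adjustment_mediator)
    res = estimate(df, None, cfg, rng=0)
    assert "x_helpful:bses_total" in res.model_y.coefficients
    assert res.estimates.nie == res.estimates.tce - res.estimates.nde


def test_draw_y_mode_agrees_with_analytic_mode(recovery_mediation_config):
    df = gm.generate(recovery_config(1500), seed=41)
    base = MediationConfig(
        adjustment_outcome=recovery_mediation_config.adjustment_outcome,
        adjustment_mediator=recovery_mediation_config.adjustment_mediator,
        mc_draws=400)
    drawn = MediationConfig(
        adjustment_outcome=recovery_mediation_config.adjustment_outcome,
        adjustment_mediator=recovery_mediation_config.adjustment_mediator,
        mc_draws=400, draw_y=True)
    a = estimate(df, None, base, rng=5)
    b = estimate(df, None, drawn, rng=5)
    # drawing Bernoulli outcomes adds MC noise but targets the same means
    assert b.means.mu_11 == pytest.approx(a.means.mu_11, abs=0.01)
    assert b.means.mu_00 == pytest.approx(a.means.mu_00, abs=0.01)


def test_rare_outcome_nie_matches_product_of_coefficients():
    """In the rare-outcome, gaussian-mediator, no-interaction limit the
    simulated NIE approaches mu_10 * (exp(b_m * a_x) - 1)."""
    cfg = recovery_config(40_000)
    y_model = dict(cfg.y_model)
    y_model["intercept"] = -4.5  # prevalence ~ 2-4%
    import dataclasses
    rare = dataclasses.replace(cfg, y_model=y_model)
    df = gm.generate(rare, seed=55)
    assert df["y_exclusive"].mean() < 0.05
    mcfg = MediationConfig(
        adjustment_outcome=("age", "caesarean", "hiv", "educ_grade12",
                            "hps_high", "infant_age"),
        adjustment_mediator=("age", "caesarean", "hps_high", "educ_grade12"),
        mc_draws=300)
    res = estimate(df, None, mcfg, rng=9)
    a_x = res.model_m.coefficients["x_helpful"]
    b_m = res.model_y.coefficients["bses_total"]
    approx_nie = res.means.mu_10 * (np.exp(b_m * a_x) - 1.0)
    assert res.estimates.nie == pytest.approx(approx_nie, rel=0.10)


def test_counterfactual_means_validate_bounds():
    with pytest.raises(ValueError, match="outside"):
        CounterfactualMeans(1.2, 0.5, 0.5)
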