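import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from gmediate import glm
from gmediate.glm import (
    DesignSpec,
    GlmError,
    RankDeficientError,
    coefficient_test,
    expand_categoricals,
    fit,
    predict_linear,
)


def _random_table(rng, n, k=3, binary_response=False):
    data = {f"c{j}": rng.standard_normal(n) for j in range(k)}
    df = pd.DataFrame(data)
    lp = 0.3 + sum((j + 1) * 0.2 * df[f"c{j}"] for j in range(k))
    if binary_response:
        df["y"] = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
    else:
        df["y"] = lp + rng.standard_normal(n)
    return df


def test_gaussian_exact_line_is_interpolated():
    df = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0]})
    df["y"] = 1.0 + 2.0 * df["x"]
    model = fit(DesignSpec("y", ("x",), family="gaussian"), df)
    assert model.coefficients["intercept"] == pytest.approx(1.0, abs=1e-10)
    assert model.coefficients["x"] == pytest.approx(2.0, abs=1e-10)
    assert model.residual_sd == pytest.approx(0.0, abs=1e-8)
    assert coefficient_test(model, "x").se == pytest.approx(0.0, abs=1e-8)


def test_intercept_only_logit_matches_logit_of_mean():
    df = pd.DataFrame({"y": [0.0, 1.0] * 20, "one_more": np.arange(40.0)})
    model = fit(DesignSpec("y", (), family="binomial"), df)
    assert model.converged
    assert model.coefficients["intercept"] == pytest.approx(0.0, abs=1e-8)


def test_gaussian_matches_normal_equations_oracle():
    rng = np.random.default_rng(42)
    df = _random_table(rng, 10)
    spec = DesignSpec("y", ("c0", "c1", "c2"), family="gaussian")
    model = fit(spec, df)
    x = np.column_stack([np.ones(10)] + [df[c] for c in spec.terms])
    beta_oracle = np.linalg.solve(x.T @ x, x.T @ df["y"].to_numpy())
    np.testing.assert_allclose(model.params, beta_oracle, atol=1e-8)


def test_logit_matches_statsmodels_and_fd_hessian():
    rng = np.random.default_rng(7)
    df = _random_table(rng, 300, binary_response=True)
    spec = DesignSpec("y", ("c0", "c1", "c2"), family="binomial")
    model = fit(spec, df)
    assert model.converged

    x = np.column_stack([np.ones(len(df))] + [df[c] for c in spec.terms])
    sm_fit = sm.Logit(df["y"].to_numpy(), x).fit(disp=0)
    np.testing.assert_allclose(model.params, sm_fit.params, atol=1e-6)
    assert model.loglik == pytest.approx(sm_fit.llf, abs=1e-6)

    # standard errors against a finite-difference Hessian of the loglik
    def loglik(beta):
        eta = x @ beta
        return float(df["y"].to_numpy() @ eta - np.logaddexp(0, eta).sum())

    p = len(model.params)
    h = 1e-5
    hess = np.empty((p, p))
    for i in range(p):
        for j in range(p):
            bpp = model.params.copy(); bpp[i] += h; bpp[j] += h
            bpm = model.params.copy(); bpm[i] += h; bpm[j] -= h
            bmp = model.params.copy(); bmp[i] -= h; bmp[j] += h
            bmm = model.params.copy(); bmm[i] -= h; bmm[j] -= h
            hess[i, j] = (loglik(bpp) - loglik(bpm) - loglik(bmp)
                          + loglik(bmm)) / (4 * h * h)
    se_oracle = np.sqrt(np.diag(np.linalg.inv(-hess)))
    for term, j in (("c0", 1), ("c1", 2), ("c2", 3)):
        assert coefficient_test(model, term).se == pytest.approx(
            se_oracle[j], abs=1e-6)


def test_gaussian_residuals_orthogonal_to_design():
    rng = np.random.default_rng(3)
    df = _random_table(rng, 500)
    spec = DesignSpec("y", ("c0", "c1", "c2"), family="gaussian")
    model = fit(spec, df)
    x = np.column_stack([np.ones(len(df))] + [df[c] for c in spec.terms])
    resid = df["y"].to_numpy() - x @ model.params
    assert np.abs(x.T @ resid).max() < 1e-8 * len(df)


def test_logit_fitted_probabilities_average_to_outcome_mean():
    rng = np.random.default_rng(11)
    df = _random_table(rng, 400, binary_response=True)
    model = fit(DesignSpec("y", ("c0", "c1", "c2"), family="binomial"), df)
    from scipy.special import expit
    probs = expit(predict_linear(model, df))
    assert probs.mean() == pytest.approx(df["y"].mean(), abs=1e-9)


def test_fit_invariant_to_row_order():
    rng = np.random.default_rng(19)
    df = _random_table(rng, 200, binary_response=True)
    spec = DesignSpec("y", ("c0", "c1", "c2"), family="binomial")
    a = fit(spec, df)
    b = fit(spec, df.sample(frac=1.0, random_state=5).reset_index(drop=True))
    np.testing.assert_allclose(a.params, b.params, atol=1e-9)


def test_rank_deficiency_names_collinear_column():
    rng = np.random.default_rng(23)
    df = _random_table(rng, 50)
    df["dup"] = 2.0 * df["c0"]
    with pytest.raises(RankDeficientError) as err:
        fit(DesignSpec("y", ("c0", "dup"), family="gaussian"), df)
    assert "dup" in err.value.columns


def test_perfect_separation_is_flagged_not_silent():
    df = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20)] +
                       np.linspace(0, 0.1, 40),
                       "y": np.r_[np.zeros(20), np.ones(20)]})
    model = fit(DesignSpec("y", ("x",), family="binomial"), df)
    assert not model.converged
    assert model.warnings


def test_binomial_requires_01_response():
    df = pd.DataFrame({"x": np.arange(10.0), "y": np.arange(10.0)})
    with pytest.raises(GlmError, match="0/1"):
        fit(DesignSpec("y", ("x",), family="binomial"), df)


def test_predict_linear_examples():
    rng = np.random.default_rng(31)
    df = _random_table(rng, 30)
    model = fit(DesignSpec("y", ("c0", "c1", "c2"), family="gaussian"), df)
    rec = pd.DataFrame({"c0": [0.5], "c1": [-1.0], "c2": [2.0]})
    expected = (model.coefficients["intercept"]
                + 0.5 * model.coefficients["c0"]
                - 1.0 * model.coefficients["c1"]
                + 2.0 * model.coefficients["c2"])
    assert predict_linear(model, rec)[0] == pytest.approx(expected, abs=1e-12)
    with pytest.raises(GlmError, match="missing"):
        predict_linear(model, rec.drop(columns="c2"))


def test_wald_type_i_error_is_calibrated():
    """Under a true null slope, the Wald test rejects at ~5%."""
    rng = np.random.default_rng(20250904)
    n, reps = 200, 5000
    rejections = 0
    spec = DesignSpec("y", ("x",), family="gaussian")
    for _ in range(reps):
        df = pd.DataFrame({"x": rng.standard_normal(n),
                           "y": rng.standard_normal(n)})
        res = coefficient_test(fit(spec, df), "x")
        rejections += res.p < 0.05
    assert 0.04 <= rejections / reps <= 0.06


def test_categorical_expansion_uses_modal_reference():
    df = pd.DataFrame({
        "y": np.arange(6.0),
        "rel": ["single", "single", "single", "married", "partner", "partner"],
    })
    out, mapping = expand_categoricals(df, ["rel"])
    assert mapping["rel"]["reference"] == "single"
    assert set(mapping["rel"]["indicators"]) == {"rel_married", "rel_partner"}
    assert out["rel_married"].sum() == 1
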