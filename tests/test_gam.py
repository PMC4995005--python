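"""Additive-model engine: basis oracle, exact recoveries, invariants.

The cubic-regression-spline construction is checked against frozen
reference values computed with mgcv (smoothCon(s(x, bs="cr", k=5),
knots=0..4, absorb.cons=FALSE, scale.penalty=FALSE)), which matches
this implementation to machine precision.
"""

import numpy as np
import pandas as pd
import pytest

from soilgam.basis import OrthoPoly, crs_design, crs_knots, crs_penalty, sum_to_zero_constraint
from soilgam.errors import BasisError, SingularFitError
from soilgam.gam import (
    GAMConfig,
    ModelSpec,
    ModelTerm,
    explained_deviance,
    explained_deviance_values,
    fit_gam,
    significance_code,
    term_significance,
)

# ---- frozen mgcv reference (knots 0..4, evaluation points below) ----
MGCV_X = np.array(
    [
        [0.3995535714285714, 0.7276785714285714, -0.16071428571428573,
         0.04017857142857143, -0.006696428571428572],
        [-0.07366071428571429, 0.5669642857142857, 0.6071428571428572,
         -0.1205357142857143, 0.020089285714285716],
        [0.020089285714285716, -0.12053571428571427, 0.6071428571428571,
         0.5669642857142857, -0.07366071428571429],
        [-0.004875, 0.02925, -0.117, 0.46575, 0.626875],
        [1.0, 0.0, 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, 1.0],
    ]
)
MGCV_S = np.array(
    [
        [1.6071428571428572, -3.642857142857143, 2.571428571428571,
         -0.6428571428571429, 0.10714285714285715],
        [-3.642857142857143, 9.857142857142858, -9.428571428571427,
         3.857142857142857, -0.6428571428571429],
        [2.571428571428571, -9.428571428571427, 13.714285714285714,
         -9.428571428571429, 2.571428571428572],
        [-0.6428571428571429, 3.857142857142857, -9.428571428571429,
         9.857142857142858, -3.642857142857143],
        [0.10714285714285715, -0.6428571428571429, 2.571428571428572,
         -3.642857142857143, 1.6071428571428572],
    ]
)


def test_crs_matches_mgcv_reference():
    knots = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
    x = np.array([0.5, 1.5, 2.5, 3.7, 0.0, 4.0])
    np.testing.assert_allclose(crs_design(x, knots), MGCV_X, atol=1e-12)
    np.testing.assert_allclose(crs_penalty(knots), MGCV_S, atol=1e-12)


def test_crs_penalty_rank_and_null_space():
    # curvature penalty of a k-knot natural spline has rank k-2
    knots = crs_knots(np.linspace(0, 1, 20), 5)
    S = crs_penalty(knots)
    assert np.linalg.matrix_rank(S, tol=1e-10) == 3
    # constants and the linear function at the knots are unpenalized
    for v in (np.ones(5), knots):
        assert v @ S @ v == pytest.approx(0.0, abs=1e-10)
    # after the sum-to-zero constraint (4 columns) the rank stays k-2
    N = crs_design(np.linspace(0, 1, 20), knots)
    Z = sum_to_zero_constraint(N.mean(axis=0))
    assert Z.shape == (5, 4)
    assert np.linalg.matrix_rank(Z.T @ S @ Z, tol=1e-10) == 3
    assert np.abs((N @ Z).mean(axis=0)).max() < 1e-12


def test_crs_interpolates_knot_values():
    knots = np.array([0.0, 0.5, 1.2, 2.0, 3.0])
    np.testing.assert_allclose(crs_design(knots, knots), np.eye(5), atol=1e-12)


def test_crs_too_few_distinct_values():
    with pytest.raises(BasisError, match="k"):
        crs_knots(np.array([1.0, 1.0, 2.0, 2.0]), 5)


def test_orthopoly_reproduces_raw_polynomial():
    rng = np.random.default_rng(0)
    x = rng.uniform(-2, 2, 60)
    poly = OrthoPoly(3)
    Q = poly.fit(x)
    # columns are orthogonal and mean-centered
    np.testing.assert_allclose(Q.mean(axis=0), 0, atol=1e-12)
    off = Q.T @ Q - np.diag(np.diag(Q.T @ Q))
    assert np.abs(off).max() < 1e-8
    # new-data map evaluates the same basis
    np.testing.assert_allclose(poly.apply(x), Q, atol=1e-10)


def test_linear_recovery_exact():
    x = np.linspace(0, 1, 50)
    df = pd.DataFrame({"y": 2 * x + 1, "x": x})
    fit = fit_gam(ModelSpec("y", (ModelTerm("x", "I"),), includes_time=False), df,
                  config=GAMConfig(standardize=False))
    np.testing.assert_allclose(fit.fitted, df["y"], atol=1e-8)
    slope = fit.beta[1]  # single centered column, unstandardized
    assert slope == pytest.approx(2.0, abs=1e-8)
    assert fit.intercept + (-x.mean()) * slope + 0 == pytest.approx(
        fit.predict(pd.DataFrame({"x": [0.0]}))[0], abs=1e-8
    )


def test_poly2_in_span_exact():
    x = np.linspace(-1, 1, 50)
    df = pd.DataFrame({"y": x**2, "x": x})
    fit = fit_gam(ModelSpec("y", (ModelTerm("x", "poly2"),), includes_time=False), df)
    np.testing.assert_allclose(fit.fitted, df["y"], atol=1e-8)


def test_spline_fit_quality_fixed_seed():
    rng = np.random.default_rng(11)
    x = rng.uniform(0, 1, 200)
    truth = np.sin(2 * np.pi * x)
    df = pd.DataFrame({"y": truth + rng.normal(0, 0.1, 200), "x": x})
    fit = fit_gam(ModelSpec("y", (ModelTerm("x", "s"),), includes_time=False), df,
                  config=GAMConfig(k=10))
    assert np.mean((fit.fitted - truth) ** 2) < 0.02


def test_by_land_use_columns_masked():
    rng = np.random.default_rng(2)
    df = pd.DataFrame(
        {
            "y": rng.normal(size=40),
            "x": rng.normal(size=40),
            "land_use": ["cropland"] * 20 + ["grassland"] * 20,
        }
    )
    spec = ModelSpec("y", (ModelTerm("x", "I", by_land_use=True),), includes_time=False)
    fit = fit_gam(spec, df)
    X = fit.design.matrix(df)
    blk = [b for b in fit.design.blocks if b.name.startswith("x:")][0]
    cols = X[:, blk.sl]
    assert cols.shape[1] == 2
    # each column is constant (its centering offset) off its own level
    assert np.ptp(cols[20:, 0]) == pytest.approx(0.0, abs=1e-12)
    assert np.ptp(cols[:20, 1]) == pytest.approx(0.0, abs=1e-12)
    # land-use main effect automatically included
    assert any(b.name == "land_use" for b in fit.design.blocks)


def test_component_decomposition_and_centering(model_table):
    spec = ModelSpec(
        "rs_control",
        (ModelTerm("bacterial_j", "I"), ModelTerm("sand", "s"),
         ModelTerm("cn_ratio", "I", by_land_use=True)),
    )
    fit = fit_gam(spec, model_table)
    recon = fit.intercept + fit.components.sum(axis=1).to_numpy()
    np.testing.assert_allclose(recon, fit.fitted, atol=1e-8)
    X = fit.design.matrix(fit.data)
    # every non-intercept design column is mean-centered on training rows
    assert np.abs(X[:, 1:].mean(axis=0)).max() < 1e-8
    # effective df at least the number of unpenalized coefficients
    assert fit.edf >= fit.design.n_unpenalized - 1e-8


def test_prediction_on_training_rows_and_time_effects(model_table):
    spec = ModelSpec("rs_control", (ModelTerm("soc", "I"),))
    fit = fit_gam(spec, model_table)
    np.testing.assert_allclose(fit.predict(fit.data), fit.fitted, atol=1e-10)
    # intercept-plus-time model: new row at a known date gets that date's effect
    fit0 = fit_gam(ModelSpec("rs_control"), model_table)
    day = fit.data["day"].iloc[0]
    row = fit.data.iloc[[0]]
    time_block = fit0.components["time"].iloc[0]
    assert fit0.predict(row)[0] == pytest.approx(fit0.intercept + time_block, abs=1e-10)
    # linearity: doubling x moves the prediction by slope * dx
    d1 = fit.data.iloc[[0]].copy()
    d2 = d1.copy()
    d2["soc"] = d2["soc"] * 2
    blk = [b for b in fit.design.blocks if b.name.startswith("soc")][0]
    slope = fit.beta[blk.sl][0] / fit.design.blocks[-1].encoder.sd
    assert fit.predict(d2)[0] - fit.predict(d1)[0] == pytest.approx(
        slope * float(d1["soc"].iloc[0]), rel=1e-8
    )


def test_unseen_time_level_gets_zero_effect(model_table):
    fit = fit_gam(ModelSpec("rs_control"), model_table)
    row = model_table.iloc[[0]].copy()
    row["day"] = 999
    assert fit.predict(row)[0] == pytest.approx(fit.intercept, abs=1e-10)


def test_explained_deviance_cases():
    assert explained_deviance_values([0.0, 1.0, 2.0], [0.5, 1.0, 1.5]) == pytest.approx(
        75.0, abs=1e-10
    )
    y = np.array([1.0, 2.0, 4.0, 3.0])
    assert explained_deviance_values(y, y) == pytest.approx(100.0, abs=1e-10)
    assert explained_deviance_values(y, np.full(4, y.mean())) == pytest.approx(
        0.0, abs=1e-10
    )


def test_intercept_only_zero_deviance_explained():
    df = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0]})
    fit = fit_gam(ModelSpec("y", (), includes_time=False), df)
    assert explained_deviance(fit) == pytest.approx(0.0, abs=1e-8)


def test_nesting_ols_terms_never_increase_deviance():
    rng = np.random.default_rng(5)
    df = pd.DataFrame(
        {"y": rng.normal(size=80), "a": rng.normal(size=80), "b": rng.normal(size=80)}
    )
    base = fit_gam(ModelSpec("y", (ModelTerm("a", "I"),), includes_time=False), df)
    bigger = fit_gam(
        ModelSpec("y", (ModelTerm("a", "I"), ModelTerm("b", "poly2")),
                  includes_time=False), df
    )
    assert bigger.rss <= base.rss + 1e-10


def test_penalty_limit_is_linear_fit():
    rng = np.random.default_rng(8)
    x = rng.uniform(0, 1, 100)
    y = np.sin(3 * x) + rng.normal(0, 0.2, 100)
    df = pd.DataFrame({"y": y, "x": x})
    # force lambda -> huge: the spline collapses onto its null space (a line)
    cfg = GAMConfig(log_lambda_bounds=(25.0, 25.0))
    smooth = fit_gam(ModelSpec("y", (ModelTerm("x", "s"),), includes_time=False), df,
                     config=cfg)
    lin = fit_gam(ModelSpec("y", (ModelTerm("x", "I"),), includes_time=False), df)
    np.testing.assert_allclose(smooth.fitted, lin.fitted, atol=1e-4)


def test_significance_codes_and_strong_effect():
    assert significance_code(0.0005) == "***"
    assert significance_code(0.005) == "**"
    assert significance_code(0.03) == "*"
    assert significance_code(0.07) == "°"
    assert significance_code(0.2) == "ns"
    rng = np.random.default_rng(4)
    x = rng.normal(size=100)
    df = pd.DataFrame({"y": 5 * x + rng.normal(0, 0.1, 100), "x": x})
    fit = fit_gam(ModelSpec("y", (ModelTerm("x", "I"),), includes_time=False), df)
    sig = term_significance(fit)
    assert sig.loc[0, "code"] == "***"


def test_reml_criterion_close_to_gcv(model_table):
    spec = ModelSpec("rs_control", (ModelTerm("bacterial_j", "I"),))
    gcv = fit_gam(spec, model_table, config=GAMConfig(criterion="gcv"))
    reml = fit_gam(spec, model_table, config=GAMConfig(criterion="reml"))
    # same model, slightly different shrinkage; fits agree closely
    assert np.corrcoef(gcv.fitted, reml.fitted)[0, 1] > 0.999


def test_singular_fit_detected():
    df = pd.DataFrame({"y": [1.0, 2.0], "a": [0.0, 1.0], "b": [1.0, 0.0]})
    with pytest.raises(SingularFitError):
        fit_gam(
            ModelSpec("y", (ModelTerm("a", "I"), ModelTerm("b", "I")),
                      includes_time=False),
            df,
        )
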