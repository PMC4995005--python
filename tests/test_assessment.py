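"""RPIQ, variance partitioning, BIC and the kinetics ANOVA."""

import numpy as np
import pandas as pd
import pytest

from soilgam.assessment import (
    assess_model,
    bic,
    kinetics_anova,
    relative_importance,
    rpiq,
)
from soilgam.errors import DataError, NumericError
from soilgam.gam import GAMConfig, ModelSpec, ModelTerm, explained_deviance, fit_gam
from soilgam.selection import loso_msep


def test_rpiq_hand_values():
    y = [1.0, 1.0, 3.0, 3.0]  # Q1 = 1, Q3 = 3 -> IQR 2
    assert rpiq(y, 4.0) == pytest.approx(1.0, abs=1e-12)
    assert rpiq(y, 1.0) == pytest.approx(2.0, abs=1e-12)


def test_rpiq_scale_invariance():
    rng = np.random.default_rng(0)
    y = rng.normal(size=50)
    msep = 0.4
    c = 3.7  # rescaling response and predictions rescales MSEP by c^2
    assert rpiq(c * y, msep * c**2) == pytest.approx(rpiq(y, msep), rel=1e-12)


def test_rpiq_guards():
    with pytest.raises(NumericError):
        rpiq([1.0, 2.0, 3.0, 4.0], 0.0)
    with pytest.raises(DataError):
        rpiq([1.0, 2.0, 3.0], 1.0)


def _fit_on_components(c1, c2, y):
    df = pd.DataFrame({"y": y, "a": c1, "b": c2})
    spec = ModelSpec("y", (ModelTerm("a", "I"), ModelTerm("b", "I")),
                     includes_time=False)
    return fit_gam(spec, df)


def test_relative_importance_orthogonal_components_sum_to_pct_dev():
    rng = np.random.default_rng(1)
    q, _ = np.linalg.qr(np.column_stack([np.ones(60), rng.standard_normal((60, 2))]))
    c1, c2 = q[:, 1], q[:, 2]
    y = 2 * c1 + c2 + 0.1 * q[:, 0]  # constant part goes to the intercept
    fit = _fit_on_components(c1, c2, y)
    imp = relative_importance(fit)
    pct = explained_deviance(fit)
    assert imp["importance_pct"].sum() == pytest.approx(pct, abs=1e-6)
    # each orthogonal component's share is its marginal R^2
    marg = relative_importance(fit, attribution="marginal")
    np.testing.assert_allclose(imp["importance_pct"], marg["importance_pct"], atol=1e-6)


def test_relative_importance_single_component_equals_pct_dev():
    rng = np.random.default_rng(2)
    x = rng.normal(size=40)
    df = pd.DataFrame({"y": x + rng.normal(0, 0.5, 40), "x": x})
    fit = fit_gam(ModelSpec("y", (ModelTerm("x", "I"),), includes_time=False), df)
    imp = relative_importance(fit)
    assert len(imp) == 1
    assert imp["importance_pct"].iloc[0] == pytest.approx(explained_deviance(fit),
                                                          abs=1e-6)


def test_relative_importance_sequential_shared_variance():
    """y = c1 + c2 with corr(c1, c2) = 0.5 exactly: the first-listed
    component takes the shared part.  Closed form: var(y) = 3, seq share
    of c1 = corr(y, c1)^2 = (1.5)^2/3 = 75%, c2 adds the remaining 25%."""
    rng = np.random.default_rng(3)
    q, _ = np.linalg.qr(np.column_stack([np.ones(80), rng.standard_normal((80, 2))]))
    u1, u2 = q[:, 1] * np.sqrt(80), q[:, 2] * np.sqrt(80)  # unit-variance, orthogonal
    c1 = u1
    c2 = 0.5 * u1 + np.sqrt(1 - 0.25) * u2  # sample corr exactly 0.5
    y = c1 + c2
    fit = _fit_on_components(c1, c2, y)
    imp = relative_importance(fit)
    np.testing.assert_allclose(imp["importance_pct"], [75.0, 25.0], atol=1e-6)
    assert imp.attrs["remainder"] == pytest.approx(0.0, abs=1e-6)


def test_relative_importance_remainder_identity(model_table):
    spec = ModelSpec("rs_control", (ModelTerm("bacterial_j", "I"),
                                    ModelTerm("sand", "s")))
    fit = fit_gam(spec, model_table)
    imp = relative_importance(fit)
    total = imp["importance_pct"].sum() + imp.attrs["remainder"]
    assert total == pytest.approx(explained_deviance(fit), abs=1e-6)
    assert (imp["importance_pct"] >= -1e-10).all()
    assert imp["component"].iloc[0] == "time"  # time attributed first


def test_bic_hand_value_and_monotonicity():
    class Dummy:
        n = 100
        rss = 100.0
        edf = 3.0

    assert bic(Dummy()) == pytest.approx(3 * np.log(100), abs=1e-10)
    worse = Dummy()
    worse.rss = 150.0
    assert bic(worse) > bic(Dummy())


def test_bic_ordering_of_nested_fits():
    rng = np.random.default_rng(4)
    x = rng.normal(size=120)
    noise = rng.normal(size=120)
    df = pd.DataFrame({"y": x + 0.3 * noise, "x": x, "junk": rng.normal(size=120)})
    good = fit_gam(ModelSpec("y", (ModelTerm("x", "I"),), includes_time=False), df)
    overfit = fit_gam(
        ModelSpec("y", (ModelTerm("x", "I"), ModelTerm("junk", "s")),
                  includes_time=False), df
    )
    assert bic(good) < bic(overfit)


def _kinetics_frame(seed=0, shift=0.0, land_use_gap=0.0, time_gap=0.0, n_rep=3,
                    days=(3, 7, 14, 21)):
    rng = np.random.default_rng(seed)
    rows = []
    for lu in ("cropland", "grassland"):
        for site in range(5):
            for rep in range(n_rep):
                for i, d in enumerate(days):
                    y = shift + rng.normal(0, 1)
                    y += land_use_gap * (lu == "grassland")
                    y += time_gap * i
                    rows.append({"land_use": lu, "day": d, "value": y})
    return pd.DataFrame(rows)


def test_kinetics_anova_overwhelming_time_separation():
    df = _kinetics_frame(seed=1, time_gap=10.0)
    res = kinetics_anova(df, "value")
    letters = res["time_letters"]
    assert len(set(letters.values())) == len(letters)  # all levels distinct
    a = res["anova"].set_index("effect")
    assert a.loc["time", "p_value"] < 1e-4


def test_kinetics_anova_translation_invariance():
    base = _kinetics_frame(seed=2, land_use_gap=0.5)
    shifted = base.copy()
    shifted["value"] = shifted["value"] + 1.0
    r1 = kinetics_anova(base, "value")
    r2 = kinetics_anova(shifted, "value")
    np.testing.assert_allclose(r1["anova"]["F"], r2["anova"]["F"], rtol=1e-10)
    assert r1["time_letters"] == r2["time_letters"]


def test_kinetics_anova_identical_means_single_letter_group():
    df = _kinetics_frame(seed=3)
    res = kinetics_anova(df, "value")
    # no true differences: all time levels typically share a letter
    letters = set(res["time_letters"].values())
    assert any(len(s) >= 1 for s in letters)
    a = res["anova"].set_index("effect")
    assert a.loc["land_use", "p_value"] > 0.001


def test_assess_model_report_block(model_table, default_dataset):
    spec = ModelSpec("rs_control", (ModelTerm("bacterial_j", "I"),))
    fit = fit_gam(spec, model_table)
    msep, _ = loso_msep(spec, model_table)
    rep = assess_model(fit, msep)
    assert rep.response == "rs_control"
    assert rep.terms[0]["covariate"] == "Time"
    assert rep.terms[1]["covariate"] == "Bacterial J'"
    assert rep.rpiq == pytest.approx(
        rpiq(model_table["rs_control"].dropna(), msep), rel=1e-10
    )
    assert 0 < rep.pct_deviance <= 100
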