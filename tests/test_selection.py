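"""Leave-one-soil-out MSEP, VIF screening and the stepwise search."""

import itertools

import numpy as np
import pandas as pd
import pytest

from soilgam.errors import DataError
from soilgam.gam import GAMConfig, ModelSpec, ModelTerm
from soilgam.selection import (
    SelectionConfig,
    loso_msep,
    prediction_mse,
    stepwise_select,
    vif_prescreen,
)


def _response_data(n_sites=20, n_rep=3, n_dates=8, sigma=0.3, effects=(), seed=0,
                   n_noise=0):
    """Site-level covariates with a time-structured response (direct scale)."""
    rng = np.random.default_rng(seed)
    date_eff = np.linspace(1.5, -1.5, n_dates)
    days = [3, 7, 14, 21, 28, 44, 60, 80][:n_dates]
    cov_names = [name for name, _ in effects] + [f"noise{i}" for i in range(n_noise)]
    site_cov = {c: rng.standard_normal(n_sites) for c in cov_names}
    rows = []
    for i in range(n_sites):
        land_use = "cropland" if i < n_sites // 2 else "grassland"
        for rep in range(1, n_rep + 1):
            for d in range(n_dates):
                y = date_eff[d] + rng.normal(0, sigma)
                for name, amp in effects:
                    y += amp * site_cov[name][i]
                rows.append(
                    {"site_id": f"S{i:02d}", "land_use": land_use, "replicate": rep,
                     "day": days[d], "y": y,
                     **{c: site_cov[c][i] for c in cov_names}}
                )
    data = pd.DataFrame(rows)
    site_table = data.drop_duplicates("site_id")[["site_id", "land_use"] + cov_names]
    return data, site_table.reset_index(drop=True)


def test_prediction_mse_hand_example():
    assert prediction_mse([1.0, 2.0, 3.0], [1.0, 1.0, 1.0]) == pytest.approx(
        5.0 / 3.0, abs=1e-12
    )


def test_loso_msep_hand_case():
    """Intercept-only model, 3 single-value soils: fold predictions are
    the training means, so the MSEP is computable by hand (= 4.5)."""
    data = pd.DataFrame(
        {
            "site_id": ["A", "A", "B", "B", "C", "C"],
            "day": [3, 7] * 3,
            "y": [0.0, 0.0, 3.0, 3.0, 3.0, 3.0],
        }
    )
    msep, preds = loso_msep(ModelSpec("y", (), includes_time=False), data)
    # fold A: train mean 3 -> err 9 twice; folds B, C: mean 1.5 -> err 2.25 x2
    assert msep == pytest.approx(27.0 / 6.0, abs=1e-10)
    assert len(preds) == 6


def test_loso_perfect_predictor_and_fold_count(model_table):
    const = model_table.copy()
    const["flat"] = 1.0
    # response identical for all rows of a date -> time model predicts exactly
    day_mean = {d: float(i) for i, d in enumerate(sorted(const["day"].unique()))}
    const["det"] = const["day"].map(day_mean)
    msep, preds = loso_msep(ModelSpec("det"), const)
    assert msep == pytest.approx(0.0, abs=1e-9)  # up to residual ridge shrinkage
    assert preds["site_id"].nunique() == 20
    counts = preds.groupby("site_id").size()
    assert (counts == 24).all()  # every fold holds out all rows of one soil


def test_fold_hygiene_held_out_rows_do_not_influence_their_prediction(model_table):
    spec = ModelSpec("rs_control", (ModelTerm("soc", "I"),))
    _, preds = loso_msep(spec, model_table)
    soil = "S01"
    perturbed = model_table.copy()
    perturbed.loc[perturbed["site_id"] == soil, "rs_control"] += 100.0
    _, preds2 = loso_msep(spec, perturbed)
    a = preds[preds["site_id"] == soil]["y_hat"].to_numpy()
    b = preds2[preds2["site_id"] == soil]["y_hat"].to_numpy()
    np.testing.assert_allclose(a, b, atol=1e-10)


def test_vif_orthogonal_collinear_and_thresholds():
    rng = np.random.default_rng(0)
    n = 20
    # unit columns orthogonal to each other AND to the intercept
    q, _ = np.linalg.qr(np.column_stack([np.ones(n), rng.standard_normal((n, 4))]))
    s1 = q[:, 1]
    orth = q[:, 2]
    r = q[:, 3]
    site = pd.DataFrame(
        {
            "site_id": [f"S{i}" for i in range(n)],
            "s1": s1,
            "orthogonal": orth,
            "twice_s1": 2 * s1,
            # R^2 on s1 exactly 0.8 -> VIF 5 (excluded); 0.75 -> VIF 4 (kept)
            "r2_08": np.sqrt(0.8) * s1 + np.sqrt(0.2) * r,
            "r2_075": np.sqrt(0.75) * s1 + np.sqrt(0.25) * r,
        }
    )
    admissible, vifs = vif_prescreen(
        ["orthogonal", "twice_s1", "r2_08", "r2_075"], ["s1"], site
    )
    assert vifs["orthogonal"] == pytest.approx(1.0, abs=1e-9)
    assert np.isinf(vifs["twice_s1"])
    assert vifs["r2_08"] == pytest.approx(5.0, rel=1e-9)
    assert vifs["r2_075"] == pytest.approx(4.0, rel=1e-9)
    assert admissible == ["orthogonal", "r2_075"]


def test_vif_empty_selection_admits_everything():
    site = pd.DataFrame({"site_id": ["a", "b", "c"], "x": [1.0, 2.0, 3.0],
                         "z": [2.0, 4.0, 6.0]})
    admissible, vifs = vif_prescreen(["x", "z"], [], site)
    assert admissible == ["x", "z"]
    assert set(vifs.values()) == {1.0}


def test_stepwise_matches_exhaustive_identity_search():
    """Greedy search vs brute force over all identity-term subsets."""
    data, site = _response_data(
        effects=[("x1", 0.8)], n_noise=2, sigma=0.3, seed=3
    )
    cfg = SelectionConfig(candidates=("x1", "noise0", "noise1"), forms=("I",),
                          interaction_mode="never")
    spec, trace, _ = stepwise_select(data, "y", site, cfg)
    best = np.inf
    for r in range(4):
        for subset in itertools.combinations(("x1", "noise0", "noise1"), r):
            cand = ModelSpec("y", tuple(ModelTerm(c, "I") for c in subset))
            m, _ = loso_msep(cand, data)
            best = min(best, m)
    assert trace.final_msep <= best * 1.01
    assert any(t.covariate == "x1" for t in spec.terms)


def test_stepwise_deterministic(model_table, default_dataset):
    ds, _ = default_dataset
    cfg = SelectionConfig(candidates=("bacterial_j", "soc"), forms=("I", "poly2"),
                          interaction_mode="never")
    out1 = stepwise_select(model_table, "rs_control", ds.sites, cfg)
    out2 = stepwise_select(model_table, "rs_control", ds.sites, cfg)
    assert out1[0] == out2[0]
    assert out1[1].to_json() == out2[1].to_json()


def test_trace_monotone_and_msep_reproducible(model_table, default_dataset):
    ds, _ = default_dataset
    cfg = SelectionConfig(candidates=("bacterial_j", "ph"), forms=("I",),
                          interaction_mode="never")
    spec, trace, _ = stepwise_select(model_table, "rs_control", ds.sites, cfg)
    mseps = [s.msep_before for s in trace.steps]
    assert all(b < a for a, b in zip(mseps, mseps[1:]))
    assert trace.steps[-1].move == "stop"
    recomputed, _ = loso_msep(spec, model_table, cfg.gam)
    assert recomputed == pytest.approx(trace.final_msep, rel=1e-9)


def test_remove_move_drops_redundant_injected_term():
    """A noisy proxy in the starting model is removed after the true
    covariate (its superior substitute) enters."""
    data, site = _response_data(effects=[("x1", 1.0)], sigma=0.3, seed=0)
    rng = np.random.default_rng(100)
    proxy = dict(
        zip(site["site_id"], site["x1"].to_numpy() + 0.7 * rng.standard_normal(len(site)))
    )
    data["proxy"] = data["site_id"].map(proxy)
    site = site.copy()
    site["proxy"] = site["site_id"].map(proxy)
    cfg = SelectionConfig(candidates=("x1", "proxy"), forms=("I",),
                          interaction_mode="never")
    start = ModelSpec("y", (ModelTerm("proxy", "I"),))
    spec, trace, _ = stepwise_select(data, "y", site, cfg, initial=start)
    moves = [(s.move, s.term) for s in trace.steps]
    assert ("add", "x1:I") in moves
    assert ("remove", "proxy:I") in moves
    assert [t.covariate for t in spec.terms] == ["x1"]


def test_loso_needs_three_soils():
    data = pd.DataFrame({"site_id": ["A", "B"], "day": [3, 3], "y": [1.0, 2.0]})
    with pytest.raises(DataError):
        loso_msep(ModelSpec("y", (), includes_time=False), data)
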