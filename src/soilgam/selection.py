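"""Cross-validated stepwise covariate selection.

The search starts from the simplest admissible model, intercept plus
the random time factor, and greedily improves the leave-one-soil-out
mean squared error of prediction (MSEP):

1. compute the MSEP of the current model;
2. screen the not-yet-selected covariates for collinearity with the
   selected ones (variance inflation factor, threshold 4, computed at
   site level on the raw covariates);
3. enumerate candidate moves — add one admissible covariate under each
   functional form (I, poly2, poly3, s), with and/or without the
   land-use interaction, or remove one selected term;
4. evaluate the MSEP of every candidate;
5. accept the best move if its MSEP is strictly smaller, else stop.

The fold unit is an entire soil: all its dates, treatments and
replicates are held out together, so a soil never contributes to its
own prediction.  The procedure is deterministic: candidates are
enumerated in config order (forms I, poly2, poly3, s; plain before
interacting) and ties are broken by fewer effective degrees of
freedom, then enumeration order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, SoilGamError
from .gam import FORMS, GAMConfig, FittedGAM, ModelSpec, ModelTerm, fit_gam

logger = logging.getLogger(__name__)


@dataclass
class SelectionConfig:
    candidates: tuple[str, ...] = ()
    forms: tuple[str, ...] = FORMS
    interaction_mode: str = "both"  # both | always | never
    vif_threshold: float = 4.0
    max_iter: int = 50
    gam: GAMConfig = field(default_factory=GAMConfig)

    def __post_init__(self):
        if self.interaction_mode not in ("both", "always", "never"):
            raise ConfigError(f"unknown interaction_mode {self.interaction_mode!r}")
        bad = set(self.forms) - set(FORMS)
        if bad:
            raise ConfigError(f"unknown form(s) {sorted(bad)}")


def prediction_mse(y, y_hat) -> float:
    """Mean squared error of prediction: (1/N) sum (y - y_hat)^2."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size == 0:
        raise DataError("y and y_hat must be nonempty and of equal length")
    return float(np.mean((y - y_hat) ** 2))


def loso_msep(
    spec: ModelSpec,
    data: pd.DataFrame,
    config: GAMConfig | None = None,
    *,
    shared_design: bool = True,
) -> tuple[float, pd.DataFrame]:
    """Leave-one-soil-out MSEP of a model.

    For each soil, the model is refit (smoothing parameters included) on
    the remaining soils and used to predict every held-out row; MSEP is
    the mean squared prediction error over all held-out rows.  Folds
    whose model cannot be fit are skipped with a warning and N adjusted.

    With ``shared_design`` (the default) models containing no spline
    term build the model matrix once and form each fold's normal
    equations by subtracting the held-out soil's cross-product blocks.
    For identity, polynomial, land-use and time blocks this is
    algebraically identical to refitting per fold: those bases are
    affine families whose centering/scaling constants are absorbed by
    the intercept, so the per-fold fit and prediction are unchanged (to
    float noise) while the fold loop becomes much cheaper.  Spline
    models always take the literal per-fold path, because their knots
    are placed at quantiles of the training fold's covariate values and
    must not see the held-out soil.

    Returns (msep, predictions frame with columns site_id/y/y_hat).
    """
    config = config or GAMConfig()
    if data.attrs:
        data = data.copy(deep=False)
        data.attrs = {}
    data = data.loc[np.isfinite(data[spec.response].to_numpy(float))].reset_index(drop=True)
    soils = pd.unique(data["site_id"])
    if len(soils) < 3:
        raise DataError(f"need >= 3 soils for leave-one-soil-out CV, got {len(soils)}")
    if shared_design and not any(t.form == "s" for t in spec.terms):
        return _loso_msep_shared(spec, data, soils, config)
    preds = []
    skipped = []
    for soil in soils:
        # each fold re-optimizes its smoothing parameters from a fixed,
        # data-independent start: a held-out soil can never influence
        # its own prediction, not even through the lambda search
        test = data[data["site_id"] == soil]
        train = data[data["site_id"] != soil]
        try:
            fit = fit_gam(spec, train, config=config)
            y_hat = fit.predict(test)
        except SoilGamError as exc:
            logger.warning("fold %r skipped: %s", soil, exc)
            skipped.append(str(soil))
            continue
        preds.append(
            pd.DataFrame(
                {
                    "site_id": soil,
                    "y": test[spec.response].to_numpy(float),
                    "y_hat": y_hat,
                }
            )
        )
    if not preds:
        raise DataError("every cross-validation fold failed")
    out = pd.concat(preds, ignore_index=True)
    out.attrs["skipped_folds"] = skipped
    msep = prediction_mse(out["y"], out["y_hat"])
    return msep, out


def _loso_msep_shared(spec, data, soils, config):
    """Fold loop on precomputed per-soil cross-product blocks."""
    from .gam import GAMDesign, _embed_penalties, optimize_crossprods

    design = GAMDesign(spec, config)
    X = design.build(data)
    y = data[spec.response].to_numpy(float)
    site_ids = data["site_id"].to_numpy()
    penalties = design.penalties
    embedded = _embed_penalties(penalties, design.n_cols)
    XtX_full = X.T @ X
    Xty_full = X.T @ y
    yty_full = float(y @ y)
    n_full = len(y)
    preds = []
    skipped = []
    for soil in soils:
        mask = site_ids == soil
        Xs = X[mask]
        ys = y[mask]
        XtX = XtX_full - Xs.T @ Xs
        Xty = Xty_full - Xs.T @ ys
        yty = yty_full - float(ys @ ys)
        n_tr = n_full - int(mask.sum())
        if n_tr <= design.n_unpenalized:
            logger.warning("fold %r skipped: too few training rows", soil)
            skipped.append(str(soil))
            continue
        try:
            _, beta, _, _, _, _ = optimize_crossprods(
                XtX, Xty, yty, penalties, embedded, n_tr, design.n_unpenalized,
                config,
            )
        except SoilGamError as exc:
            logger.warning("fold %r skipped: %s", soil, exc)
            skipped.append(str(soil))
            continue
        preds.append(
            pd.DataFrame({"site_id": soil, "y": ys, "y_hat": Xs @ beta})
        )
    if not preds:
        raise DataError("every cross-validation fold failed")
    out = pd.concat(preds, ignore_index=True)
    out.attrs["skipped_folds"] = skipped
    return prediction_mse(out["y"], out["y_hat"]), out


def vif_prescreen(
    candidates,
    selected,
    site_table: pd.DataFrame,
    threshold: float = 4.0,
) -> tuple[list, dict]:
    """Variance-inflation screening of candidates against selected covariates.

    Each candidate is regressed (OLS with intercept, site-level rows, raw
    covariate values) on the selected covariates; VIF = 1/(1 - R^2).
    Candidates with VIF above ``threshold`` are excluded; exact
    collinearity records VIF = inf.  With nothing selected all
    candidates are admissible (VIF = 1).
    """
    selected = [s for s in selected]
    vifs = {}
    admissible = []
    n = len(site_table)
    X = (
        np.column_stack(
            [np.ones(n)] + [site_table[s].to_numpy(float) for s in selected]
        )
        if selected
        else np.ones((n, 1))
    )
    for c in candidates:
        yv = site_table[c].to_numpy(float)
        tss = float(((yv - yv.mean()) ** 2).sum())
        if not selected or tss == 0:
            vifs[c] = 1.0
            admissible.append(c)
            continue
        coef, *_ = np.linalg.lstsq(X, yv, rcond=None)
        rss = float(((yv - X @ coef) ** 2).sum())
        r2 = 1.0 - rss / tss
        vif = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        vifs[c] = float(vif)
        if vif <= threshold:
            admissible.append(c)
    return admissible, vifs


@dataclass
class SelectionStep:
    move: str  # add | remove | stop
    term: str | None
    msep_before: float
    msep_after: float | None
    n_candidates: int
    vif_excluded: dict


@dataclass
class SelectionTrace:
    response: str
    steps: list = field(default_factory=list)

    @property
    def final_msep(self) -> float:
        return self.steps[-1].msep_before

    def validate(self):
        """Accepted moves must strictly decrease MSEP; last step is stop."""
        if not self.steps or self.steps[-1].move != "stop":
            raise SoilGamError("trace does not end in a stop step")
        for s in self.steps[:-1]:
            if not (s.msep_after < s.msep_before):
                raise SoilGamError("accepted step did not decrease MSEP")

    def to_json(self) -> str:
        return json.dumps(
            {
                "response": self.response,
                "steps": [
                    {
                        "move": s.move,
                        "term": s.term,
                        "msep_before": s.msep_before,
                        "msep_after": s.msep_after,
                        "n_candidates": s.n_candidates,
                        "vif_excluded": s.vif_excluded,
                    }
                    for s in self.steps
                ],
            },
            indent=2,
        )


def _candidate_moves(spec: ModelSpec, admissible, cfg: SelectionConfig):
    """Enumerate add and remove moves in deterministic order."""
    moves = []
    flags = {"both": (False, True), "always": (True,), "never": (False,)}[
        cfg.interaction_mode
    ]
    for cov in admissible:
        for form in cfg.forms:
            for by_lu in flags:
                term = ModelTerm(cov, form, by_lu)
                moves.append(("add", term, spec.with_term(term)))
    for t in spec.terms:
        moves.append(("remove", t, spec.without(t.covariate)))
    return moves


def stepwise_select(
    data: pd.DataFrame,
    response: str,
    site_table: pd.DataFrame,
    config: SelectionConfig | None = None,
    initial: ModelSpec | None = None,
) -> tuple[ModelSpec, SelectionTrace, FittedGAM]:
    """Run the full selection loop for one response.

    ``data`` is the model table (one row per design cell with the
    response, site_id, land_use, day and covariate columns);
    ``site_table`` has one row per soil and is used for VIF screening.
    ``initial`` overrides the default intercept+time starting model
    (its covariates are taken out of the pool).
    Returns the selected spec, the trace and the final fit on all data.
    """
    cfg = config or SelectionConfig()
    candidates = list(cfg.candidates) or [
        c
        for c in site_table.columns
        if c not in ("site_id", "land_use") and c in data.columns
    ]
    unknown = [c for c in candidates if c not in data.columns]
    if unknown:
        raise ConfigError(f"candidate covariate(s) not in data: {unknown}")
    spec = initial if initial is not None else ModelSpec(response=response)
    current_msep, _ = loso_msep(spec, data, cfg.gam)
    trace = SelectionTrace(response=response)
    pool = [c for c in candidates if c not in {t.covariate for t in spec.terms}]
    for _ in range(cfg.max_iter):
        selected_covs = [t.covariate for t in spec.terms]
        admissible, vifs = vif_prescreen(
            pool, selected_covs, site_table, cfg.vif_threshold
        )
        excluded = {c: v for c, v in vifs.items() if c not in admissible}
        moves = _candidate_moves(spec, admissible, cfg)
        if not moves:
            trace.steps.append(
                SelectionStep("stop", None, current_msep, None, 0, excluded)
            )
            break
        results = []
        for order, (kind, term, cand_spec) in enumerate(moves):
            try:
                msep, _ = loso_msep(cand_spec, data, cfg.gam)
            except SoilGamError as exc:
                logger.warning("candidate %s skipped: %s", term.label, exc)
                continue
            results.append((msep, order, kind, term, cand_spec))
        if not results:
            trace.steps.append(
                SelectionStep("stop", None, current_msep, None, len(moves), excluded)
            )
            break
        best_msep = min(r[0] for r in results)
        # ties (within numerical noise): fewer effective df, then order
        tied = [r for r in results if r[0] <= best_msep * (1 + 1e-12)]
        if len(tied) > 1:
            edfs = []
            for msep, order, kind, term, cand_spec in tied:
                edfs.append((fit_gam(cand_spec, data, config=cfg.gam).edf, order))
            pick = tied[int(np.lexsort((
                [o for _, o in edfs], [e for e, _ in edfs]
            ))[0])]
        else:
            pick = tied[0]
        msep, order, kind, term, cand_spec = pick
        logger.info(
            "%s: best move %s %s MSEP %.6g (current %.6g, %d candidates)",
            response, kind, term.label, msep, current_msep, len(moves),
        )
        if msep < current_msep:
            trace.steps.append(
                SelectionStep(kind, term.label, current_msep, msep, len(moves), excluded)
            )
            if kind == "add":
                pool.remove(term.covariate)
            else:
                pool.append(term.covariate)
                pool.sort(
                    key=lambda c: candidates.index(c) if c in candidates else len(candidates)
                )
            spec = cand_spec
            current_msep = msep
        else:
            trace.steps.append(
                SelectionStep("stop", None, current_msep, None, len(moves), excluded)
            )
            break
    else:
        raise SoilGamError(
            f"selection iteration cap ({cfg.max_iter}) reached; trace: {trace.to_json()}"
        )
    trace.validate()
    final_fit = fit_gam(spec, data, config=cfg.gam)
    return spec, trace, final_fit
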