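"""Post-selection model assessment.

Quality of a selected model is summarized by the percentage of
explained deviance (%Dev, goodness of fit), the leave-one-soil-out
MSEP and the derived RPIQ (inter-quartile range of the response over
root MSEP, a scale-free index of predictive quality), plus a BIC for
model-family comparison.  The relative importance of each model
component is obtained by variance partitioning: the per-term columns
of the linear predictor are treated as explanatory variables in a
redundancy analysis of the (single) response, and each component is
credited with its sequential sum of squares as a share of the total
response sum of squares.

The kinetics comparison between land uses is a two-way ANOVA per
mineralisation kinetic with land use fixed and time random (fixed
effects tested against the interaction mean square), with Tukey HSD
letters across sampling times and per-time land-use contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, NumericError
from .gam import (
    FittedGAM,
    GAMConfig,
    RELATION_CODES,
    explained_deviance,
    significance_code,
    term_significance,
)


def rpiq(response_values, msep: float) -> float:
    """Ratio of the response inter-quartile range to root MSEP.

    Quartiles use linear-interpolation quantiles.  A zero MSEP means a
    perfect predictor, for which the ratio is undefined.
    """
    y = np.asarray(response_values, dtype=float)
    y = y[np.isfinite(y)]
    if y.size < 4:
        raise DataError(f"need >= 4 response values for quartiles, got {y.size}")
    if msep <= 0:
        raise NumericError("MSEP is zero: RPIQ undefined (perfect prediction)")
    q1, q3 = np.percentile(y, [25, 75], method="linear")
    return float((q3 - q1) / np.sqrt(msep))


def relative_importance(fitted: FittedGAM, attribution: str = "sequential") -> pd.DataFrame:
    """Share of response variance attributed to each linear-predictor component.

    ``sequential`` regresses the response on the component columns in
    model order (time first, then terms in selection order) and credits
    each component with its sequential sum of squares / total SS x 100,
    so shared variance goes to the earlier component; ``marginal``
    credits each component with its standalone R^2 x 100.  The
    difference between %Dev and the attributed total is returned in the
    ``remainder`` attribute (shared / unattributed variance).
    """
    if attribution not in ("sequential", "marginal"):
        raise DataError(f"unknown attribution mode {attribution!r}")
    C = fitted.components.to_numpy(float)
    names = list(fitted.components.columns)
    y = fitted.y
    yc = y - y.mean()
    tss = float(yc @ yc)
    if tss <= 0:
        raise NumericError("response has zero variance")
    n = len(y)
    shares = []
    if attribution == "marginal":
        for j in range(C.shape[1]):
            X = np.column_stack([np.ones(n), C[:, j]])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(((y - X @ coef) ** 2).sum())
            shares.append(100.0 * (1.0 - rss / tss))
    else:
        prev_rss = tss
        X = np.ones((n, 1))
        for j in range(C.shape[1]):
            X = np.column_stack([X, C[:, j]])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(((y - X @ coef) ** 2).sum())
            shares.append(100.0 * (prev_rss - rss) / tss)
            prev_rss = rss
    out = pd.DataFrame({"component": names, "importance_pct": shares})
    pct_dev = explained_deviance(fitted)
    out.attrs["pct_deviance"] = pct_dev
    out.attrs["remainder"] = pct_dev - float(np.sum(shares))
    return out


def bic(fitted: FittedGAM) -> float:
    """Gaussian profile BIC, n ln(RSS/n) + edf ln(n), with effective df."""
    if fitted.rss <= 0:
        raise NumericError("zero RSS: BIC undefined (degenerate likelihood)")
    n = fitted.n
    return float(n * np.log(fitted.rss / n) + fitted.edf * np.log(n))


# ---------------------------------------------------------------------------
# kinetics ANOVA (land use fixed, time random) with Tukey groupings
# ---------------------------------------------------------------------------


def _tukey_letters(means: pd.Series, nobs: pd.Series, mse: float, df_err: float,
                   alpha: float = 0.05) -> dict:
    """Compact letter display from pairwise Tukey HSD comparisons."""
    levels = list(means.index)
    diff = {}
    for a, b in combinations(levels, 2):
        se = np.sqrt(mse / 2 * (1 / nobs[a] + 1 / nobs[b]))
        q = abs(means[a] - means[b]) / se
        p = stats.studentized_range.sf(q, len(levels), df_err)
        diff[(a, b)] = p < alpha
    # insert-absorb algorithm: grow letter groups of mutually similar levels
    order = sorted(levels, key=lambda l: means[l])
    groups: list[set] = []
    for lev in order:
        placed = False
        for g in groups:
            if all(not diff.get((min(lev, o), max(lev, o)), diff.get((o, lev), False))
                   if (min(lev, o), max(lev, o)) in diff or (o, lev) in diff
                   else True
                   for o in g):
                g.add(lev)
                placed = True
        if not placed:
            groups.append({lev})
    # drop groups fully contained in another
    groups = [g for g in groups if not any(g < h for h in groups)]
    letters = {lev: "" for lev in levels}
    for i, g in enumerate(sorted(groups, key=lambda g: min(means[l] for l in g))):
        for lev in g:
            letters[lev] += chr(ord("a") + i)
    return {lev: "".join(sorted(s)) for lev, s in letters.items()}


def kinetics_anova(
    rates: pd.DataFrame,
    value_col: str,
    *,
    alpha: float = 0.05,
) -> dict:
    """Two-way ANOVA of one kinetic with land use fixed and time random.

    ``rates`` needs columns land_use, day, and ``value_col`` (one row
    per microcosm per date).  With time random, the land-use and time
    mean squares are tested against the interaction mean square and the
    interaction against the residual.  Returns the ANOVA table, Tukey
    HSD letters across sampling times, and the land-use contrast
    (Welch t test) with a significance code at each time.  Unbalanced
    designs are handled with type-II sums of squares.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = rates.dropna(subset=[value_col]).copy()
    if df["land_use"].nunique() < 2 or df["day"].nunique() < 2:
        raise DataError("need >= 2 levels of land use and time")
    df["_y"] = df[value_col].astype(float)
    counts = df.groupby(["land_use", "day"]).size()
    balanced = counts.nunique() == 1
    full_design = df["land_use"].nunique() * df["day"].nunique()
    if len(counts) < full_design:
        raise DataError("empty cell(s) in the land-use x time design")
    model = smf.ols("_y ~ C(land_use) * C(day)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2 if not balanced else 1)
    table = table.rename(
        index={
            "C(land_use)": "land_use",
            "C(day)": "time",
            "C(land_use):C(day)": "land_use:time",
            "Residual": "residual",
        }
    )
    ms = table["sum_sq"] / table["df"]
    # mixed-model F ratios: fixed and random main effects over interaction MS
    out_rows = []
    for eff, denom in (("land_use", "land_use:time"), ("time", "land_use:time"),
                       ("land_use:time", "residual")):
        F = ms[eff] / ms[denom]
        p = float(stats.f.sf(F, table.loc[eff, "df"], table.loc[denom, "df"]))
        out_rows.append(
            {"effect": eff, "df": table.loc[eff, "df"],
             "denom_df": table.loc[denom, "df"], "F": float(F), "p_value": p,
             "code": significance_code(p)}
        )
    anova = pd.DataFrame(out_rows)

    # Tukey letters across times (pooled over land use), residual-based error
    mse = float(ms["residual"])
    df_err = float(table.loc["residual", "df"])
    means = df.groupby("day")["_y"].mean()
    nobs = df.groupby("day")["_y"].size()
    letters = _tukey_letters(means, nobs, mse, df_err, alpha=alpha)

    # land-use contrast at each time
    contrasts = []
    for day, sub in df.groupby("day"):
        a, b = sorted(sub["land_use"].unique())
        ya = sub.loc[sub["land_use"] == a, "_y"]
        yb = sub.loc[sub["land_use"] == b, "_y"]
        t, p = stats.ttest_ind(ya, yb, equal_var=False)
        contrasts.append(
            {"day": day, "mean_" + str(a): ya.mean(), "mean_" + str(b): yb.mean(),
             "t": float(t), "p_value": float(p), "code": significance_code(float(p))}
        )
    return {
        "anova": anova,
        "time_letters": letters,
        "land_use_contrasts": pd.DataFrame(contrasts),
        "balanced": balanced,
    }


# ---------------------------------------------------------------------------
# assembled per-response report
# ---------------------------------------------------------------------------


@dataclass
class AssessmentReport:
    """Model-level quality plus one row per component (time first)."""

    response: str
    df: float
    pct_deviance: float
    msep: float
    rpiq: float
    terms: list = field(default_factory=list)

    def to_dict(self):
        return {
            "response": self.response,
            "df": self.df,
            "pct_deviance": self.pct_deviance,
            "msep": self.msep,
            "rpiq": self.rpiq,
            "terms": self.terms,
        }


COVARIATE_LABELS = {
    "clay": "Clay",
    "silt": "Silt",
    "sand": "Sand",
    "clay_fine_silt": "Clay+Fine Silt",
    "soc": "SOC",
    "cn_ratio": "C:N ratio",
    "ph": "pH",
    "molecular_biomass": "Molecular biomass",
    "bacterial_richness": "Bacterial richness",
    "fungal_richness": "Fungal richness",
    "bacterial_h": "Bacterial H'",
    "fungal_h": "Fungal H'",
    "bacterial_j": "Bacterial J'",
    "fungal_j": "Fungal J'",
    "bacterial_invd": "Bacterial 1/D",
    "fungal_invd": "Fungal 1/D",
}


def assess_model(
    fitted: FittedGAM,
    msep: float,
    *,
    attribution: str = "sequential",
    gam_config: GAMConfig | None = None,
) -> AssessmentReport:
    """Assemble the per-response report block from a final fit and its MSEP."""
    imp = relative_importance(fitted, attribution=attribution)
    imp_map = dict(zip(imp["component"], imp["importance_pct"]))
    sig = term_significance(fitted, config=gam_config)
    sig_map = dict(zip(sig["term"], sig["code"]))
    terms = []
    if fitted.spec.includes_time:
        terms.append(
            {
                "covariate": "Time",
                "interaction": False,
                "relation": RELATION_CODES["time"],
                "significance": sig_map.get("time", ""),
                "relative_importance_pct": round(imp_map.get("time", 0.0), 1),
            }
        )
    for t in fitted.spec.terms:
        terms.append(
            {
                "covariate": COVARIATE_LABELS.get(t.covariate, t.covariate),
                "interaction": bool(t.by_land_use),
                "relation": RELATION_CODES[t.form],
                "significance": sig_map.get(t.label, ""),
                "relative_importance_pct": round(imp_map.get(t.label, 0.0), 1),
            }
        )
    return AssessmentReport(
        response=fitted.spec.response,
        df=fitted.edf,
        pct_deviance=explained_deviance(fitted),
        msep=msep,
        rpiq=rpiq(fitted.y, msep),
        terms=terms,
    )
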