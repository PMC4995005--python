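"""Penalized additive models for the log mineralisation rates.

Model structure: Gaussian response, identity link,

    E(y) = alpha + f_1(x_1) + ... + f_p(x_p) + time

where each f_j is one of the functional forms in :mod:`soilgam.basis`
and ``time`` is a random factor — per-sampling-date intercepts shrunk
by a ridge penalty, the penalized-regression equivalent of a random
intercept for temporal pseudo-replication.  Terms may interact with
land use, in which case one basis copy is active per land-use level
(and a land-use main effect is added, since an interaction without its
main effect is ill-posed).

Smoothing parameters (the ridge weight for time, one curvature weight
per spline term) are chosen by GCV, or REML when configured.  Fitting
is penalized least squares on precomputed cross-products, so evaluating
a candidate smoothing parameter costs O(p^3) only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .basis import OrthoPoly, crs_design, crs_knots, crs_penalty, sum_to_zero_constraint
from .errors import (
    BasisError,
    ConfigError,
    DataError,
    DegenerateResponseError,
    SingularFitError,
)

logger = logging.getLogger(__name__)

FORMS = ("I", "poly2", "poly3", "s")

#: Relation codes used in report tables.
RELATION_CODES = {"I": "I", "poly2": "P2", "poly3": "P3", "s": "s", "time": "RF"}


def significance_code(p: float) -> str:
    """Star codes: *** p<=0.001, ** <=0.01, * <=0.05, ° <=0.1, else ns."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    if p <= 0.1:
        return "°"
    return "ns"


@dataclass(frozen=True)
class ModelTerm:
    """One covariate term: functional form plus optional land-use interaction."""

    covariate: str
    form: str = "I"
    by_land_use: bool = False

    def __post_init__(self):
        if self.form not in FORMS:
            raise ConfigError(f"unknown form {self.form!r}; choose from {FORMS}")

    @property
    def label(self) -> str:
        return f"{self.covariate}:{self.form}" + (":by_lu" if self.by_land_use else "")


@dataclass(frozen=True)
class ModelSpec:
    """A candidate additive model: response, terms, mandatory time factor."""

    response: str
    terms: tuple[ModelTerm, ...] = ()
    includes_time: bool = True
    includes_land_use_main: bool = False

    def __post_init__(self):
        object.__setattr__(self, "terms", tuple(self.terms))
        names = [t.covariate for t in self.terms]
        if len(set(names)) != len(names):
            raise ConfigError(f"covariate appears twice in model: {names}")

    @property
    def needs_land_use(self) -> bool:
        return self.includes_land_use_main or any(t.by_land_use for t in self.terms)

    def with_term(self, term: ModelTerm) -> "ModelSpec":
        return replace(self, terms=self.terms + (term,))

    def without(self, covariate: str) -> "ModelSpec":
        return replace(self, terms=tuple(t for t in self.terms if t.covariate != covariate))

    def to_json(self) -> str:
        return json.dumps(
            {
                "response": self.response,
                "includes_time": self.includes_time,
                "includes_land_use_main": self.includes_land_use_main,
                "terms": [
                    {"covariate": t.covariate, "form": t.form, "by_land_use": t.by_land_use}
                    for t in self.terms
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        d = json.loads(text)
        return cls(
            response=d["response"],
            terms=tuple(ModelTerm(**t) for t in d["terms"]),
            includes_time=d.get("includes_time", True),
            includes_land_use_main=d.get("includes_land_use_main", False),
        )


@dataclass
class GAMConfig:
    k: int = 5  # spline basis dimension
    criterion: str = "gcv"  # or "reml"
    standardize: bool = True
    log_lambda_bounds: tuple[float, float] = (-10.0, 16.0)
    ridge_floor: float = 1e-7  # minimum smoothing parameter (numerical)
    scalar_xatol: float = 0.02  # log-lambda tolerance, single penalty
    nm_maxfev_per_lam: int = 45  # simplex budget, multiple penalties

    def __post_init__(self):
        if self.criterion not in ("gcv", "reml"):
            raise ConfigError(f"unknown smoothing criterion {self.criterion!r}")


# ---------------------------------------------------------------------------
# encoders: training-fitted column builders reusable on new data
# ---------------------------------------------------------------------------


class _Encoder:
    """One model-matrix block; fit() on training data, apply() on new."""

    name: str
    penalties: list  # list of (local column index array, penalty matrix)

    def fit(self, data: pd.DataFrame) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def apply(self, data: pd.DataFrame) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class _InterceptEncoder(_Encoder):
    name = "intercept"
    penalties = []

    def fit(self, data):
        return np.ones((len(data), 1))

    def apply(self, data):
        return np.ones((len(data), 1))


class _TimeEncoder(_Encoder):
    """Centered per-date indicators with a ridge penalty (random intercept)."""

    name = "time"

    def __init__(self, column: str = "day"):
        self.column = column
        self.levels = None
        self.means = None
        self.penalties = []

    def fit(self, data):
        days = data[self.column].to_numpy()
        self.levels = np.array(sorted(pd.unique(days)))
        raw = (days[:, None] == self.levels[None, :]).astype(float)
        self.means = raw.mean(axis=0)
        self.penalties = [(np.arange(len(self.levels)), np.eye(len(self.levels)))]
        return raw - self.means

    def apply(self, data):
        days = data[self.column].to_numpy()
        known = np.isin(days, self.levels)
        if not known.all():
            logger.warning(
                "%d row(s) at unseen sampling dates: time effect set to 0",
                int((~known).sum()),
            )
        raw = (days[:, None] == self.levels[None, :]).astype(float)
        out = raw - self.means
        out[~known] = 0.0
        return out


class _LandUseEncoder(_Encoder):
    """Centered indicator for the second land-use level (main effect)."""

    name = "land_use"
    penalties = []

    def __init__(self):
        self.levels = None
        self.mean = None

    def fit(self, data):
        self.levels = sorted(pd.unique(data["land_use"]))
        if len(self.levels) < 2:
            raise DataError("land-use main effect requested but only one level present")
        col = (data["land_use"].to_numpy() == self.levels[1]).astype(float)
        self.mean = col.mean()
        return (col - self.mean)[:, None]

    def apply(self, data):
        col = (data["land_use"].to_numpy() == self.levels[1]).astype(float)
        return (col - self.mean)[:, None]


class _TermEncoder(_Encoder):
    """Covariate term in any functional form, optionally by land use."""

    def __init__(self, term: ModelTerm, config: GAMConfig):
        self.term = term
        self.config = config
        self.name = term.label
        self.mu = 0.0
        self.sd = 1.0
        self.levels = [None]  # by-land-use levels, or the single dummy level
        self.poly = None
        self.knots = None
        self.Z = None
        self.col_means = None
        self.penalties = []

    def _z(self, data):
        x = data[self.term.covariate].to_numpy(float)
        if not np.isfinite(x).all():
            raise DataError(f"non-finite values in covariate {self.term.covariate!r}")
        return (x - self.mu) / self.sd

    def fit(self, data):
        x = data[self.term.covariate].to_numpy(float)
        if not np.isfinite(x).all():
            raise DataError(f"non-finite values in covariate {self.term.covariate!r}")
        if np.unique(x).size < 2:
            raise BasisError(f"covariate {self.term.covariate!r} is constant")
        if self.config.standardize:
            self.mu = x.mean()
            self.sd = x.std()
            if self.sd == 0:
                raise BasisError(f"covariate {self.term.covariate!r} has zero variance")
        z = self._z(data)
        form = self.term.form
        if form == "I":
            base = z[:, None]
        elif form in ("poly2", "poly3"):
            self.poly = OrthoPoly(degree=2 if form == "poly2" else 3)
            base = self.poly.fit(z)
        else:  # penalized cubic regression spline
            self.knots = crs_knots(z, self.config.k)
            N = crs_design(z, self.knots)
            S = crs_penalty(self.knots)
            self.Z = sum_to_zero_constraint(N.mean(axis=0))
            base = N @ self.Z
            self._S_con = self.Z.T @ S @ self.Z
        cols, pens = self._expand(base, data, fitting=True)
        self.col_means = cols.mean(axis=0)
        self.penalties = pens
        return cols - self.col_means

    def _basis(self, data):
        z = self._z(data)
        form = self.term.form
        if form == "I":
            return z[:, None]
        if form in ("poly2", "poly3"):
            return self.poly.apply(z)
        if (z < self.knots[0]).any() or (z > self.knots[-1]).any():
            logger.debug(
                "covariate %s outside training range: spline extrapolated linearly",
                self.term.covariate,
            )
        return crs_design(z, self.knots) @ self.Z

    def _expand(self, base, data, fitting=False):
        """Replicate the basis per land-use level for interaction terms."""
        if not self.term.by_land_use:
            pens = []
            if self.term.form == "s":
                pens = [(np.arange(base.shape[1]), self._S_con)]
            return base, pens
        if fitting:
            self.levels = sorted(pd.unique(data["land_use"]))
            if len(self.levels) < 2:
                raise DataError(
                    f"by-land-use term {self.term.covariate!r} needs two land-use levels"
                )
        lu = data["land_use"].to_numpy()
        p = base.shape[1]
        cols = np.zeros((len(data), p * len(self.levels)))
        pens = []
        for i, lev in enumerate(self.levels):
            mask = (lu == lev).astype(float)
            cols[:, i * p : (i + 1) * p] = base * mask[:, None]
            if self.term.form == "s":
                pens.append((np.arange(i * p, (i + 1) * p), self._S_con))
        return cols, pens

    def apply(self, data):
        base = self._basis(data)
        cols, _ = self._expand(base, data)
        return cols - self.col_means


# ---------------------------------------------------------------------------
# design assembly and penalized least squares
# ---------------------------------------------------------------------------


@dataclass
class _Block:
    name: str
    encoder: _Encoder
    sl: slice
    penalties: list  # (global column indices, penalty matrix)


@dataclass
class GAMDesign:
    """Fitted design: encoders plus global penalty layout."""

    spec: ModelSpec
    config: GAMConfig
    blocks: list = field(default_factory=list)
    n_cols: int = 0

    def build(self, data: pd.DataFrame) -> np.ndarray:
        encoders: list[_Encoder] = [_InterceptEncoder()]
        if self.spec.includes_time:
            encoders.append(_TimeEncoder())
        if self.spec.needs_land_use:
            encoders.append(_LandUseEncoder())
        encoders.extend(_TermEncoder(t, self.config) for t in self.spec.terms)
        mats, self.blocks, start = [], [], 0
        for enc in encoders:
            cols = enc.fit(data)
            pens = [(np.asarray(idx) + start, S) for idx, S in enc.penalties]
            self.blocks.append(_Block(enc.name, enc, slice(start, start + cols.shape[1]), pens))
            mats.append(cols)
            start += cols.shape[1]
        self.n_cols = start
        return np.hstack(mats)

    def matrix(self, data: pd.DataFrame) -> np.ndarray:
        return np.hstack([b.encoder.apply(data) for b in self.blocks])

    @property
    def penalties(self):
        return [p for b in self.blocks for p in b.penalties]

    @property
    def n_unpenalized(self) -> int:
        pen_cols = set()
        for idx, _ in self.penalties:
            pen_cols.update(idx.tolist())
        return self.n_cols - len(pen_cols)


def _embed_penalties(penalties, p):
    """Expand local penalty blocks to full (p, p) matrices once per fit."""
    out = []
    for idx, S in penalties:
        P = np.zeros((p, p))
        P[np.ix_(idx, idx)] = S
        out.append(P)
    return out


def _penalized_solve(XtX, Xty, yty, embedded, lam, rhs=None):
    """Solve the penalized normal equations; return beta, edf, rss, H.

    ``embedded`` are full-size penalty matrices (see _embed_penalties);
    the hot path is a single LAPACK solve against [Xty | XtX].
    """
    A = XtX.copy()
    for P, l in zip(embedded, lam):
        A += l * P
    if rhs is None:
        rhs = np.concatenate([Xty[:, None], XtX], axis=1)
    jitter = 0.0
    for _ in range(4):
        try:
            sol = np.linalg.solve(A, rhs)
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 100, 1e-10 * max(np.trace(A) / A.shape[0], 1.0))
            A = A + jitter * np.eye(A.shape[0])
    else:  # pragma: no cover - defensive
        raise SingularFitError("penalized normal equations are singular")
    beta = sol[:, 0]
    H = sol[:, 1:]  # A^-1 XtX; trace = effective df
    edf = float(np.trace(H))
    rss = float(max(yty - 2 * beta @ Xty + beta @ XtX @ beta, 0.0))
    return beta, edf, rss, H


@dataclass
class FittedGAM:
    """A fitted additive model with per-term components.

    ``components`` holds one column per block (time counted as one
    component): the block's contribution to the linear predictor at each
    training observation.  Intercept + sum of components reproduces the
    fitted values.
    """

    spec: ModelSpec
    design: GAMDesign
    beta: np.ndarray
    lam: np.ndarray
    edf: float
    edf_blocks: dict
    rss: float
    tss: float
    n: int
    y: np.ndarray
    fitted: np.ndarray
    components: pd.DataFrame
    criterion_value: float
    data: pd.DataFrame

    @property
    def intercept(self) -> float:
        return float(self.beta[0])

    @property
    def scale(self) -> float:
        return self.rss / max(self.n - self.edf, 1.0)

    @property
    def deviance(self) -> float:
        return self.rss

    @property
    def null_deviance(self) -> float:
        return self.tss

    def predict(self, newdata: pd.DataFrame) -> np.ndarray:
        X = self.design.matrix(newdata)
        return X @ self.beta


def fit_gam(
    spec: ModelSpec,
    data: pd.DataFrame,
    weights=None,
    config: GAMConfig | None = None,
    lam0: np.ndarray | None = None,
) -> FittedGAM:
    """Fit an additive model by penalized least squares.

    Gaussian response, identity link; smoothing parameters for the time
    ridge and any spline terms are optimized by the configured criterion
    (GCV default).  ``weights`` are optional observation weights;
    ``lam0`` warm-starts the smoothing-parameter search (used by
    cross-validation, where the full-data optimum is a good start).
    """
    config = config or GAMConfig()
    if spec.response not in data.columns:
        raise DataError(f"response column {spec.response!r} not in data")
    if data.attrs:
        data = data.copy(deep=False)
        data.attrs = {}  # attrs are deep-copied on every slice; drop them
    data = data.loc[np.isfinite(data[spec.response].to_numpy(float))].reset_index(drop=True)
    y = data[spec.response].to_numpy(float)
    n = y.size
    design = GAMDesign(spec, config)
    X = design.build(data)
    if weights is not None:
        w = np.sqrt(np.asarray(weights, float))
        Xw, yw = X * w[:, None], y * w
    else:
        Xw, yw = X, y
    if n <= design.n_unpenalized:
        raise SingularFitError(
            f"{n} observations but {design.n_unpenalized} unpenalized coefficients"
        )
    XtX = Xw.T @ Xw
    Xty = Xw.T @ yw
    yty = float(yw @ yw)
    penalties = design.penalties
    embedded = _embed_penalties(penalties, design.n_cols)
    lam, beta, edf, rss, H, crit_val = optimize_crossprods(
        XtX, Xty, yty, penalties, embedded, n, design.n_unpenalized, config, lam0
    )
    fitted = X @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    edf_blocks = {}
    diagH = np.diag(H)
    for b in design.blocks:
        edf_blocks[b.name] = float(diagH[b.sl].sum())
    comp = {b.name: X[:, b.sl] @ beta[b.sl] for b in design.blocks if b.name != "intercept"}
    components = pd.DataFrame(comp, index=data.index)
    return FittedGAM(
        spec=spec,
        design=design,
        beta=beta,
        lam=lam,
        edf=edf,
        edf_blocks=edf_blocks,
        rss=rss,
        tss=tss,
        n=n,
        y=y,
        fitted=fitted,
        components=components,
        criterion_value=crit_val,
        data=data,
    )


def _single_penalty_gcv(XtX, Xty, yty, P, n, config):
    """Exact GCV search for one penalty via the Demmler–Reinsch form.

    With B = XtX + P = C C' and M = C^-1 P C^-T = U diag(d) U',
    A(lam) = C U diag(1 - d + lam d) U' C', so edf and RSS are O(p)
    functions of lam and the GCV profile can be scanned densely and
    refined by golden section at negligible cost.  Returns (lam, gcv)
    or None when the decomposition is numerically unusable.
    """
    lo, hi = config.log_lambda_bounds
    B = XtX + P
    jitter = 0.0
    for _ in range(3):
        try:
            C = np.linalg.cholesky(B + (jitter * np.eye(B.shape[0]) if jitter else 0.0))
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 100, 1e-10 * max(np.trace(B) / B.shape[0], 1.0))
    else:
        return None
    Ci = linalg.solve_triangular(C, np.eye(C.shape[0]), lower=True, check_finite=False)
    M = Ci @ P @ Ci.T
    d, U = np.linalg.eigh((M + M.T) / 2)
    d = np.clip(d, 0.0, 1.0)
    w = U.T @ (Ci @ Xty)
    w2 = w**2

    def stats(lam_arr):
        g = 1.0 - d + lam_arr[:, None] * d  # (L, p)
        edf = ((1.0 - d) / g).sum(axis=1)
        rss = yty - 2.0 * (w2 / g).sum(axis=1) + (w2 * (1.0 - d) / g**2).sum(axis=1)
        return edf, np.maximum(rss, 0.0)

    def gcv(log_lam):
        lam_arr = np.exp(np.atleast_1d(log_lam))
        edf, rss = stats(lam_arr)
        return n * rss / np.maximum(n - edf, 1e-8) ** 2

    grid = np.linspace(lo, hi, 131)
    vals = gcv(grid)
    j = int(np.argmin(vals))
    a, b = grid[max(j - 1, 0)], grid[min(j + 1, len(grid) - 1)]
    # golden-section refinement on the bracketing interval
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    c1, c2 = b - invphi * (b - a), a + invphi * (b - a)
    f1, f2 = float(gcv(c1)[0]), float(gcv(c2)[0])
    for _ in range(40):
        if b - a < 1e-4:
            break
        if f1 < f2:
            b, c2, f2 = c2, c1, f1
            c1 = b - invphi * (b - a)
            f1 = float(gcv(c1)[0])
        else:
            a, c1, f1 = c1, c2, f2
            c2 = a + invphi * (b - a)
            f2 = float(gcv(c2)[0])
    x = (a + b) / 2.0
    return float(np.exp(x)), float(gcv(x)[0])


def optimize_crossprods(XtX, Xty, yty, penalties, embedded, n, n_unpen, config,
                        lam0=None):
    """Choose smoothing parameters and solve, given cross-products only.

    Shared by :func:`fit_gam` and the cross-validation fast path (which
    subtracts one soil's cross-product blocks per fold).  Returns
    (lam, beta, edf, rss, H, criterion_value).
    """
    rhs = np.concatenate([Xty[:, None], XtX], axis=1)
    n_lam = len(penalties)
    lo, hi = config.log_lambda_bounds

    def crit(log_lam):
        lam = np.exp(np.clip(log_lam, lo, hi))
        lam = np.maximum(lam, config.ridge_floor)
        _, edf, rss, _ = _penalized_solve(XtX, Xty, yty, embedded, lam, rhs)
        if config.criterion == "gcv":
            denom = max(n - edf, 1e-8)
            return n * rss / denom**2
        return _minus2_reml(XtX, Xty, yty, penalties, lam, n, n_unpen)

    x0 = np.zeros(n_lam) if lam0 is None or len(lam0) != n_lam else np.log(
        np.maximum(lam0, config.ridge_floor)
    )
    if n_lam == 0:
        lam = np.array([])
        crit_val = float("nan")
    elif n_lam == 1 and config.criterion == "gcv" and lam0 is None:
        dr = _single_penalty_gcv(XtX, Xty, yty, embedded[0], n, config)
        if dr is None:
            raise SingularFitError("penalized normal equations are singular")
        lam = np.array([dr[0]])
        crit_val = dr[1]
    elif n_lam == 1:
        if lam0 is not None and len(lam0) == 1:
            # local golden-section around the warm start
            res = optimize.minimize_scalar(
                lambda v: crit(np.array([v])),
                bounds=(max(lo, x0[0] - 4.0), min(hi, x0[0] + 4.0)),
                method="bounded", options={"xatol": 5e-2},
            )
        else:
            res = optimize.minimize_scalar(
                lambda v: crit(np.array([v])), bounds=(lo, hi), method="bounded",
                options={"xatol": config.scalar_xatol},
            )
        lam = np.exp(np.array([res.x]))
        crit_val = float(res.fun)
    else:
        budget = config.nm_maxfev_per_lam * n_lam if lam0 is None else 25 * n_lam
        res = optimize.minimize(
            crit, x0, method="Nelder-Mead",
            options={"xatol": 0.15, "fatol": 1e-8, "maxfev": budget},
        )
        lam = np.exp(np.clip(res.x, lo, hi))
        crit_val = float(res.fun)
    lam = np.maximum(lam, config.ridge_floor) if n_lam else lam
    beta, edf, rss, H = _penalized_solve(XtX, Xty, yty, embedded, lam, rhs)
    return lam, beta, edf, rss, H, crit_val


def _minus2_reml(XtX, Xty, yty, penalties, lam, n, n_unpen):
    """Gaussian -2 REML with the scale profiled out.

    With H = X'X + S_lam, penalized RSS Dp and Mp unpenalized
    coefficients, the profiled restricted likelihood is

        -2 l_r = (n - Mp) (log(2 pi phi) + 1) + log|H| - log|S_lam|_+

    where phi = Dp / (n - Mp) and |.|_+ is the pseudo-determinant.
    """
    A = XtX.copy()
    log_det_S = 0.0
    for (idx, S), l in zip(penalties, lam):
        A[np.ix_(idx, idx)] += l * S
        ev = np.linalg.eigvalsh(S)
        pos = ev[ev > 1e-10 * ev.max()]
        log_det_S += pos.size * np.log(l) + float(np.log(pos).sum())
    sign, log_det_A = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(A, Xty)
    rss = max(yty - 2 * beta @ Xty + beta @ XtX @ beta, 0.0)
    pen = sum(
        l * float(beta[idx] @ S @ beta[idx]) for (idx, S), l in zip(penalties, lam)
    )
    dp = max(rss + pen, 1e-300)
    nm = max(n - n_unpen, 1)
    phi = dp / nm
    return nm * (np.log(2 * np.pi * phi) + 1.0) + log_det_A - log_det_S


def predict(fitted: FittedGAM, newdata: pd.DataFrame) -> np.ndarray:
    """Evaluate the linear predictor on new data."""
    return fitted.predict(newdata)


def explained_deviance_values(y, fitted_values) -> float:
    """Percent deviance explained from raw values: 100 (1 - RSS/TSS)."""
    y = np.asarray(y, dtype=float)
    f = np.asarray(fitted_values, dtype=float)
    tss = float(((y - y.mean()) ** 2).sum())
    if tss <= 0:
        raise DegenerateResponseError("response has zero variance")
    rss = float(((y - f) ** 2).sum())
    return 100.0 * (1.0 - rss / tss)


def explained_deviance(fitted: FittedGAM) -> float:
    """Percent of null deviance explained: 100 (1 - RSS/TSS) for Gaussian."""
    if fitted.null_deviance <= 0:
        raise DegenerateResponseError("response has zero variance")
    return 100.0 * (1.0 - fitted.deviance / fitted.null_deviance)


def term_significance(fitted: FittedGAM, config: GAMConfig | None = None) -> pd.DataFrame:
    """Approximate F tests per model block (time and covariate terms).

    Each block is dropped in turn and the model refit (smoothing
    parameters re-optimized); F = (ΔRSS / edf_term) / scale_full with
    denominator df = n - edf_full.  For unpenalized single-column terms
    this is the exact F test; for smooths it is the usual effective-df
    approximation.
    """
    config = config or fitted.design.config
    rows = []
    denom_df = max(fitted.n - fitted.edf, 1.0)
    for b in fitted.design.blocks:
        if b.name in ("intercept", "land_use"):
            continue
        if b.name == "time":
            reduced = replace(fitted.spec, includes_time=False)
        else:
            cov = b.name.split(":", 1)[0]
            reduced = fitted.spec.without(cov)
            if fitted.spec.includes_land_use_main and not reduced.needs_land_use:
                reduced = replace(reduced, includes_land_use_main=True)
        red_fit = fit_gam(reduced, fitted.data, config=config)
        df_t = max(fitted.edf_blocks[b.name], 1e-8)
        delta = max(red_fit.rss - fitted.rss, 0.0)
        F = (delta / df_t) / max(fitted.scale, 1e-300)
        p = float(stats.f.sf(F, df_t, denom_df))
        rows.append(
            {
                "term": b.name,
                "edf": fitted.edf_blocks[b.name],
                "F": F,
                "p_value": p,
                "code": significance_code(p),
            }
        )
    return pd.DataFrame(rows)
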