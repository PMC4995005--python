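"""Seeded generator of synthetic incubation experiments.

The generator emulates the structure the analysis assumes: 20 soils
split evenly between cropland and grassland, two treatments (control
and residue-amended) x 3 replicates x 8 sampling dates; site covariates
drawn from per-land-use multivariate normals with an intercorrelated
diversity block; double-pool exponential decay kinetics for both soil
and residue carbon; configurable covariate effects (linear, polynomial
or smooth, optionally land-use-specific) acting multiplicatively on the
rates; multiplicative lognormal noise; and exact two-endmember 13C
mixing of the respired CO2.  A :class:`GroundTruth` records the
realized soil/residue fluxes and the injected effect functions for
parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import DEFAULT_SCHEDULE, Dataset, schedule_intervals
from .errors import ConfigError, DataError


@dataclass(frozen=True)
class EffectSpec:
    """One injected covariate effect on a mineralisation kinetic.

    ``shape`` is the functional form of the effect on the log rate:
    linear, quad, cubic or smooth (a sine).  ``amplitude`` is in ln
    units per covariate standard deviation.  With ``by_land_use`` the
    effect applies with opposite sign in the two land uses.
    """

    covariate: str
    shape: str = "linear"  # linear | quad | cubic | smooth
    amplitude: float = 0.3
    by_land_use: bool = False
    response: str = "rs_control"

    def evaluate(self, z: np.ndarray) -> np.ndarray:
        if self.shape == "linear":
            g = z
        elif self.shape == "quad":
            g = z**2 - 1.0
        elif self.shape == "cubic":
            g = z**3 - 3 * z  # Hermite: orthogonal to linear under N(0,1)
        elif self.shape == "smooth":
            g = np.sin(1.5 * z)
        else:
            raise ConfigError(f"unknown effect shape {self.shape!r}")
        return self.amplitude * g


#: per-covariate (cropland mean, grassland mean, sd); units as in SiteRecord
_COV_PARAMS = {
    "clay": (250.0, 300.0, 80.0),
    "silt": (380.0, 330.0, 90.0),
    "soc": (15.0, 21.0, 6.0),
    "cn_ratio": (9.8, 10.8, 1.4),
    "ph": (6.6, 6.4, 1.1),
    "molecular_biomass": (18.0, 30.0, 9.0),
    "bacterial_richness": (1000.0, 1050.0, 140.0),
    "fungal_richness": (340.0, 360.0, 80.0),
    "bacterial_h": (5.7, 5.9, 0.30),
    "fungal_h": (3.9, 4.1, 0.40),
    "bacterial_j": (0.82, 0.85, 0.035),
    "fungal_j": (0.66, 0.70, 0.055),
    "bacterial_invd": (60.0, 110.0, 28.0),
    "fungal_invd": (11.0, 14.0, 5.0),
}

_BACTERIAL_BLOCK = ("bacterial_richness", "bacterial_h", "bacterial_j", "bacterial_invd")
_FUNGAL_BLOCK = ("fungal_richness", "fungal_h", "fungal_j", "fungal_invd")


@dataclass
class KineticsParams:
    """Double-pool first-order decay: amounts (ug C/g soil) and rates (1/day)."""

    fast_pool: float
    fast_rate: float
    slow_pool: float
    slow_rate: float

    def interval_amount(self, t0: np.ndarray, t1: np.ndarray) -> np.ndarray:
        """CO2 evolved in (t0, t1]: integral of the decay rate."""
        return self.fast_pool * (np.exp(-self.fast_rate * t0) - np.exp(-self.fast_rate * t1)) + (
            self.slow_pool * (np.exp(-self.slow_rate * t0) - np.exp(-self.slow_rate * t1))
        )


@dataclass
class GeneratorConfig:
    n_per_land_use: dict = field(default_factory=lambda: {"cropland": 10, "grassland": 10})
    n_replicates: int = 3
    schedule: tuple = DEFAULT_SCHEDULE
    diversity_correlation: float = 0.8
    effects: tuple = (
        EffectSpec("bacterial_j", "linear", -0.4, False, "rs_control"),
        EffectSpec("soc", "linear", 0.3, False, "rs_amended"),
        EffectSpec("fungal_invd", "smooth", -0.3, False, "pe"),
    )
    soil_kinetics: KineticsParams = field(
        default_factory=lambda: KineticsParams(150.0, 0.08, 6000.0, 0.0015)
    )
    residue_kinetics: KineticsParams = field(
        default_factory=lambda: KineticsParams(600.0, 0.15, 900.0, 0.004)
    )
    pe_multiplier: float = 1.2
    noise_sigma: float = 0.15  # lognormal sigma on interval amounts
    a13_soil: float = 1.08  # atom %, natural abundance
    a13_residue: float = 3.0  # atom %, labelled residue
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        if not (0 <= self.diversity_correlation < 1):
            raise ConfigError("diversity_correlation must be in [0, 1)")
        for kin in (self.soil_kinetics, self.residue_kinetics):
            if min(kin.fast_pool, kin.slow_pool) <= 0:
                raise ConfigError("kinetic pool sizes must be positive")
        known = set(_COV_PARAMS) | {"sand", "clay_fine_silt"}
        for e in self.effects:
            if e.covariate not in known:
                raise ConfigError(f"effect on unknown covariate {e.covariate!r}")


@dataclass
class GroundTruth:
    """Realized per-cell fluxes and injected effect functions."""

    cells: pd.DataFrame  # site_id, treatment, replicate, t_start, t_end, rs, rr, pe
    effects: tuple
    effect_grid: pd.DataFrame  # covariate, z, response, value

    def write(self, outdir) -> None:
        """Write truth_cells.csv plus a truth.json effect summary."""
        import json
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(outdir / "truth_cells.csv", index=False, float_format="%.12g")
        payload = {
            "effects": [
                {"covariate": e.covariate, "shape": e.shape, "amplitude": e.amplitude,
                 "by_land_use": e.by_land_use, "response": e.response}
                for e in self.effects
            ],
            "effect_grid": self.effect_grid.to_dict(orient="list"),
        }
        (outdir / "truth.json").write_text(json.dumps(payload, indent=2))


def _correlation_matrix(names, rho: float) -> np.ndarray:
    k = len(names)
    C = np.eye(k)
    for block in (_BACTERIAL_BLOCK, _FUNGAL_BLOCK):
        idx = [names.index(b) for b in block if b in names]
        for i in idx:
            for j in idx:
                if i != j:
                    C[i, j] = rho
    return C


def generate_sites(config: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw the per-soil covariate table.

    Covariates come from per-land-use multivariate normals; the four
    bacterial (and four fungal) diversity indexes share a configurable
    block correlation.  Sand closes the texture triplet to 1000 g/kg
    and clay+fine-silt is clay plus 55% of silt, so the texture block
    carries realistic near-collinearity.  Index invariants (J' in
    [0,1], 1/D in [1, richness], H' <= ln richness) are enforced by
    clipping after the draw.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    names = list(_COV_PARAMS)
    C = _correlation_matrix(names, config.diversity_correlation)
    L = np.linalg.cholesky(C)
    frames = []
    counter = 1
    for land_use in ("cropland", "grassland"):
        n = config.n_per_land_use.get(land_use, 0)
        z = rng.standard_normal((n, len(names))) @ L.T
        cols = {}
        for j, name in enumerate(names):
            mu_c, mu_g, sd = _COV_PARAMS[name]
            mu = mu_c if land_use == "cropland" else mu_g
            cols[name] = mu + sd * z[:, j]
        df = pd.DataFrame(cols)
        df.insert(0, "land_use", land_use)
        df.insert(0, "site_id", [f"S{counter + i:02d}" for i in range(n)])
        counter += n
        frames.append(df)
    sites = pd.concat(frames, ignore_index=True)
    # texture closure and derived fraction
    sites["clay"] = sites["clay"].clip(lower=30.0)
    sites["silt"] = sites["silt"].clip(lower=50.0)
    total = sites["clay"] + sites["silt"]
    over = total > 950.0
    sites.loc[over, ["clay", "silt"]] = (
        sites.loc[over, ["clay", "silt"]].mul(950.0 / total[over], axis=0)
    )
    sites["sand"] = 1000.0 - sites["clay"] - sites["silt"]
    sites["clay_fine_silt"] = sites["clay"] + 0.55 * sites["silt"]
    # enforce index invariants
    sites["soc"] = sites["soc"].clip(lower=3.0)
    sites["cn_ratio"] = sites["cn_ratio"].clip(lower=5.0)
    sites["ph"] = sites["ph"].clip(lower=3.8, upper=8.6)
    sites["molecular_biomass"] = sites["molecular_biomass"].clip(lower=1.0)
    for prefix in ("bacterial", "fungal"):
        rich = sites[f"{prefix}_richness"].clip(lower=10.0).round()
        sites[f"{prefix}_richness"] = rich
        sites[f"{prefix}_j"] = sites[f"{prefix}_j"].clip(0.05, 0.98)
        sites[f"{prefix}_h"] = np.minimum(
            sites[f"{prefix}_h"].clip(lower=0.1), np.log(rich)
        )
        sites[f"{prefix}_invd"] = sites[f"{prefix}_invd"].clip(lower=1.0, upper=rich)
    from .datamodel import SITE_COLUMNS

    return sites[list(SITE_COLUMNS)]


def _effect_log_multipliers(sites: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Per-site ln multipliers for each response from the injected effects."""
    out = pd.DataFrame(
        0.0, index=sites.index, columns=["rs_control", "rs_amended", "rr", "pe"]
    )
    for e in config.effects:
        x = sites[e.covariate].to_numpy(float)
        z = (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)
        g = e.evaluate(z)
        if e.by_land_use:
            sign = np.where(sites["land_use"].to_numpy() == "grassland", -1.0, 1.0)
            g = g * sign
        out[e.response] += g
    return out


def generate_respiration(
    sites: pd.DataFrame, config: GeneratorConfig, seed: int | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate interval CO2 amounts and 13C abundances per microcosm.

    Soil-derived and residue-derived amounts follow the configured
    double-pool kinetics scaled by exp(injected covariate effects); the
    amended soil-derived flux additionally carries the priming
    multiplier.  Each component amount gets independent multiplicative
    lognormal noise, and the amended 13C abundance is the exact
    abundance-weighted endmember mix of the realized components, so
    mass-balance partitioning recovers them exactly.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    intervals = schedule_intervals(config.schedule)
    t0 = np.array([a for a, _ in intervals])
    t1 = np.array([b for _, b in intervals])
    base_soil = config.soil_kinetics.interval_amount(t0, t1)
    base_residue = config.residue_kinetics.interval_amount(t0, t1)
    effects = _effect_log_multipliers(sites, config)
    rows = []
    truth_rows = []
    for i, site in sites.iterrows():
        m_ctrl = math.exp(effects.loc[i, "rs_control"])
        m_amd = math.exp(effects.loc[i, "rs_amended"])
        m_rr = math.exp(effects.loc[i, "rr"])
        m_pe = config.pe_multiplier * math.exp(effects.loc[i, "pe"])
        if min(m_ctrl, m_amd, m_rr, m_pe) <= 0:
            raise ConfigError("configured effects produce nonpositive rates")
        for rep in range(1, config.n_replicates + 1):
            noise = lambda: (
                rng.lognormal(0.0, config.noise_sigma, size=len(intervals))
                if config.noise_sigma > 0
                else np.ones(len(intervals))
            )
            rs_ctrl = base_soil * m_ctrl * noise()
            # amended soil flux = control-level flux x priming multiplier
            # (x any effects targeted directly at the amended response)
            rs_amd = base_soil * m_ctrl * m_amd * m_pe * noise()
            rr_amd = base_residue * m_rr * noise()
            rt = rs_amd + rr_amd
            a13 = (rs_amd * config.a13_soil + rr_amd * config.a13_residue) / rt
            for j in range(len(intervals)):
                rows.append(
                    (site["site_id"], "control", rep, t0[j], t1[j], rs_ctrl[j], np.nan)
                )
                rows.append(
                    (site["site_id"], "amended", rep, t0[j], t1[j], rt[j], a13[j])
                )
                truth_rows.append(
                    (site["site_id"], "amended", rep, t0[j], t1[j], rs_amd[j], rr_amd[j],
                     rs_amd[j] / rs_ctrl[j])
                )
    resp = pd.DataFrame(
        rows,
        columns=["site_id", "treatment", "replicate", "t_start", "t_end",
                 "co2_interval", "a13_total"],
    )
    cells = pd.DataFrame(
        truth_rows,
        columns=["site_id", "treatment", "replicate", "t_start", "t_end", "rs", "rr", "pe"],
    )
    zg = np.linspace(-2.5, 2.5, 101)
    grid = pd.concat(
        [
            pd.DataFrame(
                {"covariate": e.covariate, "z": zg, "response": e.response,
                 "value": e.evaluate(zg)}
            )
            for e in config.effects
        ],
        ignore_index=True,
    ) if config.effects else pd.DataFrame(columns=["covariate", "z", "response", "value"])
    return resp, GroundTruth(cells=cells, effects=tuple(config.effects), effect_grid=grid)


def generate_dataset(
    config: GeneratorConfig | None = None, seed: int | None = None
) -> tuple[Dataset, GroundTruth]:
    """Full synthetic experiment: sites, respiration, endmembers."""
    config = config or GeneratorConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    sites = generate_sites(config)
    resp, truth = generate_respiration(sites, config)
    endmembers = pd.DataFrame(
        {
            "site_id": sites["site_id"],
            "a13_soil": config.a13_soil,
            "a13_residue": config.a13_residue,
        }
    )
    ds = Dataset(
        sites=sites, respiration=resp, endmembers=endmembers, schedule=config.schedule
    ).validate()
    return ds, truth


# ---------------------------------------------------------------------------
# OTU tables with target diversity
# ---------------------------------------------------------------------------


def _geometric_evenness(theta: float, s: int) -> float:
    """J' of the geometric abundance series p_i ~ theta^i, i = 0..s-1."""
    if s == 1:
        return float("nan")
    if theta >= 1.0:
        return 1.0
    w = theta ** np.arange(s)
    p = w / w.sum()
    h = -(p * np.log(p)).sum()
    return float(h / np.log(s))


def generate_otu_table(
    targets: pd.DataFrame, seed: int = 0, depth: int | None = 50_000
) -> pd.DataFrame:
    """OTU count table matching target (richness, evenness) per sample.

    ``targets`` needs columns sample_id, richness, evenness_j.  Relative
    abundances follow a geometric series whose decay is tuned by
    bisection so the expected composition hits the target J'; counts are
    multinomial at ``depth`` reads.  ``depth=None`` returns the exact
    expected composition (the infinite-depth limit) as float abundances.
    """
    rng = np.random.default_rng(seed)
    recs = []
    for _, row in targets.iterrows():
        s = int(row["richness"])
        if s < 1:
            raise DataError("target richness must be >= 1")
        j_target = float(row.get("evenness_j", 1.0))
        if s == 1:
            theta = 1.0
        elif j_target >= 1.0:
            theta = 1.0
        else:
            if not (0 < j_target < 1):
                raise DataError(f"unreachable evenness target {j_target} for richness {s}")
            lo, hi = 1e-6, 1.0
            for _ in range(80):
                mid = 0.5 * (lo + hi)
                if _geometric_evenness(mid, s) < j_target:
                    lo = mid
                else:
                    hi = mid
            theta = 0.5 * (lo + hi)
        w = theta ** np.arange(s)
        p = w / w.sum()
        if depth is None:
            counts = p
        else:
            counts = rng.multinomial(depth, p).astype(float)
        for i, c in enumerate(counts):
            if c > 0:
                recs.append((row["sample_id"], f"OTU{i + 1:05d}", c))
    return pd.DataFrame(recs, columns=["sample_id", "otu_id", "count"])
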