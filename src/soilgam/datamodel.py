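"""Tabular data model for the incubation experiment.

The experiment crosses soils (sites) with two microcosm treatments
(``control`` and residue-``amended``), three replicates and a fixed
schedule of CO2 sampling dates.  Site covariates combine abiotic soil
properties with molecular biomass and bacterial/fungal diversity
indexes.  Tables are held as pandas DataFrames with canonical column
names; :mod:`soilgam.io` maps arbitrary file headers onto them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, IntegrityError, ReferentialError

#: Default CO2 sampling schedule in days; the first interval starts at day 0.
DEFAULT_SCHEDULE: tuple[int, ...] = (3, 7, 14, 21, 28, 44, 60, 80)

LAND_USES = ("cropland", "grassland")
TREATMENTS = ("control", "amended")

#: Candidate covariates carried by each site record, in canonical order.
SITE_COVARIATES: tuple[str, ...] = (
    "clay",
    "silt",
    "sand",
    "clay_fine_silt",
    "soc",
    "cn_ratio",
    "ph",
    "molecular_biomass",
    "bacterial_richness",
    "fungal_richness",
    "bacterial_h",
    "fungal_h",
    "bacterial_j",
    "fungal_j",
    "bacterial_invd",
    "fungal_invd",
)

SITE_COLUMNS: tuple[str, ...] = ("site_id", "land_use") + SITE_COVARIATES
RESPIRATION_COLUMNS: tuple[str, ...] = (
    "site_id",
    "treatment",
    "replicate",
    "t_start",
    "t_end",
    "co2_interval",
    "a13_total",
)
ENDMEMBER_COLUMNS: tuple[str, ...] = ("site_id", "a13_soil", "a13_residue")

#: The four mineralisation kinetics modelled downstream.
RESPONSES = ("rs_control", "rs_amended", "rr", "pe")


def schedule_intervals(schedule) -> list[tuple[float, float]]:
    """Contiguous (t_start, t_end] intervals implied by a sampling schedule."""
    days = list(schedule)
    if sorted(set(days)) != days or (days and days[0] <= 0):
        raise DataError(f"schedule must be strictly increasing positive days, got {days}")
    return list(zip([0.0] + [float(d) for d in days[:-1]], [float(d) for d in days]))


@dataclass
class Dataset:
    """Validated experiment tables plus the sampling schedule."""

    sites: pd.DataFrame
    respiration: pd.DataFrame
    endmembers: pd.DataFrame
    schedule: tuple[int, ...] = DEFAULT_SCHEDULE

    def __post_init__(self):
        self.schedule = tuple(self.schedule)

    @property
    def n_sites(self) -> int:
        return self.sites["site_id"].nunique()

    def design_cells(self) -> pd.DataFrame:
        """All (site, treatment, replicate, interval) cells of a complete design."""
        intervals = schedule_intervals(self.schedule)
        reps = sorted(self.respiration["replicate"].unique()) or [1, 2, 3]
        idx = pd.MultiIndex.from_product(
            [sorted(self.sites["site_id"].unique()), TREATMENTS, reps, range(len(intervals))],
            names=["site_id", "treatment", "replicate", "interval"],
        )
        out = idx.to_frame(index=False)
        out["t_start"] = [intervals[i][0] for i in out["interval"]]
        out["t_end"] = [intervals[i][1] for i in out["interval"]]
        return out.drop(columns="interval")

    def missing_cells(self) -> pd.DataFrame:
        """Design cells with no respiration record (exact completeness check)."""
        expected = self.design_cells()
        key = ["site_id", "treatment", "replicate", "t_start", "t_end"]
        got = self.respiration[key]
        merged = expected.merge(got.assign(_seen=1), on=key, how="left")
        return merged[merged["_seen"].isna()][key].reset_index(drop=True)

    def validate(self) -> "Dataset":
        validate_sites(self.sites)
        validate_respiration(self.respiration, self.schedule)
        validate_endmembers(self.endmembers)
        orphans = set(self.respiration["site_id"]) - set(self.sites["site_id"])
        if orphans:
            raise ReferentialError(
                f"respiration rows reference unknown site(s): {sorted(orphans)}"
            )
        return self


def validate_sites(sites: pd.DataFrame, atol: float = 50.0) -> None:
    """Check site covariate invariants.

    ``atol`` is the tolerance (g/kg) on the clay+silt+sand closure; the
    5-fraction granulometry never closes exactly.
    """
    if sites["site_id"].duplicated().any():
        dupes = sites.loc[sites["site_id"].duplicated(), "site_id"].tolist()
        raise IntegrityError(f"duplicate site_id(s): {dupes}")
    bad_lu = set(sites["land_use"]) - set(LAND_USES)
    if bad_lu:
        raise DataError(f"unknown land_use value(s): {sorted(bad_lu)}")
    tex = sites[["clay", "silt", "sand"]].to_numpy(float)
    if (tex < 0).any():
        raise DataError("negative texture fraction")
    total = tex.sum(axis=1)
    if (total > 1000.0 + atol).any():
        bad = sites.loc[total > 1000.0 + atol, "site_id"].tolist()
        raise DataError(f"clay+silt+sand exceeds 1000 g/kg for site(s) {bad}")
    for prefix in ("bacterial", "fungal"):
        j = sites[f"{prefix}_j"].to_numpy(float)
        invd = sites[f"{prefix}_invd"].to_numpy(float)
        h = sites[f"{prefix}_h"].to_numpy(float)
        rich = sites[f"{prefix}_richness"].to_numpy(float)
        eps = 1e-8
        if ((j < -eps) | (j > 1 + eps)).any():
            raise DataError(f"{prefix} evenness J' outside [0, 1]")
        if ((invd < 1 - eps) | (invd > rich + eps)).any():
            raise DataError(f"{prefix} inverse Simpson outside [1, richness]")
        if ((h < -eps) | (h > np.log(np.maximum(rich, 1.0)) + eps)).any():
            raise DataError(f"{prefix} Shannon H' outside [0, ln richness]")


def validate_respiration(resp: pd.DataFrame, schedule=DEFAULT_SCHEDULE) -> None:
    if (resp["t_end"].to_numpy(float) <= resp["t_start"].to_numpy(float)).any():
        raise DataError("respiration interval with t_end <= t_start")
    if (resp["t_start"].to_numpy(float) < 0).any():
        raise DataError("negative t_start")
    if (resp["co2_interval"].to_numpy(float) < 0).any():
        raise DataError("negative interval CO2 amount")
    allowed = {(a, b) for a, b in schedule_intervals(schedule)}
    seen = set(zip(resp["t_start"].astype(float), resp["t_end"].astype(float)))
    if not seen <= allowed:
        raise DataError(
            f"interval(s) {sorted(seen - allowed)} not in configured schedule {list(schedule)}"
        )
    bad_tr = set(resp["treatment"]) - set(TREATMENTS)
    if bad_tr:
        raise DataError(f"unknown treatment value(s): {sorted(bad_tr)}")
    key = ["site_id", "treatment", "replicate", "t_start", "t_end"]
    dup = resp.duplicated(subset=key)
    if dup.any():
        first = resp.loc[dup, key].iloc[0].to_dict()
        raise IntegrityError(f"duplicate design cell: {first}")
    # a13 is required for amended microcosms only
    amended = resp[resp["treatment"] == "amended"]
    if amended["a13_total"].isna().any():
        n = int(amended["a13_total"].isna().sum())
        raise DataError(f"{n} amended row(s) missing a13_total")


def validate_endmembers(end: pd.DataFrame) -> None:
    if end["site_id"].duplicated().any():
        raise IntegrityError("duplicate endmember rows per site")
    a_s = end["a13_soil"].to_numpy(float)
    a_r = end["a13_residue"].to_numpy(float)
    if (a_s <= 0).any() or (a_r <= 0).any():
        raise DataError("isotope abundances must be positive")
    if (a_r == a_s).any():
        raise DataError("a13_residue equals a13_soil for some site")


@dataclass
class DesignSummary:
    """Row counts and completeness per treatment, reported by the reader."""

    n_sites: int
    n_respiration_rows: int
    rows_per_treatment: dict = field(default_factory=dict)
    n_missing_cells: int = 0

    def __str__(self):
        per = ", ".join(f"{k}={v}" for k, v in self.rows_per_treatment.items())
        return (
            f"{self.n_sites} sites, {self.n_respiration_rows} respiration rows"
            f" ({per}); {self.n_missing_cells} missing design cells"
        )


def summarize_design(ds: Dataset) -> DesignSummary:
    return DesignSummary(
        n_sites=ds.n_sites,
        n_respiration_rows=len(ds.respiration),
        rows_per_treatment=ds.respiration["treatment"].value_counts().to_dict(),
        n_missing_cells=len(ds.missing_cells()),
    )
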