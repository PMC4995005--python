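"""Diversity indexes from OTU count tables.

Four indexes per sample, computed from relative abundances p_i of OTUs
with positive counts:

* richness  S  = number of OTUs present
* Shannon   H' = -sum p_i ln p_i    (natural log by default)
* evenness  J' = H' / ln S          (undefined for S = 1)
* inverse Simpson 1/D = 1 / sum p_i^2

1/D weights abundant OTUs: adding a rare singleton barely moves it,
unlike H'.  No rarefaction is applied; sequencing depth is carried
through for QC only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError


@dataclass(frozen=True)
class DiversityProfile:
    richness: int
    shannon_h: float
    evenness_j: float  # NaN when richness == 1
    inv_simpson: float
    depth: int = 0

    def as_dict(self):
        return {
            "richness": self.richness,
            "shannon_h": self.shannon_h,
            "evenness_j": self.evenness_j,
            "inv_simpson": self.inv_simpson,
            "depth": self.depth,
        }


def diversity_profile(counts, base: float = np.e) -> DiversityProfile:
    """Compute richness, H', J' and 1/D for one sample.

    ``counts`` are nonnegative OTU counts; zero-count OTUs are dropped
    from every sum (the 0*ln 0 := 0 convention).  ``base`` sets the
    Shannon log base (natural by default); J' is base-invariant.
    """
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise DataError("negative OTU count")
    total = c.sum()
    if total <= 0:
        raise DataError("all-zero sample: diversity undefined")
    p = c[c > 0] / total
    richness = int(p.size)
    h = float(-(p * np.log(p)).sum() / np.log(base))
    if richness > 1:
        j = float(h / (np.log(richness) / np.log(base)))
    else:
        j = float("nan")
    inv_d = float(1.0 / (p**2).sum())
    return DiversityProfile(richness, h, j, inv_d, depth=int(round(total)))


def profiles_from_table(table: pd.DataFrame, base: float = np.e) -> pd.DataFrame:
    """Per-sample profiles from a wide OTU table (samples x OTUs).

    Accepts either a wide frame indexed by sample with OTU columns, or a
    long frame with columns (sample_id, otu_id, count).
    """
    if {"sample_id", "otu_id", "count"} <= set(table.columns):
        wide = table.pivot_table(
            index="sample_id", columns="otu_id", values="count", aggfunc="sum", fill_value=0
        )
    else:
        wide = table.set_index("sample_id") if "sample_id" in table.columns else table
    rows = {}
    for sample, counts in wide.iterrows():
        rows[sample] = diversity_profile(counts.to_numpy(), base=base).as_dict()
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out.reset_index()


def merge_profiles(
    bacterial: pd.DataFrame, fungal: pd.DataFrame, *, aggregate_replicates: bool = False
) -> pd.DataFrame:
    """Combine bacterial and fungal profile frames into site covariates.

    Column names follow the site-table convention (``bacterial_h`` etc.).
    With ``aggregate_replicates`` the sample_id is assumed to be
    ``<site>_<replicate>`` and indexes are averaged per site.
    """
    def prep(df, prefix):
        df = df.rename(
            columns={
                "richness": f"{prefix}_richness",
                "shannon_h": f"{prefix}_h",
                "evenness_j": f"{prefix}_j",
                "inv_simpson": f"{prefix}_invd",
            }
        ).drop(columns=["depth"], errors="ignore")
        if aggregate_replicates:
            df["site_id"] = df["sample_id"].astype(str).str.rsplit("_", n=1).str[0]
            df = df.drop(columns="sample_id").groupby("site_id", as_index=False).mean()
        else:
            df = df.rename(columns={"sample_id": "site_id"})
        return df

    return prep(bacterial, "bacterial").merge(prep(fungal, "fungal"), on="site_id")
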