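"""CSV readers/writers and header mapping.

Interchange format is delimited text (UTF-8, header row).  A schema
config decouples file headers from canonical column names so that
spreadsheet exports with arbitrary headers can be ingested without
editing the files::

    schema:
      sites:        {"Site": site_id, "pH water": ph, ...}
      respiration:  {...}
      endmembers:   {...}
    schedule: [3, 7, 14, 21, 28, 44, 60, 80]
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .datamodel import (
    DEFAULT_SCHEDULE,
    ENDMEMBER_COLUMNS,
    RESPIRATION_COLUMNS,
    SITE_COLUMNS,
    Dataset,
    DesignSummary,
    summarize_design,
)
from .errors import SchemaError, SoilGamError


def _apply_schema(df: pd.DataFrame, required, mapping, table: str, optional=()):
    """Rename columns via ``mapping`` and verify all required ones exist."""
    if mapping:
        df = df.rename(columns=dict(mapping))
    missing = [c for c in required if c not in df.columns and c not in optional]
    if missing:
        raise SchemaError(missing, table=table)
    for c in optional:
        if c not in df.columns:
            df[c] = float("nan")
    return df[[c for c in required if c in df.columns]]


def read_sites(path, mapping=None) -> pd.DataFrame:
    return _apply_schema(pd.read_csv(path), SITE_COLUMNS, mapping, "sites")


def read_respiration(path, mapping=None) -> pd.DataFrame:
    df = _apply_schema(
        pd.read_csv(path), RESPIRATION_COLUMNS, mapping, "respiration", optional=("a13_total",)
    )
    df["replicate"] = df["replicate"].astype(int)
    return df


def read_endmembers(path, mapping=None) -> pd.DataFrame:
    return _apply_schema(pd.read_csv(path), ENDMEMBER_COLUMNS, mapping, "endmembers")


def read_dataset(
    sites_path,
    respiration_path,
    endmembers_path,
    schema_config: dict | None = None,
) -> tuple[Dataset, DesignSummary]:
    """Read and validate the three experiment tables.

    Returns the validated :class:`Dataset` together with a
    :class:`DesignSummary` of row counts and design completeness.
    """
    cfg = schema_config or {}
    schema = cfg.get("schema", {})
    ds = Dataset(
        sites=read_sites(sites_path, schema.get("sites")),
        respiration=read_respiration(respiration_path, schema.get("respiration")),
        endmembers=read_endmembers(endmembers_path, schema.get("endmembers")),
        schedule=tuple(cfg.get("schedule", DEFAULT_SCHEDULE)),
    ).validate()
    return ds, summarize_design(ds)


def write_dataset(ds: Dataset, outdir) -> dict:
    """Write sites/respiration/endmembers CSVs; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sites": outdir / "sites.csv",
        "respiration": outdir / "respiration.csv",
        "endmembers": outdir / "endmembers.csv",
    }
    ds.sites.to_csv(paths["sites"], index=False, float_format="%.12g")
    ds.respiration.to_csv(paths["respiration"], index=False, float_format="%.12g")
    ds.endmembers.to_csv(paths["endmembers"], index=False, float_format="%.12g")
    return paths


REPORT_COLUMNS = (
    "response",
    "df",
    "pct_deviance",
    "rpiq",
    "msep",
    "covariate",
    "interaction",
    "relation",
    "significance",
    "relative_importance_pct",
)


def write_report(reports, path_csv, path_json=None) -> pd.DataFrame:
    """Write assessment reports as one covariate row per model block.

    ``reports`` is a sequence of :class:`soilgam.assessment.AssessmentReport`
    (or dicts with the same fields).  The CSV mirrors the layout of a
    per-model summary table: model-level quality indexes repeated on the
    first row of each block, then one row per selected covariate with its
    relation type, land-use interaction flag, significance code and
    relative importance.
    """
    rows = []
    payload = []
    for rep in reports:
        d = rep if isinstance(rep, dict) else rep.to_dict()
        payload.append(d)
        terms = d.get("terms", [])
        if not terms:
            raise SoilGamError(f"report for {d.get('response')!r} has no terms (not even time)")
        for j, t in enumerate(terms):
            rows.append(
                {
                    "response": d["response"],
                    "df": round(d["df"], 2) if j == 0 else "",
                    "pct_deviance": round(d["pct_deviance"], 1) if j == 0 else "",
                    "rpiq": round(d["rpiq"], 2) if j == 0 else "",
                    "msep": round(d["msep"], 6) if j == 0 else "",
                    "covariate": t["covariate"],
                    "interaction": "YES" if t.get("interaction") else "NO",
                    "relation": t["relation"],
                    "significance": t.get("significance", ""),
                    "relative_importance_pct": t.get("relative_importance_pct", ""),
                }
            )
    table = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    table.to_csv(path_csv, index=False)
    if path_json is not None:
        Path(path_json).write_text(json.dumps(payload, indent=2, default=float))
    return table
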