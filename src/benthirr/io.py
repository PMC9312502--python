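"""Delimited-table readers and writers.

All tables are plain text, comma-delimited by default with tab accepted,
decimal point only.  Validation is strict: offending rows raise with the
taxon/row named, nothing is silently dropped.

Community tables are long format::

    station, date, taxon, abundance_ind_m2, biomass_afdw_g_m2
        [, depth_cm][, median_grain_um][, replicate]

Rows are grouped into one :class:`~benthirr.datatypes.CommunitySample` per
(station, date).  Values are normally already pooled to m⁻² units; with
``pooling="replicate_mean"`` the reader instead expects per-grab counts and
weights in a ``replicate`` column plus the grab area, divides by the area
and averages over replicates (the pooling mode is always explicit, never
inferred from the data).
"""

from __future__ import annotations

import math
import os
from typing import Iterable, Sequence

import pandas as pd

from .datatypes import (
    SCORE_COLUMNS,
    CommunitySample,
    IndexResult,
    MeasurementRecord,
    SchemaError,
    ScoreEntry,
    ScoreTable,
    TaxonRecord,
    ValidationError,
)

_COMMUNITY_REQUIRED = ("station", "date", "taxon", "abundance_ind_m2", "biomass_afdw_g_m2")
_MEASUREMENT_REQUIRED = ("core_id", "quantity", "value")


def _read_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a comma- or tab-delimited text table."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep)


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing column(s): {', '.join(missing)}")


def _opt(row, col):
    """Optional cell: None when the column is absent or the value is NaN."""
    if col not in row.index:
        return None
    v = row[col]
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return float(v)


def read_score_table(path: str | os.PathLike) -> ScoreTable:
    """Read a per-taxon trait score table.

    Required columns: ``taxon`` plus the eight score columns
    (``ft_diff, bt_diff, l_diff, ft_adv, bt_adv, l_adv, m_bpc, r_bpc``);
    optional ``lit_depth_cm`` carries literature burrow depths for
    theoretical depth profiles.
    """
    df = _read_table(path)
    _require_columns(df, ("taxon", *SCORE_COLUMNS), "score table")
    entries = []
    for _, row in df.iterrows():
        entries.append(
            ScoreEntry(
                taxon=str(row["taxon"]).strip(),
                **{c: float(row[c]) for c in SCORE_COLUMNS},
                lit_depth_cm=_opt(row, "lit_depth_cm"),
            )
        )
    return ScoreTable(entries)


def write_score_table(table: ScoreTable, path: str | os.PathLike) -> None:
    table.to_frame().to_csv(path, index=False)


def read_community_table(
    path: str | os.PathLike,
    *,
    pooling: str = "pooled",
    grab_area_m2: float | None = None,
) -> list[CommunitySample]:
    """Read long-format community data into samples, one per (station, date).

    pooling="pooled"          rows are already in ind·m⁻² / g·m⁻² (default)
    pooling="replicate_mean"  rows are per-grab counts/weights in a
                              ``replicate`` column; divided by
                              ``grab_area_m2`` and averaged over replicates
    """
    df = _read_table(path)
    _require_columns(df, _COMMUNITY_REQUIRED, "community table")

    if pooling == "replicate_mean":
        if grab_area_m2 is None or not grab_area_m2 > 0:
            raise ValueError("replicate_mean pooling requires a positive grab_area_m2")
        if "replicate" not in df.columns:
            raise SchemaError("replicate_mean pooling requires a 'replicate' column")
        n_rep = (
            df.groupby(["station", "date"])["replicate"].nunique().rename("n_rep")
        )
        df = df.merge(n_rep, on=["station", "date"])
        df["abundance_ind_m2"] = df["abundance_ind_m2"] / grab_area_m2 / df["n_rep"]
        df["biomass_afdw_g_m2"] = df["biomass_afdw_g_m2"] / grab_area_m2 / df["n_rep"]
        keep = [c for c in ("depth_cm", "median_grain_um") if c in df.columns]
        df = (
            df.groupby(["station", "date", "taxon"], as_index=False)
            .agg({"abundance_ind_m2": "sum", "biomass_afdw_g_m2": "sum",
                  **{c: "first" for c in keep}})
        )
    elif pooling != "pooled":
        raise ValueError(f"unknown pooling mode {pooling!r}")

    samples: list[CommunitySample] = []
    for (station, date), grp in df.groupby(["station", "date"], sort=True):
        records = []
        grain: float | None = None
        for _, row in grp.iterrows():
            g = _opt(row, "median_grain_um")
            if g is not None:
                grain = g
            taxon = str(row["taxon"]).strip()
            if taxon == "" or taxon.lower() == "nan":
                continue  # station present with no fauna → empty sample
            records.append(
                TaxonRecord(
                    taxon=taxon,
                    abundance=float(row["abundance_ind_m2"]),
                    biomass_afdw=float(row["biomass_afdw_g_m2"]),
                    depth_measured=_opt(row, "depth_cm"),
                )
            )
        samples.append(
            CommunitySample(
                station_id=str(station),
                date=str(date),
                records=records,
                median_grain_um=grain,
            )
        )
    return samples


def read_measurement_table(path: str | os.PathLike) -> list[MeasurementRecord]:
    """Read a core-measurement table (tracer inventories, irrigation, fluxes)."""
    df = _read_table(path)
    _require_columns(df, _MEASUREMENT_REQUIRED, "measurement table")
    records = []
    for _, row in df.iterrows():
        records.append(
            MeasurementRecord(
                core_id=str(row["core_id"]),
                quantity=str(row["quantity"]),
                value=float(row["value"]),
                layer_top_cm=_opt(row, "layer_top_cm"),
                layer_bottom_cm=_opt(row, "layer_bottom_cm"),
            )
        )
    return records


def write_index_table(results: Sequence[IndexResult], path: str | os.PathLike) -> None:
    """Write one row per sample: station, date, system, BIPc, BPc, coverage %.

    An empty result list yields a header-only file.
    """
    rows = []
    for r in results:
        station, _, date = r.sample_id.partition("/")
        rows.append(
            {
                "station": station,
                "date": date,
                "system": r.system,
                "bipc": r.bipc,
                "bpc": r.bpc,
                "coverage_abundance_pct": r.coverage_abundance_pct,
                "coverage_biomass_pct": r.coverage_biomass_pct,
            }
        )
    cols = ["station", "date", "system", "bipc", "bpc",
            "coverage_abundance_pct", "coverage_biomass_pct"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_index_table(path: str | os.PathLike) -> pd.DataFrame:
    df = _read_table(path)
    _require_columns(df, ("station", "date", "system", "bipc", "bpc"), "index table")
    return df
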