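"""CSV readers/writers for lineage tables, hotspot metadata and bare rate
tables.

All files are UTF-8, comma-separated, "." decimal, no thousands
separators, with a header row.  Empty cells mean "absent".  Unknown
extra columns are accepted with a warning (forward compatibility);
missing required columns, non-numeric cells and duplicate lineage ids
are hard errors that name the offending row/column.
"""

from __future__ import annotations

import math
import warnings
from typing import List

import pandas as pd

from .errors import ValidationError
from .hotspots import HotspotMeta, HotspotSummary
from .rates import LineageRecord

LINEAGE_COLUMNS = [
    "lineage_id",
    "family",
    "hotspot",
    "n_species",
    "crown_age_min",
    "crown_age_mean",
    "crown_age_max",
    "pleistocene_count",
]
LINEAGE_REQUIRED = ["lineage_id", "family", "hotspot", "n_species", "crown_age_mean"]

HOTSPOT_REQUIRED = ["hotspot", "area_km2", "species_total"]
RATE_REQUIRED = ["lineage_id", "hotspot", "rate"]


def _read_csv(path, required: List[str], known: List[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except Exception as exc:
        raise ValidationError(f"{path}: cannot read CSV: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        warnings.warn(f"{path}: ignoring unknown column(s) {unknown}", stacklevel=3)
    return df


def _opt_float(value, path, row, col):
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"{path} row {row}: column {col!r} is not numeric: {value!r}")


def _opt_int(value, path, row, col):
    f = _opt_float(value, path, row, col)
    if f is None:
        return None
    if f != int(f):
        raise ValidationError(f"{path} row {row}: column {col!r} must be an integer: {value!r}")
    return int(f)


def read_lineage_csv(path) -> List[LineageRecord]:
    """Read a lineage table into validated :class:`LineageRecord` rows."""
    df = _read_csv(path, LINEAGE_REQUIRED, LINEAGE_COLUMNS)
    if df["lineage_id"].duplicated().any():
        dupes = sorted(df.loc[df["lineage_id"].duplicated(), "lineage_id"])
        raise ValidationError(f"{path}: duplicate lineage_id(s): {dupes}")
    records = []
    for i, row in df.iterrows():
        n = _opt_int(row["n_species"], path, i, "n_species")
        if n is None:
            raise ValidationError(f"{path} row {i}: n_species is required")
        mean_age = _opt_float(row["crown_age_mean"], path, i, "crown_age_mean")
        if mean_age is None:
            raise ValidationError(f"{path} row {i}: crown_age_mean is required")
        try:
            records.append(
                LineageRecord(
                    lineage_id=str(row["lineage_id"]),
                    family=str(row["family"]),
                    hotspot=str(row["hotspot"]),
                    n_species=n,
                    crown_age_mean=mean_age,
                    crown_age_min=_opt_float(row.get("crown_age_min"), path, i, "crown_age_min"),
                    crown_age_max=_opt_float(row.get("crown_age_max"), path, i, "crown_age_max"),
                    pleistocene_count=_opt_int(
                        row.get("pleistocene_count"), path, i, "pleistocene_count"
                    ),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from exc
    if not records:
        raise ValidationError(f"{path}: no lineage rows")
    return records


def write_lineage_csv(records: List[LineageRecord], path) -> None:
    rows = [
        {
            "lineage_id": r.lineage_id,
            "family": r.family,
            "hotspot": r.hotspot,
            "n_species": r.n_species,
            "crown_age_min": r.crown_age_min,
            "crown_age_mean": r.crown_age_mean,
            "crown_age_max": r.crown_age_max,
            "pleistocene_count": r.pleistocene_count,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=LINEAGE_COLUMNS)
    df["pleistocene_count"] = df["pleistocene_count"].astype("Int64")
    df.to_csv(path, index=False, encoding="utf-8")


def read_hotspot_csv(path) -> List[HotspotMeta]:
    """Read hotspot metadata (area, richness, optional printed cells)."""
    known = [
        "hotspot",
        "area_km2",
        "species_total",
        "species_endemic",
        "species_per_km2_printed",
        "mean_rate_printed",
        "speciation_density_printed",
    ]
    df = _read_csv(path, HOTSPOT_REQUIRED, known)
    if df["hotspot"].duplicated().any():
        dupes = sorted(df.loc[df["hotspot"].duplicated(), "hotspot"])
        raise ValidationError(f"{path}: duplicate hotspot(s): {dupes}")
    metas = []
    for i, row in df.iterrows():
        area = _opt_float(row["area_km2"], path, i, "area_km2")
        total = _opt_int(row["species_total"], path, i, "species_total")
        if area is None or total is None:
            raise ValidationError(f"{path} row {i}: area_km2 and species_total required")
        try:
            metas.append(
                HotspotMeta(
                    hotspot=str(row["hotspot"]),
                    area_km2=area,
                    species_total=total,
                    species_endemic=_opt_int(
                        row.get("species_endemic"), path, i, "species_endemic"
                    ),
                    species_per_km2_printed=_opt_float(
                        row.get("species_per_km2_printed"), path, i, "species_per_km2_printed"
                    ),
                    mean_rate_printed=_opt_float(
                        row.get("mean_rate_printed"), path, i, "mean_rate_printed"
                    ),
                    speciation_density_printed=_opt_float(
                        row.get("speciation_density_printed"),
                        path,
                        i,
                        "speciation_density_printed",
                    ),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from exc
    if not metas:
        raise ValidationError(f"{path}: no hotspot rows")
    return metas


def read_rate_csv(path) -> pd.DataFrame:
    """Read a bare ``lineage_id,hotspot,rate`` table (e.g., literature
    rates for hotspots whose per-lineage data come from other studies)."""
    df = _read_csv(path, RATE_REQUIRED, RATE_REQUIRED)
    if df["lineage_id"].duplicated().any():
        dupes = sorted(df.loc[df["lineage_id"].duplicated(), "lineage_id"])
        raise ValidationError(f"{path}: duplicate lineage_id(s): {dupes}")
    for i, v in df["rate"].items():
        _opt_float(v, path, i, "rate")
    df["rate"] = df["rate"].astype(float)
    return df


def write_summary_csv(summaries: List[HotspotSummary], path) -> None:
    pd.DataFrame([s.__dict__ for s in summaries]).to_csv(
        path, index=False, encoding="utf-8", float_format="%.10g"
    )
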