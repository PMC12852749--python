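"""Domain types, standards registry and sample-table / site-geometry I/O.

The package models a monitored river reach as a set of sampling *sites*,
each subdivided laterally into up to three *sectors* (main channel, east
bank, west bank), visited in two *seasons*.  Every measured value is one
:class:`SampleRecord`; the regulatory context (permissible limit, ideal
value, index weight, objective direction) lives in a registry of
:class:`ParameterDef` loaded from a human-editable YAML file.

A shipped default registry encodes the surface-water limits of Egyptian
Law 48/1982 for the parameters whose limits are statutory (COD, BOD, DO,
TDS, pH, phenol, TN, NH3-N, TP, fluoride, sulfate, chloride); the
remaining routinely monitored parameters (temperature, alkalinity,
hardness, turbidity, TSS, NO3-N, conductivity) carry documented,
non-statutory placeholder guidelines and are excluded from the indices
by default.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

SECTORS = ("main", "east", "west")
SEASONS = ("summer", "winter")
OBJECTIVES = ("ceiling", "floor", "range")


class ConfigError(ValueError):
    """Raised for an invalid standards/weights/scenario configuration."""


class DataError(ValueError):
    """Raised for an invalid or inconsistent sample table."""


@dataclass(frozen=True)
class ParameterDef:
    """One monitored parameter and its regulatory standard.

    ``objective`` gives the direction of the standard: ``ceiling`` (values
    above the limit violate), ``floor`` (values below violate, e.g.
    dissolved oxygen) or ``range`` (values outside [low, high] violate,
    e.g. pH).  ``standard_limit`` is a float, or a (low, high) pair for
    range objectives.  ``ideal`` is the value at which the quality rating
    is zero; ``weight`` the relative importance in the weighted
    arithmetic index; ``guideline`` the objective used by the CCME-style
    index (defaults to the standard limit).  ``statutory`` records
    whether the limit is printed in Law 48/1982 or is a documented
    placeholder.
    """

    name: str
    unit: str
    objective: str
    standard_limit: float | tuple[float, float]
    ideal: float
    weight: float
    guideline: float | tuple[float, float] | None = None
    statutory: bool = True

    def __post_init__(self) -> None:
        if self.objective not in OBJECTIVES:
            raise ConfigError(
                f"parameter {self.name!r}: unknown objective {self.objective!r}"
            )
        if not self.weight > 0:
            raise ConfigError(f"parameter {self.name!r}: weight must be > 0")
        if self.objective == "range":
            low, high = self.standard_limit  # type: ignore[misc]
            if not low < high:
                raise ConfigError(
                    f"parameter {self.name!r}: range limit needs low < high"
                )
        else:
            si = float(self.standard_limit)  # type: ignore[arg-type]
            if si == self.ideal:
                raise ConfigError(
                    f"parameter {self.name!r}: standard limit equals ideal value "
                    "(degenerate quality-rating denominator)"
                )
        if self.guideline is None:
            object.__setattr__(self, "guideline", self.standard_limit)


class StandardsRegistry:
    """Mapping of parameter name -> :class:`ParameterDef`."""

    def __init__(self, params: Iterable[ParameterDef]):
        self._params: dict[str, ParameterDef] = {}
        for p in params:
            if p.name in self._params:
                raise ConfigError(f"duplicate parameter {p.name!r} in standards")
            self._params[p.name] = p

    def __getitem__(self, name: str) -> ParameterDef:
        try:
            return self._params[name]
        except KeyError:
            raise KeyError(f"parameter {name!r} not in standards registry") from None

    def __contains__(self, name: str) -> bool:
        return name in self._params

    def __iter__(self):
        return iter(self._params.values())

    def __len__(self) -> int:
        return len(self._params)

    @property
    def names(self) -> list[str]:
        return list(self._params)

    def statutory(self) -> list[ParameterDef]:
        return [p for p in self if p.statutory]

    def get(self, name: str, default=None):
        return self._params.get(name, default)


@dataclass(frozen=True)
class SamplingSite:
    """One sampling point: a (site, lateral sector) pair with coordinates.

    Coordinates are decimal degrees, WGS84, longitude east / latitude
    north (columns are always named, never positional).
    """

    site_id: str
    longitude: float
    latitude: float
    sector: str = "main"
    city: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if self.sector not in SECTORS:
            raise DataError(f"site {self.site_id!r}: unknown sector {self.sector!r}")
        if not (math.isfinite(self.longitude) and math.isfinite(self.latitude)):
            raise DataError(f"site {self.site_id!r}: non-finite coordinates")

    @property
    def key(self) -> tuple[str, str]:
        return (self.site_id, self.sector)


@dataclass(frozen=True)
class SampleRecord:
    """One measured value at a (site, sector) point in one season."""

    site_id: str
    sector: str
    season: str
    parameter: str
    value: float
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.season not in SEASONS:
            raise DataError(f"unknown season {self.season!r}")
        if self.sector not in SECTORS:
            raise DataError(f"unknown sector {self.sector!r}")
        if not math.isfinite(self.value):
            raise DataError(
                f"non-finite value for {self.parameter!r} at {self.site_id}/{self.sector}"
            )


@dataclass
class Dataset:
    """A validated collection of sites and sample records."""

    sites: list[SamplingSite]
    records: list[SampleRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        keys = {s.key for s in self.sites}
        if len(keys) != len(self.sites):
            raise DataError("duplicate (site_id, sector) in site list")
        for r in self.records:
            if (r.site_id, r.sector) not in keys:
                raise DataError(
                    f"record for {r.parameter!r} refers to unknown point "
                    f"({r.site_id!r}, {r.sector!r})"
                )

    @property
    def site_index(self) -> dict[tuple[str, str], SamplingSite]:
        return {s.key: s for s in self.sites}

    def to_frame(self):
        """Long-form pandas DataFrame of records joined with coordinates."""
        import pandas as pd

        idx = self.site_index
        rows = [
            {
                "site_id": r.site_id,
                "sector": r.sector,
                "season": r.season,
                "latitude": idx[(r.site_id, r.sector)].latitude,
                "longitude": idx[(r.site_id, r.sector)].longitude,
                "parameter": r.parameter,
                "value": r.value,
                "replicate": r.replicate,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Standards configuration

_DEFAULT_STANDARDS = "standards_egypt48.yaml"


def default_standards_path() -> Path:
    """Path to the shipped default standards/weights configuration."""
    return Path(str(resources.files("riverwqi") / "data" / _DEFAULT_STANDARDS))


def load_standards(config_path: str | Path | None = None) -> StandardsRegistry:
    """Load a standards registry from a YAML configuration file.

    Each entry declares ``unit``, ``objective`` (ceiling/floor/range),
    ``limit`` (number, or [low, high] for range), and optionally
    ``ideal`` (default 0 for ceiling parameters), ``weight`` (default 1),
    ``guideline`` (default: the limit) and ``statutory`` (default true).
    """
    path = Path(config_path) if config_path is not None else default_standards_path()
    if not path.exists():
        raise ConfigError(f"standards file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "parameters" not in doc:
        raise ConfigError(f"standards file {path} lacks a 'parameters' section")
    params = []
    seen: set[str] = set()
    for name, entry in doc["parameters"].items():
        if name in seen:
            raise ConfigError(f"duplicate parameter {name!r} in {path}")
        seen.add(name)
        if not isinstance(entry, Mapping):
            raise ConfigError(f"parameter {name!r}: entry must be a mapping")
        try:
            objective = entry["objective"]
            raw_limit = entry["limit"]
        except KeyError as exc:
            raise ConfigError(f"parameter {name!r}: missing key {exc}") from None
        if objective == "range":
            limit: float | tuple[float, float] = (
                float(raw_limit[0]),
                float(raw_limit[1]),
            )
        else:
            limit = float(raw_limit)
        raw_guideline = entry.get("guideline")
        if raw_guideline is None:
            guideline = None
        elif isinstance(raw_guideline, (list, tuple)):
            guideline = (float(raw_guideline[0]), float(raw_guideline[1]))
        else:
            guideline = float(raw_guideline)
        params.append(
            ParameterDef(
                name=name,
                unit=str(entry.get("unit", "")),
                objective=objective,
                standard_limit=limit,
                ideal=float(entry.get("ideal", 0.0)),
                weight=float(entry.get("weight", 1.0)),
                guideline=guideline,
                statutory=bool(entry.get("statutory", True)),
            )
        )
    return StandardsRegistry(params)


# ---------------------------------------------------------------------------
# Sample tables (UTF-8 CSV, header row)

_SAMPLE_COLUMNS = (
    "site_id",
    "sector",
    "season",
    "latitude",
    "longitude",
    "parameter",
    "value",
)


def load_samples(path: str | Path, registry: StandardsRegistry) -> Dataset:
    """Read a delimited sample table and validate it against the registry.

    Required columns: site_id, sector, season, latitude, longitude,
    parameter, value.  Optional: unit (must then match the registry
    unit), replicate.  Errors report the offending 1-based data row.
    """
    path = Path(path)
    sites: dict[tuple[str, str], SamplingSite] = {}
    records: list[SampleRecord] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in _SAMPLE_COLUMNS if c not in header]
        if missing:
            raise DataError(f"{path}: missing columns {missing}")
        for i, row in enumerate(reader, start=1):
            pname = row["parameter"].strip()
            if pname not in registry:
                raise DataError(
                    f"{path} row {i}: unknown parameter {pname!r} "
                    "(not in standards registry)"
                )
            if "unit" in header and row.get("unit", "").strip():
                expected = registry[pname].unit
                if row["unit"].strip() != expected:
                    raise DataError(
                        f"{path} row {i}: unit {row['unit']!r} for {pname!r} "
                        f"does not match registry unit {expected!r}"
                    )
            try:
                value = float(row["value"])
                lat = float(row["latitude"])
                lon = float(row["longitude"])
            except ValueError as exc:
                raise DataError(f"{path} row {i}: unparseable number ({exc})") from None
            replicate = int(row.get("replicate") or 0)
            site = SamplingSite(
                site_id=row["site_id"].strip(),
                sector=row["sector"].strip(),
                longitude=lon,
                latitude=lat,
                city=row.get("city", "").strip(),
            )
            prior = sites.get(site.key)
            if prior is None:
                sites[site.key] = site
            elif (prior.longitude, prior.latitude) != (lon, lat):
                raise DataError(
                    f"{path} row {i}: point {site.key} re-declared with "
                    "different coordinates"
                )
            records.append(
                SampleRecord(
                    site_id=site.site_id,
                    sector=site.sector,
                    season=row["season"].strip(),
                    parameter=pname,
                    value=value,
                    replicate=replicate,
                )
            )
    return Dataset(sites=list(sites.values()), records=records, provenance=str(path))


def write_samples(dataset: Dataset, path: str | Path, registry=None) -> None:
    """Write a Dataset back to the standard CSV sample-table format."""
    path = Path(path)
    idx = dataset.site_index
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        cols = list(_SAMPLE_COLUMNS) + ["replicate"]
        if registry is not None:
            cols.append("unit")
        writer.writerow(cols)
        for r in dataset.records:
            s = idx[(r.site_id, r.sector)]
            row = [
                r.site_id,
                r.sector,
                r.season,
                repr(s.latitude),
                repr(s.longitude),
                r.parameter,
                repr(r.value),
                r.replicate,
            ]
            if registry is not None:
                row.append(registry[r.parameter].unit)
            writer.writerow(row)


# ---------------------------------------------------------------------------
# Site geometry (GeoJSON, RFC 7946)


def write_sites_geo(sites: Iterable[SamplingSite], path: str | Path) -> None:
    """Write sampling points as a GeoJSON FeatureCollection."""
    sites = list(sites)
    if not sites:
        raise DataError("cannot write GeoJSON for an empty site list")
    features = [
        {
            "type": "Feature",
            "geometry": {
                "type": "Point",
                "coordinates": [s.longitude, s.latitude],
            },
            "properties": {
                "site_id": s.site_id,
                "sector": s.sector,
                "city": s.city,
                "description": s.description,
            },
        }
        for s in sites
    ]
    doc = {"type": "FeatureCollection", "features": features}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def read_sites_geo(path: str | Path) -> list[SamplingSite]:
    """Read sampling points back from a GeoJSON FeatureCollection."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise DataError(f"{path}: not a GeoJSON FeatureCollection")
    sites = []
    for feat in doc.get("features", []):
        lon, lat = feat["geometry"]["coordinates"][:2]
        props = feat.get("properties", {})
        sites.append(
            SamplingSite(
                site_id=props.get("site_id", ""),
                sector=props.get("sector", "main"),
                longitude=float(lon),
                latitude=float(lat),
                city=props.get("city", ""),
                description=props.get("description", ""),
            )
        )
    return sites


def read_mask_polygon(path: str | Path):
    """Read a corridor mask polygon from a GeoJSON file (Polygon feature)."""
    from shapely.geometry import shape

    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") == "FeatureCollection":
        geoms = [shape(f["geometry"]) for f in doc["features"]]
    elif doc.get("type") == "Feature":
        geoms = [shape(doc["geometry"])]
    else:
        geoms = [shape(doc)]
    from shapely.ops import unary_union

    return unary_union(geoms)
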