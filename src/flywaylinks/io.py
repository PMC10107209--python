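"""Readers and writers for the four input kinds and the link table.

Formats are deliberately plain: delimited tables (CSV/TSV) for records,
populations and links; GeoJSON FeatureCollections (WGS84 lon/lat) for
country boundaries and seasonal ranges; a single YAML (or JSON) file for
the analysis constants plus the study-region subregion mapping.

Validation is total: any row or feature violating a type invariant is
rejected with an error naming it.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from . import geometry as geo
from .types import (
    DEVICES,
    SEASONS,
    SPECIES_GROUPS,
    TRENDS,
    AnalysisConfig,
    Country,
    CountryLayer,
    MigrationRecord,
    MigratoryLink,
    PopulationSizeEntry,
    PopulationTable,
    RangeSet,
    SpeciesRange,
    StudyRegion,
)

log = logging.getLogger(__name__)

RECORD_COLUMNS = [
    "record_id",
    "species_id",
    "species_group",
    "breeding_country",
    "nonbreeding_country",
    "device",
    "study_id",
    "year_published",
]

LINK_COLUMNS = [
    "species_id",
    "breeding_country",
    "nonbreeding_country",
    "status",
    "record_count",
    "strength_pct",
]


def _read_table(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def read_records(path: str | Path, country_layer: CountryLayer) -> list[MigrationRecord]:
    """Read and validate a migration-record table.

    Every breeding country must be a European code of the layer and every
    nonbreeding country a sub-Saharan (African) code; violations raise with
    the offending row number (1-based, excluding the header).
    """
    df = _read_table(path, RECORD_COLUMNS)
    european = set(country_layer.european_codes())
    african = set(country_layer.african_codes())
    records: list[MigrationRecord] = []
    seen_ids: set[str] = set()
    group_of: dict[str, str] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rid = row.record_id
        if rid in seen_ids:
            raise ValueError(f"row {i}: duplicate record_id {rid!r}")
        seen_ids.add(rid)
        if row.species_group not in SPECIES_GROUPS:
            raise ValueError(f"row {i}: unknown species_group {row.species_group!r}")
        prev = group_of.setdefault(row.species_id, row.species_group)
        if prev != row.species_group:
            raise ValueError(
                f"row {i}: species {row.species_id!r} appears as both {prev!r} "
                f"and {row.species_group!r}"
            )
        if row.breeding_country not in european:
            raise ValueError(
                f"row {i}: breeding_country {row.breeding_country!r} is not a "
                "European country of the layer"
            )
        if row.nonbreeding_country not in african:
            raise ValueError(
                f"row {i}: nonbreeding_country {row.nonbreeding_country!r} is not a "
                "sub-Saharan country of the layer"
            )
        if row.device not in DEVICES:
            raise ValueError(f"row {i}: unknown device {row.device!r}")
        year_raw = str(row.year_published).strip()
        year = int(year_raw) if year_raw else None
        records.append(
            MigrationRecord(
                record_id=rid,
                species_id=row.species_id,
                species_group=row.species_group,
                breeding_country=row.breeding_country,
                nonbreeding_country=row.nonbreeding_country,
                device=row.device,
                study_id=row.study_id,
                year_published=year,
            )
        )
    log.info("read %d migration records from %s", len(records), path)
    return records


def write_records(records: Iterable[MigrationRecord], path: str | Path) -> None:
    rows = [
        {
            "record_id": r.record_id,
            "species_id": r.species_id,
            "species_group": r.species_group,
            "breeding_country": r.breeding_country,
            "nonbreeding_country": r.nonbreeding_country,
            "device": r.device,
            "study_id": r.study_id,
            "year_published": "" if r.year_published is None else r.year_published,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(path, index=False)


def read_country_layer(path: str | Path, region: StudyRegion) -> CountryLayer:
    """Read a GeoJSON country layer, attaching continent and subregion.

    Every feature must carry a ``code`` property present in the study-region
    mapping. Invalid geometries are repaired by zero-width buffering with a
    logged warning.
    """
    with open(path) as fh:
        fc = json.load(fh)
    countries = []
    for i, feat in enumerate(fc.get("features", [])):
        props = feat.get("properties", {})
        code = props.get("code")
        if not code:
            raise ValueError(f"feature {i}: missing 'code' property")
        if code not in region:
            raise ValueError(f"feature {i}: country code {code!r} absent from the subregion mapping")
        continent, subregion = region.lookup(code)
        geom = geo.repair(shape(feat["geometry"]), label=f"country {code}")
        countries.append(
            Country(
                code=code,
                name=props.get("name", code),
                continent=continent,
                subregion=subregion,
                geometry=geom,
            )
        )
    layer = CountryLayer(countries)
    log.info("read %d countries from %s", len(layer), path)
    return layer


def write_country_layer(layer: CountryLayer, path: str | Path) -> None:
    fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"code": c.code, "name": c.name},
                "geometry": mapping(c.geometry),
            }
            for c in layer
        ],
    }
    with open(path, "w") as fh:
        json.dump(fc, fh)


def read_ranges(path: str | Path) -> RangeSet:
    """Read seasonal species ranges from GeoJSON (``species_id``, ``season``
    feature properties); invalid geometries are repaired."""
    with open(path) as fh:
        fc = json.load(fh)
    ranges = []
    for i, feat in enumerate(fc.get("features", [])):
        props = feat.get("properties", {})
        species = props.get("species_id")
        season = props.get("season")
        if not species:
            raise ValueError(f"feature {i}: missing 'species_id' property")
        if season not in SEASONS:
            raise ValueError(f"feature {i}: unknown season {season!r}")
        geom = geo.repair(shape(feat["geometry"]), label=f"range {species}/{season}")
        ranges.append(SpeciesRange(species_id=species, season=season, geometry=geom))
    rs = RangeSet(ranges)
    log.info("read %d species ranges from %s", len(rs), path)
    return rs


def write_ranges(ranges: RangeSet | Iterable[SpeciesRange], path: str | Path) -> None:
    fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"species_id": r.species_id, "season": r.season},
                "geometry": mapping(r.geometry),
            }
            for r in ranges
        ],
    }
    with open(path, "w") as fh:
        json.dump(fc, fh)


def read_population_table(path: str | Path, country_layer: CountryLayer | None = None) -> PopulationTable:
    """Read the national breeding-population table (CSV)."""
    df = _read_table(path, ["species_id", "country", "pop_size", "trend"])
    entries = []
    european = set(country_layer.european_codes()) if country_layer is not None else None
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            size = float(row.pop_size)
        except ValueError:
            raise ValueError(f"row {i}: pop_size {row.pop_size!r} is not a number") from None
        if size < 0:
            raise ValueError(f"row {i}: negative pop_size {size}")
        if row.trend not in TRENDS:
            raise ValueError(f"row {i}: unknown trend {row.trend!r}")
        if european is not None and row.country not in european:
            raise ValueError(f"row {i}: country {row.country!r} is not a European country of the layer")
        entries.append(
            PopulationSizeEntry(species_id=row.species_id, country=row.country, pop_size=size, trend=row.trend)
        )
    table = PopulationTable(entries)
    log.info("read %d population entries from %s", len(table), path)
    return table


def write_population_table(table: PopulationTable | Iterable[PopulationSizeEntry], path: str | Path) -> None:
    rows = [
        {"species_id": e.species_id, "country": e.country, "pop_size": e.pop_size, "trend": e.trend}
        for e in table
    ]
    pd.DataFrame(rows, columns=["species_id", "country", "pop_size", "trend"]).to_csv(path, index=False)


def write_links(links: Iterable[MigratoryLink], path: str | Path, round_digits: int | None = None) -> None:
    """Write the link table (machine-readable twin of the link appendix)."""
    rows = []
    for l in links:
        rows.append(
            {
                "species_id": l.species_id,
                "breeding_country": l.breeding_country,
                "nonbreeding_country": l.nonbreeding_country,
                "status": l.status,
                "record_count": l.record_count,
                "strength_pct": l.strength_pct,
            }
        )
    df = pd.DataFrame(rows, columns=LINK_COLUMNS)
    if round_digits is not None and len(df):
        df["record_count"] = df["record_count"].round(round_digits)
        df["strength_pct"] = df["strength_pct"].round(round_digits)
    df.to_csv(path, index=False)


def read_links(path: str | Path) -> list[MigratoryLink]:
    df = _read_table(path, LINK_COLUMNS)
    links = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.status not in ("observed", "inferred"):
            raise ValueError(f"row {i}: unknown link status {row.status!r}")
        links.append(
            MigratoryLink(
                species_id=row.species_id,
                breeding_country=row.breeding_country,
                nonbreeding_country=row.nonbreeding_country,
                status=row.status,
                record_count=float(row.record_count) if str(row.record_count) else None,
                strength_pct=float(row.strength_pct) if str(row.strength_pct) else None,
            )
        )
    return links


def load_config(path: str | Path) -> tuple[AnalysisConfig, StudyRegion]:
    """Load the analysis config and study-region mapping from YAML/JSON.

    Layout::

        analysis:
          min_records_per_population: 3
          coverage_threshold_pct: 50
          equal_area_crs: cea
          random_seed: 0
        study_region:
          Europe:
            western Europe: [FRA, ESP, ...]
            ...
          Africa:
            western Africa: [MLI, SEN, ...]
            ...
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - {"analysis", "study_region"}
    if unknown:
        raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
    analysis = raw.get("analysis", {})
    allowed = {f.name for f in AnalysisConfig.__dataclass_fields__.values()}
    bad = set(analysis) - allowed
    if bad:
        raise ValueError(f"{path}: unknown analysis key(s) {sorted(bad)}")
    config = AnalysisConfig(**analysis)
    membership: dict[str, tuple[str, str]] = {}
    for continent, subregions in raw.get("study_region", {}).items():
        if continent not in ("Europe", "Africa"):
            raise ValueError(f"{path}: unknown continent {continent!r} in study_region")
        for subregion, codes in subregions.items():
            for code in codes:
                if code in membership:
                    raise ValueError(f"{path}: country {code!r} listed twice in study_region")
                membership[code] = (continent, subregion)
    return config, StudyRegion(membership)


def dump_config(config: AnalysisConfig, region: StudyRegion, path: str | Path) -> None:
    by_continent: dict[str, dict[str, list[str]]] = {}
    for code in sorted(region.membership):
        continent, subregion = region.membership[code]
        by_continent.setdefault(continent, {}).setdefault(subregion, []).append(code)
    payload = {
        "analysis": {
            "min_records_per_population": config.min_records_per_population,
            "coverage_threshold_pct": config.coverage_threshold_pct,
            "equal_area_crs": config.equal_area_crs,
            "random_seed": config.random_seed,
        },
        "study_region": by_continent,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
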