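"""Derive, infer and quantify migratory links.

The pipeline turns migration records into links in four steps:

1. group records by population (species x breeding country) and drop
   populations with fewer than ``min_records_per_population`` records;
2. count the distinct nonbreeding countries of the retained records into
   *observed* links;
3. infer further links geometrically: take the minimum convex polygon of
   the per-country centroids of the species' nonbreeding range clipped to
   each observed country, and add an *inferred* link for every other
   country whose in-range territory touches that hull;
4. interpolate a record count for each inferred link from the density of
   records (records per km^2 of in-country nonbreeding range) in
   neighbouring observed countries, then convert all counts into link
   strengths: the percentage of the population's records, observed or
   interpolated, assigned to each nonbreeding country.

Strengths are kept at full precision; inferred counts stay fractional so
that strengths always sum to exactly 100 per population.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from typing import Iterable, Mapping, Sequence

from shapely.geometry import MultiPoint, Point
from shapely.geometry.base import BaseGeometry

from . import geometry as geo
from .types import (
    INFERRED,
    OBSERVED,
    AnalysisConfig,
    CountryLayer,
    MigrationRecord,
    MigratoryLink,
    PopulationKey,
    PopulationLinkSet,
    RangeSet,
    SpeciesRange,
)

log = logging.getLogger(__name__)


def filter_populations(
    records: Iterable[MigrationRecord], min_n: int = 3
) -> tuple[dict[PopulationKey, list[MigrationRecord]], dict[PopulationKey, int]]:
    """Group records by population and drop under-sampled populations.

    Returns (retained populations -> their records, excluded populations ->
    their record counts). No record is lost or duplicated: every input
    record lands in exactly one of the two groups.
    """
    grouped: dict[PopulationKey, list[MigrationRecord]] = defaultdict(list)
    for rec in records:
        grouped[rec.population].append(rec)
    retained = {k: v for k, v in grouped.items() if len(v) >= min_n}
    excluded = {k: len(v) for k, v in grouped.items() if len(v) < min_n}
    if excluded:
        log.info(
            "excluded %d population(s) with fewer than %d records (%d records dropped)",
            len(excluded),
            min_n,
            sum(excluded.values()),
        )
    return retained, excluded


def derive_observed_links(
    retained: Mapping[PopulationKey, Sequence[MigrationRecord]]
) -> list[PopulationLinkSet]:
    """Count each population's records into observed links.

    One link per distinct (species, breeding, nonbreeding) triple, with
    ``record_count`` the number of individuals on that triple. Link order
    within a population is deterministic (by nonbreeding country code).
    """
    link_sets = []
    for pop in sorted(retained):
        recs = retained[pop]
        counts = Counter(r.nonbreeding_country for r in recs)
        links = tuple(
            MigratoryLink(
                species_id=pop.species_id,
                breeding_country=pop.breeding_country,
                nonbreeding_country=dest,
                status=OBSERVED,
                record_count=float(n),
            )
            for dest, n in sorted(counts.items())
        )
        link_sets.append(PopulationLinkSet(population=pop, links=links, n_records_retained=len(recs)))
    return link_sets


def nonbreeding_centroid(range_: SpeciesRange | BaseGeometry, country_geometry: BaseGeometry) -> Point | None:
    """Area-weighted centroid of the species' nonbreeding range within one
    country, as a lon/lat point; ``None`` when the intersection is empty.

    The centroid is computed in the equal-area projection so multi-part
    intersections are weighted by true area.
    """
    geom = range_.geometry if isinstance(range_, SpeciesRange) else range_
    if isinstance(range_, SpeciesRange) and range_.season != "nonbreeding":
        raise ValueError(f"expected a nonbreeding range, got season {range_.season!r}")
    if not geom.is_valid:
        raise ValueError("invalid range geometry (should have been repaired on ingest)")
    inter = geom.intersection(country_geometry)
    if inter.is_empty or geo.equal_area_km2(inter) == 0.0:
        return None
    return geo.area_weighted_centroid(inter)


class _SpeciesGeometry:
    """Cached per-species clips of the nonbreeding range against every
    African country: equal-area geometry, area and centroid. Building the
    cache once per species keeps repeated inference/interpolation cheap."""

    def __init__(self, nonbreeding_range: BaseGeometry, countries: CountryLayer):
        self.countries = countries
        self.clip_ea: dict[str, BaseGeometry] = {}
        self.area_km2: dict[str, float] = {}
        self.centroid_ea: dict[str, Point] = {}
        for code in countries.african_codes():
            inter = nonbreeding_range.intersection(countries.geometry(code))
            if inter.is_empty:
                continue
            ea = geo.to_equal_area(inter)
            area = ea.area / geo.M2_PER_KM2
            if area <= 0.0:
                continue
            self.clip_ea[code] = ea
            self.area_km2[code] = area
            self.centroid_ea[code] = ea.centroid

    def in_range_codes(self) -> list[str]:
        return sorted(self.area_km2)


def infer_links(
    link_set: PopulationLinkSet,
    range_: SpeciesRange | BaseGeometry | None,
    countries: CountryLayer,
    _cache: _SpeciesGeometry | None = None,
) -> list[MigratoryLink]:
    """Infer links to countries lying between the observed ones.

    Builds the convex hull of the nonbreeding-range centroids of all
    observed-link countries (in the equal-area plane). Every country that
    is not an observed destination, holds a positive-area slice of the
    species' nonbreeding range, and whose in-range slice intersects the
    hull (boundary touch counts) gains one inferred link with no record
    count yet. With a single observed country there is nothing between
    links, so nothing is inferred; with two, the hull degenerates to the
    segment joining the two centroids.
    """
    if _cache is not None:
        cache = _cache
    else:
        geom = range_.geometry if isinstance(range_, SpeciesRange) else range_
        cache = _SpeciesGeometry(geom, countries)
    observed = set(link_set.observed_countries())
    centroids = [cache.centroid_ea[c] for c in sorted(observed) if c in cache.centroid_ea]
    if len(centroids) < 2:
        return []
    hull = MultiPoint(centroids).convex_hull
    inferred = []
    for code in cache.in_range_codes():
        if code in observed:
            continue
        if cache.clip_ea[code].intersects(hull):
            inferred.append(
                MigratoryLink(
                    species_id=link_set.population.species_id,
                    breeding_country=link_set.population.breeding_country,
                    nonbreeding_country=code,
                    status=INFERRED,
                )
            )
    return inferred


def interpolate_record_count(
    link: MigratoryLink,
    link_set: PopulationLinkSet,
    range_: SpeciesRange | BaseGeometry | None,
    countries: CountryLayer,
    _cache: _SpeciesGeometry | None = None,
) -> float:
    """Interpolate a record count for an inferred link from neighbours.

    For each observed-link country sharing a boundary with the inferred
    country (fallback: the two observed countries with nearest range
    centroids), compute the record density — observed records per km^2 of
    the species' nonbreeding range within that country — and transfer the
    mean density onto the inferred country's in-range area. The result is
    fractional and never negative.
    """
    if link.status != INFERRED:
        raise ValueError("interpolate_record_count expects an inferred link")
    if _cache is not None:
        cache = _cache
    else:
        geom = range_.geometry if isinstance(range_, SpeciesRange) else range_
        cache = _SpeciesGeometry(geom, countries)
    dest = link.nonbreeding_country
    if dest not in cache.area_km2:
        raise ValueError(f"inferred country {dest!r} holds no nonbreeding range")
    counts = {l.nonbreeding_country: l.record_count for l in link_set.observed()}
    observed_codes = [c for c in sorted(counts) if c in cache.area_km2]
    if not observed_codes:
        raise ValueError("no observed country with nonbreeding range to interpolate from")
    dest_geom = countries.geometry(dest)
    neighbours = [c for c in observed_codes if countries.geometry(c).intersects(dest_geom)]
    if not neighbours:
        dest_centroid = cache.centroid_ea[dest]
        by_distance = sorted(observed_codes, key=lambda c: (cache.centroid_ea[c].distance(dest_centroid), c))
        neighbours = by_distance[:2]
    densities = [counts[c] / cache.area_km2[c] for c in neighbours]
    return (sum(densities) / len(densities)) * cache.area_km2[dest]


def compute_strengths(link_set: PopulationLinkSet) -> PopulationLinkSet:
    """Convert record counts into link strengths (percent of the population).

    strength = 100 x record_count / total records across all links of the
    population (observed or interpolated); strengths sum to 100 exactly up
    to floating point.
    """
    if any(l.record_count is None for l in link_set.links):
        raise ValueError("all links need a record_count before strengths can be computed")
    total = sum(l.record_count for l in link_set.links)
    if total <= 0:
        raise ValueError(f"population {link_set.population} has zero total record count")
    links = tuple(l.with_strength(100.0 * l.record_count / total) for l in link_set.links)
    return PopulationLinkSet(
        population=link_set.population, links=links, n_records_retained=link_set.n_records_retained
    )


def build_links(
    records: Iterable[MigrationRecord],
    ranges: RangeSet,
    countries: CountryLayer,
    config: AnalysisConfig = AnalysisConfig(),
) -> tuple[list[PopulationLinkSet], dict[PopulationKey, int]]:
    """Full record -> link pipeline for every population.

    Returns the per-population link sets (observed + inferred, with counts
    and strengths) and the excluded populations with their record counts.
    Populations whose species has no nonbreeding range map get observed
    links only, with a logged warning.
    """
    retained, excluded = filter_populations(records, config.min_records_per_population)
    link_sets = derive_observed_links(retained)
    caches: dict[str, _SpeciesGeometry | None] = {}
    out = []
    for ls in link_sets:
        species = ls.population.species_id
        if species not in caches:
            rng = ranges.nonbreeding(species)
            if rng is None:
                log.warning("species %s has no nonbreeding range; skipping inference", species)
                caches[species] = None
            else:
                caches[species] = _SpeciesGeometry(rng, countries)
        cache = caches[species]
        links = list(ls.links)
        if cache is not None:
            inferred = infer_links(ls, None, countries, _cache=cache)
            for l in inferred:
                links.append(l.with_count(interpolate_record_count(l, ls, None, countries, _cache=cache)))
        full = PopulationLinkSet(population=ls.population, links=tuple(links), n_records_retained=ls.n_records_retained)
        out.append(compute_strengths(full))
    return out, excluded


def all_links(link_sets: Iterable[PopulationLinkSet]) -> list[MigratoryLink]:
    """Flatten link sets into one deterministic link list."""
    links = [l for ls in link_sets for l in ls.links]
    links.sort(key=lambda l: (l.species_id, l.breeding_country, l.nonbreeding_country))
    return links
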