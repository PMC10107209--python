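"""Knowledge gaps and priorities for future tracking.

A species is *present* in a European country when the population table
holds a positive breeding population there, and in an African country
when its nonbreeding range overlaps the country with positive area. It
counts as *tracked* for a country when any migratory link (observed or
inferred) touches that country. The gap metric is the percentage of
present species that are untracked.

Priorities target species with decreasing European populations: for each
such species and each subregion, untracked countries are added greedily
in descending population-share (Europe) or range-share (Africa) order
until the cumulative share of countries with tracking reaches the
coverage threshold (default 50% of the subregional population).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import pandas as pd

from . import geometry as geo
from .types import (
    AnalysisConfig,
    CountryLayer,
    GapEntry,
    PopulationTable,
    PriorityCombo,
    RangeSet,
)

log = logging.getLogger(__name__)


def species_presence(
    country: str,
    group: str,
    pop_table: PopulationTable,
    ranges: RangeSet,
    countries: CountryLayer,
    species_groups: Mapping[str, str],
) -> list[str]:
    """Species of a group present in one country.

    European countries use the population table (pop_size > 0); African
    countries use positive-area overlap of the nonbreeding range (a
    boundary touch does not count).
    """
    present = []
    if countries[country].continent == "Europe":
        for species in pop_table.species_ids():
            if species_groups.get(species) != group:
                continue
            entry = pop_table.get(species, country)
            if entry is not None and entry.pop_size > 0:
                present.append(species)
    else:
        geom = countries.geometry(country)
        for species in ranges.species_ids():
            if species_groups.get(species) != group:
                continue
            rng = ranges.nonbreeding(species)
            if rng is None:
                continue
            if geo.equal_area_km2(rng.intersection(geom)) > 0:
                present.append(species)
    return sorted(present)


def tracked_species(links: pd.DataFrame, country: str, countries: CountryLayer) -> set[str]:
    """Species with any link (observed or inferred) touching the country."""
    col = "breeding_country" if countries[country].continent == "Europe" else "nonbreeding_country"
    return set(links.loc[links[col] == country, "species_id"])


def gap_percentage(
    country: str,
    group: str,
    presence: Iterable[str],
    links: pd.DataFrame,
    countries: CountryLayer,
) -> GapEntry | None:
    """Gap entry for one country and group; ``None`` (with a warning) when
    no species of the group is present."""
    present = sorted(set(presence))
    if not present:
        log.warning("no %s species present in %s; gap entry omitted", group, country)
        return None
    tracked = tracked_species(links, country, countries) & set(present)
    return GapEntry(
        country=country,
        species_group=group,
        n_species_present=len(present),
        n_species_tracked=len(tracked),
    )


def select_priority_countries(
    species_id: str,
    subregion: str,
    shares: Mapping[str, float],
    tracked_countries: Iterable[str],
    threshold_pct: float = 50.0,
) -> list[PriorityCombo]:
    """Greedy selection of priority countries within one subregion.

    ``shares`` maps each country of the subregion to the species' share of
    the subregional population (or range) there. Coverage starts from the
    summed shares of already-tracked countries; if below the threshold,
    untracked countries are added largest-share first (ties by country
    code) until coverage reaches the threshold or countries run out.
    """
    tracked = set(tracked_countries)
    coverage = float(sum(shares.get(c, 0.0) for c in tracked if c in shares))
    if coverage >= threshold_pct:
        return []
    combos = []
    candidates = sorted(
        (c for c in shares if c not in tracked), key=lambda c: (-shares[c], c)
    )
    for c in candidates:
        if coverage >= threshold_pct:
            break
        before = coverage
        coverage = coverage + shares[c]
        combos.append(
            PriorityCombo(
                species_id=species_id,
                subregion=subregion,
                country=c,
                share_pct=shares[c],
                coverage_before=before,
                coverage_after=coverage,
            )
        )
    return combos


def subregional_shares(
    species_id: str,
    subregion: str,
    countries: CountryLayer,
    pop_table: PopulationTable,
    ranges: RangeSet,
) -> dict[str, float]:
    """Share of the species' subregional population (Europe, from the
    population table) or subregional nonbreeding range (Africa, by
    equal-area overlap) held by each country of the subregion."""
    codes = countries.codes(subregion=subregion)
    if not codes:
        return {}
    continent = countries[codes[0]].continent
    shares: dict[str, float] = {}
    if continent == "Europe":
        entries = {
            e.country: e.pop_size
            for e in pop_table.entries_for(species_id)
            if e.country in set(codes) and e.pop_size > 0
        }
        total = sum(entries.values())
        if total <= 0:
            return {}
        shares = {c: 100.0 * s / total for c, s in entries.items()}
    else:
        rng = ranges.nonbreeding(species_id)
        if rng is None:
            return {}
        areas = {}
        for c in codes:
            a = geo.equal_area_km2(rng.intersection(countries.geometry(c)))
            if a > 0:
                areas[c] = a
        total = sum(areas.values())
        if total <= 0:
            return {}
        shares = {c: 100.0 * a / total for c, a in areas.items()}
    return shares


def priority_atlas(
    links: pd.DataFrame,
    pop_table: PopulationTable,
    ranges: RangeSet,
    countries: CountryLayer,
    species_groups: Mapping[str, str],
    config: AnalysisConfig = AnalysisConfig(),
) -> tuple[list[PriorityCombo], pd.DataFrame]:
    """Priority species-country combinations across the whole flyway.

    Runs the greedy selector for every species with a decreasing European
    trend, in every subregion of both continents where the species occurs.
    Combinations are deduplicated: a country appears at most once per
    species (the first subregional run that selects it keeps it). Returns
    the combo list and per-country counts of priority species by group.
    """
    decreasing = [s for s in pop_table.species_ids() if pop_table.trend(s) == "decreasing"]
    combos: list[PriorityCombo] = []
    seen: set[tuple[str, str]] = set()
    subregion_list = [
        (cont, sub) for cont in ("Europe", "Africa") for sub in countries.subregions(cont)
    ]
    for species in decreasing:
        for _, subregion in subregion_list:
            shares = subregional_shares(species, subregion, countries, pop_table, ranges)
            if not shares:
                continue
            codes = set(countries.codes(subregion=subregion))
            col = (
                "breeding_country"
                if countries[next(iter(codes))].continent == "Europe"
                else "nonbreeding_country"
            )
            tracked = set(
                links.loc[links["species_id"] == species, col]
            ) & codes
            for combo in select_priority_countries(
                species, subregion, shares, tracked, config.coverage_threshold_pct
            ):
                key = (species, combo.country)
                if key in seen:
                    continue
                seen.add(key)
                combos.append(combo)
    rows = []
    for c in countries:
        n_by_group = {"landbird": 0, "raptor": 0}
        for combo in combos:
            if combo.country == c.code:
                g = species_groups.get(combo.species_id)
                if g in n_by_group:
                    n_by_group[g] += 1
        for group, n in n_by_group.items():
            rows.append(
                {
                    "country": c.code,
                    "continent": c.continent,
                    "species_group": group,
                    "n_priority_species": n,
                }
            )
    counts = pd.DataFrame(rows).sort_values(["country", "species_group"]).reset_index(drop=True)
    return combos, counts


def gaps_frame(
    links: pd.DataFrame,
    pop_table: PopulationTable,
    ranges: RangeSet,
    countries: CountryLayer,
    species_groups: Mapping[str, str],
) -> pd.DataFrame:
    """Gap table (country, group, present, tracked, gap_pct) for all
    countries and both groups, omitting empty country/group pairs."""
    rows = []
    for c in countries:
        for group in ("landbird", "raptor"):
            present = species_presence(c.code, group, pop_table, ranges, countries, species_groups)
            entry = gap_percentage(c.code, group, present, links, countries)
            if entry is None:
                continue
            rows.append(
                {
                    "country": entry.country,
                    "species_group": entry.species_group,
                    "n_species_present": entry.n_species_present,
                    "n_species_tracked": entry.n_species_tracked,
                    "gap_pct": entry.gap_pct,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["country", "species_group", "n_species_present", "n_species_tracked", "gap_pct"],
    )


def priorities_frame(combos: Iterable[PriorityCombo]) -> pd.DataFrame:
    rows = [
        {
            "species_id": c.species_id,
            "subregion": c.subregion,
            "country": c.country,
            "share_pct": c.share_pct,
            "coverage_before": c.coverage_before,
            "coverage_after": c.coverage_after,
        }
        for c in combos
    ]
    return pd.DataFrame(
        rows,
        columns=["species_id", "subregion", "country", "share_pct", "coverage_before", "coverage_after"],
    )
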