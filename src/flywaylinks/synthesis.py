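"""Country-, species- and flyway-level syntheses of the link table.

Everything here is a deterministic aggregation of the link table plus the
population table and range maps: per-country connectivity summaries,
per-species importance of each African nonbreeding country, flyway-wide
link/species counts, cumulative knowledge trends over time, and a
saturating fit of links gained against tracking effort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import geometry as geo
from .links import all_links
from .types import (
    CountryLayer,
    MigrationRecord,
    MigratoryLink,
    PopulationLinkSet,
    PopulationTable,
    RangeSet,
)

log = logging.getLogger(__name__)


def links_frame(
    link_sets: Iterable[PopulationLinkSet], species_groups: Mapping[str, str]
) -> pd.DataFrame:
    """Flatten link sets into the canonical link table (one row per link)."""
    rows = [
        {
            "species_id": l.species_id,
            "species_group": species_groups[l.species_id],
            "breeding_country": l.breeding_country,
            "nonbreeding_country": l.nonbreeding_country,
            "status": l.status,
            "record_count": l.record_count,
            "strength_pct": l.strength_pct,
        }
        for l in all_links(link_sets)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "species_id",
            "species_group",
            "breeding_country",
            "nonbreeding_country",
            "status",
            "record_count",
            "strength_pct",
        ],
    )


def european_population_share(
    pop_table: PopulationTable,
    species_id: str,
    country: str,
    scope: str = "european",
    countries: CountryLayer | None = None,
) -> float:
    """Percent of a species' European (or subregional) population breeding
    in one country: 100 x pop_size(country) / total pop_size over the scope.

    ``scope="subregional"`` restricts the total to the subregion of
    ``country`` and requires the country layer for the subregion lookup.
    """
    entries = pop_table.entries_for(species_id)
    if not entries:
        raise ValueError(f"species {species_id!r} absent from the population table")
    if scope == "subregional":
        if countries is None:
            raise ValueError("subregional scope needs the country layer")
        subregion = countries[country].subregion
        entries = [e for e in entries if countries[e.country].subregion == subregion]
    elif scope != "european":
        raise ValueError(f"unknown scope {scope!r}")
    total = sum(e.pop_size for e in entries)
    if total <= 0:
        raise ValueError(f"zero total population for species {species_id!r} in scope {scope!r}")
    entry = pop_table.get(species_id, country)
    size = entry.pop_size if entry is not None else 0.0
    return 100.0 * size / total


def range_share(
    ranges: RangeSet,
    countries: CountryLayer,
    species_id: str,
    african_country: str,
    scope: str = "sub-Saharan",
) -> float:
    """Percent of a species' sub-Saharan (or subregional) nonbreeding range
    falling in one African country, by equal-area measurement."""
    rng = ranges.nonbreeding(species_id)
    if rng is None:
        raise ValueError(f"species {species_id!r} has no nonbreeding range")
    if scope == "sub-Saharan":
        scope_codes = countries.african_codes()
    elif scope == "subregional":
        scope_codes = countries.codes(subregion=countries[african_country].subregion)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    total = sum(geo.equal_area_km2(rng.intersection(countries.geometry(c))) for c in scope_codes)
    if total <= 0:
        raise ValueError(
            f"nonbreeding range of {species_id!r} does not intersect scope {scope!r}"
        )
    part = geo.equal_area_km2(rng.intersection(countries.geometry(african_country)))
    return 100.0 * part / total


@dataclass(frozen=True)
class CountrySummary:
    """Connectivity summary for one country and species group."""

    country: str
    continent: str
    species_group: str
    n_links: int
    n_species_tracked: int
    n_partner_countries: int
    links: tuple[MigratoryLink, ...]  # ordered by descending strength


def _touching(df: pd.DataFrame, country: str, continent: str) -> pd.DataFrame:
    col = "breeding_country" if continent == "Europe" else "nonbreeding_country"
    return df[df[col] == country]


def country_connectivity(
    links: pd.DataFrame, country: str, countries: CountryLayer
) -> list[CountrySummary]:
    """Per-group connectivity summary for one country.

    Links are ordered by descending strength, then partner country code.
    A country with no links yields summaries with zero counts.
    """
    continent = countries[country].continent
    partner_col = "nonbreeding_country" if continent == "Europe" else "breeding_country"
    sub = _touching(links, country, continent)
    out = []
    for group in ("landbird", "raptor"):
        g = sub[sub["species_group"] == group]
        ordered = g.sort_values(
            ["strength_pct", partner_col], ascending=[False, True], kind="mergesort"
        )
        link_objs = tuple(
            MigratoryLink(
                species_id=r.species_id,
                breeding_country=r.breeding_country,
                nonbreeding_country=r.nonbreeding_country,
                status=r.status,
                record_count=r.record_count,
                strength_pct=r.strength_pct,
            )
            for r in ordered.itertuples(index=False)
        )
        out.append(
            CountrySummary(
                country=country,
                continent=continent,
                species_group=group,
                n_links=len(g),
                n_species_tracked=g["species_id"].nunique(),
                n_partner_countries=g[partner_col].nunique(),
                links=link_objs,
            )
        )
    return out


@dataclass(frozen=True)
class SpeciesImportance:
    species_id: str
    african_country: str
    importance_pct: float


def species_importance(
    link_sets: Iterable[PopulationLinkSet],
    pop_table: PopulationTable,
    species_id: str,
) -> list[SpeciesImportance]:
    """Importance of each African country for a species' European population.

    Each tracked population contributes strength/100 x (its share of the
    species' European population) to every nonbreeding country it links
    to; contributions are summed per African country. Untracked
    populations contribute nothing, so the importances sum to the share of
    the European population that is tracked at all.
    """
    totals: dict[str, float] = {}
    for ls in link_sets:
        if ls.population.species_id != species_id:
            continue
        share = european_population_share(pop_table, species_id, ls.population.breeding_country)
        for l in ls.links:
            totals[l.nonbreeding_country] = (
                totals.get(l.nonbreeding_country, 0.0) + l.strength_pct / 100.0 * share
            )
    return [
        SpeciesImportance(species_id=species_id, african_country=c, importance_pct=v)
        for c, v in sorted(totals.items())
    ]


def flyway_counts(links: pd.DataFrame, countries: CountryLayer) -> pd.DataFrame:
    """Per-country (n_links, n_species_tracked), per species group and
    overall — the table behind flyway-scale connectivity maps."""
    rows = []
    for c in countries:
        sub = _touching(links, c.code, c.continent)
        for group in ("landbird", "raptor", "all"):
            g = sub if group == "all" else sub[sub["species_group"] == group]
            rows.append(
                {
                    "country": c.code,
                    "continent": c.continent,
                    "species_group": group,
                    "n_links": len(g),
                    "n_species_tracked": g["species_id"].nunique(),
                }
            )
    return pd.DataFrame(rows).sort_values(["country", "species_group"]).reset_index(drop=True)


def cumulative_trends(
    records: Sequence[MigrationRecord], link_sets: Iterable[PopulationLinkSet]
) -> pd.DataFrame:
    """Cumulative number of studies and links per year.

    A link is dated by the earliest year among the studies contributing
    records to its population (inferred links carry no records of their
    own but were revealed by those same studies). Studies without a year
    are excluded with a warning, as are links dated only by such studies.
    """
    study_year: dict[str, int] = {}
    undated_studies: set[str] = set()
    for r in records:
        if r.year_published is None:
            undated_studies.add(r.study_id)
        else:
            y = study_year.get(r.study_id)
            study_year[r.study_id] = r.year_published if y is None else min(y, r.year_published)
    undated_studies -= set(study_year)
    if undated_studies:
        log.warning("excluding %d study(ies) without a publication year", len(undated_studies))

    pop_year: dict[tuple[str, str], int] = {}
    for r in records:
        y = study_year.get(r.study_id)
        if y is None:
            continue
        key = (r.species_id, r.breeding_country)
        pop_year[key] = y if key not in pop_year else min(pop_year[key], y)

    link_years = []
    n_undated_links = 0
    for ls in link_sets:
        y = pop_year.get(tuple(ls.population))
        if y is None:
            n_undated_links += len(ls.links)
            continue
        link_years.extend([y] * len(ls.links))
    if n_undated_links:
        log.warning("excluding %d link(s) with no dated contributing study", n_undated_links)

    years = sorted(set(study_year.values()) | set(link_years))
    sy = np.array(sorted(study_year.values()))
    ly = np.array(sorted(link_years))
    rows = [
        {
            "year": y,
            "cumulative_studies": int(np.searchsorted(sy, y, side="right")),
            "cumulative_links": int(np.searchsorted(ly, y, side="right")),
        }
        for y in years
    ]
    return pd.DataFrame(rows, columns=["year", "cumulative_studies", "cumulative_links"])


@dataclass(frozen=True)
class EffortCurveFit:
    """Saturating (Michaelis-Menten) fit of links against records per
    population: links = a*n/(b+n). ``a`` is the asymptotic number of links,
    ``b`` the effort at which half of them are found."""

    asymptote: float
    half_saturation: float
    rss: float
    reached_95pct_asymptote: bool

    def predict(self, n: np.ndarray) -> np.ndarray:
        n = np.asarray(n, dtype=float)
        return self.asymptote * n / (self.half_saturation + n)


def fit_effort_curve(pairs: Sequence[tuple[float, float]]) -> EffortCurveFit:
    """Least-squares saturating fit of (records per population, links) pairs.

    Also reports whether the curve reaches 95% of its asymptote within the
    observed effort range (it does iff max(n) >= 19*b).
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 populations to fit the effort curve")
    n = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(n) == 0:
        raise ValueError("degenerate data: no variation in records per population")

    def mm(x, a, b):
        return a * x / (b + x)

    p0 = (max(y.max(), 1.0), max(np.median(n), 1.0))
    popt, _ = curve_fit(mm, n, y, p0=p0, bounds=([1e-9, 1e-9], [np.inf, np.inf]), maxfev=20000)
    a, b = float(popt[0]), float(popt[1])
    rss = float(np.sum((y - mm(n, a, b)) ** 2))
    return EffortCurveFit(
        asymptote=a,
        half_saturation=b,
        rss=rss,
        reached_95pct_asymptote=bool(n.max() >= 19.0 * b),
    )
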