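"""Domain types shared by all pipeline stages.

The unit of raw input is the *migration record*: one tracked individual,
already classified to a European breeding country and the sub-Saharan
country where it spent most of the nonbreeding season. Records aggregate
into *populations* (one species in one breeding country) and populations
project onto *migratory links* (population -> nonbreeding country edges)
whose strength is the percentage of the population's individuals assigned
to that nonbreeding country.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, NamedTuple

from shapely.geometry.base import BaseGeometry

SPECIES_GROUPS = ("landbird", "raptor")
DEVICES = ("GLS", "PTT", "GPS")
SEASONS = ("breeding", "nonbreeding", "resident")
TRENDS = ("decreasing", "other")

EUROPE_SUBREGIONS = ("western Europe", "central Europe", "northern Europe", "eastern Europe")
AFRICA_SUBREGIONS = ("western Africa", "central Africa", "southern Africa", "eastern Africa")

OBSERVED = "observed"
INFERRED = "inferred"


class PopulationKey(NamedTuple):
    """A species breeding in one European country."""

    species_id: str
    breeding_country: str


@dataclass(frozen=True)
class MigrationRecord:
    """One tracked individual's breeding -> nonbreeding country pair.

    ``year_published`` may be ``None`` when the source study carries no
    usable year; such records are kept for link building but excluded
    from the time-trend summaries.
    """

    record_id: str
    species_id: str
    species_group: str
    breeding_country: str
    nonbreeding_country: str
    device: str
    study_id: str
    year_published: int | None

    @property
    def population(self) -> PopulationKey:
        return PopulationKey(self.species_id, self.breeding_country)


@dataclass(frozen=True)
class Country:
    code: str
    name: str
    continent: str
    subregion: str
    geometry: BaseGeometry


class CountryLayer:
    """Country polygons keyed by ISO 3166-1 alpha-3 code, with continent
    and subregion attributes. Codes are the sole country identity used by
    the pipeline; names are display-only."""

    def __init__(self, countries: Iterable[Country]):
        self._countries: dict[str, Country] = {}
        for c in countries:
            if c.code in self._countries:
                raise ValueError(f"duplicate country code {c.code!r}")
            self._countries[c.code] = c

    def __len__(self) -> int:
        return len(self._countries)

    def __iter__(self) -> Iterator[Country]:
        return iter(self._countries.values())

    def __contains__(self, code: str) -> bool:
        return code in self._countries

    def __getitem__(self, code: str) -> Country:
        try:
            return self._countries[code]
        except KeyError:
            raise KeyError(f"unknown country code {code!r}") from None

    def geometry(self, code: str) -> BaseGeometry:
        return self[code].geometry

    def codes(self, continent: str | None = None, subregion: str | None = None) -> list[str]:
        return sorted(
            c.code
            for c in self
            if (continent is None or c.continent == continent)
            and (subregion is None or c.subregion == subregion)
        )

    def european_codes(self) -> list[str]:
        return self.codes(continent="Europe")

    def african_codes(self) -> list[str]:
        return self.codes(continent="Africa")

    def subregions(self, continent: str) -> list[str]:
        return sorted({c.subregion for c in self if c.continent == continent})


@dataclass(frozen=True)
class SpeciesRange:
    """One seasonal range polygon for one species (WGS84 multipolygon)."""

    species_id: str
    season: str
    geometry: BaseGeometry


class RangeSet:
    """Seasonal range layers, at most one geometry per (species, season)."""

    def __init__(self, ranges: Iterable[SpeciesRange]):
        self._ranges: dict[tuple[str, str], SpeciesRange] = {}
        for r in ranges:
            key = (r.species_id, r.season)
            if key in self._ranges:
                raise ValueError(f"duplicate range for species {r.species_id!r}, season {r.season!r}")
            self._ranges[key] = r

    def __len__(self) -> int:
        return len(self._ranges)

    def __iter__(self) -> Iterator[SpeciesRange]:
        return iter(self._ranges.values())

    def get(self, species_id: str, season: str) -> SpeciesRange | None:
        return self._ranges.get((species_id, season))

    def nonbreeding(self, species_id: str) -> BaseGeometry | None:
        r = self.get(species_id, "nonbreeding")
        return None if r is None else r.geometry

    def species_ids(self) -> list[str]:
        return sorted({r.species_id for r in self})


@dataclass(frozen=True)
class PopulationSizeEntry:
    """National breeding population estimate with the species' European trend."""

    species_id: str
    country: str
    pop_size: float
    trend: str


class PopulationTable:
    """Population size entries keyed by (species, country)."""

    def __init__(self, entries: Iterable[PopulationSizeEntry]):
        self._entries: dict[tuple[str, str], PopulationSizeEntry] = {}
        for e in entries:
            key = (e.species_id, e.country)
            if key in self._entries:
                raise ValueError(f"duplicate population entry for {key}")
            self._entries[key] = e
        trends: dict[str, str] = {}
        for e in self._entries.values():
            prev = trends.setdefault(e.species_id, e.trend)
            if prev != e.trend:
                raise ValueError(
                    f"trend must be constant per species; {e.species_id!r} has both "
                    f"{prev!r} and {e.trend!r}"
                )

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[PopulationSizeEntry]:
        return iter(self._entries.values())

    def get(self, species_id: str, country: str) -> PopulationSizeEntry | None:
        return self._entries.get((species_id, country))

    def entries_for(self, species_id: str) -> list[PopulationSizeEntry]:
        return sorted(
            (e for e in self._entries.values() if e.species_id == species_id),
            key=lambda e: e.country,
        )

    def species_ids(self) -> list[str]:
        return sorted({e.species_id for e in self._entries.values()})

    def trend(self, species_id: str) -> str | None:
        for e in self._entries.values():
            if e.species_id == species_id:
                return e.trend
        return None


@dataclass(frozen=True)
class MigratoryLink:
    """A (species, breeding country, nonbreeding country) edge.

    Observed links carry an integer record count >= 1; inferred links carry
    an interpolated, possibly fractional count. ``strength_pct`` is filled
    in once the whole population's counts are known.
    """

    species_id: str
    breeding_country: str
    nonbreeding_country: str
    status: str
    record_count: float | None = None
    strength_pct: float | None = None

    @property
    def population(self) -> PopulationKey:
        return PopulationKey(self.species_id, self.breeding_country)

    def with_count(self, count: float) -> "MigratoryLink":
        return replace(self, record_count=count)

    def with_strength(self, pct: float) -> "MigratoryLink":
        return replace(self, strength_pct=pct)


@dataclass(frozen=True)
class PopulationLinkSet:
    """All migratory links of one population, plus its retained record count."""

    population: PopulationKey
    links: tuple[MigratoryLink, ...]
    n_records_retained: int

    def observed(self) -> tuple[MigratoryLink, ...]:
        return tuple(l for l in self.links if l.status == OBSERVED)

    def inferred(self) -> tuple[MigratoryLink, ...]:
        return tuple(l for l in self.links if l.status == INFERRED)

    def observed_countries(self) -> list[str]:
        return sorted(l.nonbreeding_country for l in self.observed())


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable constants of the analysis.

    ``min_records_per_population`` is the retention filter (populations with
    fewer records are dropped); ``coverage_threshold_pct`` drives the greedy
    priority selection; ``equal_area_crs`` names the projection used for all
    areas and centroids (only the built-in cylindrical equal-area transform,
    ``"cea"``, is supported).
    """

    min_records_per_population: int = 3
    coverage_threshold_pct: float = 50.0
    equal_area_crs: str = "cea"
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.min_records_per_population < 1:
            raise ValueError("min_records_per_population must be >= 1")
        if not (0 < self.coverage_threshold_pct <= 100):
            raise ValueError("coverage_threshold_pct must be in (0, 100]")
        if self.equal_area_crs != "cea":
            raise ValueError(f"unsupported equal_area_crs {self.equal_area_crs!r}")


@dataclass(frozen=True)
class GapEntry:
    """Knowledge-gap summary for one country and species group."""

    country: str
    species_group: str
    n_species_present: int
    n_species_tracked: int

    @property
    def gap_pct(self) -> float:
        return 100.0 * (self.n_species_present - self.n_species_tracked) / self.n_species_present


@dataclass(frozen=True)
class PriorityCombo:
    """One species x country recommendation from the coverage rule."""

    species_id: str
    subregion: str
    country: str
    share_pct: float
    coverage_before: float
    coverage_after: float


@dataclass(frozen=True)
class StudyRegion:
    """The configured study-region country sets: which codes count as
    Europe (excluding Russia) and sub-Saharan Africa, and their subregions."""

    membership: Mapping[str, tuple[str, str]] = field(default_factory=dict)

    def lookup(self, code: str) -> tuple[str, str]:
        try:
            return self.membership[code]
        except KeyError:
            raise KeyError(f"country code {code!r} is not in the configured study region") from None

    def __contains__(self, code: str) -> bool:
        return code in self.membership

    def european(self) -> set[str]:
        return {c for c, (cont, _) in self.membership.items() if cont == "Europe"}

    def african(self) -> set[str]:
        return {c for c, (cont, _) in self.membership.items() if cont == "Africa"}
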