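"""Synthetic flyway generator.

Builds a fully synthetic study system with the statistical structure the
analysis assumes: two rectangular "continents" tessellated into contiguous
countries, species with breeding ranges in the north and contiguous
nonbreeding ranges in the south, log-normal national population sizes,
Dirichlet true connectivity per population, and tracking records sampled
i.i.d. (multinomially) from that truth with realistic effort biases —
including populations drawn with fewer than three records, so the
retention filter is exercised.

Everything is deterministic under the seed: one root seed sequence is
split hierarchically (world / species / records), so redrawing records
never perturbs the geography.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from shapely.geometry import MultiPoint, Point, box
from shapely.ops import unary_union, voronoi_diagram

from . import io as fio
from .links import _SpeciesGeometry, compute_strengths
from .types import (
    OBSERVED,
    AnalysisConfig,
    Country,
    CountryLayer,
    MigrationRecord,
    MigratoryLink,
    PopulationKey,
    PopulationLinkSet,
    PopulationSizeEntry,
    PopulationTable,
    RangeSet,
    SpeciesRange,
    StudyRegion,
)

log = logging.getLogger(__name__)

# Abstract continental rectangles (lon/lat degrees), roughly where Europe
# and sub-Saharan Africa sit so latitudinal area distortion is realistic.
EUROPE_BOX = (-10.0, 36.0, 30.0, 60.0)
AFRICA_BOX = (-15.0, -34.0, 40.0, 12.0)

_EUROPE_QUADRANTS = {
    ("W", "N"): "northern Europe",
    ("E", "N"): "eastern Europe",
    ("W", "S"): "western Europe",
    ("E", "S"): "central Europe",
}
_AFRICA_QUADRANTS = {
    ("W", "N"): "western Africa",
    ("E", "N"): "eastern Africa",
    ("W", "S"): "southern Africa",
    ("E", "S"): "central Africa",
}


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic flyway.

    Defaults emulate the real study system at desk scale: a few dozen
    countries and species (keeping the roughly 3:1 landbird:raptor ratio),
    median national populations of ~10^4 with heavy log-normal spread,
    mean tracked sample sizes of ~8 records per population with real mass
    below 3, stronger tracking effort in western/central Europe, and a
    decreasing-trend fraction of 38/118.
    """

    n_countries_europe: int = 12
    n_countries_africa: int = 16
    n_landbirds: int = 18
    n_raptors: int = 6
    breeding_countries_mean: float = 2.5
    nonbreeding_countries_mean: float = 4.0
    range_hole_prob: float = 0.15
    pop_size_log_mean: float = 9.2
    pop_size_log_sigma: float = 1.5
    dirichlet_concentration: float = 1.0
    tracking_probability: float = 0.5
    sample_size_mean: float = 8.0
    sample_size_dispersion: float = 1.2
    missing_year_prob: float = 0.02
    effort_bias: Mapping[str, float] = field(
        default_factory=lambda: {
            "western Europe": 1.5,
            "central Europe": 1.5,
            "northern Europe": 1.0,
            "eastern Europe": 0.4,
        }
    )
    group_bias: Mapping[str, float] = field(
        default_factory=lambda: {"landbird": 1.0, "raptor": 1.3}
    )
    decreasing_fraction: float = 38.0 / 118.0
    seed: int = 0


@dataclass
class SyntheticWorld:
    """A complete synthetic study system plus its generative truth."""

    params: SimulationParams
    countries: CountryLayer
    region: StudyRegion
    ranges: RangeSet
    pop_table: PopulationTable
    species_groups: dict[str, str]
    truth: dict[PopulationKey, dict[str, float]]
    records: list[MigrationRecord]

    def write(self, out_dir: str | Path, config: AnalysisConfig = AnalysisConfig()) -> dict[str, Path]:
        """Emit the four input files core readers consume, plus the config."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "records": out / "records.csv",
            "countries": out / "countries.geojson",
            "ranges": out / "ranges.geojson",
            "populations": out / "populations.csv",
            "config": out / "config.yaml",
        }
        fio.write_records(self.records, paths["records"])
        fio.write_country_layer(self.countries, paths["countries"])
        fio.write_ranges(self.ranges, paths["ranges"])
        fio.write_population_table(self.pop_table, paths["populations"])
        fio.dump_config(config, self.region, paths["config"])
        return paths


def _tessellate(
    box_coords: tuple[float, float, float, float],
    n: int,
    prefix: str,
    quadrants: Mapping[tuple[str, str], str],
    continent: str,
    rng: np.random.Generator,
) -> list[Country]:
    if n < len(quadrants):
        raise ValueError(f"need at least {len(quadrants)} countries per continent, got {n}")
    x0, y0, x1, y1 = box_coords
    rect = box(x0, y0, x1, y1)
    # margin keeps seed points off the boundary so every cell is 2-D
    mx, my = 0.05 * (x1 - x0), 0.05 * (y1 - y0)
    pts = np.column_stack(
        (rng.uniform(x0 + mx, x1 - mx, n), rng.uniform(y0 + my, y1 - my, n))
    )
    cells = voronoi_diagram(MultiPoint(pts), envelope=rect)
    countries = []
    remaining = [g.intersection(rect) for g in cells.geoms]
    xm, ym = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    for i, (px, py) in enumerate(pts):
        cell = next(g for g in remaining if g.covers(Point(px, py)))
        quad = ("W" if px < xm else "E", "N" if py >= ym else "S")
        code = f"{prefix}{i:02d}"
        countries.append(
            Country(
                code=code,
                name=f"{continent} country {i}",
                continent=continent,
                subregion=quadrants[quad],
                geometry=cell,
            )
        )
    return countries


def generate_world(params: SimulationParams, rng: np.random.Generator | None = None) -> tuple[CountryLayer, StudyRegion]:
    """Tessellate the two continental rectangles into contiguous countries
    (Voronoi cells of seeded points, clipped), assigning subregions by
    quadrant of the seed point."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(params.seed).spawn(3)[0])
    europe = _tessellate(EUROPE_BOX, params.n_countries_europe, "E", _EUROPE_QUADRANTS, "Europe", rng)
    africa = _tessellate(AFRICA_BOX, params.n_countries_africa, "A", _AFRICA_QUADRANTS, "Africa", rng)
    layer = CountryLayer(europe + africa)
    region = StudyRegion({c.code: (c.continent, c.subregion) for c in layer})
    return layer, region


def _contiguous_subset(
    codes: list[str], layer: CountryLayer, k: int, rng: np.random.Generator
) -> list[str]:
    """Grow a contiguous set of k countries by randomized adjacency walk."""
    adj = {
        c: [d for d in codes if d != c and layer.geometry(c).intersects(layer.geometry(d))]
        for c in codes
    }
    seed_country = codes[rng.integers(len(codes))]
    chosen = [seed_country]
    frontier = set(adj[seed_country])
    while len(chosen) < k and frontier:
        nxt = sorted(frontier)[rng.integers(len(frontier))]
        chosen.append(nxt)
        frontier |= set(adj[nxt])
        frontier -= set(chosen)
    return chosen


def generate_species(
    layer: CountryLayer, params: SimulationParams, rng: np.random.Generator | None = None
) -> tuple[RangeSet, PopulationTable, dict[str, str], dict[PopulationKey, dict[str, float]]]:
    """Generate species ranges, national population sizes, trends and the
    true per-population connectivity proportions.

    Breeding ranges are unions of >=1 European countries; nonbreeding
    ranges are unions of contiguous African countries with optional
    "holes" (dropped members) so that link inference has work to do. True
    proportions are Dirichlet draws over the countries the nonbreeding
    range overlaps, so truth support never escapes the range.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(params.seed).spawn(3)[1])
    european = layer.european_codes()
    african = layer.african_codes()
    ranges = []
    entries = []
    groups: dict[str, str] = {}
    truth: dict[PopulationKey, dict[str, float]] = {}
    n_species = params.n_landbirds + params.n_raptors
    for i in range(n_species):
        group = "landbird" if i < params.n_landbirds else "raptor"
        species = f"{'LB' if group == 'landbird' else 'RP'}{i:02d}"
        groups[species] = group
        trend = "decreasing" if rng.random() < params.decreasing_fraction else "other"

        k_b = 1 + rng.poisson(max(params.breeding_countries_mean - 1.0, 0.0))
        k_b = min(k_b, len(european))
        breeding = sorted(rng.choice(european, size=k_b, replace=False).tolist())
        breeding_geom = unary_union([layer.geometry(c) for c in breeding])
        ranges.append(SpeciesRange(species, "breeding", breeding_geom))

        k_n = min(2 + rng.poisson(max(params.nonbreeding_countries_mean - 2.0, 0.0)), len(african))
        nb_countries = _contiguous_subset(african, layer, k_n, rng)
        keep = [nb_countries[0]] + [
            c for c in nb_countries[1:] if rng.random() >= params.range_hole_prob
        ]
        nb_geom = unary_union([layer.geometry(c) for c in sorted(keep)])
        ranges.append(SpeciesRange(species, "nonbreeding", nb_geom))

        for c in breeding:
            size = float(np.round(rng.lognormal(params.pop_size_log_mean, params.pop_size_log_sigma)))
            entries.append(PopulationSizeEntry(species, c, max(size, 1.0), trend))

        support = sorted(keep)
        for c in breeding:
            alpha = np.full(len(support), params.dirichlet_concentration)
            props = rng.dirichlet(alpha)
            truth[PopulationKey(species, c)] = dict(zip(support, props.tolist()))
    return RangeSet(ranges), PopulationTable(entries), groups, truth


def sample_records(
    truth: Mapping[PopulationKey, Mapping[str, float]],
    layer: CountryLayer,
    groups: Mapping[str, str],
    params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> list[MigrationRecord]:
    """Sample tracking records from the true connectivity.

    Each population is tracked with a probability scaled by its subregion
    and group effort bias; tracked populations get a negative-binomial
    number of records (mass below 3 included), each record's nonbreeding
    country drawn i.i.d. from the true proportions. Study ids, years and
    devices are attached synthetically (raptor studies start earlier,
    landbirds are mostly geolocator-tracked).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(params.seed).spawn(3)[2])
    records: list[MigrationRecord] = []
    rid = 0
    r = params.sample_size_dispersion
    p_nb = r / (r + params.sample_size_mean)
    for pop in sorted(truth):
        species, bc = pop
        group = groups[species]
        bias = params.effort_bias.get(layer[bc].subregion, 1.0) * params.group_bias.get(group, 1.0)
        if rng.random() >= min(params.tracking_probability * bias, 1.0):
            continue
        n = int(rng.negative_binomial(r, p_nb))
        if n == 0:
            continue
        support = sorted(truth[pop])
        probs = np.array([truth[pop][c] for c in support])
        counts = rng.multinomial(n, probs)
        dests = [c for c, k in zip(support, counts) for _ in range(k)]
        rng.shuffle(dests)
        n_studies = 1 + n // 8
        year_lo = 1996 if group == "raptor" else 2009
        study_years: list[int | None] = [
            None if rng.random() < params.missing_year_prob else int(rng.integers(year_lo, 2022))
            for _ in range(n_studies)
        ]
        for j, dest in enumerate(dests):
            s = j % n_studies
            device = (
                str(rng.choice(["PTT", "GPS"]))
                if group == "raptor"
                else ("GLS" if rng.random() < 0.8 else "GPS")
            )
            records.append(
                MigrationRecord(
                    record_id=f"r{rid:06d}",
                    species_id=species,
                    species_group=group,
                    breeding_country=bc,
                    nonbreeding_country=dest,
                    device=device,
                    study_id=f"study_{species}_{bc}_{s}",
                    year_published=study_years[s],
                )
            )
            rid += 1
    log.info("sampled %d records from %d populations", len(records), len(truth))
    return records


def simulate(params: SimulationParams) -> SyntheticWorld:
    """World -> species -> truth -> records, all from one root seed."""
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(params.seed).spawn(3)]
    layer, region = generate_world(params, streams[0])
    ranges, pop_table, groups, truth = generate_species(layer, params, streams[1])
    records = sample_records(truth, layer, groups, params, streams[2])
    return SyntheticWorld(
        params=params,
        countries=layer,
        region=region,
        ranges=ranges,
        pop_table=pop_table,
        species_groups=groups,
        truth=truth,
        records=records,
    )


def _link_set_from_counts(pop: PopulationKey, counts: Mapping[str, int]) -> PopulationLinkSet:
    links = tuple(
        MigratoryLink(pop.species_id, pop.breeding_country, dest, OBSERVED, float(k))
        for dest, k in sorted(counts.items())
        if k > 0
    )
    return PopulationLinkSet(pop, links, int(sum(counts.values())))


@dataclass(frozen=True)
class RecoveryReport:
    """Strength-recovery and inference-sensitivity summary.

    ``max_errors[n]`` holds one entry per (replicate, population): the
    maximum absolute difference, in percentage points, between estimated
    and true link strengths over all countries of that population.
    ``support_recall[n]`` holds the matching fraction of true-support
    countries that gained a link (observed or inferred).
    """

    n_values: tuple[int, ...]
    max_errors: dict[int, list[float]]
    support_recall: dict[int, list[float]]

    def median_max_error(self, n: int) -> float:
        return float(np.median(self.max_errors[n]))

    def median_recall(self, n: int) -> float:
        return float(np.median(self.support_recall[n]))


def recovery_experiment(
    params: SimulationParams,
    n_reps: int = 200,
    n_values: Sequence[int] = (3, 20, 500),
    max_populations: int = 12,
) -> RecoveryReport:
    """End-to-end validation of the strength estimator.

    Generates one world with true connectivity, then repeatedly draws n
    records per population (multinomially, which is exactly i.i.d.
    sampling of n individuals), runs the full link engine — observed
    links, hull inference, density interpolation, strengths — and compares
    estimated strengths against the generative truth. Populations beyond
    ``max_populations`` are dropped to keep the experiment cheap; each
    retained (replicate, population) pair is one recovery trial.
    """
    world = simulate(params)
    rng = np.random.default_rng(np.random.SeedSequence(params.seed).spawn(4)[3])
    pops = sorted(world.truth)[:max_populations]
    caches = {
        s: _SpeciesGeometry(world.ranges.nonbreeding(s), world.countries)
        for s in sorted({p.species_id for p in pops})
    }
    from .links import infer_links, interpolate_record_count

    max_errors: dict[int, list[float]] = {n: [] for n in n_values}
    recall: dict[int, list[float]] = {n: [] for n in n_values}
    for n in n_values:
        for _ in range(n_reps):
            for pop in pops:
                support = sorted(world.truth[pop])
                probs = np.array([world.truth[pop][c] for c in support])
                counts = rng.multinomial(n, probs)
                ls = _link_set_from_counts(pop, dict(zip(support, counts.tolist())))
                if ls.n_records_retained == 0:
                    continue
                cache = caches[pop.species_id]
                links = list(ls.links)
                for l in infer_links(ls, None, world.countries, _cache=cache):
                    links.append(
                        l.with_count(interpolate_record_count(l, ls, None, world.countries, _cache=cache))
                    )
                full = compute_strengths(
                    PopulationLinkSet(pop, tuple(links), ls.n_records_retained)
                )
                est = {l.nonbreeding_country: l.strength_pct for l in full.links}
                err = max(
                    abs(est.get(c, 0.0) - 100.0 * world.truth[pop].get(c, 0.0))
                    for c in set(est) | set(support)
                )
                max_errors[n].append(err)
                recall[n].append(
                    sum(1 for c in support if c in est) / len(support)
                )
    return RecoveryReport(tuple(n_values), max_errors, recall)
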