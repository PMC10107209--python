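import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from shapely.geometry import box
from shapely.ops import unary_union

from flywaylinks import geometry as geo
from flywaylinks.links import (
    build_links,
    compute_strengths,
    derive_observed_links,
    filter_populations,
    infer_links,
    interpolate_record_count,
    nonbreeding_centroid,
)
from flywaylinks.simulate import SimulationParams, simulate
from flywaylinks.types import (
    Country,
    CountryLayer,
    MigrationRecord,
    MigratoryLink,
    PopulationKey,
    PopulationLinkSet,
)

from ._oracles import brute_force_inferred, interpolated_count
from .conftest import make_strip_layer


def rec(i, species="LB00", breeding="EA0", dest="AB0"):
    return MigrationRecord(f"r{i}", species, "landbird", breeding, dest, "GLS", "s1", 2015)


class TestFilterPopulations:
    def test_population_below_minimum_excluded(self):
        records = [rec(1), rec(2)]
        retained, excluded = filter_populations(records, min_n=3)
        assert retained == {}
        assert excluded == {PopulationKey("LB00", "EA0"): 2}

    def test_population_at_boundary_retained(self):
        records = [rec(1), rec(2), rec(3)]
        retained, excluded = filter_populations(records, min_n=3)
        assert list(retained) == [PopulationKey("LB00", "EA0")]
        assert excluded == {}

    def test_matches_brute_force_on_random_population_sizes(self):
        rng = np.random.default_rng(42)
        sizes = rng.integers(1, 11, size=40)
        records = []
        i = 0
        for p, n in enumerate(sizes):
            for _ in range(n):
                records.append(rec(i, species=f"LB{p:02d}"))
                i += 1
        retained, excluded = filter_populations(records, min_n=3)
        assert len(retained) == int((sizes >= 3).sum())
        # no record lost or duplicated
        assert sum(len(v) for v in retained.values()) + sum(excluded.values()) == len(records)


class TestObservedLinks:
    def test_direct_count_example(self):
        records = [rec(i, dest="AB0") for i in range(3)] + [rec(i + 3, dest="AC0") for i in range(2)]
        retained, _ = filter_populations(records, 3)
        (ls,) = derive_observed_links(retained)
        counts = {l.nonbreeding_country: l.record_count for l in ls.links}
        assert counts == {"AB0": 3.0, "AC0": 2.0}
        assert ls.n_records_retained == 5

    def test_matches_groupby_oracle_on_synthetic_table(self, default_world):
        records = default_world.records
        retained, _ = filter_populations(records, 3)
        link_sets = derive_observed_links(retained)
        got = Counter(
            (l.species_id, l.breeding_country, l.nonbreeding_country, l.record_count)
            for ls in link_sets
            for l in ls.links
        )
        df = pd.DataFrame(
            [(r.species_id, r.breeding_country, r.nonbreeding_country) for r in records],
            columns=["s", "b", "n"],
        )
        pop_sizes = df.groupby(["s", "b"]).size()
        big = pop_sizes[pop_sizes >= 3].index
        expected = Counter(
            (s, b, n, float(k))
            for (s, b, n), k in df.groupby(["s", "b", "n"]).size().items()
            if (s, b) in set(big)
        )
        assert got == expected

    def test_record_counts_conserved(self, default_world):
        retained, _ = filter_populations(default_world.records, 3)
        for ls in derive_observed_links(retained):
            assert sum(l.record_count for l in ls.links) == ls.n_records_retained


class TestNonbreedingCentroid:
    def test_range_covering_rectangular_country_gives_center(self, strip_layer):
        c = nonbreeding_centroid(box(-5, -5, 10, 10), strip_layer.geometry("AB0"))
        assert c.x == pytest.approx(0.5, abs=1e-9)
        expected_lat = math.degrees(math.asin((math.sin(0) + math.sin(math.radians(1))) / 2))
        assert c.y == pytest.approx(expected_lat, abs=1e-9)

    def test_empty_intersection_gives_none(self, strip_layer):
        assert nonbreeding_centroid(box(50, 50, 51, 51), strip_layer.geometry("AB0")) is None

    def test_two_disjoint_equal_squares_give_midpoint(self):
        country = box(0, 0, 10, 1)
        rng = unary_union([box(0, 0, 1, 1), box(3, 0, 4, 1)])
        c = nonbreeding_centroid(rng, country)
        assert c.x == pytest.approx(2.0, abs=1e-9)  # midpoint of 0.5 and 3.5


def link_set(species, breeding, counts):
    links = tuple(
        MigratoryLink(species, breeding, d, "observed", float(n)) for d, n in sorted(counts.items())
    )
    return PopulationLinkSet(PopulationKey(species, breeding), links, int(sum(counts.values())))


class TestInferLinks:
    def test_country_between_two_observed_is_inferred(self, strip_layer):
        rng = unary_union([strip_layer.geometry(c) for c in ("AB0", "AD0", "AC0", "AX0")])
        ls = link_set("LB00", "EA0", {"AB0": 3, "AC0": 2})
        inferred = infer_links(ls, rng, strip_layer)
        assert [l.nonbreeding_country for l in inferred] == ["AD0"]
        assert all(l.status == "inferred" for l in inferred)

    def test_country_outside_hull_not_inferred(self, strip_layer):
        # AX0 lies east of both observed countries, outside the hull
        rng = unary_union([strip_layer.geometry(c) for c in ("AB0", "AD0", "AC0", "AX0")])
        ls = link_set("LB00", "EA0", {"AB0": 3, "AC0": 2})
        assert "AX0" not in {l.nonbreeding_country for l in infer_links(ls, rng, strip_layer)}

    def test_country_outside_range_not_inferred(self, strip_layer):
        # AD0 sits between the observed countries but holds no range
        rng = unary_union([strip_layer.geometry(c) for c in ("AB0", "AC0")])
        ls = link_set("LB00", "EA0", {"AB0": 3, "AC0": 2})
        assert infer_links(ls, rng, strip_layer) == []

    def test_single_observed_country_infers_nothing(self, strip_layer):
        rng = unary_union([strip_layer.geometry(c) for c in ("AB0", "AD0", "AC0")])
        ls = link_set("LB00", "EA0", {"AB0": 5})
        assert infer_links(ls, rng, strip_layer) == []

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle_on_random_worlds(self, seed):
        params = SimulationParams(
            n_countries_europe=5, n_countries_africa=8, n_landbirds=3, n_raptors=1, seed=seed
        )
        world = simulate(params)
        link_sets, _ = build_links(world.records, world.ranges, world.countries)
        for ls in link_sets:
            rng_geom = world.ranges.nonbreeding(ls.population.species_id)
            got = {l.nonbreeding_country for l in ls.inferred()}
            expected = brute_force_inferred(
                world.countries, rng_geom, set(ls.observed_countries())
            )
            assert got == expected, (seed, ls.population)


class TestInterpolateRecordCount:
    def test_single_neighbour_density_transfer(self, strip_layer):
        # range covers AB0 fully and the western half of AD0
        rng = box(0, 0, 1.5, 1)
        ls = link_set("LB00", "EA0", {"AB0": 4})
        link = MigratoryLink("LB00", "EA0", "AD0", "inferred")
        got = interpolate_record_count(link, ls, rng, strip_layer)
        area_b = geo.equal_area_km2(box(0, 0, 1, 1))
        area_d = geo.equal_area_km2(box(1, 0, 1.5, 1))
        assert got == pytest.approx(4.0 / area_b * area_d, rel=1e-9)

    def test_equal_densities_give_density_times_area(self, strip_layer):
        rng = unary_union([strip_layer.geometry(c) for c in ("AB0", "AD0", "AC0")])
        # AB0 and AC0 hold equal areas, equal counts -> equal densities
        ls = link_set("LB00", "EA0", {"AB0": 6, "AC0": 6})
        link = MigratoryLink("LB00", "EA0", "AD0", "inferred")
        got = interpolate_record_count(link, ls, rng, strip_layer)
        d = 6.0 / geo.equal_area_km2(strip_layer.geometry("AB0").intersection(rng))
        assert got == pytest.approx(d * geo.equal_area_km2(strip_layer.geometry("AD0")), rel=1e-9)

    def test_fallback_to_nearest_centroids_when_no_shared_boundary(self):
        layer = CountryLayer(
            [
                Country("EA0", "e", "Europe", "western Europe", box(0, 50, 2, 52)),
                Country("AB0", "b", "Africa", "western Africa", box(0, 0, 1, 1)),
                Country("AD0", "d", "Africa", "western Africa", box(2, 0, 3, 1)),
                Country("AC0", "c", "Africa", "eastern Africa", box(4, 0, 5, 1)),
            ]
        )
        rng = unary_union([layer.geometry(c) for c in ("AB0", "AD0", "AC0")])
        ls = link_set("LB00", "EA0", {"AB0": 2, "AC0": 8})
        link = MigratoryLink("LB00", "EA0", "AD0", "inferred")
        got = interpolate_record_count(link, ls, rng, layer)
        ab = 2.0 / geo.equal_area_km2(layer.geometry("AB0"))
        ac = 8.0 / geo.equal_area_km2(layer.geometry("AC0"))
        assert got == pytest.approx((ab + ac) / 2 * geo.equal_area_km2(layer.geometry("AD0")), rel=1e-9)

    def test_matches_independent_formula_on_random_worlds(self):
        checked = 0
        for seed in range(8):
            params = SimulationParams(
                n_countries_europe=5, n_countries_africa=8, n_landbirds=3, n_raptors=1,
                seed=100 + seed,
            )
            world = simulate(params)
            link_sets, _ = build_links(world.records, world.ranges, world.countries)
            for ls in link_sets:
                rng_geom = world.ranges.nonbreeding(ls.population.species_id)
                counts = {l.nonbreeding_country: l.record_count for l in ls.observed()}
                for l in ls.inferred():
                    expected = interpolated_count(
                        world.countries, rng_geom, counts, l.nonbreeding_country
                    )
                    assert l.record_count == pytest.approx(expected, rel=1e-9)
                    checked += 1
        assert checked > 10  # the worlds actually produced inferred links


class TestComputeStrengths:
    def test_single_link_population_is_100(self):
        ls = compute_strengths(link_set("LB00", "EA0", {"AB0": 7}))
        assert ls.links[0].strength_pct == pytest.approx(100.0)

    def test_three_records_split_two_to_one(self):
        ls = compute_strengths(link_set("LB00", "EA0", {"AB0": 2, "AC0": 1}))
        by = {l.nonbreeding_country: l.strength_pct for l in ls.links}
        assert by["AB0"] == pytest.approx(200.0 / 3.0)
        assert by["AC0"] == pytest.approx(100.0 / 3.0)
        assert round(by["AB0"]) == 67 and round(by["AC0"]) == 33

    def test_nine_link_population_mean_strength(self):
        counts = {f"A{i:02d}": c for i, c in enumerate([9, 7, 5, 4, 3, 3, 2, 2, 1])}
        ls = compute_strengths(link_set("LB00", "EA0", counts))
        mean = sum(l.strength_pct for l in ls.links) / len(ls.links)
        assert mean == pytest.approx(100.0 / 9.0)
        assert round(mean, 1) == 11.1

    def test_zero_total_is_error(self):
        ls = PopulationLinkSet(
            PopulationKey("LB00", "EA0"),
            (MigratoryLink("LB00", "EA0", "AB0", "observed", 0.0),),
            0,
        )
        with pytest.raises(ValueError, match="zero total"):
            compute_strengths(ls)

    @given(
        counts=st.lists(st.integers(min_value=0, max_value=50), min_size=2, max_size=8).filter(
            lambda c: sum(c) > 0
        ),
        extra=st.integers(min_value=1, max_value=10),
    )
    def test_adding_records_never_decreases_own_strength(self, counts, extra):
        names = [f"A{i:02d}" for i in range(len(counts))]
        base = {n: c for n, c in zip(names, counts) if c > 0}
        before = compute_strengths(link_set("LB00", "EA0", base))
        boosted = dict(base)
        boosted[names[0]] = boosted.get(names[0], 0) + extra
        after = compute_strengths(link_set("LB00", "EA0", boosted))
        s_before = {l.nonbreeding_country: l.strength_pct for l in before.links}.get(names[0], 0.0)
        s_after = {l.nonbreeding_country: l.strength_pct for l in after.links}[names[0]]
        assert s_after >= s_before - 1e-9

    @given(
        counts=st.lists(st.integers(min_value=1, max_value=30), min_size=1, max_size=9)
    )
    def test_strengths_always_sum_to_100(self, counts):
        ls = compute_strengths(
            link_set("LB00", "EA0", {f"A{i:02d}": c for i, c in enumerate(counts)})
        )
        assert sum(l.strength_pct for l in ls.links) == pytest.approx(100.0, abs=1e-6)


class TestBuildLinks:
    def test_pipeline_invariants_on_synthetic_world(self, default_world):
        w = default_world
        link_sets, excluded = build_links(w.records, w.ranges, w.countries)
        n_input = len(w.records)
        n_retained = sum(ls.n_records_retained for ls in link_sets)
        assert n_retained + sum(excluded.values()) == n_input
        for ls in link_sets:
            assert ls.n_records_retained >= 3
            assert sum(l.record_count for l in ls.observed()) == ls.n_records_retained
            assert sum(l.strength_pct for l in ls.links) == pytest.approx(100.0, abs=1e-6)
            obs = {l.nonbreeding_country for l in ls.observed()}
            inf = {l.nonbreeding_country for l in ls.inferred()}
            assert obs.isdisjoint(inf)
            rng_geom = w.ranges.nonbreeding(ls.population.species_id)
            for c in inf:
                assert geo.equal_area_km2(rng_geom.intersection(w.countries.geometry(c))) > 0

    def test_under_sampled_populations_absent_from_output(self, default_world):
        w = default_world
        link_sets, excluded = build_links(w.records, w.ranges, w.countries)
        out_pops = {ls.population for ls in link_sets}
        assert out_pops.isdisjoint(excluded)
        sizes = Counter(r.population for r in w.records)
        for pop, n in sizes.items():
            assert (pop in out_pops) == (n >= 3)
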