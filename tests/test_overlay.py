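"""Co-occurrence, continuity, corridor construction, route attribution."""

import math

import pytest
from shapely.geometry import box

from forestroutes.errors import UnknownEcoregionError
from forestroutes.geometry import (
    EARTH_RADIUS_KM,
    RegionSet,
    SpeciesRange,
    area_km2,
)
from forestroutes.overlay import (
    attribute_routes,
    build_corridors,
    classify_continuity,
    select_cooccurring,
)
from forestroutes.stats import venn_counts
from forestroutes.synthetic import species_ranges


@pytest.fixture()
def two_regions():
    return RegionSet(
        regions={"A": box(-10, -5, -5, 5), "B": box(5, -5, 10, 5)},
        focal=("A", "B"),
    )


def _sp(geom, sid="sp"):
    return SpeciesRange(species_id=sid, order_name="O", geometry=geom)


class TestSelectCooccurring:
    def test_range_covering_both_regions_is_retained(self, two_regions):
        kept = select_cooccurring([_sp(box(-12, -6, 12, 6))], two_regions)
        assert len(kept) == 1

    def test_range_in_one_region_is_dropped(self, two_regions):
        assert select_cooccurring([_sp(box(-9, -4, -6, 4))], two_regions) == []

    def test_zero_area_boundary_contact_is_dropped_at_tau_zero(self, two_regions):
        # touches region B exactly along its western edge: overlap area 0
        edge_toucher = box(-9, -4, 5, 4)
        assert select_cooccurring([_sp(edge_toucher)], two_regions, tau_km2=0.0) == []

    def test_input_order_preserved(self, two_regions):
        sps = [_sp(box(-12, -6, 12, 6), f"s{i}") for i in range(5)]
        assert [r.species_id for r in select_cooccurring(sps, two_regions)] == [
            f"s{i}" for i in range(5)
        ]


class TestClassifyContinuity:
    def test_single_spanning_rectangle_is_continuous(self, two_regions):
        assert classify_continuity(_sp(box(-9, -1, 9, 1)), two_regions) == "continuous"

    def test_far_apart_blobs_are_disjunct_at_epsilon_zero(self, two_regions):
        blobs = box(-9, -1, -6, 1).union(box(6, -1, 9, 1))
        assert classify_continuity(_sp(blobs), two_regions, epsilon_km=0.0) == "disjunct"

    def test_five_km_gap_merges_under_ten_km_epsilon(self):
        # two blobs whose latitude gap is exactly 5 km on the equal-area plane
        gap_deg = math.degrees(math.asin(5.0 / EARTH_RADIUS_KM))
        lower = box(0, -1, 1, 0)
        upper = box(0, gap_deg, 1, 1 + gap_deg)
        regions = RegionSet(regions={"A": lower, "B": upper}, focal=("A", "B"))
        sp = _sp(lower.union(upper))
        assert classify_continuity(sp, regions, epsilon_km=10.0) == "continuous"
        assert classify_continuity(sp, regions, epsilon_km=1.0) == "disjunct"

    def test_single_component_cooccurring_range_always_continuous(self, two_regions):
        for shift in (0.0, 1.0, 2.0):
            geom = box(-9 + shift, -2, 9 + shift, 2)
            sp = _sp(geom)
            assert select_cooccurring([sp], two_regions)
            assert classify_continuity(sp, two_regions, epsilon_km=0.0) == "continuous"


class TestBuildCorridors:
    ECO = {"A": box(0, 0, 2, 1), "B": box(3, 0, 5, 1), "C": box(1, 0, 4, 1)}

    def test_disjoint_union_is_additive(self):
        cs = build_corridors(self.ECO, {"Eastern": {"ecoregions": ["A", "B"]}})
        got = area_km2(cs.corridors["Eastern"])
        want = area_km2(self.ECO["A"]) + area_km2(self.ECO["B"])
        assert got == pytest.approx(want, rel=1e-9)

    def test_unknown_ecoregions_listed_in_error(self):
        with pytest.raises(UnknownEcoregionError) as exc:
            build_corridors(self.ECO, {"Eastern": {"ecoregions": ["A", "Z", "Q"]}})
        assert exc.value.names == ["Q", "Z"]

    def test_overlapping_extra_polygon_gives_union_not_sum(self):
        extra = box(1, 0, 3, 1)  # overlaps ecoregion A on [1,2]x[0,1]
        cs = build_corridors(
            self.ECO, {"Eastern": {"ecoregions": ["A"]}}, {"Eastern": [extra]}
        )
        got = area_km2(cs.corridors["Eastern"])
        union_oracle = area_km2(box(0, 0, 3, 1))
        assert got == pytest.approx(union_oracle, rel=1e-9)
        assert got < area_km2(self.ECO["A"]) + area_km2(extra)


class TestAttributeRoutes:
    def test_single_and_triple_band_overlap(self, world):
        only_e = _sp(box(-61, 6, -44, 9))
        all_three = _sp(box(-61, -9, -44, 9))
        a1 = attribute_routes(only_e, world.corridors)
        a3 = attribute_routes(all_three, world.corridors)
        assert a1.routes == frozenset({"Eastern"})
        assert a3.routes == frozenset({"Eastern", "Central", "Western"})

    def test_tau_threshold_drops_small_overlaps(self, world):
        # tiny toe into Central, broad overlap with Western
        geom = box(-61, -9, -44, -6).union(box(-50, -2.4, -49.9, -2.3))
        small = attribute_routes(_sp(geom), world.corridors, tau_km2=0.0)
        assert small.routes == frozenset({"Central", "Western"})
        thresholded = attribute_routes(_sp(geom), world.corridors, tau_km2=1000.0)
        assert thresholded.routes == frozenset({"Western"})

    def test_tau_monotonicity(self, world, species_small):
        ranges = species_ranges(species_small)
        for tau_lo, tau_hi in [(0.0, 100.0), (100.0, 1e5)]:
            for r in ranges:
                lo = attribute_routes(r, world.corridors, tau_km2=tau_lo).routes
                hi = attribute_routes(r, world.corridors, tau_km2=tau_hi).routes
                assert hi <= lo

    def test_overlap_areas_recorded_for_all_corridors(self, world):
        a = attribute_routes(_sp(box(-61, 6, -44, 9)), world.corridors)
        assert set(a.overlap_areas) == {"Eastern", "Central", "Western"}
        assert a.overlap_areas["Central"] == 0.0


def test_venn_partition_reconciles_with_assignment_count(world, species_small):
    ranges = species_ranges(species_small)
    assignments = [attribute_routes(r, world.corridors) for r in ranges]
    counts = venn_counts(assignments)
    assert sum(counts.values()) == len(assignments)


def test_exact_recovery_on_synthetic_world(world, species_small):
    kept = select_cooccurring(species_ranges(species_small), world.regions)
    assert len(kept) == len(species_small)
    for spec, rng in zip(species_small, species_ranges(species_small)):
        cont = classify_continuity(rng, world.regions, epsilon_km=0.0)
        routes = attribute_routes(rng, world.corridors).routes
        assert routes == spec.true_combo
        assert cont == spec.continuity_truth
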