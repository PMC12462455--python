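import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleoibd.proximity import (
    EXCLUDED,
    GEOGRAPHIC_PROXIMITY,
    MORTUARY_PROXIMITY,
    classify_pairs,
    compare_pair_sets,
    haversine_km,
    pair_values,
)
from paleoibd.segments import Individual, PairIBDSummary


def person(iid, mortuary, region, lat, lon):
    return Individual(id=iid, mortuary_group=mortuary, region=region, lat=lat, lon=lon)


class TestHaversine:
    def test_identical_points(self):
        assert haversine_km(47.0, 102.0, 47.0, 102.0) == 0.0

    def test_one_degree_meridian(self):
        # 1 degree of latitude = pi/180 * R
        expected = math.pi / 180.0 * 6371.0
        assert haversine_km(47.0, 102.0, 48.0, 102.0) == pytest.approx(expected, abs=0.01)
        assert expected == pytest.approx(111.19, abs=0.01)

    def test_antipodal(self):
        assert haversine_km(0.0, 0.0, 0.0, 180.0) == pytest.approx(
            math.pi * 6371.0, abs=0.1
        )

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            haversine_km(91.0, 0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            haversine_km(0.0, 181.0, 0.0, 0.0)

    @settings(max_examples=50, deadline=None)
    @given(
        lat1=st.floats(-89, 89), lon1=st.floats(-179, 179),
        lat2=st.floats(-89, 89), lon2=st.floats(-179, 179),
    )
    def test_symmetry_and_nonnegativity(self, lat1, lon1, lat2, lon2):
        d1 = haversine_km(lat1, lon1, lat2, lon2)
        d2 = haversine_km(lat2, lon2, lat1, lon1)
        assert d1 == pytest.approx(d2, abs=1e-9)
        assert d1 >= 0


class TestClassifyPairs:
    def test_same_mortuary_distant_is_mortuary_proximity(self):
        # same tradition, ~360 km apart, one member in the focal region
        a = person("A", "DSKC", "central", 47.0, 102.0)
        b = person("B", "DSKC", "northern", 50.2, 100.2)
        [pc] = classify_pairs([a, b], focal_region="central")
        assert pc.distance_km > 200
        assert pc.cls == MORTUARY_PROXIMITY

    def test_different_mortuary_same_site_is_geographic_proximity(self):
        a = person("A", "DSKC", "central", 47.0, 102.0)
        b = person("B", "figure", "central", 47.0, 102.0)
        [pc] = classify_pairs([a, b], focal_region="central")
        assert pc.cls == GEOGRAPHIC_PROXIMITY

    def test_same_culture_near_is_excluded(self):
        a = person("A", "DSKC", "central", 47.0, 102.0)
        b = person("B", "DSKC", "central", 48.3, 102.0)  # ~145 km
        [pc] = classify_pairs([a, b], focal_region="central")
        assert pc.distance_km < 200
        assert pc.cls == EXCLUDED

    def test_two_by_two_definition_table(self):
        # exhaustive check of (same_mortuary x same_region) for focal members
        focal = "central"
        near = (47.0, 102.0)
        far = (52.0, 110.0)
        cases = [
            (("DSKC", focal, *near), ("DSKC", focal, *near), EXCLUDED),
            (("DSKC", focal, *near), ("fig", focal, *near), GEOGRAPHIC_PROXIMITY),
            (("DSKC", focal, *near), ("DSKC", "east", *far), MORTUARY_PROXIMITY),
            (("DSKC", focal, *near), ("fig", "east", *far), EXCLUDED),
        ]
        for spec_a, spec_b, expected in cases:
            a = person("A", spec_a[0], spec_a[1], spec_a[2], spec_a[3])
            b = person("B", spec_b[0], spec_b[1], spec_b[2], spec_b[3])
            [pc] = classify_pairs([a, b], focal_region=focal)
            assert pc.cls == expected, (spec_a, spec_b)

    def test_classification_symmetric_in_order(self):
        a = person("A", "DSKC", "central", 47.0, 102.0)
        b = person("B", "DSKC", "northern", 50.2, 100.2)
        [p1] = classify_pairs([a, b], "central")
        [p2] = classify_pairs([b, a], "central")
        assert p1.cls == p2.cls and p1.pair == p2.pair

    def test_missing_coordinates_skipped_with_warning(self):
        a = person("A", "DSKC", "central", 47.0, 102.0)
        b = Individual(id="B", mortuary_group="DSKC", region="central")
        with pytest.warns(UserWarning, match="B"):
            assert classify_pairs([a, b], "central") == []

    def test_threshold_monotonicity(self, rng):
        people = [
            person(f"P{k}", rng.choice(["DSKC", "fig"]), "central",
                   float(rng.uniform(44, 50)), float(rng.uniform(98, 108)))
            for k in range(12)
        ]
        rank = {MORTUARY_PROXIMITY: 0, EXCLUDED: 1, GEOGRAPHIC_PROXIMITY: 2}
        lo = classify_pairs(people, "central", threshold_km=100)
        hi = classify_pairs(people, "central", threshold_km=400)
        for pl, ph in zip(lo, hi):
            # raising the threshold can only move a pair "toward" geographic
            assert rank[ph.cls] >= rank[pl.cls]


class TestComparePairSets:
    def test_identical_multisets(self):
        res = compare_pair_sets([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["p"] == pytest.approx(1.0)

    def test_exact_enumeration_oracle(self):
        res = compare_pair_sets([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res["method"] == "exact"
        assert res["p"] == pytest.approx(0.1)  # 2 of 20 orderings

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            compare_pair_sets([], [1.0])

    def test_exact_vs_asymptotic_agreement(self, rng):
        # tie-free samples of size 10-12: both routes agree within 0.01
        for _ in range(50):
            n_a, n_b = rng.integers(10, 13, size=2)
            a = rng.normal(0, 1, n_a)
            b = rng.normal(0.5, 1, n_b)
            exact = compare_pair_sets(a, b, exact_max_n=12)
            approx = compare_pair_sets(a, b, exact_max_n=0)
            assert exact["method"] == "exact"
            assert approx["method"] == "asymptotic"
            assert abs(exact["p"] - approx["p"]) < 0.01


class TestPairValues:
    def test_zero_pairs_included_by_default(self):
        summaries = {
            ("A", "B"): PairIBDSummary(("A", "B"), 20.0, 15.0, 2),
        }
        pairs = [("A", "B"), ("A", "C")]
        np.testing.assert_allclose(pair_values(summaries, pairs), [20.0, 0.0])
        np.testing.assert_allclose(
            pair_values(summaries, pairs, include_zero=False), [20.0]
        )

    def test_max_measure(self):
        summaries = {("A", "B"): PairIBDSummary(("A", "B"), 20.0, 15.0, 2)}
        np.testing.assert_allclose(
            pair_values(summaries, [("A", "B")], measure="max"), [15.0]
        )
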