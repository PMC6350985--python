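"""Interval algebra against O(n^2) brute-force oracles and partition
invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glibind import (
    classify_gli,
    conservation_bins,
    ctcf_colocalize,
    filter_mouse_intensity,
    percentage,
    within_distance,
)
from glibind.regions import CONSERVATION_BIN_LETTERS, Region
from glibind.simulate import generate_region_sets


def gap(a, b):
    return max(b.start - a.end, a.start - b.end, 0)


def brute_within(a_list, b_list, d):
    return [
        any(r.chrom == s.chrom and gap(r, s) <= d for s in b_list) for r in a_list
    ]


def random_regions(rng, n, chroms=("c1", "c2"), span=100_000, width_max=400):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, span))
        out.append(
            Region(str(rng.choice(chroms)), start, start + int(rng.integers(1, width_max)))
        )
    return out


class TestWithinDistance:
    def test_identical_intervals_flagged_at_zero(self):
        a = [Region("c", 10, 50)]
        assert within_distance(a, a, 0).all()

    def test_boundary_of_the_gap_rule(self):
        a = [Region("c", 0, 100)]
        assert within_distance(a, [Region("c", 350, 400)], 250).all()
        assert not within_distance(a, [Region("c", 351, 400)], 250).any()

    def test_matches_brute_force(self, rng):
        a = random_regions(rng, 300)
        b = random_regions(rng, 300)
        for d in (0, 100, 250):
            np.testing.assert_array_equal(within_distance(a, b, d), brute_within(a, b, d))

    def test_order_independence(self, rng):
        a = random_regions(rng, 100)
        b = random_regions(rng, 100)
        shuffled = list(a)
        rng.shuffle(shuffled)
        flags = dict(zip(map(id, a), within_distance(a, b, 250)))
        flags_shuffled = dict(zip(map(id, shuffled), within_distance(shuffled, b, 250)))
        assert all(flags[k] == flags_shuffled[k] for k in flags)

    @settings(max_examples=50, derandomize=True)
    @given(
        starts=st.lists(st.integers(0, 5_000), min_size=1, max_size=20),
        d1=st.integers(0, 300),
        d2=st.integers(0, 300),
    )
    def test_monotone_in_distance(self, starts, d1, d2):
        lo, hi = sorted((d1, d2))
        a = [Region("c", s, s + 50) for s in starts]
        b = [Region("c", 2_500, 2_600)]
        assert (~within_distance(a, b, lo) | within_distance(a, b, hi)).all()


def brute_clusters(peaks, d):
    """Union-find single linkage over all same-chromosome pairs."""
    parent = list(range(len(peaks)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(peaks)):
        for j in range(i + 1, len(peaks)):
            if peaks[i].chrom == peaks[j].chrom and gap(peaks[i], peaks[j]) <= d:
                parent[find(i)] = find(j)
    clusters = {}
    for i in range(len(peaks)):
        clusters.setdefault(find(i), []).append(i)
    return list(clusters.values())


class TestClassifyGli:
    def test_far_apart_sets_have_no_gis(self):
        g1 = [Region("c", i * 10_000, i * 10_000 + 100) for i in range(5)]
        g2 = [Region("c", i * 10_000 + 5_000, i * 10_000 + 5_100) for i in range(5)]
        part = classify_gli(g1, g2, 250)
        assert part.counts == {"G1": 5, "G2": 5, "GIS": 0}

    def test_identical_sets_are_all_gis(self):
        g1 = [Region("c", i * 10_000, i * 10_000 + 100) for i in range(5)]
        part = classify_gli(g1, list(g1), 250)
        assert part.counts["G1"] == 0 and part.counts["G2"] == 0
        assert part.counts["GIS"] == 5
        assert len(part.gis_members) == 10

    def test_matches_brute_force_union_find(self, rng):
        g1 = random_regions(rng, 150, span=50_000)
        g2 = random_regions(rng, 150, span=50_000)
        part = classify_gli(g1, g2, 250)
        tagged = [(r, "g1") for r in g1] + [(r, "g2") for r in g2]
        expected_gis = []
        expected_only = {"g1": [], "g2": []}
        for members in brute_clusters([t[0] for t in tagged], 250):
            tags = {tagged[i][1] for i in members}
            regions = [tagged[i][0] for i in members]
            if len(tags) == 2:
                expected_gis.append(
                    (regions[0].chrom, min(r.start for r in regions), max(r.end for r in regions))
                )
            else:
                expected_only[tags.pop()].extend(regions)
        assert sorted((r.chrom, r.start, r.end) for r in part.gis) == sorted(expected_gis)
        assert sorted((r.chrom, r.start) for r in part.g1_only) == sorted(
            (r.chrom, r.start) for r in expected_only["g1"]
        )
        assert sorted((r.chrom, r.start) for r in part.g2_only) == sorted(
            (r.chrom, r.start) for r in expected_only["g2"]
        )

    def test_count_conservation(self, rng):
        g1 = random_regions(rng, 100)
        g2 = random_regions(rng, 120)
        part = classify_gli(g1, g2, 250)
        assert len(part.g1_only) + len(part.g2_only) + len(part.gis_members) == 220

    def test_planted_cooccupancy_recovered(self, rng):
        lengths = {"c1": 20_000_000}
        ref, _ = generate_region_sets([], 700, 0.0, lengths, seed=5, width=200, label="g1")
        g2, flags = generate_region_sets(ref, 700, 0.3, lengths, seed=6, width=200, label="g2")
        part = classify_gli(ref, g2, 250)
        fraction = part.counts["GIS"] / (part.counts["GIS"] + part.counts["G1"])
        assert abs(fraction - 0.30) <= 0.03


class TestCtcfColocalize:
    def test_empty_ctcf_gives_empty_sets(self, rng):
        part = classify_gli(random_regions(rng, 20), random_regions(rng, 20), 250)
        coloc = ctcf_colocalize(part, [], 250)
        assert coloc.counts == {"l": 0, "k": 0, "n": 0}

    def test_printed_fraction_arithmetic(self):
        assert percentage(5_304, 10_004) == 53.0

    def test_matches_brute_force(self, rng):
        part = classify_gli(
            random_regions(rng, 100, span=50_000), random_regions(rng, 100, span=50_000), 250
        )
        ctcf = random_regions(rng, 80, span=50_000)
        coloc = ctcf_colocalize(part, ctcf, 250)
        for key, regions in (("l", part.g1_only), ("k", part.g2_only), ("n", part.gis)):
            expected = [r for r, f in zip(regions, brute_within(regions, ctcf, 250)) if f]
            assert getattr(coloc, key) == expected


class TestConservationBins:
    def test_no_human_overlap_populates_mouse_only_bins(self):
        mg1 = [Region("c", 0, 100)]
        mg3 = [Region("c", 10_000, 10_100)]
        bins = conservation_bins([], [], mg1, mg3, 250)
        assert bins.counts == {"p": 1, "q": 1}

    def test_quad_flagged_region_lands_in_one_bin(self):
        shared = [Region("c", 0, 100)]
        bins = conservation_bins(shared, shared, shared, shared, 250)
        assert sum(bins.counts.values()) == 2  # two mouse entries, one bin each
        assert set(bins.counts) == {"z"}

    def test_partition_is_exhaustive_and_disjoint(self, rng):
        mg1 = random_regions(rng, 60, span=30_000)
        mg3 = random_regions(rng, 80, span=30_000)
        bins = conservation_bins(
            random_regions(rng, 50, span=30_000),
            random_regions(rng, 50, span=30_000),
            mg1,
            mg3,
            250,
        )
        assert sum(bins.counts.values()) == len(mg1) + len(mg3)

    def test_matches_brute_force_membership_vectors(self, rng):
        hg1 = random_regions(rng, 40, span=30_000)
        hg2 = random_regions(rng, 40, span=30_000)
        mg1 = random_regions(rng, 40, span=30_000)
        mg3 = random_regions(rng, 40, span=30_000)
        bins = conservation_bins(hg1, hg2, mg1, mg3, 250)
        expected = {}
        for region in mg1 + mg3:
            vec = tuple(
                int(any(region.chrom == s.chrom and gap(region, s) <= 250 for s in group))
                for group in (hg1, hg2, mg1, mg3)
            )
            expected.setdefault(CONSERVATION_BIN_LETTERS[vec], []).append(region)
        assert bins.counts == {k: len(v) for k, v in expected.items()}
        for letter, members in expected.items():
            assert bins.bins[letter] == members


class TestFilterMouseIntensity:
    def test_strict_cutoff_boundary(self):
        regions = [Region("c", i * 1_000, i * 1_000 + 100, score=s)
                   for i, s in enumerate([2.9, 3.0, 3.1])]
        kept = filter_mouse_intensity(regions, 3.0)
        assert [r.score for r in kept] == [3.1]

    def test_published_distribution_retains_over_three_quarters(self, rng):
        scores = rng.normal(5.4, 2.5, 100_000)
        regions = [Region("c", 0, 100, score=float(s)) for s in scores]
        kept = filter_mouse_intensity(regions, 3.0)
        assert len(kept) / len(regions) > 0.75

    def test_minus_infinity_cutoff_is_identity(self):
        regions = [Region("c", 0, 100, score=-5.0), Region("c", 200, 300, score=0.1)]
        assert filter_mouse_intensity(regions, float("-inf")) == regions

    def test_missing_scores_rejected(self):
        with pytest.raises(ValueError):
            filter_mouse_intensity([Region("c", 0, 100)], 3.0)
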