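import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from founderhap.io import GeneticMap, GenotypeRecord, Marker
from founderhap.sharing import (
    delineate_shared_region,
    marker_sharing_status,
    region_sizes,
    sharing_table,
)


def tiny_map(n_markers, variant_after=0):
    """Markers at 1,2,...cM; variant between index variant_after and +1."""
    markers = tuple(Marker(f"M{i}", "1", float(i + 1)) for i in range(n_markers))
    return GeneticMap(markers, "V", variant_after + 1.5)


def carriers(gmap, rows):
    return [
        GenotypeRecord(f"I{i}", f"F{i}", True,
                       tuple((min(a, b), max(a, b)) for a, b in row))
        for i, row in enumerate(rows)
    ]


class TestMarkerSharingStatus:
    def test_overlapping_heterozygotes_share_one_allele(self):
        gmap = tiny_map(1)
        gt = carriers(gmap, [[(150, 152)], [(152, 154)], [(150, 152)]])
        s = marker_sharing_status(gmap, gt, "M0")
        assert s.status == "shared"
        assert s.shared_alleles == frozenset({152})

    def test_disjoint_pairs_discordant(self):
        gmap = tiny_map(1)
        gt = carriers(gmap, [[(150, 152)], [(154, 156)]])
        s = marker_sharing_status(gmap, gt, "M0")
        assert s.status == "discordant"
        assert s.shared_alleles == frozenset()

    def test_identical_homozygotes(self):
        gmap = tiny_map(1)
        gt = carriers(gmap, [[(151, 151)]] * 3)
        s = marker_sharing_status(gmap, gt, "M0")
        assert (s.status, s.shared_alleles) == ("shared", frozenset({151}))

    def test_fewer_than_two_informative_is_uninformative(self):
        gmap = tiny_map(1)
        gt = carriers(gmap, [[(150, 152)], [(0, 0)], [(0, 0)]])
        assert marker_sharing_status(gmap, gt, "M0").status == "uninformative"


class TestDelineation:
    def test_study_pattern(self, gmap, genotypes):
        """Figure-shaped sharing pattern gives the published marker pairs."""
        region = delineate_shared_region(gmap, genotypes)
        statuses = {s.marker: s.status for s in region.per_marker}
        assert statuses["D14S1065"] == "shared"
        assert statuses["D14S258"] == "shared"
        assert statuses["D14S1028"] == "discordant"
        assert region.minimal == ("D14S1047", "D14S270")
        assert (region.maximal_left, region.maximal_right) == ("D14S1028", "D14S983")
        assert region.size_cM_min == pytest.approx(2.13)
        assert region.size_cM_max == pytest.approx(6.54)
        assert region.size_bp_min == 1_920_000
        assert region.size_bp_max == 4_140_000

    def test_all_shared_spans_whole_map_with_open_bounds(self):
        gmap = tiny_map(4, variant_after=1)
        gt = carriers(gmap, [[(1, 2)] * 4, [(2, 3)] * 4])
        region = delineate_shared_region(gmap, gt)
        assert region.minimal == ("M0", "M3")
        assert region.maximal_left is None and region.maximal_right is None
        assert region.open_left and region.open_right
        assert region.size_cM_max == pytest.approx(gmap.span_cM())

    def test_adjacent_discordance_empties_minimal_interval(self):
        gmap = tiny_map(2)
        gt = carriers(gmap, [[(1, 2), (1, 2)], [(3, 4), (3, 4)]])
        region = delineate_shared_region(gmap, gt)
        assert region.minimal is None
        assert region.warning is not None
        assert region.size_cM_min == 0.0

    def test_uninformative_does_not_break_run_nor_anchor_it(self):
        # markers: shared, missing-everywhere, shared | variant | shared
        gmap = tiny_map(4, variant_after=2)
        gt = carriers(gmap, [
            [(1, 1), (0, 0), (1, 1), (1, 1)],
            [(1, 2), (0, 0), (1, 2), (1, 2)],
        ])
        region = delineate_shared_region(gmap, gt)
        assert region.minimal == ("M0", "M3")

    def test_fewer_than_two_carriers_rejected(self):
        gmap = tiny_map(2)
        with pytest.raises(ValueError):
            delineate_shared_region(gmap, carriers(gmap, [[(1, 1), (1, 1)]]))

    def test_region_sizes_degenerate_and_two_marker_cases(self):
        gmap = tiny_map(2)
        gt = carriers(gmap, [[(1, 2), (1, 2)], [(2, 3), (2, 3)]])
        region = delineate_shared_region(gmap, gt)
        # bounds of min and max coincide with the two map markers
        assert region.minimal == ("M0", "M1")
        sizes = region_sizes(region, gmap)
        assert sizes[0] == sizes[1] == pytest.approx(1.0) == pytest.approx(gmap.span_cM())

    def test_sharing_table_lists_every_marker(self, gmap, genotypes):
        text = sharing_table(delineate_shared_region(gmap, genotypes))
        for name in gmap.marker_names:
            assert name in text
        assert "minimal=D14S1047-D14S270" in text


# --------------------------------------------------------------------------
# Exhaustive oracle: enumerate allele series over candidate intervals


def oracle_region(gmap, gts):
    """Independent delineation by explicit haplotype-series enumeration."""
    n = len(gmap.markers)
    alphabet = range(1, 5)

    def interval_shared(i, j):
        for series in itertools.product(alphabet, repeat=j - i + 1):
            if all(
                series[m - i] in g.allele_set(m)
                for g in gts
                for m in range(i, j + 1)
            ):
                return True
        return False

    la = gmap.variant_left_index
    ra = la + 1
    # minimal: widen the interval around the variant while it stays shared
    left = la
    while left - 1 >= 0 and interval_shared(left - 1, ra):
        left -= 1
    right = ra
    while right + 1 < n and interval_shared(la, right + 1):
        right += 1
    minimal = None
    if la >= 0 and ra < n and interval_shared(la, ra):
        minimal = (gmap.markers[left].name, gmap.markers[right].name)
    # maximal: first single-marker discordance on each side
    ml = next((k for k in range(la, -1, -1) if not interval_shared(k, k)), None)
    mr = next((k for k in range(ra, n) if not interval_shared(k, k)), None)
    return (
        minimal,
        gmap.markers[ml].name if ml is not None else None,
        gmap.markers[mr].name if mr is not None else None,
    )


@settings(max_examples=300, deadline=None, derandomize=True)
@given(
    n_markers=st.integers(2, 4),
    variant_after=st.integers(0, 2),
    data=st.data(),
)
def test_delineation_matches_exhaustive_oracle(n_markers, variant_after, data):
    variant_after = min(variant_after, n_markers - 2)
    gmap = tiny_map(n_markers, variant_after)
    n_carriers = data.draw(st.integers(2, 4))
    rows = data.draw(
        st.lists(
            st.lists(st.tuples(st.integers(1, 4), st.integers(1, 4)),
                     min_size=n_markers, max_size=n_markers),
            min_size=n_carriers, max_size=n_carriers,
        )
    )
    gts = carriers(gmap, rows)
    region = delineate_shared_region(gmap, gts)
    assert (region.minimal, region.maximal_left, region.maximal_right) == oracle_region(gmap, gts)


@settings(max_examples=150, deadline=None, derandomize=True)
@given(data=st.data())
def test_adding_a_carrier_only_shrinks_intervals(data):
    """On fully observed genotypes, an extra carrier can only reduce sharing."""
    gmap = tiny_map(4, variant_after=1)
    rows = data.draw(
        st.lists(
            st.lists(st.tuples(st.integers(1, 4), st.integers(1, 4)), min_size=4, max_size=4),
            min_size=3, max_size=4,
        )
    )
    gts = carriers(gmap, rows)
    before = delineate_shared_region(gmap, gts[:-1])
    after = delineate_shared_region(gmap, gts)
    assert after.size_cM_min <= before.size_cM_min
    assert after.size_cM_max <= before.size_cM_max
    # nesting holds for every input
    for r in (before, after):
        if r.minimal is not None:
            assert r.size_cM_min <= r.size_cM_max


@settings(max_examples=100, deadline=None, derandomize=True)
@given(perm=st.permutations(list(range(6))))
def test_carrier_order_invariance(gmap, genotypes, perm):
    base = delineate_shared_region(gmap, genotypes)
    shuffled = delineate_shared_region(gmap, [genotypes[i] for i in perm])
    assert shuffled.minimal == base.minimal
    assert (shuffled.maximal_left, shuffled.maximal_right) == (base.maximal_left, base.maximal_right)
    assert shuffled.per_marker == base.per_marker
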