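import math

import numpy as np
import pytest

from founderhap.age import cM_to_theta
from founderhap.io import GeneticMap, Marker, read_genotypes, read_map
from founderhap.sharing import delineate_shared_region
from founderhap.simulate import (
    SimulationConfig,
    allele_freqs_for_heterozygosity,
    default_allele_freqs,
    family_labels,
    simulate_cohort,
    simulate_minimal_spans,
    write_fixture,
)


def line_map(*cm_positions, variant_cM):
    markers = tuple(Marker(f"M{i}", "1", c, het=0.75) for i, c in enumerate(cm_positions))
    return GeneticMap(markers, "V", variant_cM)


class TestHeterozygosityFreqs:
    def test_mean_het_at_equifrequent_bound(self):
        assert allele_freqs_for_heterozygosity(0.75, 4) == pytest.approx((0.25,) * 4)

    def test_equifrequent_sextet(self):
        f = allele_freqs_for_heterozygosity(1 - 1 / 6, 6)
        assert f == pytest.approx((1 / 6,) * 6)

    def test_low_het_quadratic_solution(self):
        f = allele_freqs_for_heterozygosity(0.63, 4)
        assert f[0] == pytest.approx(0.55)
        assert f[1:] == pytest.approx(((1 - f[0]) / 3,) * 3)
        assert 1 - sum(p * p for p in f) == pytest.approx(0.63, abs=1e-9)

    def test_infeasible_het_names_bound(self):
        with pytest.raises(ValueError, match="1 - 1/k"):
            allele_freqs_for_heterozygosity(0.8, 4)

    @pytest.mark.parametrize("H,k", [(0.63, 4), (0.7, 5), (0.83, 8), (0.4, 2)])
    def test_reproduces_target_het(self, H, k):
        f = allele_freqs_for_heterozygosity(H, k)
        assert sum(f) == pytest.approx(1.0, abs=1e-12)
        assert 1 - sum(p * p for p in f) == pytest.approx(H, abs=1e-9)


class TestSimulateCohort:
    def test_no_meioses_means_full_founder_haplotype(self, gmap):
        cfg = SimulationConfig(map=gmap, generations=0, lineages=4,
                               allele_freqs=default_allele_freqs(gmap), seed=1)
        cohort = simulate_cohort(cfg)
        founder = cohort.founder_haplotype
        for rec, truth in zip(cohort.genotypes, cohort.truth):
            assert all(truth.founder_markers)
            for i, m in enumerate(gmap.markers):
                assert founder[m.name] in rec.allele_set(i)
        region = delineate_shared_region(gmap, cohort.genotypes)
        assert all(s.status == "shared" for s in region.per_marker)

    def test_retention_matches_haldane_closed_form(self):
        """Founder-allele retention ~ (1-theta)^g at a 10 cM marker, g=10."""
        gmap = line_map(0.0, 20.0, variant_cM=10.0)
        cfg = SimulationConfig(map=gmap, generations=10, lineages=10_000,
                               allele_freqs=default_allele_freqs(gmap), seed=7)
        cohort = simulate_cohort(cfg)
        expected = (1 - cM_to_theta(10.0)) ** 10   # 0.90937^10 ~ 0.387
        assert expected == pytest.approx(0.3867, abs=5e-5)
        for side in (0, 1):
            freq = np.mean([t.founder_markers[side] for t in cohort.truth])
            se = math.sqrt(expected * (1 - expected) / 10_000)
            assert abs(freq - expected) < 3 * se

    def test_one_sided_segment_length_is_exponential(self):
        """Mean retained length ~ (1/g)(1-exp(-gD)) Morgans, ~5 cM at g=20."""
        gmap = line_map(0.0, 100.0, variant_cM=50.0)
        cfg = SimulationConfig(map=gmap, generations=20, lineages=5_000,
                               allele_freqs=default_allele_freqs(gmap), seed=8)
        cohort = simulate_cohort(cfg)
        g, D = 20, 0.5
        expected = (1 - math.exp(-g * D)) / g    # Morgans
        for vals in (np.array([t.left_cM for t in cohort.truth]) / 100,
                     np.array([t.right_cM for t in cohort.truth]) / 100):
            se = vals.std(ddof=1) / math.sqrt(len(vals))
            assert abs(vals.mean() - expected) < 3 * se

    def test_population_allele_heterozygosity_converges(self):
        """Sample het of non-founder draws matches the configured H."""
        gmap = line_map(0.0, 300.0, variant_cM=300.0)  # marker 3 Morgans away
        H = 0.7
        freqs = {"M0": (tuple(100 + 2 * i for i in range(6)),
                        allele_freqs_for_heterozygosity(H, 6)),
                 "M1": (tuple(100 + 2 * i for i in range(6)),
                        allele_freqs_for_heterozygosity(H, 6))}
        cfg = SimulationConfig(map=gmap, generations=40, lineages=5_000,
                               allele_freqs=freqs, seed=9)
        cohort = simulate_cohort(cfg)
        # at 3 Morgans and g=40 retention is ~(0.5)^40: both alleles population
        pairs = [(r.alleles[0]) for r, t in zip(cohort.genotypes, cohort.truth)
                 if not t.founder_markers[0]]
        het = np.mean([a != b for a, b in pairs])
        se = math.sqrt(H * (1 - H) / len(pairs))
        assert abs(het - H) < 3 * se

    def test_deterministic_and_lineage_stable(self, gmap, tmp_path):
        freqs = default_allele_freqs(gmap)
        cfg = SimulationConfig(map=gmap, generations=10, lineages=5,
                               allele_freqs=freqs, n_families=5, seed=11)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        assert a.genotypes == b.genotypes and a.truth == b.truth
        pa = write_fixture(a, tmp_path / "a")
        pb = write_fixture(b, tmp_path / "b")
        for key in pa:
            assert pa[key].read_bytes() == pb[key].read_bytes()
        # adding a lineage leaves earlier lineages' draws untouched
        bigger = simulate_cohort(
            SimulationConfig(map=gmap, generations=10, lineages=6,
                             allele_freqs=freqs, n_families=5, seed=11))
        assert bigger.genotypes[:5] == a.genotypes[:5]

    def test_stepwise_mutation_can_break_sharing(self, gmap):
        freqs = default_allele_freqs(gmap)
        base = SimulationConfig(map=gmap, generations=8, lineages=6,
                                allele_freqs=freqs, seed=13)
        mut = SimulationConfig(map=gmap, generations=8, lineages=6,
                               allele_freqs=freqs, mutation_rate=0.4, seed=13)
        r0 = delineate_shared_region(gmap, simulate_cohort(base).genotypes)
        r1 = delineate_shared_region(gmap, simulate_cohort(mut).genotypes)
        assert r1.size_cM_min <= r0.size_cM_min

    def test_config_validation(self, gmap):
        freqs = default_allele_freqs(gmap)
        with pytest.raises(ValueError):
            SimulationConfig(map=gmap, generations=-1, lineages=2, allele_freqs=freqs)
        with pytest.raises(ValueError):
            SimulationConfig(map=gmap, generations=1, lineages=0, allele_freqs=freqs)
        bad = dict(freqs)
        labels, probs = bad["D14S61"]
        bad["D14S61"] = (labels, tuple(p * 0.9 for p in probs))
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(map=gmap, generations=1, lineages=2, allele_freqs=bad)
        with pytest.raises(ValueError, match="outside ladder"):
            SimulationConfig(map=gmap, generations=1, lineages=2, allele_freqs=freqs,
                             founder_haplotype={"D14S61": 9999})


class TestWriteFixture:
    def test_roundtrip_and_family_grouping(self, gmap, tmp_path):
        cfg = SimulationConfig(map=gmap, generations=22, lineages=6,
                               allele_freqs=default_allele_freqs(gmap),
                               n_families=5, seed=42)
        cohort = simulate_cohort(cfg)
        paths = write_fixture(cohort, tmp_path)
        back_map = read_map(paths["map"])
        back = read_genotypes(paths["genotypes"], back_map)
        assert [r.alleles for r in back] == [r.alleles for r in cohort.genotypes]
        assert len(back) == 6
        assert len({r.family_id for r in back}) == 5
        truth_lines = paths["truth"].read_text().splitlines()
        assert len(truth_lines) == 1 + 6  # header + one row per lineage

    def test_family_labels(self):
        assert family_labels(6, 5) == ["FAM1", "FAM2", "FAM3", "FAM4", "FAM5", "FAM1"]
        assert len(set(family_labels(4))) == 4
        with pytest.raises(ValueError):
            family_labels(3, 7)


class TestVectorisedSpans:
    def test_matches_full_pipeline_distribution(self, gmap):
        """Dual route: vectorised span simulator vs cohort+delineation."""
        freqs = default_allele_freqs(gmap)
        rng = np.random.default_rng(21)
        fast = simulate_minimal_spans(gmap, 10, 3, 3000, rng, freqs)
        slow = []
        for seed in range(250):
            cfg = SimulationConfig(map=gmap, generations=10, lineages=3,
                                   allele_freqs=freqs, seed=100 + seed)
            region = delineate_shared_region(gmap, simulate_cohort(cfg).genotypes)
            slow.append(region.size_cM_min)
        slow = np.asarray(slow)
        se = math.sqrt(fast.var() / fast.size + slow.var() / slow.size)
        assert abs(fast.mean() - slow.mean()) < 3 * se

    def test_zero_generations_spans_whole_map(self, gmap):
        rng = np.random.default_rng(5)
        spans = simulate_minimal_spans(gmap, 0, 4, 50, rng)
        assert spans == pytest.approx(np.full(50, gmap.span_cM()))
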