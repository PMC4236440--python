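"""Genotype calling, marker discovery, segregation filtering."""

import math

import pytest

from i2brad import (
    LocusObservation,
    call_sample_genotype,
    chi_square_1_2_1,
    discover_markers,
    genotype_progeny,
    overall_missing_rate,
    segregation_filter,
)
from i2brad.genotyping import (
    MarkerRecord,
    SampleCall,
    TagAnchorIndex,
    anchor_tags,
    collapse_alleles,
)

from conftest import make_tag


def _obs(counts, sample="s", site=0):
    return LocusObservation(sample, site, counts)


class TestCallSampleGenotype:
    def test_below_min_depth_missing(self):
        call = call_sample_genotype(_obs({"A" * 33: 1}))
        assert call.call == "missing" and call.total_depth == 1

    def test_balanced_het(self):
        a, b = "A" * 33, "C" * 33
        call = call_sample_genotype(_obs({a: 10, b: 10}))
        assert call.call == "het" and set(call.alleles) == {a, b}

    def test_rare_second_allele_hom(self):
        a, b = "A" * 33, "C" * 33
        call = call_sample_genotype(_obs({a: 999, b: 1}))  # f ~ 0.001 < 0.010
        assert call.call == "hom" and call.alleles == (a,)

    def test_ambiguous_zone_missing(self):
        # f must land in [0.010, 0.011]: 1 of 96 reads gives f ~ 0.0104
        call = call_sample_genotype(_obs({"A" * 33: 95, "C" * 33: 1}))
        assert call.call == "missing"

    def test_single_allele_hom(self):
        call = call_sample_genotype(_obs({"A" * 33: 7}))
        assert call.call == "hom"

    def test_tie_flagged(self):
        call = call_sample_genotype(_obs({"C" * 33: 5, "A" * 33: 5}))
        assert call.tie_broken
        assert call.alleles[0] == "A" * 33 or call.call == "het"


class TestDiscoverMarkers:
    def _hom(self, allele, site=0):
        return SampleCall(site, "hom", (allele,), 20)

    def test_single_snp_marker(self):
        a = "A" * 33
        b = "A" * 16 + "C" + "A" * 16
        markers, _ = discover_markers({0: self._hom(a)}, {0: self._hom(b)})
        assert len(markers) == 1
        assert markers[0].snp_positions == (16,)

    def test_monomorphic_skipped(self):
        a = "A" * 33
        markers, skipped = discover_markers({0: self._hom(a)}, {0: self._hom(a)})
        assert markers == [] and skipped["monomorphic"] == 1

    def test_three_snps_too_divergent(self):
        a = "A" * 33
        b = "C" * 3 + "A" * 30
        markers, skipped = discover_markers({0: self._hom(a)}, {0: self._hom(b)})
        assert markers == [] and skipped["too_divergent"] == 1

    def test_het_parent_skipped(self):
        a, b = "A" * 33, "C" * 33
        het = SampleCall(0, "het", (a, b), 20)
        markers, skipped = discover_markers({0: het}, {0: self._hom(b)})
        assert markers == [] and skipped["parent_not_hom"] == 1


class TestGenotypeProgeny:
    A = "A" * 33
    B = "A" * 16 + "C" + "A" * 16

    def _marker(self):
        return MarkerRecord(0, self.A, self.B, (16,))

    def test_parental_hom_and_het_mapping(self):
        m = self._marker()
        calls = [
            {0: SampleCall(0, "hom", (self.A,), 9)},
            {0: SampleCall(0, "hom", (self.B,), 9)},
            {0: SampleCall(0, "het", tuple(sorted((self.A, self.B))), 9)},
            {},  # sample absent at the site
        ]
        genotype_progeny([m], calls)
        assert m.progeny_genotypes == ["aa", "bb", "ab", "missing"]
        assert m.missing_rate == 0.25

    def test_foreign_allele_missing(self):
        m = self._marker()
        foreign = "G" * 33
        calls = [
            {0: SampleCall(0, "hom", (foreign,), 9)},
            {0: SampleCall(0, "het", tuple(sorted((self.A, foreign))), 9)},
        ]
        genotype_progeny([m], calls)
        assert m.progeny_genotypes == ["missing", "missing"]


class TestChiSquare:
    def test_perfect_ratio(self):
        stat, p = chi_square_1_2_1(25, 50, 25)
        assert stat == 0.0 and p == 1.0

    def test_worked_example(self):
        # (30-25)^2/25 + (50-50)^2/50 + (20-25)^2/25 = 2.0
        stat, p = chi_square_1_2_1(30, 50, 20)
        assert stat == pytest.approx(2.0)
        assert p == pytest.approx(0.3679, abs=1e-4)

    def test_fully_distorted(self):
        _, p = chi_square_1_2_1(100, 0, 0)
        assert p < 1e-10

    @pytest.mark.parametrize(
        "counts", [(3, 6, 3), (6, 4, 2), (5, 5, 2), (2, 8, 2), (7, 4, 1), (6, 6, 0)]
    )
    def test_asymptotic_close_to_exact_multinomial_tail(self, counts):
        """The chi-square tail tracks the exact multinomial tail at n = 12.

        The exact tail (mid-p, enumerated over all (aa, ab, bb) outcomes
        under (1/4, 1/2, 1/4)) is a step function with jumps up to ~0.07 at
        this sample size, so mid-tail agreement is only within that
        discreteness; in the rejection-relevant region (p < 0.1, where the
        distortion filter makes its decision) the two agree within 0.02.
        """
        n = sum(counts)
        stat_obs, p_asym = chi_square_1_2_1(*counts)
        above = at = 0.0
        for a in range(n + 1):
            for h in range(n - a + 1):
                b = n - a - h
                s = sum(
                    (o - e) ** 2 / e
                    for o, e in zip((a, h, b), (n / 4, n / 2, n / 4))
                )
                prob = (
                    math.comb(n, a)
                    * math.comb(n - a, h)
                    * (0.25**a)
                    * (0.5**h)
                    * (0.25**b)
                )
                if s > stat_obs + 1e-12:
                    above += prob
                elif s >= stat_obs - 1e-12:
                    at += prob
        exact_midp = above + 0.5 * at
        tolerance = 0.02 if p_asym < 0.1 else 0.07
        assert abs(p_asym - exact_midp) < tolerance


class TestSegregationFilter:
    def _marker_with(self, genos):
        m = MarkerRecord(0, "A" * 33, "C" * 33, (0,))
        m.progeny_genotypes = genos
        return m

    def test_perfect_marker_retained(self):
        m = self._marker_with(["aa"] * 25 + ["ab"] * 50 + ["bb"] * 25)
        kept, report = segregation_filter([m])
        assert kept == [m] and report["kept"] == 1
        assert m.chi2_statistic == 0.0

    def test_distorted_dropped(self):
        m = self._marker_with(["aa"] * 100)
        kept, report = segregation_filter([m])
        assert kept == [] and report["dropped_distorted"] == 1

    def test_worked_example_retained(self):
        m = self._marker_with(["aa"] * 30 + ["ab"] * 50 + ["bb"] * 20)
        kept, _ = segregation_filter([m])
        assert kept == [m]
        assert m.chi2_statistic == pytest.approx(2.0)
        assert m.chi2_p == pytest.approx(0.3679, abs=1e-4)

    def test_missing_rate_threshold_is_ge(self):
        genos = ["missing"] * 20 + ["aa"] * 20 + ["ab"] * 40 + ["bb"] * 20
        m = self._marker_with(genos)  # missing rate exactly 0.20
        kept, report = segregation_filter([m])
        assert kept == [] and report["dropped_missing"] == 1

    def test_all_missing_dropped(self):
        m = self._marker_with(["missing"] * 10)
        _, report = segregation_filter([m])
        assert report["dropped_all_missing"] == 1


class TestOverallMissingRate:
    def test_extremes_and_fixture(self):
        def mk(genos):
            m = MarkerRecord(0, "A" * 33, "C" * 33, (0,))
            m.progeny_genotypes = genos
            return m

        assert overall_missing_rate([mk(["aa"] * 4)]) == 0.0
        assert overall_missing_rate([mk(["missing"] * 4)]) == 1.0
        ms = [mk(["aa", "missing", "ab", "bb"]), mk(["aa"] * 4), mk(["missing", "aa", "aa", "aa"])]
        assert overall_missing_rate(ms) == pytest.approx(2 / 12)


class TestAnchoringAndCollapse:
    def test_anchor_exact_and_two_mismatches(self, rng):
        ref = make_tag(rng)
        index = TagAnchorIndex({ref: [0]})
        mutated = "G" + ref[1:32] + ("A" if ref[32] != "A" else "C")
        stacks = anchor_tags({ref: 3, mutated: 2}, index)
        assert stacks[0][ref] == 3 and stacks[0][mutated] == 2

    def test_anchor_rejects_distance_ties_and_multimaps(self, rng):
        ref1 = make_tag(rng)
        ref2 = "C" + ref1[1:] if ref1[0] != "C" else "G" + ref1[1:]
        # query equidistant (1) from ref1 and ref2
        query = ("T" if ref1[0] not in "T" else "G") + ref1[1:]
        stacks = anchor_tags({query: 5}, TagAnchorIndex({ref1: [0], ref2: [1]}))
        assert stacks == {}
        stacks = anchor_tags({ref1: 5}, TagAnchorIndex({ref1: [0, 1]}))
        assert stacks == {}

    def test_collapse_absorbs_singletons(self):
        a = "A" * 33
        err = "A" * 10 + "G" + "A" * 22
        out = collapse_alleles({a: 19, err: 1})
        assert out == {a: 20}

    def test_collapse_keeps_true_het_alleles(self):
        a, b = "A" * 33, "A" * 16 + "C" + "A" * 16
        out = collapse_alleles({a: 10, b: 9})
        assert out == {a: 10, b: 9}

    def test_collapse_drops_orphans(self):
        a = "A" * 33
        far = "C" * 33
        out = collapse_alleles({a: 9, far: 1})
        assert out == {a: 9}
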