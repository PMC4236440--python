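"""Site scanning, tag extraction and canonicalization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from i2brad import (
    ENZYMES,
    canonicalize,
    count_tags,
    extract_tags,
    find_overlapping_tags,
    find_unique_tags,
    get_enzyme,
    reverse_complement,
    scan_sites,
)
from i2brad.enzymes import ConfigurationError, NotATagError, UnsupportedOperationError

from conftest import brute_force_scan, make_tag, quadratic_overlaps, random_sequence


class TestRegistry:
    def test_builtin_enzymes(self):
        assert set(ENZYMES) == {"BsaXI", "AlfI", "EcoRI", "SbfI", "HindIII"}
        bsa = ENZYMES["BsaXI"]
        assert bsa.tag_length == 33
        assert bsa.minus_pattern == reverse_complement(bsa.plus_pattern)
        assert bsa.overhang_length == 3 and bsa.tags_per_site == 1
        for name in ("AlfI", "EcoRI", "SbfI", "HindIII"):
            assert ENZYMES[name].is_self_complementary
        assert ENZYMES["EcoRI"].tags_per_site == 2

    def test_unknown_enzyme(self):
        with pytest.raises(ConfigurationError):
            get_enzyme("DpnII")


class TestScanSites:
    def test_alfi_single_site(self):
        sites = scan_sites({"s": "GCAAAAAAATGC"}, "AlfI")
        assert len(sites) == 1
        assert sites[0].start == 0 and sites[0].orientation == "plus_form"

    def test_empty_genome(self):
        assert scan_sites({}, "BsaXI") == []
        assert scan_sites({"s": ""}, "EcoRI") == []

    def test_n_bases_never_match(self):
        assert scan_sites({"s": "GCANNNNNNTGC"}, "AlfI") == []

    def test_overlapping_occurrences_all_reported(self):
        # plus-form motif instances at offsets 0 and 4 share seven bases
        seq = "ACTTACTCTCCCTCC"
        hits = brute_force_scan(seq, "ACNNNNNCTCC")
        assert hits == [0, 4]
        sites = scan_sites({"s": seq}, "BsaXI")
        plus = [s.start for s in sites if s.orientation == "plus_form"]
        assert plus == hits

    def test_matches_brute_force_oracle(self, rng):
        seq = random_sequence(rng, 100_000)
        sites = scan_sites({"chr1": seq}, "BsaXI")
        expect_plus = brute_force_scan(seq, "ACNNNNNCTCC")
        expect_minus = brute_force_scan(seq, "GGAGNNNNNGT")
        assert [s.start for s in sites if s.orientation == "plus_form"] == expect_plus
        assert [s.start for s in sites if s.orientation == "minus_form"] == expect_minus

    def test_strand_symmetry_under_reverse_complement(self, rng):
        seq = random_sequence(rng, 50_000)
        fwd = scan_sites({"s": seq}, "BsaXI")
        rev = scan_sites({"s": reverse_complement(seq)}, "BsaXI")
        n_plus = sum(s.orientation == "plus_form" for s in fwd)
        n_minus = sum(s.orientation == "minus_form" for s in fwd)
        assert len(fwd) == len(rev)
        assert sum(s.orientation == "plus_form" for s in rev) == n_minus
        assert sum(s.orientation == "minus_form" for s in rev) == n_plus

    def test_site_density_on_random_sequence(self, big_random_genome):
        # two degenerate forms, six fixed bases each: 2 * (1/4)^6 per position
        seq = big_random_genome["chrZ"]
        sites = scan_sites(big_random_genome, "BsaXI")
        n_pos = len(seq) - 10
        expected = 2 * (0.25**6) * n_pos
        sd = math.sqrt(expected)
        assert abs(len(sites) - expected) < 5 * sd


class TestCountTags:
    def test_tags_per_site(self):
        sites = scan_sites({"s": "GAATTC" * 5}, "EcoRI")
        assert len(sites) == 5
        assert count_tags(sites, "EcoRI") == 10
        bsa_sites = [None] * 5
        assert count_tags(bsa_sites, "BsaXI") == 5


class TestExtractTags:
    def test_single_site_full_tag(self, rng):
        seq = random_sequence(rng, 33)
        seq = seq[:12] + "ACGGGGGCTCC" + seq[23:]
        sites = [s for s in scan_sites({"s": seq}, "BsaXI") if s.start == 12]
        tags = extract_tags({"s": seq}, sites, "BsaXI")
        assert len(tags) == 1
        t = tags[0]
        assert (t.tag_start, t.tag_end) == (0, 33) and t.length == 33
        assert t.canonical_sequence == seq

    def test_insufficient_flank_dropped_and_counted(self):
        seq = "AAAAA" + "ACGGGGGCTCC" + "A" * 20
        sites = [s for s in scan_sites({"s": seq}, "BsaXI") if s.start == 5]
        drops = {}
        tags = extract_tags({"s": seq}, sites, "BsaXI", drop_counter=drops)
        assert tags == [] and drops["out_of_bounds"] == 1

    def test_minus_form_geometry_and_canonical(self, rng):
        up = random_sequence(rng, 10)
        down = random_sequence(rng, 12)
        seq = "T" * 7 + up + "GGAGTTTTTGT" + down + "T" * 7
        sites = [
            s
            for s in scan_sites({"s": seq}, "BsaXI")
            if s.orientation == "minus_form" and s.start == 17
        ]
        tags = extract_tags({"s": seq}, sites, "BsaXI")
        assert len(tags) == 1
        t = tags[0]
        assert (t.tag_start, t.tag_end) == (7, 40)
        assert t.canonical_sequence == reverse_complement(t.sequence)
        assert t.canonical_sequence[12:14] == "AC"
        assert t.canonical_sequence[19:23] == "CTCC"

    def test_all_tags_canonical_on_random_genome(self, rng):
        genome = {"c": random_sequence(rng, 200_000)}
        sites = scan_sites(genome, "BsaXI")
        tags = extract_tags(genome, sites, "BsaXI")
        assert tags, "expected background sites in 200 kb"
        for t in tags:
            assert t.length == 33
            assert t.canonical_sequence[12:14] == "AC"
            assert t.canonical_sequence[19:23] == "CTCC"

    def test_unsupported_enzyme(self):
        with pytest.raises(UnsupportedOperationError):
            extract_tags({"s": "A" * 50}, [], "AlfI")


class TestCanonicalize:
    def test_identity_and_involution(self, rng):
        tag = make_tag(rng, "plus")
        assert canonicalize(tag) == tag
        assert canonicalize(reverse_complement(tag)) == tag

    def test_rejects_non_tags(self):
        with pytest.raises(NotATagError):
            canonicalize("A" * 33)
        with pytest.raises(NotATagError):
            canonicalize("ACGT")

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.booleans())
    def test_idempotent_on_either_strand(self, seed, flip):
        r = np.random.default_rng(seed)
        tag = make_tag(r, "minus" if flip else "plus")
        once = canonicalize(tag)
        assert canonicalize(once) == once
        assert once[12:14] == "AC" and once[19:23] == "CTCC"


class TestUniqueness:
    def _planted_genome(self, rng):
        base = random_sequence(rng, 4000)
        tag = make_tag(rng, "plus")
        # plant the identical tag twice and scrub other accidental copies
        seq = base[:500] + tag + base[500:2000] + tag + base[2000:]
        return {"g": seq}, tag

    def test_duplicate_pair_non_unique(self, rng):
        genome, tag = self._planted_genome(rng)
        sites = scan_sites(genome, "BsaXI")
        tags = extract_tags(genome, sites, "BsaXI")
        find_unique_tags(tags)
        dup = [t for t in tags if t.canonical_sequence == tag]
        assert len(dup) >= 2 and all(t.unique is False for t in dup)
        n_unique = sum(1 for t in tags if t.unique)
        counts = {}
        for t in tags:
            counts[t.canonical_sequence] = counts.get(t.canonical_sequence, 0) + 1
        assert n_unique == sum(1 for c in counts.values() if c == 1)

    def test_all_distinct_all_unique(self, rng):
        genome = {"g": random_sequence(rng, 100_000)}
        tags = extract_tags(genome, scan_sites(genome, "BsaXI"), "BsaXI")
        seqs = [t.canonical_sequence for t in tags]
        if len(set(seqs)) == len(seqs):
            find_unique_tags(tags)
            assert all(t.unique for t in tags)

    def test_hamming_mode_and_bounds(self, rng):
        genome, tag = self._planted_genome(rng)
        tags = extract_tags(genome, scan_sites(genome, "BsaXI"), "BsaXI")
        find_unique_tags(tags, max_mismatch=2)
        dup = [t for t in tags if t.canonical_sequence == tag]
        assert all(t.unique is False for t in dup)
        with pytest.raises(ConfigurationError):
            find_unique_tags(tags, max_mismatch=3)


class TestOverlaps:
    def test_far_sites_no_overlap(self, rng):
        tag1, tag2 = make_tag(rng), make_tag(rng)
        genome = {"g": tag1 + "T" * 40 + tag2}
        tags = extract_tags(genome, scan_sites(genome, "BsaXI"), "BsaXI")
        assert find_overlapping_tags(tags) == []

    def test_close_sites_overlap(self, rng):
        # two plus-form motifs 20 bp apart: tags share 13 bp
        s = random_sequence(rng, 80)
        seq = s[:12] + "ACGAGAGCTCC" + s[23:32] + "ACTTTTTCTCC" + s[43:]
        genome = {"g": seq}
        sites = [x for x in scan_sites(genome, "BsaXI") if x.orientation == "plus_form"]
        tags = extract_tags(genome, sites, "BsaXI")
        pairs = find_overlapping_tags(tags)
        assert len(pairs) == 1

    def test_matches_quadratic_oracle(self, rng):
        genome = {"g": random_sequence(rng, 300_000)}
        tags = extract_tags(genome, scan_sites(genome, "BsaXI"), "BsaXI")
        got = {
            tuple(sorted((tags.index(a), tags.index(b))))
            for a, b in find_overlapping_tags(tags)
        }
        expected = quadratic_overlaps(
            [(t.site.sequence_id, t.tag_start, t.tag_end) for t in tags]
        )
        assert got == expected
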