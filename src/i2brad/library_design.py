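"""Sequencing-library construct model: adapters, barcodes, primers.

The pooled 2b-RAD library sandwiches the 33-nt excised tag between two
adapters. Adapter 1 carries a 5-9 nt inline sample barcode and the arm of
the Illumina multiplexing PCR primer 1.0; adapter 2 carries the arm of the
indexed PCR primer. A single-end 50-bp read therefore starts with the
barcode, covers the whole tag, and runs through into adapter 2. This module
stores the construct sequences, validates and designs barcode sets against
the published criteria, and does the amplicon/overhang arithmetic.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import edlib

from .enzymes import (
    ConfigurationError,
    ENZYMES,
    EnzymeSpec,
    get_enzyme,
)

__all__ = [
    "LibraryDesign",
    "BarcodeSet",
    "BarcodeReport",
    "DEFAULT_DESIGN",
    "validate_barcode_set",
    "design_barcodes",
    "amplicon_length",
    "overhang_fraction",
    "enumerate_overhangs",
    "construct_read",
]

# Construct sequences as printed in the library protocol.
ADAPTER1_COMMON = "ACACTCTTTCCCTACACGACGCTCTTCCGATCT"
ADAPTER2_TOP = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"
PRIMER1_0 = "AATGATACGGCGACCACCGAGATCTACACTCTTTCCCTACACGACGCTCTTCCGATCT"
INDEX_PRIMER_TEMPLATE = (
    "CAAGCAGAAGACGGCATACGAGATXXXXXXGTGACTGGAGTTCAGACGTGTGCTCTTCCGATCT"
)

BARCODE_LENGTH_RANGE = (5, 9)


@dataclass(frozen=True)
class LibraryDesign:
    """The fixed sequences and geometry of the pooled 2b-RAD construct."""

    adapter1_common: str = ADAPTER1_COMMON
    adapter2_top: str = ADAPTER2_TOP
    primer1_0: str = PRIMER1_0
    index_primer_template: str = INDEX_PRIMER_TEMPLATE
    overhang_spec: str = "NNN"
    enzyme: EnzymeSpec = ENZYMES["BsaXI"]

    def __post_init__(self) -> None:
        if not self.primer1_0.endswith(self.adapter1_common):
            raise ConfigurationError(
                "primer 1.0 must end with the adapter-1 common arm"
            )

    @property
    def tag_length(self) -> int:
        return self.enzyme.tag_length


DEFAULT_DESIGN = LibraryDesign()


@dataclass
class BarcodeSet:
    """Labelled inline barcodes, 5-9 nt each."""

    barcodes: list[tuple[str, str]]  # (sample label, sequence)

    def sequences(self) -> list[str]:
        return [seq for _, seq in self.barcodes]

    def __len__(self) -> int:
        return len(self.barcodes)


@dataclass
class BarcodeReport:
    passed: bool
    bad_length: list[str] = field(default_factory=list)
    close_pairs: list[tuple[str, str, int]] = field(default_factory=list)
    prefix_pairs: list[tuple[str, str]] = field(default_factory=list)
    site_creating: list[str] = field(default_factory=list)


def _levenshtein(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


def _fixed_match_positions(text: str, motif: str, offset: int) -> bool:
    """Motif match where motif N matches anything but a fixed base must hit a
    concrete equal base in the text (text N or placeholder never satisfies a
    fixed motif position)."""
    for i, c in enumerate(motif):
        if c == "N":
            continue
        if text[offset + i] != c:
            return False
    return True


def _creates_site(context: str, enzyme: EnzymeSpec) -> bool:
    motifs = [enzyme.plus_pattern]
    if enzyme.minus_pattern is not None:
        motifs.append(enzyme.minus_pattern)
    for motif in motifs:
        for off in range(len(context) - len(motif) + 1):
            if _fixed_match_positions(context, motif, off):
                return True
    return False


def _ligated_contexts(
    barcode: str, design: LibraryDesign
) -> Iterable[str]:
    """All resolutions of adapter + barcode + overhang + insert placeholder.

    The overhang bases are unknown at design time (they come from the
    genomic fragment), so criterion 3 — "must not recreate a recognition
    site after ligation" — is checked over every concrete completion of the
    degenerate overhang, with the insert itself left as N placeholders.
    """
    k = design.enzyme.overhang_length
    tail = "N" * design.tag_length
    for combo in itertools.product("ACGT", repeat=k):
        yield design.adapter1_common + barcode + "".join(combo) + tail


def validate_barcode_set(
    barcode_set: BarcodeSet, design: LibraryDesign = DEFAULT_DESIGN
) -> BarcodeReport:
    """Check a barcode set against the published design criteria.

    (1) lengths 5-9 nt; (2) every pair at least 2 edits apart (Levenshtein,
    so the criterion is well defined across unequal lengths); (3) no barcode
    contains or can recreate a recognition site in its ligated context, for
    any completion of the degenerate overhang. Prefix-freeness is enforced
    on top of these so that inline demultiplexing has unambiguous
    boundaries.
    """
    if not barcode_set.barcodes:
        raise ConfigurationError("empty barcode set")
    lo, hi = BARCODE_LENGTH_RANGE
    report = BarcodeReport(passed=True)
    seqs = barcode_set.sequences()
    for s in seqs:
        if not (lo <= len(s) <= hi):
            report.bad_length.append(s)
    for a, b in itertools.combinations(seqs, 2):
        d = _levenshtein(a, b)
        if d < 2:
            report.close_pairs.append((a, b, d))
    for a, b in itertools.permutations(seqs, 2):
        if b.startswith(a):
            report.prefix_pairs.append((a, b))
    for s in seqs:
        if any(_creates_site(ctx, design.enzyme) for ctx in _ligated_contexts(s, design)):
            report.site_creating.append(s)
    report.passed = not (
        report.bad_length
        or report.close_pairs
        or report.prefix_pairs
        or report.site_creating
    )
    return report


def _barcode_ok_alone(seq: str, design: LibraryDesign) -> bool:
    return not any(
        _creates_site(ctx, design.enzyme) for ctx in _ligated_contexts(seq, design)
    )


def _imbalance(seqs: Sequence[str], candidate: str) -> float:
    """Per-position base-composition imbalance of the set plus candidate.

    For each read position covered by any barcode, imbalance is the range of
    base frequencies; summed across positions. Lower is more colour-balanced
    on the sequencer.
    """
    pool = list(seqs) + [candidate]
    max_len = max(len(s) for s in pool)
    total = 0.0
    for pos in range(max_len):
        counts = {b: 0 for b in "ACGT"}
        n = 0
        for s in pool:
            if pos < len(s):
                counts[s[pos]] += 1
                n += 1
        if n:
            freqs = [c / n for c in counts.values()]
            total += max(freqs) - min(freqs)
    return total


class BarcodeInfeasibleError(RuntimeError):
    """The requested barcode set cannot be built under the constraints."""


def design_barcodes(
    n: int,
    lengths: Iterable[int] = range(5, 10),
    design: LibraryDesign = DEFAULT_DESIGN,
    seed: int = 0,
    candidates_per_step: int = 64,
) -> BarcodeSet:
    """Greedy seeded design of ``n`` mutually compatible inline barcodes.

    Lengths are drawn round-robin from ``lengths`` so the set spans the 5-9
    nt range (staggered lengths de-phase the constant recognition bases on
    the flowcell). At each step a pool of random candidates is filtered
    against all constraints and the survivor minimizing per-position
    base-composition imbalance of the set so far is kept. Deterministic for
    a fixed seed.
    """
    lengths = sorted(set(lengths))
    lo, hi = BARCODE_LENGTH_RANGE
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    if not lengths or not all(lo <= L <= hi for L in lengths):
        raise ConfigurationError(f"lengths must be within [{lo}, {hi}]")
    # Singleton-ball packing bound on Hamming distance >= 2 codes of one
    # length: at most 4^(L-1) codewords, summed over the allowed lengths.
    capacity = sum(4 ** (L - 1) for L in lengths)
    if n > capacity:
        raise BarcodeInfeasibleError(
            f"distance-2 packing bound: at most {capacity} barcodes of "
            f"lengths {lengths} exist, {n} requested"
        )
    rng = random.Random(seed)
    chosen: list[str] = []
    budget = 200 * n * max(1, candidates_per_step)
    attempts = 0
    length_cycle = itertools.cycle(lengths)
    while len(chosen) < n:
        L = next(length_cycle)
        pool: list[str] = []
        while len(pool) < candidates_per_step and attempts < budget:
            attempts += 1
            cand = "".join(rng.choice("ACGT") for _ in range(L))
            if not _barcode_ok_alone(cand, design):
                continue
            if any(_levenshtein(cand, c) < 2 for c in chosen):
                continue
            if any(cand.startswith(c) or c.startswith(cand) for c in chosen):
                continue
            pool.append(cand)
        if not pool:
            raise BarcodeInfeasibleError(
                f"no valid length-{L} barcode found after {attempts} attempts "
                f"with {len(chosen)} already chosen (distance/prefix/site "
                "constraints binding)"
            )
        best = min(pool, key=lambda c: (_imbalance(chosen, c), c))
        chosen.append(best)
    bset = BarcodeSet([(f"bc{str(i + 1).zfill(2)}", s) for i, s in enumerate(chosen)])
    report = validate_barcode_set(bset, design)
    assert report.passed, "designer produced an invalid set"
    return bset


def amplicon_length(design: LibraryDesign, barcode: str) -> int:
    """Final PCR amplicon length for one barcode, from the printed sequences.

    primer 1.0 (58 nt) + barcode (5-9 nt) + tag (33 nt) + index primer
    (64 nt): 160 bp for the shortest barcode, 164 bp for the longest.
    """
    lo, hi = BARCODE_LENGTH_RANGE
    if not (lo <= len(barcode) <= hi):
        raise ConfigurationError(f"barcode length must be in [{lo}, {hi}]")
    return (
        len(design.primer1_0)
        + len(barcode)
        + design.tag_length
        + len(design.index_primer_template)
    )


def _end_matches(overhang: str, spec: str) -> bool:
    for o, s in zip(overhang, spec):
        if s == "N":
            continue
        fixed = s if s in "ACGT" else "A"  # symbolic fixed base: any one of 4
        if o != fixed:
            return False
    return True


def overhang_fraction(
    overhang_spec: str, enzyme: EnzymeSpec | str
) -> Fraction:
    """Fraction of fragments targeted by adapters with a constrained overhang.

    Both ends of the excised fragment carry an overhang of the enzyme's
    length; an adapter whose overhang fixes ``k`` bases per end ligates only
    the matching fraction. Computed by exhaustive enumeration of all
    4^(2L) ordered overhang pairs: NNF on a 3-nt BsaXI overhang targets
    1/16 (4^4/4^6) of sites, NF on a 2-nt AlfI overhang also 1/16 (4^2/4^4).
    Spec symbols: ``N`` degenerate, any other letter a fixed base.
    """
    if isinstance(enzyme, str):
        enzyme = get_enzyme(enzyme)
    L = enzyme.overhang_length
    if len(overhang_spec) != L:
        raise ConfigurationError(
            f"overhang spec length {len(overhang_spec)} != enzyme overhang {L}"
        )
    hits = 0
    total = 0
    for end1 in itertools.product("ACGT", repeat=L):
        for end2 in itertools.product("ACGT", repeat=L):
            total += 1
            if _end_matches("".join(end1), overhang_spec) and _end_matches(
                "".join(end2), overhang_spec
            ):
                hits += 1
    return Fraction(hits, total)


def enumerate_overhangs(enzyme: EnzymeSpec | str) -> list[str]:
    """All distinct single-end overhang sequences (4^L, e.g. 64 for BsaXI)."""
    if isinstance(enzyme, str):
        enzyme = get_enzyme(enzyme)
    if enzyme.overhang_length < 1:
        raise ConfigurationError("enzyme has no overhang")
    return [
        "".join(c) for c in itertools.product("ACGT", repeat=enzyme.overhang_length)
    ]


def construct_read(
    design: LibraryDesign,
    barcode: str,
    tag: str,
    read_length: int = 50,
) -> str:
    """Sequencer-visible read: barcode + tag + adapter-2 read-through.

    The insert (barcode + 33-nt tag) is shorter than the read for every
    barcode length, so the read always runs into adapter 2: 12 nt of
    read-through with a 5-nt barcode, 8 nt with a 9-nt barcode. The caller
    chooses which strand of the tag to pass (a locus is sequenced from
    either end of the fragment with equal probability in practice).
    """
    if len(tag) != design.tag_length:
        raise ConfigurationError(
            f"tag must be {design.tag_length} nt, got {len(tag)}"
        )
    if read_length < len(barcode) + 1:
        raise ConfigurationError("read_length too short to cover the barcode")
    full = barcode + tag + design.adapter2_top
    return full[:read_length]
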