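"""Two-step read filter: inline-barcode demultiplexing and tag matching.

Raw single-end 50-bp reads begin with a 5-9 nt sample barcode followed by
the 33-nt excised tag and adapter read-through. Step 1 assigns each read to
a sample by its barcode, allowing one mismatch, and trims the barcode.
Step 2 keeps a trimmed read only if its first 33 bases contain no N and
match one of the two positional fragment forms (AC at offset 12 + CTCC at
19, or GGAG at 10 + GT at 19 for the opposite strand); survivors are
canonicalized so both sequencing strands of a locus collapse to one tag.
Everything else is counted with a reason. Quality scores play no role.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO

from .enzymes import ConfigurationError, canonicalize, reverse_complement

__all__ = [
    "SampleSheet",
    "FilterStats",
    "DemuxResult",
    "match_barcode",
    "match_tag",
    "demux_fastq",
    "demux_reads",
    "classify_rejected",
    "read_fastq",
    "write_sample_tags",
]

TAG_LENGTH = 33


@dataclass
class SampleSheet:
    """Maps (library, barcode) to sample id; one sheet may span libraries."""

    rows: list[tuple[str, str, str]]  # (library, barcode, sample id)

    def __post_init__(self) -> None:
        seen_samples = set()
        per_lib: dict[str, set[str]] = {}
        for lib, bc, sample in self.rows:
            if bc in per_lib.setdefault(lib, set()):
                raise ConfigurationError(
                    f"barcode {bc} duplicated within library {lib}"
                )
            per_lib[lib].add(bc)
            if sample in seen_samples:
                raise ConfigurationError(f"duplicate sample id {sample}")
            seen_samples.add(sample)

    def library(self, lib: str) -> dict[str, str]:
        """barcode -> sample id for one library."""
        out = {bc: sample for l, bc, sample in self.rows if l == lib}
        if not out:
            raise ConfigurationError(f"unknown library {lib!r}")
        return out

    def libraries(self) -> list[str]:
        seen: list[str] = []
        for lib, _, _ in self.rows:
            if lib not in seen:
                seen.append(lib)
        return seen

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        rows = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            lib, bc, sample = line.split("\t")
            rows.append((lib, bc.upper(), sample))
        return cls(rows)


@dataclass
class FilterStats:
    """Per-stage read accounting for one demultiplexing run.

    Conservation invariants: ``total_reads = barcode_matched +
    rejected_barcode`` and ``barcode_matched = high_quality +
    rejected_site_or_N``.
    """

    total_reads: int = 0
    barcode_matched: int = 0
    high_quality: int = 0
    rejected_barcode: int = 0
    rejected_site_or_N: int = 0
    barcode_reject_reasons: Counter = field(default_factory=Counter)
    tag_reject_reasons: Counter = field(default_factory=Counter)
    per_sample_assigned: Counter = field(default_factory=Counter)
    per_sample_high_quality: Counter = field(default_factory=Counter)

    @property
    def evenness_ratio(self) -> float:
        """Max over min per-sample high-quality read count (>= 1)."""
        counts = [c for c in self.per_sample_high_quality.values() if c > 0]
        if not counts:
            return float("nan")
        return max(counts) / min(counts)

    def to_dict(self) -> dict:
        d = {
            "total_reads": self.total_reads,
            "barcode_matched": self.barcode_matched,
            "high_quality": self.high_quality,
            "rejected_barcode": self.rejected_barcode,
            "rejected_site_or_N": self.rejected_site_or_N,
            "barcode_reject_reasons": dict(self.barcode_reject_reasons),
            "tag_reject_reasons": dict(self.tag_reject_reasons),
            "per_sample_assigned": dict(self.per_sample_assigned),
            "per_sample_high_quality": dict(self.per_sample_high_quality),
        }
        ev = self.evenness_ratio
        d["evenness_ratio"] = None if ev != ev else ev
        return d


@dataclass
class DemuxResult:
    """Canonical tag multisets per sample plus the filter accounting."""

    sample_tags: dict[str, Counter]
    stats: FilterStats
    rejected_reads: list[str] = field(default_factory=list)


def match_barcode(
    read: str, barcodes: Mapping[str, str]
) -> tuple[str, int] | tuple[None, str]:
    """Assign a read to a sample by its inline barcode prefix.

    An exact prefix match wins (longest barcode first, though a validated
    prefix-free set can only match one); otherwise the unique barcode at
    Hamming distance 1 over its own length wins. Zero or two or more
    candidates at the best tier leave the read unassigned. A barcode is only
    tested if the read retains at least a full tag after trimming it.

    Returns ``(sample_id, barcode_length)`` or ``(None, reason)`` with
    reason in ``{"too_short", "no_match", "ambiguous"}``.
    """
    usable = [bc for bc in barcodes if len(read) >= len(bc) + TAG_LENGTH]
    if not usable:
        return None, "too_short"
    usable.sort(key=len, reverse=True)
    for bc in usable:
        if read.startswith(bc):
            return barcodes[bc], len(bc)
    near = []
    for bc in usable:
        prefix = read[: len(bc)]
        mismatches = sum(a != b for a, b in zip(prefix, bc))
        if mismatches == 1:
            near.append(bc)
    if len(near) == 1:
        return barcodes[near[0]], len(near[0])
    return None, ("no_match" if not near else "ambiguous")


def match_tag(trimmed_read: str) -> tuple[str, None] | tuple[None, str]:
    """Accept or reject a barcode-trimmed read and canonicalize its tag.

    The first 33 bases must contain no N and match either positional
    fragment form; bases beyond 33 (adapter read-through) are discarded.
    Returns ``(canonical_tag, None)`` or ``(None, reason)`` with reason in
    ``{"too_short", "has_N", "no_site"}``.
    """
    if len(trimmed_read) < TAG_LENGTH:
        return None, "too_short"
    tag = trimmed_read[:TAG_LENGTH]
    if "N" in tag:
        return None, "has_N"
    try:
        return canonicalize(tag), None
    except ValueError:
        return None, "no_site"


def demux_reads(
    reads: Iterable[str],
    barcodes: Mapping[str, str],
    *,
    keep_rejected: bool = False,
) -> DemuxResult:
    """Run the two-step filter over an iterable of read sequences.

    ``barcodes`` maps barcode -> sample id for one library. Deterministic
    for a fixed input order. Set ``keep_rejected`` to retain the reads that
    matched a barcode but failed the tag filter (for downstream
    classification against a genome).
    """
    stats = FilterStats()
    sample_tags: dict[str, Counter] = {s: Counter() for s in barcodes.values()}
    rejected: list[str] = []
    for read in reads:
        read = read.upper()
        stats.total_reads += 1
        sample, info = match_barcode(read, barcodes)
        if sample is None:
            stats.rejected_barcode += 1
            stats.barcode_reject_reasons[info] += 1
            continue
        stats.barcode_matched += 1
        stats.per_sample_assigned[sample] += 1
        tag, reason = match_tag(read[info:])
        if tag is None:
            stats.rejected_site_or_N += 1
            stats.tag_reject_reasons[reason] += 1
            if keep_rejected:
                rejected.append(read[info:])
            continue
        stats.high_quality += 1
        stats.per_sample_high_quality[sample] += 1
        sample_tags[sample][tag] += 1
    return DemuxResult(sample_tags, stats, rejected)


def read_fastq(path: str | Path) -> Iterator[str]:
    """Read sequences from a (optionally gzipped) FASTQ file."""
    path = Path(path)
    if path.suffix == ".gz":
        import gzip

        with gzip.open(path, "rt") as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                yield str(rec.seq)
    else:
        with open(path) as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                yield str(rec.seq)


def demux_fastq(
    fastq: str | Path,
    sheet: SampleSheet,
    library: str | None = None,
    *,
    keep_rejected: bool = False,
) -> DemuxResult:
    """Demultiplex one library's FASTQ against its rows of the sample sheet."""
    libs = sheet.libraries()
    if library is None:
        if len(libs) != 1:
            raise ConfigurationError(
                "sheet spans several libraries; pass library explicitly"
            )
        library = libs[0]
    return demux_reads(
        read_fastq(fastq), sheet.library(library), keep_rejected=keep_rejected
    )


def write_sample_tags(result: DemuxResult, outdir: str | Path) -> list[Path]:
    """Write each sample's canonical tags as FASTA with counts in headers."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for sample, tags in sorted(result.sample_tags.items()):
        path = outdir / f"{sample}.tags.fa"
        with open(path, "w") as fh:
            for i, (tag, count) in enumerate(sorted(tags.items()), 1):
                fh.write(f">{sample}_tag{i} count={count}\n{tag}\n")
        paths.append(path)
    return paths


def classify_rejected(
    rejected_reads: Sequence[str], genome: Mapping[str, str]
) -> dict:
    """Fraction of tag-filter rejects whose first 33 bases occur in the genome.

    A rejected read whose leading 33-mer is found verbatim on either strand
    is consistent with a between-site fragment (genomic DNA carried through
    size selection without a recognition site) rather than sequencing noise.
    Exact substring lookup only.
    """
    kmers: set[str] = set()
    for seq in genome.values():
        seq = seq.upper()
        for strand in (seq, reverse_complement(seq)):
            for i in range(len(strand) - TAG_LENGTH + 1):
                kmers.add(strand[i : i + TAG_LENGTH])
    hits = sum(
        1
        for r in rejected_reads
        if len(r) >= TAG_LENGTH and r[:TAG_LENGTH].upper() in kmers
    )
    n = len(rejected_reads)
    return {
        "rejected": n,
        "genome_matched": hits,
        "fraction": hits / n if n else 0.0,
    }
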