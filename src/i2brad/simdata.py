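"""Synthetic 2b-RAD experiment generator with machine-readable truth.

Emulates the F2 mapping design end to end: a random genome carrying
planted (or natural-density) BsaXI sites, two homozygous parents differing
by one or two substitutions inside tag footprints, an F2 population
segregating 1:2:1, and barcoded single-end 50-bp reads with Poisson
per-site depth, substitution errors, a random sequencing strand per read,
adapter read-through and a configurable admixture of between-site
contaminant fragments. Every random choice is recorded in a truth set so
downstream filters, coverage accounting and genotype calls can be scored
exactly.

Defaults mirror the rice study design: 277 progeny in 12-plex libraries,
per-site depth near 10, a per-base error rate of 1e-3, and roughly a
quarter of barcode-matched reads being between-site fragments that survive
size selection. All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .enzymes import (
    ENZYMES,
    ConfigurationError,
    RecognitionSite,
    TagRecord,
    extract_tags,
    reverse_complement,
    scan_sites,
)
from .demux import SampleSheet
from .library_design import (
    DEFAULT_DESIGN,
    BarcodeSet,
    LibraryDesign,
    construct_read,
    design_barcodes,
)

__all__ = ["SimConfig", "TruthSet", "SimulatedExperiment",
           "generate_genome", "generate_parents", "generate_f2",
           "simulate_reads", "simulate_experiment"]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Knobs of the synthetic experiment; defaults follow the study design."""

    seed: int = 0
    chromosome_lengths: tuple[int, ...] = (100_000,)
    n_planted_sites: int | None = 200  # None -> natural motif density only
    snp_rate: float = 0.8  # per-tag probability that parent B differs
    n_progeny: int = 277
    read_depth: float = 10.0  # Poisson lambda per site per sample
    error_rate: float = 0.001  # per-base substitution probability
    contaminant_fraction: float = 0.25  # of reads, between-site fragments
    strand_flip_probability: float = 0.5
    read_length: int = 50
    parent_replicates: int = 1
    recombination: str = "none"  # or "poisson"
    map_length_morgans: float = 2.0  # per chromosome, poisson mode

    def __post_init__(self) -> None:
        for name in ("snp_rate", "error_rate", "contaminant_fraction",
                     "strand_flip_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.read_depth < 0:
            raise ConfigurationError("read_depth must be >= 0")
        if any(L < 100 for L in self.chromosome_lengths):
            raise ConfigurationError("chromosome lengths must be >= 100")


@dataclass
class ReadTruth:
    read_id: str
    sample_id: str
    site_id: int | None  # None for contaminants
    strand: str  # "plus" or "minus"
    n_errors: int
    contaminant: bool


@dataclass
class TruthSet:
    """Ground truth of one simulated experiment."""

    sites: list[RecognitionSite]
    tags: list[TagRecord]  # in-bounds reference tags; index = site id
    snps: list[tuple[str, int, str, str]]  # (chrom, pos, ref base, alt base)
    marker_site_ids: list[int]
    parent_alleles: dict[int, tuple[str, str]]  # site id -> (allele A, allele B)
    progeny_genotypes: np.ndarray  # (n_markers, n_progeny) of {0,1,2} B dosage
    reads: list[ReadTruth] = field(default_factory=list)

    def genotype_symbol(self, marker_idx: int, progeny_idx: int) -> str:
        return ("aa", "ab", "bb")[self.progeny_genotypes[marker_idx, progeny_idx]]


@dataclass
class SimulatedExperiment:
    config: SimConfig
    genome: dict[str, str]
    parent_a: dict[str, str]
    parent_b: dict[str, str]
    sheet: SampleSheet
    barcode_set: BarcodeSet
    libraries: dict[str, list[tuple[str, str]]]  # library -> [(read id, seq)]
    truth: TruthSet


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _fill_pattern(rng: np.random.Generator, pattern: str) -> str:
    return "".join(
        chr(_random_seq(rng, 1)[0][0]) if c == "N" else c for c in pattern
    )


def generate_genome(
    config: SimConfig,
) -> tuple[dict[str, str], list[RecognitionSite]]:
    """Random genome, optionally with planted BsaXI sites, plus site truth.

    The background is i.i.d. uniform A/C/G/T, which already carries motif
    occurrences at density 2/4^6 per position; in planted mode the requested
    number of sites (split across chromosomes by length) is written at
    evenly spaced jittered positions, alternating plus and minus forms with
    random degenerate fill. The returned truth is the full scan of the
    finished genome — planted plus background sites.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    enzyme = ENZYMES["BsaXI"]
    genome: dict[str, str] = {}
    lengths = config.chromosome_lengths
    total_len = sum(lengths)
    planted_left = config.n_planted_sites or 0
    margin = 40  # room for the 33-nt tag around any planted site
    for ci, length in enumerate(lengths):
        seq = _random_seq(rng, length)
        if config.n_planted_sites:
            share = (
                planted_left
                if ci == len(lengths) - 1
                else int(round(config.n_planted_sites * length / total_len))
            )
            share = min(share, planted_left)
            planted_left -= share
            if share:
                usable = length - 2 * margin - enzyme.pattern_length
                if usable < share * (enzyme.tag_length + 7):
                    raise ConfigurationError(
                        f"chromosome {ci} too short for {share} planted sites"
                    )
                spacing = usable / share
                for k in range(share):
                    jitter = rng.integers(0, max(1, int(spacing) - enzyme.tag_length))
                    pos = margin + int(k * spacing) + int(jitter)
                    pattern = (
                        enzyme.plus_pattern if rng.random() < 0.5 else enzyme.minus_pattern
                    )
                    filled = _fill_pattern(rng, pattern)
                    seq[pos : pos + len(filled)] = np.frombuffer(
                        filled.encode(), dtype="S1"
                    )
        genome[f"chr{ci + 1}"] = seq.tobytes().decode()
    sites = scan_sites(genome, enzyme)
    return genome, sites


def _fixed_motif_positions(site: RecognitionSite) -> set[int]:
    enzyme = ENZYMES[site.enzyme]
    motif = (
        enzyme.plus_pattern if site.orientation == "plus_form" else enzyme.minus_pattern
    )
    return {site.start + i for i, c in enumerate(motif) if c != "N"}


def generate_parents(
    genome: dict[str, str],
    tags: Sequence[TagRecord],
    snp_rate: float,
    seed: int,
    *,
    max_snps_per_tag: int = 2,
) -> tuple[dict[str, str], dict[str, str], list[tuple[str, int, str, str]]]:
    """Derive two homozygous parental haplotypes from the reference.

    Parent A is the reference itself. Parent B carries, per tag footprint
    with probability ``snp_rate``, one or two substitutions at degenerate
    tag positions — never at the motif's fixed bases, and never where the
    substitution would create or destroy any motif occurrence in the local
    context (checked against both degenerate forms) — so both parents
    digest identically. Returns both haplotype genomes and the SNP truth.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    arrays = {c: np.frombuffer(s.encode(), dtype="S1").copy() for c, s in genome.items()}
    enzyme = ENZYMES["BsaXI"]
    motifs = (enzyme.plus_pattern, enzyme.minus_pattern)

    def _local_sites(arr: np.ndarray, pos: int) -> list[tuple[int, str]]:
        lo = max(0, pos - 10)
        hi = min(len(arr), pos + 11)
        window = arr[lo : min(len(arr), hi + 10)].tobytes().decode()
        found = []
        for motif in motifs:
            for off in range(len(window) - len(motif) + 1):
                if all(
                    c == "N" or window[off + i] == c for i, c in enumerate(motif)
                ):
                    found.append((lo + off, motif))
        return found

    snps: list[tuple[str, int, str, str]] = []
    mutated_positions: set[tuple[str, int]] = set()
    for tag in tags:
        if rng.random() >= snp_rate:
            continue
        chrom = tag.site.sequence_id
        arr = arrays[chrom]
        forbidden = _fixed_motif_positions(tag.site)
        candidates = [
            p
            for p in range(tag.tag_start, tag.tag_end)
            if p not in forbidden and (chrom, p) not in mutated_positions
        ]
        if not candidates:
            continue
        k = min(1 + int(rng.random() < 0.2), max_snps_per_tag, len(candidates))
        placed = 0
        order = rng.permutation(len(candidates))
        for p in order:
            if placed == k:
                break
            pos = candidates[p]
            ref = arr[pos].decode()
            before = _local_sites(arr, pos)
            alts = list(rng.permutation([b for b in "ACGT" if b != ref]))
            for alt in alts:
                arr[pos] = str(alt).encode()
                if _local_sites(arr, pos) == before:
                    snps.append((chrom, pos, ref, str(alt)))
                    mutated_positions.add((chrom, pos))
                    placed += 1
                    break
                arr[pos] = ref.encode()  # substitution altered digestion
    parent_b = {c: a.tobytes().decode() for c, a in arrays.items()}
    parent_a = dict(genome)
    return parent_a, parent_b, snps


def generate_f2(
    marker_positions: Sequence[tuple[str, int]],
    n_progeny: int,
    seed: int,
    recombination: str = "none",
    map_length_morgans: float = 2.0,
    chromosome_lengths: dict[str, int] | None = None,
) -> np.ndarray:
    """F2 genotype truth matrix: B-allele dosage in {0, 1, 2}.

    Mode ``"none"``: each marker segregates independently with
    probabilities (1/4, 1/2, 1/4) — the expectation for any F2 locus.
    Mode ``"poisson"``: two gametes per progeny are formed per chromosome
    with Poisson-distributed crossovers over the stated genetic length, so
    nearby markers stay linked.

    Returns an (n_markers, n_progeny) integer array.
    """
    if n_progeny < 1:
        raise ConfigurationError("n_progeny must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    n_markers = len(marker_positions)
    if recombination == "none":
        gametes = rng.integers(0, 2, size=(2, n_markers, n_progeny))
        return gametes.sum(axis=0)
    if recombination != "poisson":
        raise ConfigurationError("recombination must be 'none' or 'poisson'")
    if chromosome_lengths is None:
        chromosome_lengths = {}
        for chrom, pos in marker_positions:
            chromosome_lengths[chrom] = max(chromosome_lengths.get(chrom, 0), pos + 1)
    dosage = np.zeros((n_markers, n_progeny), dtype=int)
    by_chrom: dict[str, list[int]] = {}
    for i, (chrom, _) in enumerate(marker_positions):
        by_chrom.setdefault(chrom, []).append(i)
    for chrom, idxs in by_chrom.items():
        L = chromosome_lengths[chrom]
        cm = np.array([marker_positions[i][1] / L * map_length_morgans for i in idxs])
        for j in range(n_progeny):
            for _ in range(2):  # two gametes
                n_xo = rng.poisson(map_length_morgans)
                breaks = np.sort(rng.uniform(0, map_length_morgans, size=n_xo))
                start_hap = rng.integers(0, 2)
                haps = (start_hap + np.searchsorted(breaks, cm)) % 2
                dosage[np.asarray(idxs), j] += haps
    return dosage


def _apply_errors(
    reads: list[str], rng: np.random.Generator, error_rate: float
) -> tuple[list[str], np.ndarray]:
    """I.i.d. substitution errors; returns mutated reads + per-read counts."""
    if error_rate == 0 or not reads:
        return reads, np.zeros(len(reads), dtype=int)
    lengths = np.array([len(r) for r in reads])
    n_err = rng.binomial(lengths, error_rate)
    out = list(reads)
    for i in np.nonzero(n_err)[0]:
        arr = np.frombuffer(out[i].encode(), dtype="S1").copy()
        pos = rng.choice(len(arr), size=n_err[i], replace=False)
        for p in pos:
            cur = arr[p].decode()
            arr[p] = rng.choice([b for b in "ACGT" if b != cur]).encode()
        out[i] = arr.tobytes().decode()
    return out, n_err


def _contaminant_fragment(
    rng: np.random.Generator, genome: dict[str, str], length: int = 33
) -> str:
    """A genomic 33-mer that matches neither tag orientation."""
    chroms = sorted(genome)
    for _ in range(1000):
        chrom = chroms[rng.integers(0, len(chroms))]
        seq = genome[chrom]
        if len(seq) < length:
            continue
        start = int(rng.integers(0, len(seq) - length + 1))
        frag = seq[start : start + length]
        try:
            from .enzymes import canonicalize

            canonicalize(frag)
        except ValueError:
            return frag
    raise RuntimeError("could not draw a site-free fragment")


def simulate_reads(
    experiment_samples: Sequence[tuple[str, np.ndarray | None]],
    tags: Sequence[TagRecord],
    parent_tag_seqs: tuple[dict[int, str], dict[int, str]],
    marker_site_ids: Sequence[int],
    genome: dict[str, str],
    sheet: SampleSheet,
    config: SimConfig,
    design: LibraryDesign = DEFAULT_DESIGN,
) -> tuple[dict[str, list[tuple[str, str]]], list[ReadTruth]]:
    """Generate barcoded FASTQ-ready reads per library, with per-read truth.

    ``experiment_samples`` pairs each sample id with its dosage column over
    the markers (None for parent A; parent B is passed an all-2 column).
    Per sample and site the read count is Poisson(depth); each read picks a
    haplotype according to the genotype, a sequencing strand by fair coin
    (configurable), is built through the library construct and then damaged
    by substitution errors. Between-site contaminant fragments are added on
    top so that they make up ``contaminant_fraction`` of the library in
    expectation, leaving the true per-site depth at the configured Poisson
    rate (size selection passes them through alongside the real tags).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    tag_a, tag_b = parent_tag_seqs
    marker_index = {sid: k for k, sid in enumerate(marker_site_ids)}
    sample_barcode: dict[str, tuple[str, str]] = {}
    for lib, bc, sample in sheet.rows:
        sample_barcode[sample] = (lib, bc)

    libraries: dict[str, list[tuple[str, str]]] = {lib: [] for lib in sheet.libraries()}
    truth: list[ReadTruth] = []
    n_sites = len(tags)
    c = config.contaminant_fraction
    contam_rate = n_sites * config.read_depth * (c / (1.0 - c)) if c < 1 else 0.0
    serial = 0
    for sample_id, dosage_col in experiment_samples:
        lib, barcode = sample_barcode[sample_id]
        depths = rng.poisson(config.read_depth, size=n_sites)
        raw: list[str] = []
        meta: list[tuple[int | None, str, bool]] = []
        for site_id in range(n_sites):
            for _ in range(depths[site_id]):
                k = marker_index.get(site_id)
                if dosage_col is None or k is None:
                    use_b = False
                else:
                    d = dosage_col[k]
                    use_b = d == 2 or (d == 1 and rng.random() < 0.5)
                frag = (tag_b if use_b else tag_a)[site_id]
                if rng.random() < config.strand_flip_probability:
                    frag = reverse_complement(frag)
                    strand = "minus"
                else:
                    strand = "plus"
                raw.append(construct_read(design, barcode, frag, config.read_length))
                meta.append((site_id, strand, False))
        for _ in range(rng.poisson(contam_rate)):
            frag = _contaminant_fragment(rng, genome)
            strand = "plus"
            if rng.random() < config.strand_flip_probability:
                frag = reverse_complement(frag)
                strand = "minus"
            raw.append(construct_read(design, barcode, frag, config.read_length))
            meta.append((None, strand, True))
        damaged, n_err = _apply_errors(raw, rng, config.error_rate)
        for (site_id, strand, contam), seq, ne in zip(meta, damaged, n_err):
            rid = f"read{serial:08d}"
            serial += 1
            libraries[lib].append((rid, seq))
            truth.append(
                ReadTruth(rid, sample_id, site_id, strand, int(ne), contam)
            )
    return libraries, truth


def _plus_strand_tag_seqs(
    haplotype: dict[str, str], tags: Sequence[TagRecord]
) -> dict[int, str]:
    """Per site id, the plus-strand 33-mer of a haplotype at the tag interval."""
    return {
        i: haplotype[t.site.sequence_id][t.tag_start : t.tag_end]
        for i, t in enumerate(tags)
    }


def make_sample_sheet(
    sample_ids: Sequence[str], barcode_set: BarcodeSet
) -> SampleSheet:
    """Group samples into 12-plex libraries, reusing the barcode set per group."""
    rows = []
    bcs = barcode_set.sequences()
    per_lib = len(bcs)
    for i, sample in enumerate(sample_ids):
        lib = f"lib{i // per_lib + 1:02d}"
        rows.append((lib, bcs[i % per_lib], sample))
    return SampleSheet(rows)


def simulate_experiment(
    config: SimConfig, design: LibraryDesign = DEFAULT_DESIGN
) -> SimulatedExperiment:
    """Run the full generator: genome, parents, F2, libraries, truth.

    Markers are defined at sites whose parental tag alleles differ and whose
    reference tags are unique (repeated tags are excluded from truth markers
    exactly as the pipeline excludes multi-mapping reads).
    """
    genome, sites = generate_genome(config)
    tags = extract_tags(genome, sites, "BsaXI")
    from .enzymes import find_unique_tags

    find_unique_tags(tags)
    parent_a, parent_b, snps = generate_parents(
        genome, [t for t in tags if t.unique], config.snp_rate, config.seed
    )
    tag_a = _plus_strand_tag_seqs(parent_a, tags)
    tag_b = _plus_strand_tag_seqs(parent_b, tags)
    marker_site_ids = [
        i for i, t in enumerate(tags) if t.unique and tag_a[i] != tag_b[i]
    ]
    parent_alleles = {
        i: (
            tags[i].canonical_sequence,
            tag_b[i]
            if tags[i].site.orientation == "plus_form"
            else reverse_complement(tag_b[i]),
        )
        for i in marker_site_ids
    }
    positions = [
        (tags[i].site.sequence_id, tags[i].site.start) for i in marker_site_ids
    ]
    chrom_lengths = {f"chr{k + 1}": L for k, L in enumerate(config.chromosome_lengths)}
    dosage = generate_f2(
        positions,
        config.n_progeny,
        config.seed,
        config.recombination,
        config.map_length_morgans,
        chrom_lengths,
    )

    progeny_ids = [f"F2-{i + 1:03d}" for i in range(config.n_progeny)]
    parent_ids = []
    for rep in range(config.parent_replicates):
        suffix = f"-{rep + 1}" if config.parent_replicates > 1 else ""
        parent_ids += [f"female{suffix}", f"male{suffix}"]
    sample_ids = parent_ids + progeny_ids
    n_bc = min(12, len(sample_ids))
    barcode_set = design_barcodes(n_bc, range(5, 10), design, seed=config.seed)
    sheet = make_sample_sheet(sample_ids, barcode_set)

    n_markers = len(marker_site_ids)
    all_b = np.full(n_markers, 2, dtype=int)
    samples: list[tuple[str, np.ndarray | None]] = []
    for sid in parent_ids:
        samples.append((sid, None if sid.startswith("female") else all_b))
    for j, sid in enumerate(progeny_ids):
        samples.append((sid, dosage[:, j]))

    libraries, read_truth = simulate_reads(
        samples, tags, (tag_a, tag_b), marker_site_ids, genome, sheet, config, design
    )
    truth = TruthSet(
        sites=sites,
        tags=tags,
        snps=snps,
        marker_site_ids=marker_site_ids,
        parent_alleles=parent_alleles,
        progeny_genotypes=dosage,
        reads=read_truth,
    )
    return SimulatedExperiment(
        config, genome, parent_a, parent_b, sheet, barcode_set, libraries, truth
    )


def write_fastq(reads: Sequence[tuple[str, str]], path) -> None:
    """Write (id, sequence) pairs as FASTQ with constant quality."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_fasta(genome: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
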