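"""Reference-anchored F2 genotyper with depth and segregation filters.

Each reference tag site is a candidate locus. Per sample, the canonical
tags assigned to a site form an allele stack; a genotype is called from the
stack with a minimum-depth rule and a second-allele frequency band
(frequencies below ``min_het`` are treated as sequencing error and the
sample called homozygous; above ``max_het``, heterozygous; the narrow band
in between is deliberately uncallable). Sites where the two inbred parents
are homozygous for different alleles separated by at most two substitutions
become aa x bb markers; progeny are genotyped against the parental alleles,
and markers are filtered on missing rate and a chi-square test against the
1:2:1 F2 expectation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from scipy import stats as sps

from .enzymes import ConfigurationError

__all__ = [
    "LocusObservation",
    "SampleCall",
    "MarkerRecord",
    "anchor_tags",
    "collapse_alleles",
    "call_sample_genotype",
    "discover_markers",
    "genotype_progeny",
    "segregation_filter",
    "overall_missing_rate",
    "chi_square_1_2_1",
]

GENOTYPES = ("aa", "ab", "bb", "missing")


@dataclass
class LocusObservation:
    """Allele read stack for one sample at one reference site."""

    sample_id: str
    site_id: int
    allele_counts: Mapping[str, int]


@dataclass
class SampleCall:
    site_id: int
    call: str  # "hom", "het" or "missing"
    alleles: tuple[str, ...]  # () for missing, (a,) for hom, (a, b) for het
    total_depth: int
    tie_broken: bool = False


@dataclass
class MarkerRecord:
    """An aa x bb locus: parents homozygous for different tag alleles."""

    site_id: int
    parent_a_allele: str
    parent_b_allele: str
    snp_positions: tuple[int, ...]
    progeny_genotypes: list[str] = field(default_factory=list)
    chi2_statistic: float | None = None
    chi2_p: float | None = None

    @property
    def snp_count(self) -> int:
        return len(self.snp_positions)

    @property
    def missing_rate(self) -> float:
        n = len(self.progeny_genotypes)
        return self.progeny_genotypes.count("missing") / n if n else 0.0


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


class TagAnchorIndex:
    """Reference tag lookup tolerating up to two substitutions.

    Pigeonhole banding: a 33-mer is split into three 11-nt bands, and any
    sequence within Hamming distance 2 of a reference tag matches at least
    one band exactly. Band hits are verified by full Hamming distance.
    """

    def __init__(self, index: Mapping[str, Sequence[int]]):
        self.exact = {tag: list(sites) for tag, sites in index.items()}
        self.bands: dict[tuple[int, str], set[str]] = {}
        for tag in self.exact:
            for b in range(3):
                self.bands.setdefault((b, tag[b * 11 : (b + 1) * 11]), set()).add(tag)

    def lookup(self, tag: str, max_mismatch: int = 2) -> tuple[list[int], int] | None:
        """(site ids, distance) of the best anchor, or None.

        Exact matches win; otherwise the unique reference tag at the
        smallest Hamming distance within ``max_mismatch`` wins, and ties
        between different reference tags leave the query unanchored.
        """
        sites = self.exact.get(tag)
        if sites is not None:
            return list(sites), 0
        if max_mismatch == 0:
            return None
        best: dict[str, int] = {}
        candidates: set[str] = set()
        for b in range(3):
            candidates |= self.bands.get((b, tag[b * 11 : (b + 1) * 11]), set())
        for ref in candidates:
            d = _hamming(tag, ref)
            if d <= max_mismatch:
                best[ref] = d
        if not best:
            return None
        dmin = min(best.values())
        hits = [r for r, d in best.items() if d == dmin]
        if len(hits) != 1:
            return None
        return list(self.exact[hits[0]]), dmin


def anchor_tags(
    tag_counts: Mapping[str, int],
    index: "TagAnchorIndex | Mapping[str, Sequence[int]]",
    max_mismatch: int = 2,
) -> dict[int, Counter]:
    """Assign a sample's canonical tags to reference tag loci.

    Each distinct tag is anchored to the unique closest reference tag
    within ``max_mismatch`` substitutions (default 2, the catalog-merge
    tolerance for a two-SNP allele). Tags anchoring to several loci —
    repeated reference tags or distance ties — are discarded, mirroring
    unique-mapping alignment. Returns site id -> allele read stack.
    """
    if not isinstance(index, TagAnchorIndex):
        index = TagAnchorIndex(index)
    per_site: dict[int, Counter] = {}
    for tag, count in tag_counts.items():
        hit = index.lookup(tag, max_mismatch)
        if hit is None:
            continue
        sites, _ = hit
        if len(sites) != 1:
            continue
        per_site.setdefault(sites[0], Counter())[tag] += count
    return per_site


def collapse_alleles(
    allele_counts: Mapping[str, int],
    min_stack_depth: int = 2,
    merge_distance: int = 2,
) -> dict[str, int]:
    """Absorb sub-threshold sequences into nearby true alleles.

    Sequences seen fewer than ``min_stack_depth`` times do not form alleles
    of their own (the minimum-coverage rule of stack assembly): they are
    merged into the closest allele at or above threshold within
    ``merge_distance`` substitutions — sequencing-error reads rejoin the
    allele they came from — and are dropped when nothing is close enough.
    Ties go to the deeper, then lexicographically smaller, allele.
    """
    primary = {a: c for a, c in allele_counts.items() if c >= min_stack_depth}
    out = dict(primary)
    for allele, count in allele_counts.items():
        if allele in primary:
            continue
        best = None
        for target, tcount in primary.items():
            d = _hamming(allele, target)
            if d <= merge_distance:
                key = (d, -tcount, target)
                if best is None or key < best[0]:
                    best = (key, target)
        if best is not None:
            out[best[1]] += count
    return out


def call_sample_genotype(
    obs: LocusObservation,
    min_depth: int = 2,
    min_het: float = 0.010,
    max_het: float = 0.011,
) -> SampleCall:
    """Call hom/het/missing from an allele stack.

    Stacks shallower than ``min_depth`` are missing. Otherwise, with ``f``
    the frequency of the second-most-frequent allele: ``f < min_het`` calls
    the top allele homozygous, ``f > max_het`` calls the top two alleles
    heterozygous, and ``min_het <= f <= max_het`` is an ambiguous zone
    called missing. Ties between the top alleles break lexicographically
    and are flagged.
    """
    counts = {a: c for a, c in obs.allele_counts.items() if c > 0}
    total = sum(counts.values())
    if total < min_depth:
        return SampleCall(obs.site_id, "missing", (), total)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    top_allele, top_count = ranked[0]
    tie = len(ranked) > 1 and ranked[1][1] == top_count
    if len(ranked) == 1:
        return SampleCall(obs.site_id, "hom", (top_allele,), total)
    second_allele, second_count = ranked[1]
    f = second_count / total
    if f < min_het:
        return SampleCall(obs.site_id, "hom", (top_allele,), total, tie)
    if f > max_het:
        het = tuple(sorted((top_allele, second_allele)))
        return SampleCall(obs.site_id, "het", het, total, tie)
    return SampleCall(obs.site_id, "missing", (), total, tie)


def _diff_positions(a: str, b: str) -> tuple[int, ...]:
    return tuple(i for i, (x, y) in enumerate(zip(a, b)) if x != y)


def discover_markers(
    parent_a_calls: Mapping[int, SampleCall],
    parent_b_calls: Mapping[int, SampleCall],
    max_snps: int = 2,
) -> tuple[list[MarkerRecord], Counter]:
    """Find aa x bb markers among sites called in both parents.

    A site yields a marker iff both parents are homozygous for different
    alleles differing at no more than ``max_snps`` positions (more divergent
    pairs are treated as distinct repeated loci, not alleles). Skipped sites
    are tallied by reason.
    """
    markers: list[MarkerRecord] = []
    skipped: Counter = Counter()
    for site_id in sorted(set(parent_a_calls) & set(parent_b_calls)):
        ca, cb = parent_a_calls[site_id], parent_b_calls[site_id]
        if ca.call != "hom" or cb.call != "hom":
            skipped["parent_not_hom"] += 1
            continue
        allele_a, allele_b = ca.alleles[0], cb.alleles[0]
        if allele_a == allele_b:
            skipped["monomorphic"] += 1
            continue
        diffs = _diff_positions(allele_a, allele_b)
        if len(diffs) > max_snps:
            skipped["too_divergent"] += 1
            continue
        markers.append(MarkerRecord(site_id, allele_a, allele_b, diffs))
    return markers, skipped


def genotype_progeny(
    markers: Sequence[MarkerRecord],
    progeny_calls: Sequence[Mapping[int, SampleCall]],
) -> list[MarkerRecord]:
    """Fill each marker's progeny genotype vector from per-sample calls.

    Homozygous for the parent-A allele -> aa; for the parent-B allele ->
    bb; heterozygous with exactly the two parental alleles -> ab; anything
    else (missing, foreign allele — e.g. an error stack) -> missing.
    """
    for m in markers:
        genos = []
        for calls in progeny_calls:
            c = calls.get(m.site_id)
            if c is None or c.call == "missing":
                genos.append("missing")
            elif c.call == "hom":
                if c.alleles[0] == m.parent_a_allele:
                    genos.append("aa")
                elif c.alleles[0] == m.parent_b_allele:
                    genos.append("bb")
                else:
                    genos.append("missing")
            else:  # het
                if set(c.alleles) == {m.parent_a_allele, m.parent_b_allele}:
                    genos.append("ab")
                else:
                    genos.append("missing")
        m.progeny_genotypes = genos
    return list(markers)


def chi_square_1_2_1(n_aa: int, n_ab: int, n_bb: int) -> tuple[float, float]:
    """Chi-square statistic and p-value against a 1:2:1 ratio (df = 2).

    Expected counts are (n/4, n/2, n/4) of the non-missing total; the
    asymptotic chi-square distribution is used without continuity
    correction.
    """
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ConfigurationError("no non-missing genotypes")
    expected = (n / 4, n / 2, n / 4)
    stat = sum(
        (o - e) ** 2 / e for o, e in zip((n_aa, n_ab, n_bb), expected)
    )
    return stat, float(sps.chi2.sf(stat, df=2))


def segregation_filter(
    markers: Sequence[MarkerRecord],
    max_missing: float = 0.20,
    alpha: float = 0.01,
) -> tuple[list[MarkerRecord], dict]:
    """Drop markers by missing rate, then by 1:2:1 segregation distortion.

    Markers with missing rate >= ``max_missing`` are removed first; the
    survivors' chi-square statistics are computed over non-missing progeny
    and markers with p < ``alpha`` are removed as distorted. Statistics are
    stored on the surviving and distorted records alike.
    """
    kept: list[MarkerRecord] = []
    report = {"input": len(markers), "dropped_missing": 0, "dropped_all_missing": 0,
              "dropped_distorted": 0, "kept": 0}
    for m in markers:
        counts = Counter(m.progeny_genotypes)
        n = counts["aa"] + counts["ab"] + counts["bb"]
        if n == 0:
            report["dropped_all_missing"] += 1
            continue
        if m.missing_rate >= max_missing:
            report["dropped_missing"] += 1
            continue
        m.chi2_statistic, m.chi2_p = chi_square_1_2_1(
            counts["aa"], counts["ab"], counts["bb"]
        )
        if m.chi2_p < alpha:
            report["dropped_distorted"] += 1
            continue
        kept.append(m)
    report["kept"] = len(kept)
    return kept, report


def overall_missing_rate(markers: Sequence[MarkerRecord]) -> float:
    """Total missing cells over (markers x progeny) in the genotype matrix."""
    total = sum(len(m.progeny_genotypes) for m in markers)
    if total == 0:
        raise ConfigurationError("empty genotype matrix")
    missing = sum(m.progeny_genotypes.count("missing") for m in markers)
    return missing / total


def write_genotype_matrix(
    markers: Sequence[MarkerRecord], sample_ids: Sequence[str], path
) -> None:
    """Markers x samples TSV with symbols aa/ab/bb/-."""
    sym = {"aa": "aa", "ab": "ab", "bb": "bb", "missing": "-"}
    with open(path, "w") as fh:
        fh.write("marker\t" + "\t".join(sample_ids) + "\n")
        for m in markers:
            fh.write(
                f"site{m.site_id}\t"
                + "\t".join(sym[g] for g in m.progeny_genotypes)
                + "\n"
            )


def write_joinmap_loci(markers: Sequence[MarkerRecord], path) -> None:
    """Locus rows in the mapping-software convention: a/h/b/- per progeny."""
    sym = {"aa": "a", "ab": "h", "bb": "b", "missing": "-"}
    with open(path, "w") as fh:
        for m in markers:
            fh.write(
                f"site{m.site_id} "
                + " ".join(sym[g] for g in m.progeny_genotypes)
                + "\n"
            )
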