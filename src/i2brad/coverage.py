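"""Assign canonical sample tags to reference tag loci; coverage accounting.

The reference genome's in-silico digestion defines the universe of expected
recognition sites. High-quality canonical tags from a sample are looked up
against the reference tags (exactly, or tolerating one substitution);
coverage rate is the fraction of expected sites hit by at least one read
and depth is assigned reads divided by the total expected sites — both per
the saturation-table definitions. Saturation curves come from seeded
subsampling of the assigned reads.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .enzymes import ConfigurationError, TagRecord

__all__ = [
    "CoverageReport",
    "build_tag_index",
    "assign_reads",
    "coverage_report",
    "saturation_curve",
]


@dataclass
class CoverageReport:
    total_sites: int
    covered_sites: int
    assigned_read_count: int
    depth_histogram: dict[int, int]

    @property
    def coverage_rate(self) -> float:
        return self.covered_sites / self.total_sites

    @property
    def depth(self) -> float:
        """Assigned reads over total expected sites (not covered sites)."""
        return self.assigned_read_count / self.total_sites

    def to_dict(self) -> dict:
        return {
            "total_sites": self.total_sites,
            "covered_sites": self.covered_sites,
            "coverage_rate": self.coverage_rate,
            "assigned_read_count": self.assigned_read_count,
            "depth": self.depth,
            "depth_histogram": {str(k): v for k, v in sorted(self.depth_histogram.items())},
        }


def build_tag_index(
    reference_tags: Sequence[TagRecord] | Mapping[str, Iterable[int]],
) -> dict[str, list[int]]:
    """Map canonical tag sequence -> reference site id(s).

    Site ids are the positions of the tags in the input list. Tags whose
    canonical sequences collide map to several sites (repeated loci).
    """
    if isinstance(reference_tags, Mapping):
        return {k: list(v) for k, v in reference_tags.items()}
    index: dict[str, list[int]] = {}
    for site_id, tag in enumerate(reference_tags):
        index.setdefault(tag.canonical_sequence, []).append(site_id)
    return index


def _neighbors(tag: str) -> Iterable[str]:
    for i, base in enumerate(tag):
        for b in "ACGT":
            if b != base:
                yield tag[:i] + b + tag[i + 1 :]


def assign_reads(
    tags: Iterable[str] | Counter,
    index: Mapping[str, list[int]],
    max_mismatch: int = 0,
    *,
    count_multimapped_fractionally: bool = False,
) -> tuple[dict[int, float], int]:
    """Assign canonical sample tags to reference sites.

    Exact lookup first; with ``max_mismatch=1`` a failed exact lookup tries
    all 99 single-substitution neighbors and assigns only when exactly one
    site is hit. Tags hitting several sites are unassigned by default
    (mirroring unique-mapping alignment); optionally they are split
    fractionally across their sites.

    Returns (site id -> depth, unassigned read count).
    """
    if max_mismatch not in (0, 1):
        raise ConfigurationError("max_mismatch must be 0 or 1")
    items = tags.items() if isinstance(tags, Counter) else ((t, 1) for t in tags)
    depth: dict[int, float] = {}
    unassigned = 0
    for tag, count in items:
        sites = index.get(tag)
        if sites is None and max_mismatch == 1:
            hit_sites: set[int] = set()
            for nb in _neighbors(tag):
                hit = index.get(nb)
                if hit:
                    hit_sites.update(hit)
            sites = sorted(hit_sites) if hit_sites else None
        if sites is None:
            unassigned += count
        elif len(sites) == 1:
            depth[sites[0]] = depth.get(sites[0], 0) + count
        elif count_multimapped_fractionally:
            for s in sites:
                depth[s] = depth.get(s, 0) + count / len(sites)
        else:
            unassigned += count
    return depth, unassigned


def coverage_report(
    depth: Mapping[int, float], total_sites: int
) -> CoverageReport:
    """Summarize a per-site depth vector against the expected site universe."""
    if total_sites == 0:
        raise ConfigurationError("total_sites must be > 0")
    covered = sum(1 for d in depth.values() if d >= 1)
    assigned = int(round(sum(depth.values())))
    hist = Counter(int(d) for d in depth.values())
    hist[0] = total_sites - len(depth)
    return CoverageReport(total_sites, covered, assigned, dict(hist))


def saturation_curve(
    assigned_site_ids: Sequence[int],
    total_sites: int,
    fractions: Sequence[float],
    seed: int = 0,
) -> list[tuple[float, float, float]]:
    """Coverage as a function of subsampled data size.

    ``assigned_site_ids`` lists the site hit by each assigned read (one
    entry per read). Each fraction subsamples reads without replacement;
    returns (fraction, mean depth, coverage rate) triples. Coverage is
    monotone non-decreasing in the fraction in expectation; repeatable for
    a fixed seed.
    """
    if any(not (0 < f <= 1) for f in fractions):
        raise ConfigurationError("fractions must lie in (0, 1]")
    if not assigned_site_ids:
        return []
    rng = np.random.default_rng(seed)
    ids = np.asarray(assigned_site_ids)
    out = []
    for f in fractions:
        k = int(round(f * len(ids)))
        sub = ids if k >= len(ids) else rng.choice(ids, size=k, replace=False)
        covered = len(np.unique(sub))
        out.append((f, len(sub) / total_sites, covered / total_sites))
    return out
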