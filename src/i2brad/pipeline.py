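"""End-to-end orchestration on simulator output: the in-silico experiment.

Chains the stages exactly as the protocol runs them on real data —
simulate libraries, demultiplex and filter reads, assign canonical tags to
the reference tag loci, call per-sample genotypes, discover aa x bb
markers, genotype the F2 progeny and apply the missing-rate and
segregation filters — and scores every stage against the simulator's truth
tables.
"""

from __future__ import annotations

import json
from collections import Counter
from pathlib import Path
from typing import Mapping

from .coverage import build_tag_index, coverage_report
from .demux import FilterStats, demux_reads
from .genotyping import (
    LocusObservation,
    TagAnchorIndex,
    anchor_tags,
    call_sample_genotype,
    collapse_alleles,
    discover_markers,
    genotype_progeny,
    overall_missing_rate,
    segregation_filter,
    write_genotype_matrix,
    write_joinmap_loci,
)
from .simdata import SimConfig, SimulatedExperiment, simulate_experiment

__all__ = ["run_pipeline", "genotype_samples", "score_against_truth"]


def _call_sample(
    tag_counts: Mapping[str, int],
    anchor: TagAnchorIndex,
    sample_id: str,
    min_depth: int = 2,
    min_het: float = 0.010,
    max_het: float = 0.011,
):
    calls = {}
    for site, stack in anchor_tags(tag_counts, anchor).items():
        collapsed = collapse_alleles(stack, min_stack_depth=min_depth)
        if not collapsed:
            continue
        obs = LocusObservation(sample_id, site, collapsed)
        calls[site] = call_sample_genotype(obs, min_depth, min_het, max_het)
    return calls


def genotype_samples(
    sample_tags: Mapping[str, Counter],
    ref_index: Mapping[str, list[int]],
    parent_a_samples: list[str],
    parent_b_samples: list[str],
    progeny_samples: list[str],
    *,
    max_missing: float = 0.20,
    alpha: float = 0.01,
):
    """Marker discovery + F2 genotyping from per-sample canonical tag counts.

    Replicate parent samples are pooled before calling (the protocol
    sequences each parent several times and combines the repeats).
    """
    anchor = TagAnchorIndex(ref_index)

    def pooled(samples: list[str]) -> Counter:
        total: Counter = Counter()
        for s in samples:
            total.update(sample_tags.get(s, Counter()))
        return total

    calls_a = _call_sample(pooled(parent_a_samples), anchor, "parentA")
    calls_b = _call_sample(pooled(parent_b_samples), anchor, "parentB")
    markers, skipped = discover_markers(calls_a, calls_b)
    progeny_calls = [
        _call_sample(sample_tags.get(s, Counter()), anchor, s)
        for s in progeny_samples
    ]
    genotype_progeny(markers, progeny_calls)
    kept, report = segregation_filter(markers, max_missing, alpha)
    report["skipped_sites"] = dict(skipped)
    return markers, kept, report


def score_against_truth(
    exp: SimulatedExperiment, markers, progeny_samples: list[str]
) -> dict:
    """Concordance of called genotypes with the simulator's truth matrix."""
    truth = exp.truth
    marker_pos = {sid: k for k, sid in enumerate(truth.marker_site_ids)}
    concordant = 0
    compared = 0
    missing = 0
    truth_sites_found = 0
    for m in markers:
        k = marker_pos.get(m.site_id)
        if k is None:
            continue
        truth_sites_found += 1
        # called marker may have parent alleles swapped relative to truth
        # only if discovery mislabelled parents; alleles are checked instead
        flip = m.parent_a_allele != truth.parent_alleles[m.site_id][0]
        for j, g in enumerate(m.progeny_genotypes):
            if g == "missing":
                missing += 1
                continue
            expected = truth.genotype_symbol(k, j)
            called = g
            if flip:
                called = {"aa": "bb", "bb": "aa"}.get(g, g)
            compared += 1
            if called == expected:
                concordant += 1
    total_cells = sum(len(m.progeny_genotypes) for m in markers) or 1
    return {
        "truth_markers": len(truth.marker_site_ids),
        "called_markers": len(markers),
        "called_markers_in_truth": truth_sites_found,
        "compared_cells": compared,
        "concordance": concordant / compared if compared else float("nan"),
        "missing_cells": missing,
        "missing_rate": missing / total_cells,
    }


def run_pipeline(config: SimConfig, outdir: Path | None = None) -> dict:
    """simulate -> demux -> coverage -> genotype, scored against truth.

    Returns a JSON-serializable summary; when ``outdir`` is given the
    genotype matrix, locus file and stage reports are written there.
    """
    exp = simulate_experiment(config)
    ref_index = build_tag_index(exp.truth.tags)

    sample_tags: dict[str, Counter] = {}
    stats = FilterStats()
    for lib in exp.sheet.libraries():
        reads = [seq for _, seq in exp.libraries[lib]]
        result = demux_reads(reads, exp.sheet.library(lib))
        for sample, tags in result.sample_tags.items():
            sample_tags.setdefault(sample, Counter()).update(tags)
        s = result.stats
        stats.total_reads += s.total_reads
        stats.barcode_matched += s.barcode_matched
        stats.high_quality += s.high_quality
        stats.rejected_barcode += s.rejected_barcode
        stats.rejected_site_or_N += s.rejected_site_or_N
        stats.barcode_reject_reasons.update(s.barcode_reject_reasons)
        stats.tag_reject_reasons.update(s.tag_reject_reasons)
        stats.per_sample_assigned.update(s.per_sample_assigned)
        stats.per_sample_high_quality.update(s.per_sample_high_quality)

    parent_a_samples = [s for s in sample_tags if s.startswith("female")]
    parent_b_samples = [s for s in sample_tags if s.startswith("male")]
    progeny_samples = sorted(s for s in sample_tags if s.startswith("F2-"))

    # coverage of the expected site universe by the pooled female reads
    anchor = TagAnchorIndex(ref_index)
    female: Counter = Counter()
    for s in parent_a_samples:
        female.update(sample_tags[s])
    depth: dict[int, float] = {}
    for site, stack in anchor_tags(female, anchor).items():
        depth[site] = sum(stack.values())
    cov = coverage_report(depth, len(exp.truth.tags))

    markers, kept, filter_report = genotype_samples(
        sample_tags, ref_index, parent_a_samples, parent_b_samples, progeny_samples
    )
    scoring = score_against_truth(exp, markers, progeny_samples)

    summary = {
        "config": {"seed": config.seed, "n_progeny": config.n_progeny,
                   "read_depth": config.read_depth,
                   "error_rate": config.error_rate,
                   "contaminant_fraction": config.contaminant_fraction},
        "filter_stats": stats.to_dict(),
        "coverage": cov.to_dict(),
        "markers": filter_report,
        "overall_missing_rate": overall_missing_rate(markers) if markers else None,
        "truth_scoring": scoring,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_genotype_matrix(kept, progeny_samples, outdir / "genotypes.tsv")
        write_joinmap_loci(kept, outdir / "loci.joinmap.txt")
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
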