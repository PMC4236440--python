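"""On-disk formats: FASTA input, BED/TSV writers for sites and tags.

Coordinates on disk follow the BED convention (0-based, half-open); the
strand column maps plus_form to ``+`` and minus_form to ``-``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

from Bio import SeqIO

from .enzymes import RecognitionSite, TagRecord, get_enzyme


def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-record FASTA to an id -> uppercase sequence mapping."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_sites_bed(sites: Sequence[RecognitionSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            end = s.start + get_enzyme(s.enzyme).pattern_length
            strand = "+" if s.orientation == "plus_form" else "-"
            fh.write(
                f"{s.sequence_id}\t{s.start}\t{end}\t"
                f"{s.enzyme}:{s.orientation}\t0\t{strand}\n"
            )


def write_tags_tsv(tags: Sequence[TagRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "sequence_id\ttag_start\ttag_end\torientation\t"
            "sequence\tcanonical_sequence\tunique\n"
        )
        for t in tags:
            uniq = "" if t.unique is None else str(t.unique).lower()
            fh.write(
                f"{t.site.sequence_id}\t{t.tag_start}\t{t.tag_end}\t"
                f"{t.site.orientation}\t{t.sequence}\t{t.canonical_sequence}\t{uniq}\n"
            )


def write_windows_tsv(window_set, path: str | Path) -> None:
    enzymes = sorted(
        {e for w in window_set.windows for e in w.counts}
    )
    with open(path, "w") as fh:
        header = ["sequence_id", "start", "end"]
        for e in enzymes:
            header += [f"{e}_count", f"{e}_class"]
        fh.write("\t".join(header) + "\n")
        for w in window_set.windows:
            row = [w.sequence_id, str(w.start), str(w.end)]
            for e in enzymes:
                row += [str(w.counts[e]), w.enzyme_class(e)]
            fh.write("\t".join(row) + "\n")
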