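"""Fixed-window tiling and enzyme-site occupancy classification.

A genome is tiled into consecutive non-overlapping windows (default 4000 bp,
the genome-wide average spacing of EcoRI sites across the surveyed species)
and each window is classified by how many recognition sites of an enzyme it
contains: zero sites means a scaffold of that size could never be anchored
to a map, one site allows anchoring without orientation, and two or more
allow oriented ("perfect") assembly. Cross-tabulating two enzymes quantifies
how much a second marker system adds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .enzymes import ConfigurationError, RecognitionSite

__all__ = ["WindowRecord", "WindowSet", "tile_windows", "classify_windows", "cross_tabulate"]

_CLASSES = ("zero", "one", "many")


def _classify(count: int) -> str:
    return "zero" if count == 0 else ("one" if count == 1 else "many")


@dataclass
class WindowRecord:
    sequence_id: str
    start: int
    end: int
    counts: dict[str, int] = field(default_factory=dict)

    def enzyme_class(self, enzyme: str) -> str:
        return _classify(self.counts[enzyme])


@dataclass
class WindowSet:
    """Tiled windows plus bookkeeping for discarded trailing remainders."""

    windows: list[WindowRecord]
    window_size: int
    discarded_remainders: int = 0
    sites_outside_windows: dict[str, int] = field(default_factory=dict)


def tile_windows(
    sequence_lengths: Mapping[str, int], window_size: int = 4000
) -> WindowSet:
    """Tile each sequence into consecutive windows of ``window_size``.

    A trailing partial window shorter than ``window_size`` is discarded and
    tallied in ``discarded_remainders``.
    """
    if window_size <= 0:
        raise ConfigurationError("window_size must be >= 1")
    windows: list[WindowRecord] = []
    discarded = 0
    for seq_id, length in sequence_lengths.items():
        n_full = length // window_size
        for i in range(n_full):
            windows.append(
                WindowRecord(seq_id, i * window_size, (i + 1) * window_size)
            )
        if length % window_size:
            discarded += 1
    return WindowSet(windows, window_size, discarded)


def classify_windows(
    window_set: WindowSet,
    sites_per_enzyme: Mapping[str, Sequence[RecognitionSite]],
) -> WindowSet:
    """Count sites per window for each enzyme and fill occupancy classes.

    A site belongs to the window containing its motif start coordinate;
    sites falling in a discarded trailing remainder are excluded and tallied
    in ``sites_outside_windows``.
    """
    size = window_set.window_size
    # windows are [k*size, (k+1)*size) per sequence, so lookup is arithmetic
    max_index: dict[str, int] = {}
    for w in window_set.windows:
        idx = w.start // size
        max_index[w.sequence_id] = max(max_index.get(w.sequence_id, -1), idx)
        for enzyme in sites_per_enzyme:
            w.counts.setdefault(enzyme, 0)
    by_key = {(w.sequence_id, w.start // size): w for w in window_set.windows}
    for enzyme, sites in sites_per_enzyme.items():
        outside = 0
        for s in sites:
            w = by_key.get((s.sequence_id, s.start // size))
            if w is None:
                outside += 1
            else:
                w.counts[enzyme] += 1
        window_set.sites_outside_windows[enzyme] = outside
    return window_set


def cross_tabulate(
    window_set: WindowSet, enzyme_a: str, enzyme_b: str
) -> dict:
    """Joint occupancy summary for two enzymes over classified windows.

    Returns marginal class counts for each enzyme, the two rescue classes
    (A absent but B multiply present; A single and B present), and the
    count/fraction of windows whose combined A+B site count is at least 2 —
    the windows a joint marker set could assemble with orientation.
    """
    windows = window_set.windows
    for enz in (enzyme_a, enzyme_b):
        if any(enz not in w.counts for w in windows):
            raise ConfigurationError(f"windows not classified for {enz!r}")
    n = len(windows)
    marg_a = {c: 0 for c in _CLASSES}
    marg_b = {c: 0 for c in _CLASSES}
    a_zero_b_many = 0
    a_one_b_any = 0
    combined_ge2 = 0
    for w in windows:
        ca, cb = w.counts[enzyme_a], w.counts[enzyme_b]
        marg_a[_classify(ca)] += 1
        marg_b[_classify(cb)] += 1
        if ca == 0 and cb >= 2:
            a_zero_b_many += 1
        if ca == 1 and cb >= 1:
            a_one_b_any += 1
        if ca + cb >= 2:
            combined_ge2 += 1
    frac = (lambda k: k / n if n else 0.0)
    return {
        "n_windows": n,
        "enzyme_a": enzyme_a,
        "enzyme_b": enzyme_b,
        "marginal_a": marg_a,
        "marginal_b": marg_b,
        "a_zero_b_many": {"count": a_zero_b_many, "fraction": frac(a_zero_b_many)},
        "a_one_b_any": {"count": a_one_b_any, "fraction": frac(a_one_b_any)},
        "combined_ge2": {"count": combined_ge2, "fraction": frac(combined_ge2)},
    }
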