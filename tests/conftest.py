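"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library's own scanning/binning code
paths: they slide windows position by position and test IUPAC classes
character by character, so they stay valid references however the package
implementations evolve.
"""

from __future__ import annotations

import numpy as np
import pytest

_IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "N": {"A", "C", "G", "T"},
}


def brute_force_scan(seq: str, pattern: str) -> list[int]:
    """All start positions where the IUPAC pattern matches, overlaps included."""
    seq = seq.upper()
    hits = []
    for i in range(len(seq) - len(pattern) + 1):
        if all(seq[i + j] in _IUPAC_SETS[c] for j, c in enumerate(pattern)):
            hits.append(i)
    return hits


def quadratic_overlaps(intervals: list[tuple[str, int, int]]) -> set[tuple[int, int]]:
    """Index pairs of intersecting same-sequence half-open intervals."""
    pairs = set()
    for i in range(len(intervals)):
        for j in range(i + 1, len(intervals)):
            ci, si, ei = intervals[i]
            cj, sj, ej = intervals[j]
            if ci == cj and si < ej and sj < ei:
                pairs.add((i, j))
    return pairs


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture()
def rng() -> np.random.Generator:
    # function-scoped: every test sees the same deterministic stream
    return np.random.default_rng(20140913)


@pytest.fixture(scope="session")
def big_random_genome() -> dict[str, str]:
    """One 10-Mb i.i.d. uniform sequence, shared by the density properties."""
    gen = np.random.default_rng(424242)
    bases = np.frombuffer(b"ACGT", dtype="S1")[gen.integers(0, 4, size=10_000_000)]
    return {"chrZ": bases.tobytes().decode()}


def make_tag(rng: np.random.Generator, form: str = "plus") -> str:
    """A random valid 33-nt tag in the requested orientation."""
    from i2brad import reverse_complement

    s = random_sequence(rng, 33)
    tag = s[:12] + "AC" + s[14:19] + "CTCC" + s[23:]
    return tag if form == "plus" else reverse_complement(tag)
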