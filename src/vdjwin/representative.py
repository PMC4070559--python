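"""Representative sequence selection for a clone.

One sequence is designated per clone (and only that sequence receives the
costly V(D)J designation). The representative is the longest run of read
positions whose every k-mer is present in at least a threshold fraction of
the clone's reads, preferring runs that fully contain the clone's seed
window (so germline flanks on both sides of the junction survive for the
designation step).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence


@dataclass(frozen=True)
class RepresentativeParams:
    """k_rep: k-mer length used for support counting (conventionally the
    locus seed weight). threshold: fraction of clone reads a k-mer must
    occur in to be considered supported."""

    k_rep: int = 10
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")
        if self.k_rep < 4:
            raise ValueError("k_rep must be >= 4")


def clone_kmer_presence(reads: Sequence[str], k_rep: int) -> Counter:
    """Number of clone reads containing each k-mer (presence per read,
    not occurrence count). k-mers containing N are skipped."""
    if not reads:
        raise ValueError("clone has no reads")
    support: Counter = Counter()
    for read in reads:
        seen = {
            kmer
            for i in range(len(read) - k_rep + 1)
            if "N" not in (kmer := read[i : i + k_rep])
        }
        support.update(seen)
    return support


def representative_region(
    reads: Sequence[str],
    window: str,
    params: RepresentativeParams,
) -> str:
    """Longest well-supported region across the clone's reads.

    With support threshold T = ceil(threshold × clone size), the maximal
    runs of positions whose every k-mer has support >= T are candidate
    regions. Among candidates fully containing the seed window the longest
    wins (ties: earliest read in input order, then leftmost); failing
    containment, the longest candidate merely overlapping the window;
    failing that, the window string itself.
    """
    t = math.ceil(params.threshold * len(reads))
    support = clone_kmer_presence(reads, params.k_rep)
    k = params.k_rep

    best_contain: tuple[int, int, int] | None = None  # (-len, read_idx, start)
    best_overlap: tuple[int, int, int] | None = None
    regions: dict[tuple[int, int, int], str] = {}

    for ridx, read in enumerate(reads):
        n_kmers = len(read) - k + 1
        if n_kmers <= 0:
            continue
        wpos = read.find(window)
        supported = [
            support[read[i : i + k]] >= t and "N" not in read[i : i + k]
            for i in range(n_kmers)
        ]
        i = 0
        while i < n_kmers:
            if not supported[i]:
                i += 1
                continue
            j = i
            while j + 1 < n_kmers and supported[j + 1]:
                j += 1
            start, end = i, j + k  # region = read[start:end]
            key = (-(end - start), ridx, start)
            regions[key] = read[start:end]
            if wpos >= 0:
                if start <= wpos and wpos + len(window) <= end:
                    if best_contain is None or key < best_contain:
                        best_contain = key
                elif start < wpos + len(window) and wpos < end:
                    if best_overlap is None or key < best_overlap:
                        best_overlap = key
            i = j + 1

    if best_contain is not None:
        return regions[best_contain]
    if best_overlap is not None:
        return regions[best_overlap]
    return window
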