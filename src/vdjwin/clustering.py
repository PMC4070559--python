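"""Clone identification from extracted w-windows.

A clone is, by default, the set of reads sharing a strictly identical
w-window: without sequencing errors all reads of one clone yield the same
window, so exact string identity is the most stringent clone definition
and the default. Optional extra clustering merges windows within bounded
edit distance (substitutions / plain indels / homopolymer indels counted
separately), plus unconditional user-specified window pairs.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .windows import SegStatus, WindowHit


@dataclass(frozen=True)
class ClusterParams:
    """Defaults follow the conservative convention: no merging at all
    (max_subst = max_indel = max_homo = 0), report the 20 most abundant
    clones, skip clones below 10 reads."""

    max_subst: int = 0
    max_indel: int = 0
    max_homo: int = 0
    manual_pairs: Sequence[tuple[str, str]] = ()
    top_n: int = 20
    min_reads: int = 10
    followed_windows: Sequence[str] = ()

    def __post_init__(self) -> None:
        if min(self.max_subst, self.max_indel, self.max_homo) < 0:
            raise ValueError("distance bounds must be >= 0")
        if self.top_n < 0 or self.min_reads < 0:
            raise ValueError("top_n and min_reads must be >= 0")


@dataclass
class Clone:
    """A cluster of windows with its member reads.

    ``seed_window`` is the most abundant member window (ties broken
    lexicographically); it identifies the clone in all outputs."""

    seed_window: str
    window_counts: dict[str, int]
    read_ids: list[str] = field(default_factory=list)
    representative: str | None = None
    designation: object | None = None
    followed: bool = False

    @property
    def member_windows(self) -> set[str]:
        return set(self.window_counts)

    @property
    def read_count(self) -> int:
        return sum(self.window_counts.values())

    def _reseed(self) -> None:
        self.seed_window = min(
            self.window_counts, key=lambda w: (-self.window_counts[w], w)
        )


@dataclass
class CloneTable:
    """Clones in deterministic order: read count descending, then seed
    window ascending. ``total_segmented`` counts every window-bearing
    read, including those of clones later dropped from reporting."""

    clones: list[Clone]
    total_segmented: int

    def sort(self) -> None:
        self.clones.sort(key=lambda c: (-c.read_count, c.seed_window))


def count_windows(hits: Iterable[WindowHit]) -> CloneTable:
    """Sort and count identical windows into singleton clones."""
    counts: Counter[str] = Counter()
    members: dict[str, list[str]] = {}
    for h in hits:
        if h.status is not SegStatus.SEGMENTED:
            raise ValueError(f"read {h.read_id}: only SEGMENTED hits can be counted")
        counts[h.window] += 1
        members.setdefault(h.window, []).append(h.read_id)
    clones = [
        Clone(seed_window=w, window_counts={w: n}, read_ids=list(members[w]))
        for w, n in counts.items()
    ]
    table = CloneTable(clones=clones, total_segmented=sum(counts.values()))
    table.sort()
    return table


def window_distance(a: str, b: str) -> tuple[int, int, int]:
    """Edit-operation counts of a minimum unit-cost alignment of a and b.

    Returns ``(substitutions, plain_indels, homopolymer_indels)``. Among
    minimum-cost alignments, ties are resolved toward fewer indels and
    then leftmost edits, so the returned triple is reproducible. An indel
    is homopolymer-type iff the inserted/deleted base equals the base
    immediately preceding or following its position in the other sequence
    (the signature error of flow-based sequencers).
    """
    if not a or not b:
        raise ValueError("windows must be non-empty")
    n, m = len(a), len(b)
    # D[i][j] = min edits between a[:i] and b[:j]
    D = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        D[i][0] = i
    for j in range(m + 1):
        D[0][j] = j
    for i in range(1, n + 1):
        row, prev = D[i], D[i - 1]
        ai = a[i - 1]
        for j in range(1, m + 1):
            row[j] = min(
                prev[j - 1] + (ai != b[j - 1]),
                prev[j] + 1,
                row[j - 1] + 1,
            )
    # Traceback preferring diagonal moves (fewest indels), then deletion:
    # a deterministic leftmost-edit convention.
    subs = plain = homo = 0
    i, j = n, m
    while i > 0 or j > 0:
        if (
            i > 0
            and j > 0
            and D[i][j] == D[i - 1][j - 1] + (a[i - 1] != b[j - 1])
        ):
            subs += a[i - 1] != b[j - 1]
            i, j = i - 1, j - 1
        elif i > 0 and D[i][j] == D[i - 1][j] + 1:
            base = a[i - 1]  # deleted from a, sits between b[j-1] and b[j]
            if (j > 0 and b[j - 1] == base) or (j < m and b[j] == base):
                homo += 1
            else:
                plain += 1
            i -= 1
        else:
            base = b[j - 1]  # inserted in b, sits between a[i-1] and a[i]
            if (i > 0 and a[i - 1] == base) or (i < n and a[i] == base):
                homo += 1
            else:
                plain += 1
            j -= 1
    return subs, plain, homo


def _within_bounds(a: str, b: str, params: ClusterParams) -> bool:
    s, p, h = window_distance(a, b)
    return s <= params.max_subst and p <= params.max_indel and h <= params.max_homo


def cluster_windows(table: CloneTable, params: ClusterParams) -> CloneTable:
    """Merge similar windows into clones.

    Manual pairs are merged first, unconditionally. Then a single greedy
    pass in table order compares each remaining cluster's seed window to
    the seeds of already-formed clusters (in order) and merges into the
    first one within all three distance bounds. Read counts are conserved.
    """
    clones = [
        Clone(
            seed_window=c.seed_window,
            window_counts=dict(c.window_counts),
            read_ids=list(c.read_ids),
        )
        for c in table.clones
    ]

    # unconditional manual merges
    by_window = {w: c for c in clones for w in c.window_counts}
    for wa, wb in params.manual_pairs:
        ca, cb = by_window.get(wa), by_window.get(wb)
        if ca is None or cb is None:
            missing = wa if ca is None else wb
            warnings.warn(f"manual pair references absent window {missing!r}; skipped")
            continue
        if ca is cb:
            continue
        # merge the later-ordered cluster into the earlier one
        if clones.index(cb) < clones.index(ca):
            ca, cb = cb, ca
        _merge(ca, cb)
        clones.remove(cb)
        for w in cb.window_counts:
            by_window[w] = ca

    if params.max_subst or params.max_indel or params.max_homo:
        formed: list[Clone] = []
        for c in clones:
            for target in formed:
                if _within_bounds(c.seed_window, target.seed_window, params):
                    _merge(target, c)
                    break
            else:
                formed.append(c)
        clones = formed

    for c in clones:
        c._reseed()
    out = CloneTable(clones=clones, total_segmented=table.total_segmented)
    out.sort()
    return out


def _merge(dst: Clone, src: Clone) -> None:
    for w, n in src.window_counts.items():
        dst.window_counts[w] = dst.window_counts.get(w, 0) + n
    dst.read_ids.extend(src.read_ids)


def select_clones(table: CloneTable, params: ClusterParams) -> CloneTable:
    """Keep the top_n most abundant clones with at least min_reads reads,
    plus any clone containing a followed window (kept regardless of rank
    or count, and flagged). Dropped clones remain in total_segmented."""
    followed = set(params.followed_windows)
    selected: list[Clone] = []
    n_top = 0
    for c in table.clones:
        is_followed = bool(followed & c.member_windows)
        if c.read_count >= params.min_reads and n_top < params.top_n:
            n_top += 1
            selected.append(replace_flag(c, is_followed))
        elif is_followed:
            selected.append(replace_flag(c, True))
    return CloneTable(clones=selected, total_segmented=table.total_segmented)


def replace_flag(c: Clone, followed: bool) -> Clone:
    return Clone(
        seed_window=c.seed_window,
        window_counts=dict(c.window_counts),
        read_ids=list(c.read_ids),
        representative=c.representative,
        designation=c.designation,
        followed=followed,
    )
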