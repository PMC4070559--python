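"""Refined V(D)J designation of a clone representative.

A semi-global dynamic program aligns every germline V gene against the
left of the sequence (free start on both, trimmed 3' end counted as
deletions) and every J gene mirrored from the right; the split point
maximizing the summed V and J scores fixes v_end < j_start, and the bases
in between form the N-diversity region. For VDJ loci a D gene is then
optionally placed inside the N region. Runtime is O(l*r) for a
representative of length l against a germline of total size r.

Designations print in the compact junction notation, e.g.
``TRGV5*01 -5/CC/0 TRGJ1*02``: V gene with 5 bases deleted at its 3' end,
two inserted N bases, J gene with no deletion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .germline import GermlineDB, GermlineGene

NEG = -(10**9)


@dataclass(frozen=True)
class AlignmentScoring:
    match: int = 2
    mismatch: int = -1
    gap: int = -2  # linear gap cost
    min_score: int = 10  # minimum V and J scores to accept a designation
    d_min_score: int = 8  # minimum score to place a D gene in the N region
    #: when the chosen V and J genes match the sequence exactly up to a
    #: junction insert at most this long, the designation is read off
    #: that exact decomposition instead of the scored alignment ends
    exact_junction_max: int = 25

    def __post_init__(self) -> None:
        if not (self.match > self.mismatch and self.match > self.gap):
            raise ValueError("match score must exceed mismatch and gap scores")


@dataclass
class Segmentation:
    """A V(D)J designation over a representative sequence: gene names,
    deletion counts at the joined gene ends, N-region content, and the
    0-based positions v_end (last V base) and j_start (first J base)."""

    v_name: str
    v_del: int
    n_region: str
    j_del: int
    j_name: str
    v_end: int
    j_start: int
    score: int
    d_name: str | None = None
    d5_del: int = 0
    d3_del: int = 0
    n1: str | None = None  # N bases 5' of D (VDJ only)
    n2: str | None = None  # N bases 3' of D (VDJ only)

    def __post_init__(self) -> None:
        if self.v_end >= self.j_start:
            raise ValueError("v_end must precede j_start")


def _end_profile(
    seq: str, genes: Sequence[GermlineGene], scoring: AlignmentScoring
):
    """Best alignment ending at each position of seq.

    For every e, the best semi-global score over genes g and gene offsets
    q of aligning g[:q] so that it ends exactly at seq[e], with free
    (unpenalized) starts in both sequences. Returns (score[e], q[e],
    gene_index[e]) with gene ties broken toward lexicographically smaller
    names (genes must be passed name-sorted for that) and equal-score ties
    toward smaller q: among equal-score alignments the shortest one wins,
    which rejects score-neutral gap+match extensions past the junction and
    keeps designations reconstructible.
    """
    L = len(seq)
    senc = np.frombuffer(seq.encode(), dtype=np.uint8)
    best = np.full(L, NEG, dtype=np.int64)
    best_q = np.zeros(L, dtype=np.int64)
    best_g = np.full(L, -1, dtype=np.int64)
    gap = scoring.gap
    jpos = np.arange(L + 1, dtype=np.int64)
    for gi, gene in enumerate(genes):
        g = np.frombuffer(gene.sequence.encode(), dtype=np.uint8)
        prev = np.zeros(L + 1, dtype=np.int64)  # row i=0: free start in gene
        for i in range(1, len(g) + 1):
            sub = np.where(senc == g[i - 1], scoring.match, scoring.mismatch)
            # the 0 floor allows a fresh start at any (gene, seq) offset
            # pair: both leading trims are free, as in a local alignment
            cand = np.maximum(np.maximum(prev[:-1] + sub, prev[1:] + gap), 0)
            # horizontal pass: row[j] = max(cand[j-1], row[j-1] + gap),
            # solved with a prefix max on cand - gap*j (linear gaps)
            row = np.empty(L + 1, dtype=np.int64)
            row[0] = 0  # free start in seq
            shifted = np.maximum.accumulate(
                np.concatenate(([0], cand - gap * jpos[1:]))
            )
            row[1:] = shifted[1:] + gap * jpos[1:]
            prev = row
            ends = row[1:]  # alignment ends at seq position e = j-1
            upd = (ends > best) | ((ends == best) & (i < best_q))
            if upd.any():
                best = np.where(upd, ends, best)
                best_q = np.where(upd, i, best_q)
                best_g = np.where(upd, gi, best_g)
    return best, best_q, best_g


def best_gene_alignment(
    seq: str,
    genes: Sequence[GermlineGene],
    side: str,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> tuple[GermlineGene, int, int, int]:
    """Best single-gene semi-global alignment against one side of seq.

    side "end_of_V": the gene's (possibly 3'-trimmed) prefix ends at some
    position e in seq, free start in both; returns (gene, e, deletions,
    score) with deletions = trimmed 3' bases. side "start_of_J": mirror
    from the right; deletions are trimmed 5' bases and the boundary is the
    alignment start s. Ties: shorter alignment (smaller q), then
    lexicographically smaller gene name, then smaller boundary position.
    """
    if not genes:
        raise ValueError("empty gene list")
    if not seq:
        raise ValueError("empty sequence")
    order = sorted(range(len(genes)), key=lambda i: genes[i].name)
    sorted_genes = [genes[i] for i in order]
    if side == "end_of_V":
        score, q, g = _end_profile(seq, sorted_genes, scoring)
        positions = range(len(seq))
    elif side == "start_of_J":
        rev_genes = [
            GermlineGene(x.name, x.sequence[::-1], x.gene_type) for x in sorted_genes
        ]
        score, q, g = _end_profile(seq[::-1], rev_genes, scoring)
        positions = range(len(seq))
    else:
        raise ValueError(f"unknown side {side!r}")

    best = None
    for e in positions:
        if g[e] < 0:
            continue
        gene = sorted_genes[g[e]]
        dels = len(gene.sequence) - int(q[e])
        boundary = e if side == "end_of_V" else len(seq) - 1 - e
        key = (int(score[e]), -int(q[e]), tuple(-ord(c) for c in gene.name), -boundary)
        if best is None or key > best[0]:
            best = (key, gene, boundary, dels, int(score[e]))
    _, gene, boundary, dels, sc = best
    return gene, boundary, dels, sc


def _place_d(
    n_region: str, d_genes: Sequence[GermlineGene], scoring: AlignmentScoring
):
    """Best placement of a (possibly both-ends-trimmed) D gene inside the
    N region: free ends everywhere. Returns (gene, start, end, d5, d3,
    score) or None. Small plain DP with start tracking; N regions are
    short so this is cheap."""
    best = None
    for gene in sorted(d_genes, key=lambda g: g.name):
        d, n = gene.sequence, n_region
        # D[i][j]: best score of an alignment of d[i0:i] vs n[j0:j]
        rows = [[(0, j) for j in range(len(n) + 1)]]  # (score, start in n)
        for i in range(1, len(d) + 1):
            row = [(0, 0)]
            for j in range(1, len(n) + 1):
                sc = scoring.match if d[i - 1] == n[j - 1] else scoring.mismatch
                cands = [
                    (rows[i - 1][j - 1][0] + sc, rows[i - 1][j - 1][1]),
                    (rows[i - 1][j][0] + scoring.gap, rows[i - 1][j][1]),
                    (row[j - 1][0] + scoring.gap, row[j - 1][1]),
                    (0, j),  # fresh start (free d 5' trim and n prefix)
                ]
                row.append(max(cands, key=lambda t: t[0]))
            rows.append(row)
        for i in range(1, len(d) + 1):
            for j in range(1, len(n) + 1):
                sc, start = rows[i][j]
                # trims are free: d5 implied by the fresh-start cell, d3 = len-i
                cand = (sc, -(len(d) - i), -start)
                # strict > keeps the first (lex smallest) gene on full ties
                if sc >= scoring.d_min_score and (
                    best is None or cand > best[0]
                ):
                    best = (cand, gene, start, j, i)
    if best is None:
        return None
    (sc, neg_d3, _), gene, s, e, i = best
    d3 = -neg_d3
    # recover d5: number of leading d bases trimmed = aligned length diff
    # the fresh-start DP does not track i0, so recompute by local traceback
    d5 = _d5_of(gene.sequence, n_region, s, e, i, scoring)
    return gene, s, e, d5, d3, sc


def _d5_of(d, n, start, end, i_end, scoring):
    """Recover the 5' trim of the placed D by re-running the bounded DP."""
    seg = n[start:end]
    best = (NEG, 0)
    for i0 in range(i_end):
        # global alignment of d[i0:i_end] vs seg
        a, b = d[i0:i_end], seg
        prev = [j * scoring.gap for j in range(len(b) + 1)]
        for x in range(1, len(a) + 1):
            row = [x * scoring.gap]
            for y in range(1, len(b) + 1):
                sc = scoring.match if a[x - 1] == b[y - 1] else scoring.mismatch
                row.append(
                    max(prev[y - 1] + sc, prev[y] + scoring.gap, row[-1] + scoring.gap)
                )
            prev = row
        if prev[-1] > best[0]:
            best = (prev[-1], i0)
    return best[1]


def segment_sequence(
    representative: str,
    db: GermlineDB,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> Segmentation | None:
    """Designate V, N, (D,) J parts of a V→J-oriented sequence.

    Profiles bestV(x) (best V alignment ending at e <= x) and bestJ(x)
    (best J alignment starting at s > x) are combined over all split
    points x; the maximizing split fixes the designation. Equal-score
    splits prefer the longest V, then the longest J (smallest N region).
    Returns None when no V or no J alignment reaches ``scoring.min_score``
    (the clone keeps its window but is flagged unsegmented).
    """
    L = len(representative)
    if L < 2:
        return None
    v_sorted = sorted(db.v_genes, key=lambda g: g.name)
    j_sorted = sorted(db.j_genes, key=lambda g: g.name)
    v_score, v_q, v_g = _end_profile(representative, v_sorted, scoring)

    j_rev = [GermlineGene(g.name, g.sequence[::-1], g.gene_type) for g in j_sorted]
    jr_score, jr_q, jr_g = _end_profile(representative[::-1], j_rev, scoring)
    # mirrored position: alignment ending at e' in reversed seq starts at
    # s = L-1-e' in the forward sequence
    j_score = jr_score[::-1].copy()
    j_q = jr_q[::-1].copy()
    j_g = jr_g[::-1].copy()

    # prefix max over V ends / suffix max over J starts; strict updates
    # keep the earliest V end and latest J start among score ties, again
    # rejecting score-neutral gapped extensions into the junction
    pv = np.empty(L, dtype=np.int64)
    pv_e = np.empty(L, dtype=np.int64)
    cur, cur_e = NEG, -1
    for x in range(L):
        if v_score[x] > cur:
            cur, cur_e = int(v_score[x]), x
        pv[x], pv_e[x] = cur, cur_e
    sj = np.empty(L, dtype=np.int64)
    sj_s = np.empty(L, dtype=np.int64)
    cur, cur_s = NEG, -1
    for s in range(L - 1, -1, -1):
        if j_score[s] > cur:
            cur, cur_s = int(j_score[s]), s
        sj[s], sj_s[s] = cur, cur_s

    best = None  # (total, v_end) maximized
    for x in range(L - 1):
        if pv[x] <= NEG or sj[x + 1] <= NEG:
            continue
        tot = int(pv[x] + sj[x + 1])
        v_end = int(pv_e[x])
        if best is None or tot > best[0] or (tot == best[0] and v_end > best[1]):
            best = (tot, v_end, int(sj_s[x + 1]))
    if best is None:
        return None
    tot, v_end, j_start = best
    if int(v_score[v_end]) < scoring.min_score:
        return None
    if int(j_score[j_start]) < scoring.min_score:
        return None

    v_gene = v_sorted[int(v_g[v_end])]
    j_gene = j_sorted[int(j_g[j_start])]
    v_del = len(v_gene.sequence) - int(v_q[v_end])
    j_del = len(j_gene.sequence) - int(j_q[j_start])

    # Score-maximizing alignments may absorb junction bases through
    # mismatch or gap extensions, which makes the printed deletion counts
    # inconsistent with the sequence. When both genes match the sequence
    # exactly up to a short insert, prefer that exact decomposition: it
    # reconstructs the sequence byte-for-byte.
    a = _common_prefix(representative, v_gene.sequence)
    b = _common_suffix(representative, j_gene.sequence)
    if (
        a * scoring.match >= scoring.min_score
        and b * scoring.match >= scoring.min_score
        and a < len(representative)
        and len(representative) - a - b <= scoring.exact_junction_max
    ):
        v_end = a - 1
        j_start = max(len(representative) - b, a)
        v_del = len(v_gene.sequence) - a
        j_del = len(j_gene.sequence) - (len(representative) - j_start)
    n_region = representative[v_end + 1 : j_start]

    seg = Segmentation(
        v_name=v_gene.name,
        v_del=v_del,
        n_region=n_region,
        j_del=j_del,
        j_name=j_gene.name,
        v_end=v_end,
        j_start=j_start,
        score=tot,
    )
    if db.d_genes and n_region:
        placed = _place_d(n_region, db.d_genes, scoring)
        if placed is not None:
            gene, s, e, d5, d3, dsc = placed
            seg.d_name = gene.name
            seg.d5_del = d5
            seg.d3_del = d3
            seg.n1 = n_region[:s]
            seg.n2 = n_region[e:]
            seg.score = tot + dsc
    return seg


def _common_prefix(s: str, t: str) -> int:
    n = min(len(s), len(t))
    for i in range(n):
        if s[i] != t[i]:
            return i
    return n


def _common_suffix(s: str, t: str) -> int:
    n = min(len(s), len(t))
    for i in range(1, n + 1):
        if s[-i] != t[-i]:
            return i - 1
    return n


def _fmt_del(d: int) -> str:
    return "0" if d == 0 else f"-{d}"


def format_designation(seg: Segmentation) -> str:
    """Compact junction notation: ``TRGV5*01 -5/CC/0 TRGJ1*02`` reads as
    "V gene TRGV5*01, 5 bases deleted at its 3' end; N region CC; J gene
    TRGJ1*02 with 0 bases deleted at its 5' end"."""
    if seg.d_name is not None:
        return (
            f"{seg.v_name} {_fmt_del(seg.v_del)}/{seg.n1}/{_fmt_del(seg.d5_del)} "
            f"{seg.d_name} {_fmt_del(seg.d3_del)}/{seg.n2}/{_fmt_del(seg.j_del)} "
            f"{seg.j_name}"
        )
    return (
        f"{seg.v_name} {_fmt_del(seg.v_del)}/{seg.n_region}/"
        f"{_fmt_del(seg.j_del)} {seg.j_name}"
    )


def reconstruct_from_designation(seg: Segmentation, db: GermlineDB) -> str:
    """Rebuild the recombined sequence a designation describes: trimmed V
    prefix + N (split around a trimmed D when present) + trimmed J suffix.
    Raises on unknown genes or deletions exceeding gene lengths."""
    v = db.gene(seg.v_name)
    j = db.gene(seg.j_name)
    if seg.v_del > len(v.sequence) or seg.v_del < 0:
        raise ValueError(f"v_del {seg.v_del} out of range for {v.name}")
    if seg.j_del > len(j.sequence) or seg.j_del < 0:
        raise ValueError(f"j_del {seg.j_del} out of range for {j.name}")
    v_part = v.sequence[: len(v.sequence) - seg.v_del]
    j_part = j.sequence[seg.j_del :]
    if seg.d_name is not None:
        d = db.gene(seg.d_name)
        if seg.d5_del + seg.d3_del > len(d.sequence):
            raise ValueError(f"D deletions out of range for {d.name}")
        d_part = d.sequence[seg.d5_del : len(d.sequence) - seg.d3_del]
        return v_part + (seg.n1 or "") + d_part + (seg.n2 or "") + j_part
    return v_part + seg.n_region + j_part
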