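"""Ground-truthed synthetic Rep-Seq data.

Generates (i) synthetic germline gene sets with TRγ-like length profiles
(V genes 250–310 bp, J genes 40–70 bp, optional D genes 10–35 bp),
(ii) recombined clone sequences with junction deletions and random
N-diversity insertions, and (iii) error-bearing reads — full amplicons or
random fragments — with i.i.d. substitutions (emulating hypermutation
rates such as 2/4/6/9%) and homopolymer-adjacent one-base indels
(flow-sequencer-like). Every read carries a truth record locating the
junction center, so window predictions can be scored without any external
tool or download.

All randomness flows through one integer seed; identical parameters give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .germline import GermlineDB, GermlineGene, reverse_complement
from .index import KmerIndex
from .segmentation import Segmentation, reconstruct_from_designation

_BASES = "ACGT"


@dataclass
class SimParams:
    """Study conditions for one simulated dataset. Length ranges default
    to the TRγ-like profile; deletion and N-length ranges are uniform
    draws within plausible junction-diversity bounds."""

    rng_seed: int = 0
    n_v: int = 5
    n_d: int = 0
    n_j: int = 3
    v_len_range: tuple[int, int] = (250, 310)
    d_len_range: tuple[int, int] = (10, 35)
    j_len_range: tuple[int, int] = (40, 70)
    n_clones: int = 10
    abundances: str | Sequence[float] = "geometric(0.5)"
    del_range: tuple[int, int] = (0, 8)
    n_len_range: tuple[int, int] = (0, 10)
    n_reads: int = 1000
    read_model: str = "amplicon"  # or "fragment"
    fragment_length: int = 100
    p_sub: float = 0.0
    p_homo: float = 0.0
    random_strand: bool = True
    locus: str = "TRG"

    def resolved_abundances(self) -> np.ndarray:
        """Explicit clone fractions (sum to 1)."""
        a = self.abundances
        if isinstance(a, str):
            if not a.startswith("geometric(") or not a.endswith(")"):
                raise ValueError(f"unknown abundance spec {a!r}")
            ratio = float(a[len("geometric(") : -1])
            raw = np.array([ratio**i for i in range(self.n_clones)])
            frac = raw / raw.sum()
        else:
            frac = np.asarray(a, dtype=float)
            if len(frac) != self.n_clones:
                raise ValueError("abundances length must equal n_clones")
            if abs(frac.sum() - 1.0) > 1e-9:
                raise ValueError("abundances must sum to 1")
        return frac


@dataclass(frozen=True)
class CloneTruth:
    """True recombination of one simulated clone. ``junction_center`` is
    the 0-based midpoint of the N region in full_sequence (the deletion
    point itself when N is empty)."""

    clone_id: str
    v_name: str
    v_del: int
    n_region: str
    j_del: int
    j_name: str
    full_sequence: str
    junction_center: int
    d_name: str | None = None
    d5_del: int = 0
    d3_del: int = 0
    n2_region: str | None = None


@dataclass(frozen=True)
class ReadTruth:
    """Ground truth for one read. ``true_center`` is the junction center
    in the read's V→J orientation, or None when a fragment misses the
    junction. Flanks give the read context on each side of the center."""

    read_id: str
    clone_id: str
    strand: str
    true_center: int | None
    v_flank: int = 0
    j_flank: int = 0


def _random_gene(rng: np.random.Generator, lo: int, hi: int) -> str:
    length = int(rng.integers(lo, hi + 1))
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def make_synthetic_germline(
    params: SimParams, max_retries: int = 50
) -> GermlineDB:
    """Random uniform-ACGT germline gene sets with the configured length
    ranges, regenerated until the locus seed produces an index with zero
    AMBIGUOUS words (like the TRγ germline with the weight-10 seed)."""
    if params.n_v < 1 or params.n_j < 1:
        raise ValueError("need at least one V and one J gene")
    rng = np.random.default_rng(params.rng_seed)
    locus = params.locus
    for _ in range(max_retries):
        v = [
            GermlineGene(f"{locus}V{i + 1}*01", _random_gene(rng, *params.v_len_range), "V")
            for i in range(params.n_v)
        ]
        j = [
            GermlineGene(f"{locus}J{i + 1}*01", _random_gene(rng, *params.j_len_range), "J")
            for i in range(params.n_j)
        ]
        d = [
            GermlineGene(f"{locus}D{i + 1}*01", _random_gene(rng, *params.d_len_range), "D")
            for i in range(params.n_d)
        ]
        db = GermlineDB(locus=locus, v_genes=v, j_genes=j, d_genes=d)
        if KmerIndex.build(db).n_ambiguous == 0:
            return db
    raise RuntimeError(
        f"could not generate an ambiguity-free germline in {max_retries} tries"
    )


def simulate_recombination(
    db: GermlineDB, params: SimParams, rng: np.random.Generator, clone_id: str
) -> CloneTruth:
    """One random recombination: uniform gene choice, uniform junction
    deletions (resampled if they would exceed a short gene), uniform
    N-region length and content. VDJ loci get two N regions around a
    both-ends-trimmed D."""
    v = db.v_genes[int(rng.integers(len(db.v_genes)))]
    j = db.j_genes[int(rng.integers(len(db.j_genes)))]
    lo, hi = params.del_range

    def draw_del(limit: int) -> int:
        while True:
            d = int(rng.integers(lo, hi + 1))
            if d < limit:
                return d

    v_del = draw_del(len(v.sequence))
    j_del = draw_del(len(j.sequence))
    n_lo, n_hi = params.n_len_range
    n1 = "".join(
        _BASES[i] for i in rng.integers(0, 4, size=int(rng.integers(n_lo, n_hi + 1)))
    )

    d_name = None
    d5 = d3 = 0
    n2 = None
    if db.d_genes:
        d = db.d_genes[int(rng.integers(len(db.d_genes)))]
        d5 = draw_del(len(d.sequence))
        d3 = draw_del(len(d.sequence) - d5)
        d_name = d.name
        n2 = "".join(
            _BASES[i]
            for i in rng.integers(0, 4, size=int(rng.integers(n_lo, n_hi + 1)))
        )

    seg = Segmentation(
        v_name=v.name,
        v_del=v_del,
        n_region=n1,
        j_del=j_del,
        j_name=j.name,
        v_end=0,
        j_start=1,  # positions unused for reconstruction
        score=0,
        d_name=d_name,
        d5_del=d5,
        d3_del=d3,
        n1=n1 if d_name else None,
        n2=n2,
    )
    full = reconstruct_from_designation(seg, db)
    v_part = len(v.sequence) - v_del
    junction_len = len(full) - v_part - (len(j.sequence) - j_del)
    center = v_part + junction_len // 2
    return CloneTruth(
        clone_id=clone_id,
        v_name=v.name,
        v_del=v_del,
        n_region=n1,
        j_del=j_del,
        j_name=j.name,
        full_sequence=full,
        junction_center=center,
        d_name=d_name,
        d5_del=d5,
        d3_del=d3,
        n2_region=n2,
    )


def simulate_clones(
    db: GermlineDB, params: SimParams, rng: np.random.Generator | None = None
) -> list[CloneTruth]:
    """n_clones random recombinations, each detectable and distinct.

    A draw is rejected when its full sequence collides with an earlier
    clone, or when the error-free window heuristic (locus seed, default
    window length) fails on it or returns a window already owned by
    another clone. This mirrors real repertoire data, where a clone is by
    construction something the junction assay can see, and guarantees the
    error-free round trip: the pipeline on error-free reads recovers
    exactly n_clones windows with truth-equal counts.
    """
    from .windows import SegStatus, WindowParams, predict_window

    rng = rng or np.random.default_rng(params.rng_seed + 1)
    idx = KmerIndex.build(db)
    wparams = WindowParams(w=db.w)
    clones: list[CloneTruth] = []
    seen_seq: set[str] = set()
    seen_win: set[str] = set()
    attempts = 0
    while len(clones) < params.n_clones:
        attempts += 1
        if attempts > 200 * params.n_clones:
            raise RuntimeError("could not draw distinct detectable clones")
        c = simulate_recombination(db, params, rng, f"clone{len(clones) + 1:03d}")
        if c.full_sequence in seen_seq:
            continue
        hit, _ = predict_window(idx, c.clone_id, c.full_sequence, wparams)
        if hit.status is not SegStatus.SEGMENTED or hit.window in seen_win:
            continue
        seen_seq.add(c.full_sequence)
        seen_win.add(hit.window)
        clones.append(c)
    return clones


def _mutate(
    seq: str,
    center: int | None,
    params: SimParams,
    rng: np.random.Generator,
) -> tuple[str, int | None]:
    """Apply substitutions then homopolymer indels; substitutions never
    restore the original base and never move coordinates, indels at or
    before the junction shift the recorded center."""
    bases = list(seq)
    if params.p_sub > 0:
        hit = np.nonzero(rng.random(len(bases)) < params.p_sub)[0]
        for p in hit:
            old = bases[p]
            if old in _BASES:
                choices = [b for b in _BASES if b != old]
                bases[p] = choices[int(rng.integers(3))]
    if params.p_homo > 0:
        # find runs of identical bases of length >= 2 (post-substitution)
        runs = []
        i = 0
        while i < len(bases):
            jx = i
            while jx + 1 < len(bases) and bases[jx + 1] == bases[i]:
                jx += 1
            if jx > i:
                runs.append((i, jx))
            i = jx + 1
        # apply right-to-left so earlier coordinates stay valid
        for start, end in reversed(runs):
            if rng.random() >= params.p_homo:
                continue
            if rng.random() < 0.5:
                bases.insert(end, bases[start])
                if center is not None and end <= center:
                    center += 1
            else:
                del bases[end]
                if center is not None and end <= center:
                    center -= 1
    return "".join(bases), center


def generate_reads(
    clones: Sequence[CloneTruth],
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[str, str]], list[ReadTruth]]:
    """Draw reads from clones according to the abundance profile.

    Amplicon mode emits the full clone sequence; fragment mode a uniform
    random substring of the configured length (the truth center is None
    when the fragment misses the junction). Reads may be emitted on the
    reverse strand; ``true_center`` always refers to the V→J orientation.
    """
    rng = rng or np.random.default_rng(params.rng_seed + 2)
    frac = params.resolved_abundances()
    if len(frac) != len(clones):
        raise ValueError("abundance profile does not match clone count")
    reads: list[tuple[str, str]] = []
    truths: list[ReadTruth] = []
    picks = rng.choice(len(clones), size=params.n_reads, p=frac)
    for ridx, cidx in enumerate(picks):
        clone = clones[int(cidx)]
        full = clone.full_sequence
        if params.read_model == "amplicon":
            seq, center = full, clone.junction_center
        elif params.read_model == "fragment":
            L = params.fragment_length
            if L > len(full):
                raise ValueError(
                    f"fragment length {L} exceeds clone sequence length {len(full)}"
                )
            start = int(rng.integers(0, len(full) - L + 1))
            seq = full[start : start + L]
            c = clone.junction_center
            center = c - start if start <= c < start + L else None
        else:
            raise ValueError(f"unknown read model {params.read_model!r}")

        seq, center = _mutate(seq, center, params, rng)
        strand = "+"
        out_seq = seq
        if params.random_strand and rng.random() < 0.5:
            strand = "-"
            out_seq = reverse_complement(seq)
        read_id = f"read{ridx + 1:06d}"
        reads.append((read_id, out_seq))
        truths.append(
            ReadTruth(
                read_id=read_id,
                clone_id=clone.clone_id,
                strand=strand,
                true_center=center,
                v_flank=center if center is not None else 0,
                j_flank=(len(seq) - center) if center is not None else 0,
            )
        )
    return reads, truths


def simulate_dataset(params: SimParams):
    """Convenience end-to-end generator: germline, clones, reads, truth."""
    db = make_synthetic_germline(params)
    clones = simulate_clones(db, params)
    reads, truths = generate_reads(clones, params)
    return db, clones, reads, truths


# ---- plain-text writers (reads + truth sidecars) -----------------------


def write_reads_fasta(reads, path: str | Path) -> None:
    with open(path, "w") as out:
        for rid, seq in reads:
            out.write(f">{rid}\n{seq}\n")


def write_reads_fastq(reads, path: str | Path) -> None:
    with open(path, "w") as out:
        for rid, seq in reads:
            out.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_clone_truth(clones: Sequence[CloneTruth], path: str | Path) -> None:
    cols = (
        "clone_id\tv_name\tv_del\tn_region\tj_del\tj_name\t"
        "junction_center\tfull_sequence\n"
    )
    with open(path, "w") as out:
        out.write(cols)
        for c in clones:
            out.write(
                f"{c.clone_id}\t{c.v_name}\t{c.v_del}\t{c.n_region}\t"
                f"{c.j_del}\t{c.j_name}\t{c.junction_center}\t{c.full_sequence}\n"
            )


def write_read_truth(truths: Sequence[ReadTruth], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("read_id\tclone_id\tstrand\ttrue_center\tv_flank\tj_flank\n")
        for t in truths:
            c = "" if t.true_center is None else t.true_center
            out.write(
                f"{t.read_id}\t{t.clone_id}\t{t.strand}\t{c}\t"
                f"{t.v_flank}\t{t.j_flank}\n"
            )


def load_read_truth(path: str | Path) -> list[ReadTruth]:
    truths = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            rid, cid, strand, center, vf, jf = line.rstrip("\n").split("\t")
            truths.append(
                ReadTruth(
                    read_id=rid,
                    clone_id=cid,
                    strand=strand,
                    true_center=int(center) if center else None,
                    v_flank=int(vf),
                    j_flank=int(jf),
                )
            )
    return truths
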