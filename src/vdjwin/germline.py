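"""Germline gene sets, spaced seeds, and elementary sequence utilities.

A locus is described by its V, (optional) D, and J germline gene sets.
Recombined reads are analysed against a k-word index built from the V and
J sets only; the spaced seed controls which positions of a k+d-length
subsequence contribute to the indexed word.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

DNA_ALPHABET = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Default spaced seeds per locus. The weight-10 TRG seed is the canonical
#: "#####-#####"; for loci where only the seed weight is conventional
#: (12 for TRB/IGH, 13 for TRA) a single central don't-care is used by
#: analogy with the weight-10 pattern.
DEFAULT_SEEDS = {
    "TRG": "#####-#####",
    "TRB": "######-######",
    "IGH": "######-######",
    "TRA": "######-#######",
}

#: VDJ-recombining loci (carry D genes); everything else is VJ.
VDJ_LOCI = {"TRB", "TRD", "IGH"}

DEFAULT_W_VJ = 40
DEFAULT_W_VDJ = 60


class GermlineFormatError(ValueError):
    """Raised for malformed germline FASTA input."""


def reverse_complement(s: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N} (N maps to N)."""
    invalid = set(s) - DNA_ALPHABET
    if invalid:
        raise ValueError(f"non-DNA characters in sequence: {sorted(invalid)}")
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Seed:
    """A spaced-seed pattern over ``#`` (care) and ``-`` (don't-care).

    ``weight`` is the number of care positions (the k of the k-word);
    ``span`` is the total pattern length. A contiguous seed of weight k
    is simply k ``#`` characters.
    """

    pattern: str

    def __post_init__(self) -> None:
        p = self.pattern
        if not p or set(p) - {"#", "-"}:
            raise ValueError(f"seed pattern must be over {{#,-}}: {p!r}")
        if not (p.startswith("#") and p.endswith("#")):
            raise ValueError(f"seed pattern must begin and end with '#': {p!r}")

    @property
    def weight(self) -> int:
        return self.pattern.count("#")

    @property
    def span(self) -> int:
        return len(self.pattern)

    @property
    def offsets(self) -> tuple[int, ...]:
        """0-based positions of the care symbols within the span."""
        return tuple(i for i, c in enumerate(self.pattern) if c == "#")

    @classmethod
    def contiguous(cls, k: int) -> "Seed":
        return cls("#" * k)


def apply_seed(subsequence: str, seed: Seed) -> str:
    """Extract the seed-masked word: characters at '#' positions, in order."""
    if len(subsequence) != seed.span:
        raise ValueError(
            f"subsequence length {len(subsequence)} != seed span {seed.span}"
        )
    return "".join(subsequence[i] for i in seed.offsets)


@dataclass(frozen=True)
class GermlineGene:
    """One named germline gene sequence (e.g. ``TRGV5*01``)."""

    name: str
    sequence: str
    gene_type: str  # "V", "D" or "J"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene name must be non-empty")
        if not self.sequence:
            raise GermlineFormatError(f"gene {self.name!r} has an empty sequence")
        if self.gene_type not in ("V", "D", "J"):
            raise ValueError(f"gene_type must be V, D or J: {self.gene_type!r}")


def _open_maybe_gzip(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _name_from_header(description: str, name_field: int | None) -> str:
    """IMGT-style headers are '|'-separated with the gene name in field 2;
    plain FASTA headers use the first whitespace-delimited token."""
    if name_field is not None:
        return description.split("|")[name_field].strip()
    if "|" in description:
        return description.split("|")[1].strip()
    return description.split()[0]


def load_germline_fasta(
    path: str | Path,
    gene_type: str,
    name_field: int | None = None,
) -> list[GermlineGene]:
    """Load one germline gene set from a (possibly gzipped) FASTA file.

    Sequences are uppercased and U is mapped to T so the downstream index
    sees a single DNA alphabet. Gene names must be unique within the file.

    Parameters
    ----------
    path : FASTA path, plain or ``.gz``.
    gene_type : ``"V"``, ``"D"`` or ``"J"``.
    name_field : optional 0-based '|'-field index overriding the default
        header dialect detection.
    """
    path = Path(path)
    genes: list[GermlineGene] = []
    seen: set[str] = set()
    with _open_maybe_gzip(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            name = _name_from_header(record.description, name_field)
            seq = str(record.seq).upper().replace("U", "T")
            if not seq:
                raise GermlineFormatError(
                    f"{path}: record {name!r} has an empty sequence"
                )
            if name in seen:
                raise GermlineFormatError(f"{path}: duplicate gene name {name!r}")
            seen.add(name)
            genes.append(GermlineGene(name=name, sequence=seq, gene_type=gene_type))
    if not genes:
        raise GermlineFormatError(f"{path}: no FASTA records found")
    return genes


def write_germline_fasta(genes: Iterable[GermlineGene], path: str | Path) -> None:
    with open(path, "w") as out:
        for g in genes:
            out.write(f">{g.name}\n{g.sequence}\n")


@dataclass
class GermlineDB:
    """Germline V/(D)/J gene sets for one locus, with its default seed
    and window length."""

    locus: str
    v_genes: list[GermlineGene]
    j_genes: list[GermlineGene]
    d_genes: list[GermlineGene] = field(default_factory=list)
    seed: Seed | None = None
    w: int | None = None

    def __post_init__(self) -> None:
        if not self.v_genes or not self.j_genes:
            raise ValueError("a germline database needs at least one V and one J gene")
        if self.seed is None:
            self.seed = Seed(DEFAULT_SEEDS.get(self.locus, "#####-#####"))
        if self.w is None:
            self.w = DEFAULT_W_VDJ if self.is_vdj else DEFAULT_W_VJ

    @property
    def is_vdj(self) -> bool:
        return bool(self.d_genes)

    @property
    def total_size_r(self) -> int:
        """Total germline size r: summed length of all gene sequences."""
        return sum(
            len(g.sequence) for g in self.v_genes + self.d_genes + self.j_genes
        )

    def gene(self, name: str) -> GermlineGene:
        for g in self.v_genes + self.d_genes + self.j_genes:
            if g.name == name:
                return g
        raise KeyError(f"unknown germline gene {name!r} in locus {self.locus}")


def load_germline_config(path: str | Path) -> GermlineDB:
    """Build a GermlineDB from a YAML run configuration.

    Expected keys: ``locus``, ``v``, ``j``, optional ``d``, ``seed``
    (pattern string) and ``w``; file paths are resolved relative to the
    YAML file's directory.
    """
    import yaml

    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    base = path.parent

    def resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    return GermlineDB(
        locus=cfg.get("locus", "TRG"),
        v_genes=load_germline_fasta(resolve(cfg["v"]), "V"),
        j_genes=load_germline_fasta(resolve(cfg["j"]), "J"),
        d_genes=(
            load_germline_fasta(resolve(cfg["d"]), "D") if cfg.get("d") else []
        ),
        seed=Seed(cfg["seed"]) if cfg.get("seed") else None,
        w=cfg.get("w"),
    )
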