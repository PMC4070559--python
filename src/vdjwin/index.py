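"""Labeled k-word index over germline V and J genes.

Every seed-masked k-word occurring in a forward-strand germline V (resp. J)
gene is labeled V (resp. J); words occurring in both sets are AMBIGUOUS.
This index is the heuristic's only germline knowledge: reads are scanned
against it without any alignment. For small k the index is a flat table of
4^k labels; for larger k a hash table is used — both answer queries
identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .germline import GermlineDB, Seed, apply_seed, reverse_complement

# Label codes
NONE = 0
V = 1
J = 2
AMBIGUOUS = 3

LABEL_NAMES = {NONE: "NONE", V: "V", J: "J", AMBIGUOUS: "AMBIGUOUS"}

#: weight above which the index switches from a flat 4^k table to a hash
FLAT_WEIGHT_MAX = 12

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _ENCODE[_b] = _i


def _encode(seq: str) -> np.ndarray:
    """Map a DNA string to codes A=0 C=1 G=2 T=3, anything else 4."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _masked_codes(enc: np.ndarray, offsets: tuple[int, ...], span: int):
    """Integer codes of the seed-masked words at every start position.

    Returns (codes, valid) arrays of length len(enc) - span + 1; positions
    whose masked word touches a non-ACGT base are flagged invalid.
    """
    n = len(enc) - span + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    codes = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for o in offsets:
        digit = enc[o : o + n].astype(np.int64)
        valid &= digit < 4
        codes = codes * 4 + digit
    return np.where(valid, codes, 0), valid


class Hit(NamedTuple):
    """One classified k-word occurrence in a read."""

    position: int  # 0-based start of the word's span
    label: str  # "V", "J" or "AMBIGUOUS"
    strand: str  # "+", "-" or "conflict"


@dataclass
class KmerIndex:
    seed: Seed
    storage_mode: str  # "flat" or "hash"
    _flat: np.ndarray | None = None
    _hash: dict | None = None

    # ---- construction -------------------------------------------------

    @classmethod
    def build(
        cls,
        db: GermlineDB,
        seed: Seed | None = None,
        storage_mode: str | None = None,
    ) -> "KmerIndex":
        """Index every masked k-word of the forward-strand V and J genes.

        D genes are never indexed. Words containing N are skipped. Raises
        if either gene set contributes no word at this seed (the locus is
        unusable with it). ``storage_mode`` forces "flat" or "hash";
        by default flat is used up to weight ``FLAT_WEIGHT_MAX``.
        """
        seed = seed or db.seed
        v_codes = _gene_set_codes(db.v_genes, seed)
        j_codes = _gene_set_codes(db.j_genes, seed)
        if not v_codes or not j_codes:
            which = "V" if not v_codes else "J"
            raise ValueError(
                f"no indexable {which} word at seed {seed.pattern!r}; "
                "germline genes shorter than the seed span?"
            )
        mode = storage_mode or (
            "flat" if seed.weight <= FLAT_WEIGHT_MAX else "hash"
        )
        if mode not in ("flat", "hash"):
            raise ValueError(f"unknown storage mode {mode!r}")
        idx = cls(seed=seed, storage_mode=mode)
        if mode == "flat":
            table = np.zeros(4**seed.weight, dtype=np.uint8)
            table[list(v_codes)] = V
            table[list(j_codes - v_codes)] = J
            table[list(v_codes & j_codes)] = AMBIGUOUS
            idx._flat = table
        else:
            h = {c: V for c in v_codes}
            for c in j_codes:
                h[c] = AMBIGUOUS if c in v_codes else J
            idx._hash = h
        return idx

    # ---- queries ------------------------------------------------------

    @property
    def n_ambiguous(self) -> int:
        if self._flat is not None:
            return int(np.count_nonzero(self._flat == AMBIGUOUS))
        return sum(1 for v in self._hash.values() if v == AMBIGUOUS)

    def _lookup_codes(self, codes: np.ndarray, valid: np.ndarray) -> np.ndarray:
        if self._flat is not None:
            labels = self._flat[codes]
        else:
            h = self._hash
            labels = np.fromiter(
                (h.get(int(c), NONE) for c in codes), dtype=np.uint8, count=len(codes)
            )
        labels[~valid] = NONE
        return labels

    def label_of(self, masked_word: str) -> int:
        """Label of one already-masked word (length = seed weight)."""
        if len(masked_word) != self.seed.weight:
            raise ValueError("masked word length must equal the seed weight")
        enc = _encode(masked_word)
        if (enc >= 4).any():
            return NONE
        code = 0
        for d in enc:
            code = code * 4 + int(d)
        if self._flat is not None:
            return int(self._flat[code])
        return self._hash.get(code, NONE)

    def scan_arrays(self, read: str) -> tuple[np.ndarray, np.ndarray]:
        """Forward and reverse-complement labels at every start position.

        Returns ``(f, r)`` uint8 arrays of length ``len(read) - span + 1``:
        ``f[p]`` labels the masked word of ``read[p:p+span]``, ``r[p]`` that
        of its reverse complement.
        """
        span = self.seed.span
        offsets = self.seed.offsets
        enc = _encode(read)
        fcodes, fvalid = _masked_codes(enc, offsets, span)
        if len(fcodes) == 0:
            return fcodes.astype(np.uint8), fcodes.astype(np.uint8)
        # Masked rc word char i is the complement of the window base at
        # span-1 - offsets[i]; complement of code c<4 is 3-c.
        comp = np.where(enc < 4, 3 - enc, 4).astype(np.uint8)
        rc_offsets = tuple(span - 1 - o for o in offsets)
        rcodes, rvalid = _masked_codes(comp, rc_offsets, span)
        return self._lookup_codes(fcodes, fvalid), self._lookup_codes(rcodes, rvalid)

    def classify_word(self, word: str) -> tuple[str, str]:
        """Classify one raw span-length subsequence: (label, strand).

        The word and its reverse complement are both looked up; a single
        non-NONE answer fixes the strand, two answers conflict.
        """
        if len(word) != self.seed.span:
            raise ValueError("word length must equal the seed span")
        f = self.label_of(apply_seed(word, self.seed))
        r = self.label_of(apply_seed(reverse_complement(word), self.seed))
        if f != NONE and r != NONE:
            return LABEL_NAMES[AMBIGUOUS], "conflict"
        if f != NONE:
            return LABEL_NAMES[f], "+"
        if r != NONE:
            return LABEL_NAMES[r], "-"
        return LABEL_NAMES[NONE], "+"

    def scan_sequence(self, read: str) -> list[Hit]:
        """Classify every k-word of a read; NONE positions are omitted.

        AMBIGUOUS labels and strand conflicts are retained but flagged so
        that downstream strand/boundary decisions can exclude them.
        """
        f, r = self.scan_arrays(read)
        hits: list[Hit] = []
        for p in np.nonzero((f > 0) | (r > 0))[0]:
            fl, rl = int(f[p]), int(r[p])
            if fl and rl:
                hits.append(Hit(int(p), LABEL_NAMES[AMBIGUOUS], "conflict"))
            elif fl:
                hits.append(Hit(int(p), LABEL_NAMES[fl], "+"))
            else:
                hits.append(Hit(int(p), LABEL_NAMES[rl], "-"))
        return hits

    # ---- persistence (optional; rebuilding takes seconds) -------------

    def save(self, path) -> None:
        if self._flat is not None:
            v = np.nonzero(self._flat == V)[0]
            j = np.nonzero(self._flat == J)[0]
            a = np.nonzero(self._flat == AMBIGUOUS)[0]
            entries = {
                "V": v.tolist(),
                "J": j.tolist(),
                "AMBIGUOUS": a.tolist(),
            }
        else:
            entries = {"V": [], "J": [], "AMBIGUOUS": []}
            for c, lab in self._hash.items():
                entries[LABEL_NAMES[lab]].append(c)
        with open(path, "w") as fh:
            json.dump(
                {
                    "seed": self.seed.pattern,
                    "storage_mode": self.storage_mode,
                    "entries": entries,
                },
                fh,
            )

    @classmethod
    def load(cls, path) -> "KmerIndex":
        with open(path) as fh:
            data = json.load(fh)
        seed = Seed(data["seed"])
        mode = data["storage_mode"]
        idx = cls(seed=seed, storage_mode=mode)
        entries = data["entries"]
        if mode == "flat":
            table = np.zeros(4**seed.weight, dtype=np.uint8)
            table[entries["V"]] = V
            table[entries["J"]] = J
            table[entries["AMBIGUOUS"]] = AMBIGUOUS
            idx._flat = table
        else:
            h = {}
            for name, lab in (("V", V), ("J", J), ("AMBIGUOUS", AMBIGUOUS)):
                for c in entries[name]:
                    h[int(c)] = lab
            idx._hash = h
        return idx


def _gene_set_codes(genes, seed: Seed) -> set[int]:
    codes: set[int] = set()
    for g in genes:
        c, valid = _masked_codes(_encode(g.sequence), seed.offsets, seed.span)
        codes.update(int(x) for x in c[valid])
    return codes


def build_index(
    db: GermlineDB, seed: Seed | None = None, storage_mode: str | None = None
) -> KmerIndex:
    """Convenience wrapper for :meth:`KmerIndex.build`."""
    return KmerIndex.build(db, seed, storage_mode)
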