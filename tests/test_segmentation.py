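"""V(D)J designation: DP alignments checked against a Biopython
overlap-alignment oracle, plus round-trip reconstruction."""

import numpy as np
import pytest
from Bio import Align

from vdjwin import (
    AlignmentScoring,
    GermlineDB,
    GermlineGene,
    Segmentation,
    SimParams,
    best_gene_alignment,
    format_designation,
    make_synthetic_germline,
    reconstruct_from_designation,
    segment_sequence,
    simulate_clones,
)

BASES = "ACGT"
SCORING = AlignmentScoring()


def local_aligner():
    """Independent scorer: maximizing the semi-global score over both the
    end position in seq and the gene trim, with free starts in both, is
    exactly a Smith-Waterman local alignment."""
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = SCORING.match
    a.mismatch_score = SCORING.mismatch
    a.open_gap_score = a.extend_gap_score = SCORING.gap
    return a


def oracle_best_total(seq, v_genes, j_genes):
    """Brute force over every split point and gene: best V score on the
    left part plus best J score on the right part."""
    aligner = local_aligner()
    best = None
    for x in range(len(seq) - 1):
        left, right = seq[: x + 1], seq[x + 1 :]
        v = max(aligner.score(left, g.sequence) for g in v_genes)
        j = max(aligner.score(right, g.sequence) for g in j_genes)
        if best is None or v + j > best:
            best = v + j
    return best


@pytest.fixture(scope="module")
def toy_vj_db():
    return GermlineDB(
        locus="TOY",
        v_genes=[GermlineGene("V1", "AAAACCCC", "V")],
        j_genes=[GermlineGene("J1", "GGGGTTTT", "J")],
    )


class TestBestGeneAlignment:
    def test_trimmed_v_prefix(self, toy_vj_db):
        """'AAAACC' of the V gene matches seq[0:6]: ends at e=5 with two
        3' bases trimmed, score 6 matches * 2."""
        gene, e, dels, score = best_gene_alignment(
            "AAAACCTAGGGGTTTT", toy_vj_db.v_genes, "end_of_V", SCORING
        )
        assert (gene.name, e, dels, score) == ("V1", 5, 2, 12)

    def test_intact_gene_full_score(self, toy_vj_db):
        gene, e, dels, score = best_gene_alignment(
            "TTAAAACCCCGG", toy_vj_db.v_genes, "end_of_V", SCORING
        )
        assert dels == 0
        assert score == 2 * len(gene.sequence)
        assert e == 9

    def test_j_side_mirrored(self, toy_vj_db):
        gene, s, dels, score = best_gene_alignment(
            "AAAACCTAGGGGTTTT", toy_vj_db.j_genes, "start_of_J", SCORING
        )
        assert (gene.name, s, dels, score) == ("J1", 8, 0, 16)

    def test_empty_gene_list_is_error(self):
        with pytest.raises(ValueError):
            best_gene_alignment("ACGT", [], "end_of_V", SCORING)

    def test_score_matches_overlap_oracle(self):
        """Best end_of_V score over all e equals the all-ends-free
        alignment score of the gene against the sequence."""
        rng = np.random.default_rng(31)
        aligner = local_aligner()
        for _ in range(200):
            seq = "".join(BASES[b] for b in rng.integers(0, 4, rng.integers(15, 40)))
            gene = GermlineGene(
                "g", "".join(BASES[b] for b in rng.integers(0, 4, rng.integers(8, 25))), "V"
            )
            # embed a corrupted copy so the best alignment is non-trivial
            seq = gene.sequence[: rng.integers(4, len(gene.sequence))] + seq
            _, _, _, score = best_gene_alignment(seq, [gene], "end_of_V", SCORING)
            assert score == aligner.score(seq, gene.sequence)


class TestSegmentSequence:
    def test_worked_example(self, toy_vj_db):
        seg = segment_sequence("AAAACCTAGGGGTTTT", toy_vj_db, SCORING)
        assert seg is not None
        assert (seg.v_name, seg.v_del, seg.n_region, seg.j_del, seg.j_name) == (
            "V1",
            2,
            "TA",
            0,
            "J1",
        )
        assert (seg.v_end, seg.j_start) == (5, 8)

    def test_exact_vj_concatenation(self, toy_vj_db):
        seg = segment_sequence("AAAACCCCGGGGTTTT", toy_vj_db, SCORING)
        assert (seg.v_del, seg.n_region, seg.j_del) == (0, "", 0)

    def test_unalignable_sequence_returns_none(self, toy_vj_db):
        assert segment_sequence("AC" * 10, toy_vj_db, SCORING) is None

    def test_score_equals_brute_force_oracle(self):
        """DP total equals enumeration over (gene, split, trims) on random
        small recombination-like instances."""
        rng = np.random.default_rng(77)
        scoring = AlignmentScoring(min_score=4)
        for _ in range(150):
            v_genes = [
                GermlineGene(f"V{i}", "".join(BASES[b] for b in rng.integers(0, 4, rng.integers(12, 30))), "V")
                for i in range(rng.integers(1, 4))
            ]
            j_genes = [
                GermlineGene(f"J{i}", "".join(BASES[b] for b in rng.integers(0, 4, rng.integers(12, 30))), "J")
                for i in range(rng.integers(1, 4))
            ]
            db = GermlineDB(locus="RND", v_genes=v_genes, j_genes=j_genes)
            v = v_genes[rng.integers(len(v_genes))].sequence
            j = j_genes[rng.integers(len(j_genes))].sequence
            n = "".join(BASES[b] for b in rng.integers(0, 4, rng.integers(0, 6)))
            seq = list(v[: len(v) - rng.integers(0, 4)] + n + j[rng.integers(0, 4):])
            for p in rng.integers(0, len(seq), size=2):  # sprinkle mutations
                seq[p] = BASES[rng.integers(4)]
            seq = "".join(seq)
            seg = segment_sequence(seq, db, scoring)
            assert seg is not None
            assert seg.score == oracle_best_total(seq, v_genes, j_genes)

    def test_roundtrip_on_error_free_clones(self):
        """Designating a true clone sequence and reconstructing from the
        designation must reproduce the sequence byte-exactly (deletion/N
        attribution may differ when junction bases coincide with germline
        ends, but the reconstruction cannot)."""
        params = SimParams(rng_seed=29, n_clones=30, abundances=[1 / 30] * 30)
        db = make_synthetic_germline(params)
        clones = simulate_clones(db, params)
        for clone in clones:
            seg = segment_sequence(clone.full_sequence, db, SCORING)
            assert seg is not None
            assert reconstruct_from_designation(seg, db) == clone.full_sequence


class TestDesignationFormat:
    @pytest.mark.parametrize(
        "fields,expected",
        [
            (("TRGV5*01", 5, "CC", 0, "TRGJ1*02"), "TRGV5*01 -5/CC/0 TRGJ1*02"),
            (
                ("TRGV10*02", 5, "AGAC", 3, "TRGJP1*01"),
                "TRGV10*02 -5/AGAC/-3 TRGJP1*01",
            ),
            (("TRGV10*02", 4, "", 0, "TRGJP1*01"), "TRGV10*02 -4//0 TRGJP1*01"),
        ],
    )
    def test_printed_designations(self, fields, expected):
        v, vd, n, jd, j = fields
        seg = Segmentation(
            v_name=v, v_del=vd, n_region=n, j_del=jd, j_name=j,
            v_end=10, j_start=11 + len(n), score=0,
        )
        assert format_designation(seg) == expected


class TestReconstruct:
    def test_vj_with_n(self, toy_vj_db):
        seg = Segmentation(
            v_name="V1", v_del=2, n_region="TA", j_del=0, j_name="J1",
            v_end=5, j_start=8, score=0,
        )
        assert reconstruct_from_designation(seg, toy_vj_db) == "AAAACCTAGGGGTTTT"

    def test_plain_concatenation(self, toy_vj_db):
        seg = Segmentation(
            v_name="V1", v_del=0, n_region="", j_del=0, j_name="J1",
            v_end=7, j_start=8, score=0,
        )
        assert reconstruct_from_designation(seg, toy_vj_db) == "AAAACCCCGGGGTTTT"

    def test_overlong_deletion_is_error(self, toy_vj_db):
        seg = Segmentation(
            v_name="V1", v_del=9, n_region="", j_del=0, j_name="J1",
            v_end=0, j_start=1, score=0,
        )
        with pytest.raises(ValueError):
            reconstruct_from_designation(seg, toy_vj_db)

    def test_unknown_gene_is_error(self, toy_vj_db):
        seg = Segmentation(
            v_name="nope", v_del=0, n_region="", j_del=0, j_name="J1",
            v_end=0, j_start=1, score=0,
        )
        with pytest.raises(KeyError):
            reconstruct_from_designation(seg, toy_vj_db)


class TestVdjLocus:
    def test_d_gene_placed_inside_n_region(self):
        rng = np.random.default_rng(41)
        v = "".join(BASES[b] for b in rng.integers(0, 4, 60))
        d = "".join(BASES[b] for b in rng.integers(0, 4, 16))
        j = "".join(BASES[b] for b in rng.integers(0, 4, 40))
        db = GermlineDB(
            locus="TRB",
            v_genes=[GermlineGene("V1", v, "V")],
            j_genes=[GermlineGene("J1", j, "J")],
            d_genes=[GermlineGene("D1", d, "D")],
        )
        seq = v + "AC" + d + "GT" + j
        seg = segment_sequence(seq, db, SCORING)
        assert seg is not None
        assert seg.d_name == "D1"
        assert seg.n1 == "AC" and seg.n2 == "GT"
        assert (seg.d5_del, seg.d3_del) == (0, 0)
        assert reconstruct_from_designation(seg, db) == seq
        assert " D1 " in format_designation(seg)
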