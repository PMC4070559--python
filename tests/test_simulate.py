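"""Simulator: determinism, parameter ranges, error models, ground truth."""

import numpy as np
import pytest

from vdjwin import (
    KmerIndex,
    RunConfig,
    SegStatus,
    SimParams,
    WindowParams,
    generate_reads,
    make_synthetic_germline,
    predict_window,
    run_pipeline,
    simulate_clones,
    simulate_dataset,
    simulate_recombination,
)
from vdjwin.simulate import write_reads_fasta


class TestSyntheticGermline:
    def test_gene_counts_and_length_ranges(self):
        db = make_synthetic_germline(SimParams(rng_seed=1))
        assert len(db.v_genes) == 5 and len(db.j_genes) == 3
        assert all(250 <= len(g.sequence) <= 310 for g in db.v_genes)
        assert all(40 <= len(g.sequence) <= 70 for g in db.j_genes)

    def test_no_ambiguous_words_under_locus_seed(self):
        db = make_synthetic_germline(SimParams(rng_seed=2))
        assert KmerIndex.build(db).n_ambiguous == 0

    def test_deterministic_given_seed(self):
        a = make_synthetic_germline(SimParams(rng_seed=3))
        b = make_synthetic_germline(SimParams(rng_seed=3))
        assert [(g.name, g.sequence) for g in a.v_genes + a.j_genes] == [
            (g.name, g.sequence) for g in b.v_genes + b.j_genes
        ]

    def test_zero_v_genes_is_error(self):
        with pytest.raises(ValueError):
            make_synthetic_germline(SimParams(n_v=0))

    def test_vdj_locus_gets_d_genes(self):
        db = make_synthetic_germline(SimParams(rng_seed=4, n_d=2, locus="TRB"))
        assert len(db.d_genes) == 2
        assert all(10 <= len(g.sequence) <= 35 for g in db.d_genes)
        assert db.w == 60  # VDJ default window


class TestRecombination:
    def test_deletion_and_n_length_ranges(self):
        params = SimParams(rng_seed=5)
        db = make_synthetic_germline(params)
        rng = np.random.default_rng(6)
        for i in range(1000):
            c = simulate_recombination(db, params, rng, f"c{i}")
            assert 0 <= c.v_del <= 8 and 0 <= c.j_del <= 8
            assert 0 <= len(c.n_region) <= 10

    def test_sequence_is_trimmed_concatenation(self):
        params = SimParams(rng_seed=7)
        db = make_synthetic_germline(params)
        rng = np.random.default_rng(8)
        c = simulate_recombination(db, params, rng, "c")
        v = db.gene(c.v_name).sequence
        j = db.gene(c.j_name).sequence
        expected = v[: len(v) - c.v_del] + c.n_region + j[c.j_del :]
        assert c.full_sequence == expected
        v_part = len(v) - c.v_del
        assert c.junction_center == v_part + len(c.n_region) // 2

    def test_vdj_structure(self):
        params = SimParams(rng_seed=9, n_d=2, locus="TRB")
        db = make_synthetic_germline(params)
        rng = np.random.default_rng(10)
        c = simulate_recombination(db, params, rng, "c")
        assert c.d_name is not None
        d = db.gene(c.d_name).sequence
        d_part = d[c.d5_del : len(d) - c.d3_del]
        assert d_part in c.full_sequence

    def test_distinct_detectable_clones(self):
        params = SimParams(rng_seed=11, n_clones=20)
        db = make_synthetic_germline(params)
        clones = simulate_clones(db, params)
        assert len({c.full_sequence for c in clones}) == 20
        idx = KmerIndex.build(db)
        wins = set()
        for c in clones:
            hit, _ = predict_window(idx, c.clone_id, c.full_sequence, WindowParams(w=db.w))
            assert hit.status is SegStatus.SEGMENTED
            wins.add(hit.window)
        assert len(wins) == 20


class TestGenerateReads:
    def test_error_free_amplicons_equal_clone_sequences(self):
        params = SimParams(rng_seed=12, n_reads=200, random_strand=False)
        db, clones, reads, truths = simulate_dataset(params)
        by_id = {c.clone_id: c for c in clones}
        for (rid, seq), t in zip(reads, truths):
            clone = by_id[t.clone_id]
            assert seq == clone.full_sequence
            assert t.true_center == clone.junction_center

    def test_byte_identical_outputs_for_same_seed(self, tmp_path):
        p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        for p in (p1, p2):
            _, _, reads, _ = simulate_dataset(SimParams(rng_seed=13, n_reads=100))
            write_reads_fasta(reads, p)
        assert p1.read_bytes() == p2.read_bytes()

    def test_substitution_rate_binomial(self):
        """Empirical substitution fraction within 5 binomial SD of p_sub
        over >= 1e5 simulated bases."""
        params = SimParams(rng_seed=14, n_reads=500, p_sub=0.06,
                           random_strand=False)
        db, clones, reads, truths = simulate_dataset(params)
        by_id = {c.clone_id: c for c in clones}
        n_sub = n_bases = 0
        for (rid, seq), t in zip(reads, truths):
            ref = by_id[t.clone_id].full_sequence
            n_bases += len(ref)
            n_sub += sum(a != b for a, b in zip(seq, ref))
        assert n_bases >= 100000
        p_hat = n_sub / n_bases
        sd = (0.06 * 0.94 / n_bases) ** 0.5
        assert abs(p_hat - 0.06) < 5 * sd

    def test_fragment_mode_lengths_and_truth(self):
        params = SimParams(
            rng_seed=15, n_reads=300, read_model="fragment", fragment_length=100
        )
        db, clones, reads, truths = simulate_dataset(params)
        assert all(len(seq) == 100 for _, seq in reads)
        missed = [t for t in truths if t.true_center is None]
        covered = [t for t in truths if t.true_center is not None]
        assert missed and covered  # both outcomes occur at L=100
        for t in covered:
            assert 0 <= t.true_center < 100

    def test_fragment_longer_than_clone_is_error(self):
        params = SimParams(rng_seed=16, read_model="fragment", fragment_length=10000)
        db = make_synthetic_germline(params)
        clones = simulate_clones(db, params)
        with pytest.raises(ValueError):
            generate_reads(clones, params)

    def test_abundance_fractions_within_4sd(self):
        fracs = [0.6, 0.25, 0.1, 0.05]
        params = SimParams(rng_seed=17, n_clones=4, abundances=fracs, n_reads=5000)
        db, clones, reads, truths = simulate_dataset(params)
        counts = {}
        for t in truths:
            counts[t.clone_id] = counts.get(t.clone_id, 0) + 1
        n = len(truths)
        for clone, f in zip(clones, fracs):
            sd = (f * (1 - f) / n) ** 0.5
            assert abs(counts.get(clone.clone_id, 0) / n - f) < 4 * sd


class TestErrorFreePipelineRecovery:
    def test_exact_clone_recovery(self):
        """Error-free reads: the pipeline finds exactly n_clones windows
        and per-clone read counts equal the simulated truth."""
        params = SimParams(
            rng_seed=18, n_clones=6, n_reads=600, abundances=[1 / 6] * 6
        )
        db, clones, reads, truths = simulate_dataset(params)
        report = run_pipeline(RunConfig(db=db), reads)
        assert len(report.full_table.clones) == 6
        truth_counts = {}
        for t in truths:
            truth_counts[t.clone_id] = truth_counts.get(t.clone_id, 0) + 1
        idx = KmerIndex.build(db)
        for c in clones:
            hit, _ = predict_window(idx, c.clone_id, c.full_sequence,
                                    WindowParams(w=db.w))
            match = [cl for cl in report.full_table.clones
                     if cl.seed_window == hit.window]
            assert len(match) == 1
            assert match[0].read_count == truth_counts[c.clone_id]
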