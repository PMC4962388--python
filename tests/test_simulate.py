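import io

import numpy as np
import pytest

import sctcr
from sctcr.mapping import PairBatch, write_fastq_pairs
from sctcr.simulate import (
    SimConfig,
    TruthRecord,
    evaluate_recovery,
    mix_with_background,
    ramp_error_profile,
    run_benchmark,
    simulate_chain,
    simulate_read_pairs,
)


class TestSimulateChain:
    def test_alpha_zero_insertion_is_pure_concatenation(self, refset):
        rng = np.random.default_rng(0)
        ch = simulate_chain(refset, "TRA", 0, rng)
        v = refset.get("TRA", "V", ch.v_gene).sequence
        j = refset.get("TRA", "J", ch.j_gene).sequence
        c = refset.get("TRA", "C", ch.c_gene).sequence
        assert ch.sequence == v + j + c
        assert len(ch.sequence) == len(v) + len(j) + len(c)

    def test_beta_insertions_at_both_junctions(self, refset):
        rng = np.random.default_rng(1)
        ch = simulate_chain(refset, "TRB", 9, rng)
        v = refset.get("TRB", "V", ch.v_gene).sequence
        d = refset.get("TRB", "D", ch.d_gene).sequence
        j = refset.get("TRB", "J", ch.j_gene).sequence
        c = refset.get("TRB", "C", ch.c_gene).sequence
        assert len(ch.inserted_vd) == 9 and len(ch.inserted_dj) == 9
        assert ch.sequence == v + ch.inserted_vd + d + ch.inserted_dj + j + c

    def test_deterministic_for_seed(self, refset):
        chains1 = [simulate_chain(refset, "TRB", 6, np.random.default_rng(42)) for _ in range(1)]
        chains2 = [simulate_chain(refset, "TRB", 6, np.random.default_rng(42)) for _ in range(1)]
        assert chains1[0] == chains2[0]

    def test_truth_junction_is_recorded_interval(self, refset):
        rng = np.random.default_rng(3)
        ch = simulate_chain(refset, "TRA", 6, rng)
        t = TruthRecord("c0", ch)
        lo, hi = t.junction_interval
        assert ch.sequence[lo:hi] == t.junction_nt
        j = refset.get("TRA", "J", ch.j_gene).sequence
        assert t.junction_nt == ch.inserted_vj + j


class TestSimulateReads:
    def test_pair_count_formula(self):
        rng = np.random.default_rng(0)
        template = "ACGT" * 150  # 600 bp
        cfg = SimConfig(read_len=100)
        pairs = simulate_read_pairs(template, cfg, 10, rng)
        assert len(pairs) == 30

    def test_zero_error_reads_are_template_substrings(self):
        rng = np.random.default_rng(1)
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        template = bases[rng.integers(0, 4, 700)].tobytes().decode()
        cfg = SimConfig(read_len=80, error_profile=np.zeros(80))
        from sctcr.mapping import revcomp

        for p in simulate_read_pairs(template, cfg, 20, rng):
            assert p.seq1 in template
            assert revcomp(p.seq2) in template

    def test_reads_match_recorded_placements_within_error_budget(self):
        """Each read differs from its source fragment by no more than a
        generous bound on the injected substitutions."""
        rng = np.random.default_rng(2)
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        template = bases[rng.integers(0, 4, 800)].tobytes().decode()
        rl = 100
        cfg = SimConfig(read_len=rl, error_profile=np.full(rl, 0.02))
        placements = []
        pairs = simulate_read_pairs(template, cfg, 20, rng, placements=placements)
        from sctcr.mapping import revcomp

        assert len(placements) == len(pairs)
        for p, (s, f) in zip(pairs, placements):
            m1_true = template[s : s + rl]
            m2_true = revcomp(template[s + f - rl : s + f])
            d1 = sum(a != b for a, b in zip(p.seq1, m1_true))
            d2 = sum(a != b for a, b in zip(p.seq2, m2_true))
            assert d1 <= 12 and d2 <= 12  # ~6x the expected 2 errors

    def test_realized_coverage_near_requested(self):
        rng = np.random.default_rng(3)
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        template = bases[rng.integers(0, 4, 900)].tobytes().decode()
        cfg = SimConfig(read_len=100)
        total_bases = 0
        reps = 50
        for _ in range(reps):
            pairs = simulate_read_pairs(template, cfg, 30, rng)
            total_bases += sum(len(p.seq1) + len(p.seq2) for p in pairs)
        realized = total_bases / reps / len(template)
        assert abs(realized - 30) / 30 < 0.1

    def test_template_shorter_than_read_raises(self):
        with pytest.raises(ValueError):
            simulate_read_pairs("ACGT", SimConfig(read_len=100), 10,
                                np.random.default_rng(0))


class TestMixing:
    def _tcr_pairs(self, n, rl=50):
        rng = np.random.default_rng(0)
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        return [
            sctcr.ReadPair(
                f"t{i}",
                bases[rng.integers(0, 4, rl)].tobytes().decode(),
                bases[rng.integers(0, 4, rl)].tobytes().decode(),
                "I" * rl,
                "I" * rl,
            )
            for i in range(n)
        ]

    def test_ratio_exact(self):
        tcr = self._tcr_pairs(30)
        cfg = SimConfig(read_len=50)
        pairs, manifest = mix_with_background(tcr, cfg, np.random.default_rng(1))
        n_bg = sum(1 for v in manifest.values() if v == "background")
        assert n_bg == 9970
        assert len(pairs) == 10000
        assert sum(1 for v in manifest.values() if v == "tcr") == 30

    def test_manifest_fraction(self):
        tcr = self._tcr_pairs(12)
        cfg = SimConfig(read_len=50)
        pairs, manifest = mix_with_background(tcr, cfg, np.random.default_rng(2))
        frac = sum(v == "tcr" for v in manifest.values()) / len(manifest)
        assert abs(frac - 0.003) < 1e-4

    def test_fixed_seed_byte_identical_fastq(self, tmp_path):
        tcr = self._tcr_pairs(5)
        cfg = SimConfig(read_len=50)
        outs = []
        for run in range(2):
            pairs, _ = mix_with_background(tcr, cfg, np.random.default_rng(7))
            r1, r2 = tmp_path / f"{run}_1.fq", tmp_path / f"{run}_2.fq"
            write_fastq_pairs(pairs, r1, r2)
            outs.append(r1.read_bytes() + r2.read_bytes())
        assert outs[0] == outs[1]

    def test_batch_and_list_paths_agree_on_membership(self):
        tcr = self._tcr_pairs(4)
        cfg = SimConfig(read_len=50)
        batch, manifest = mix_with_background(
            tcr, cfg, np.random.default_rng(3), as_batch=True
        )
        assert isinstance(batch, PairBatch)
        assert len(batch) == 4 + round(4 * 997 / 3)
        as_pairs = {p.read_id: p for p in batch.to_list()}
        for t in tcr:
            assert as_pairs[t.read_id].seq1 == t.seq1
            assert manifest[t.read_id] == "tcr"


class TestRecovery:
    def _truth(self, refset, seed=0):
        rng = np.random.default_rng(seed)
        ch = simulate_chain(refset, "TRA", 6, rng)
        return TruthRecord("c", ch)

    def _exact_chain(self, refset, truth):
        from sctcr.assembly import ClosedChain, annotate_chain

        ch = truth.chain
        lo, hi = truth.junction_interval
        chain = ClosedChain(
            "TRA", ch.sequence, ch.v_gene, ch.c_gene, (lo - 3, hi + 3), 50.0
        )
        return chain, annotate_chain(chain, refset)

    def test_exact_truth_chain_recovered(self, refset):
        truth = self._truth(refset)
        chain, ann = self._exact_chain(refset, truth)
        assert evaluate_recovery([chain], [ann], truth, refset).recovered

    def test_wrong_v_assignment_not_recovered(self, refset):
        truth = self._truth(refset, seed=1)
        chain, ann = self._exact_chain(refset, truth)
        wrong = [g.gene_name for g in refset.genes("TRA", "V")
                 if g.gene_name != truth.chain.v_gene][0]
        chain.v_gene = wrong
        res = evaluate_recovery([chain], [ann], truth, refset)
        assert not res.recovered
        assert "wrong_genes" in res.reasons

    def test_empty_output_not_recovered(self, refset):
        truth = self._truth(refset, seed=2)
        res = evaluate_recovery([], [], truth, refset)
        assert not res.recovered
        assert res.reasons == ["no_chain"]


class TestBenchmark:
    def test_short_reads_recover_at_high_coverage(self, refset):
        """25 bp reads (closure overlap auto-reduced) still recover chains
        at 100x with the default error ramp."""
        cfg = SimConfig(seed=77, n_chain_pairs=2, insertion_lengths=(0, 6))
        df = run_benchmark(refset, cfg, read_lens=(25,), coverages=(100,))
        assert (df.fraction > 0).all(), df.to_string()

    def test_same_seed_identical_table(self, refset):
        cfg = SimConfig(seed=5, error_profile=np.zeros(100), n_chain_pairs=1,
                        insertion_lengths=(0, 6))
        df1 = run_benchmark(refset, cfg, read_lens=(100,), coverages=(50,))
        df2 = run_benchmark(refset, cfg, read_lens=(100,), coverages=(50,))
        assert df1.equals(df2)
        assert set(df1.columns) == {"read_len", "coverage", "locus", "n",
                                    "n_recovered", "fraction"}
        assert ((df1.fraction >= 0) & (df1.fraction <= 1)).all()


def test_ramp_profile_mean_rescaling():
    p = ramp_error_profile(100, mean=0.01)
    assert p.mean() == pytest.approx(0.01)
    assert p[0] < p[-1]
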