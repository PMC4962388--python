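import numpy as np

import sctcr
from sctcr.assembly import (
    REJECTION_REASONS,
    ClosedChain,
    GapFillConfig,
    Rejection,
    annotate_chain,
    build_scaffolds,
    fill_gap,
    write_chain_outputs,
)
from sctcr.consensus import ConsensusContig
from sctcr.reference import GapEstimate
from sctcr.simulate import SimConfig, simulate_read_pairs


def _contig(seq, name="TRBVs1", class_key="TRBV", cov=50.0):
    return ConsensusContig(name, class_key, seq, cov, int(cov))


class TestScaffolds:
    def test_construction_example(self):
        v = _contig("AAAAAAAAAA", "V1")
        c = _contig("TTTTTTTTTT", "C1", "TRBC")
        (sc,) = build_scaffolds([v], [c], "TRB", GapEstimate(4, 2, 6), end_trim=3)
        assert sc.sequence == "AAAAAAA" + "NNNN" + "TTTTTTT"
        assert sc.v_flank == "AAAAAAA"
        assert sc.c_flank == "TTTTTTT"
        assert sc.gap_interval == (7, 11)

    def test_cross_product_counts_and_order(self):
        vs = [_contig("A" * 30, f"V{i}") for i in (2, 1)]
        cs = [_contig("T" * 30, f"C{j}", "TRBC") for j in (2, 1)]
        out = build_scaffolds(vs, cs, "TRB", GapEstimate(10, 5, 15))
        assert len(out) == 4
        assert [s.scaffold_id for s in out] == ["V1~C1", "V1~C2", "V2~C1", "V2~C2"]
        out3 = build_scaffolds(vs + [_contig("G" * 30, "V3")], cs[:1], "TRB",
                               GapEstimate(10, 5, 15))
        assert len(out3) == 3

    def test_empty_lists_give_empty_result(self):
        assert build_scaffolds([], [_contig("T" * 30)], "TRB", GapEstimate(10, 5, 15)) == []


def _chain_reads(chain_seq, read_len=100, coverage=60, seed=0):
    """Error-free pairs tiling a chain."""
    rng = np.random.default_rng(seed)
    cfg = SimConfig(read_len=read_len, error_profile=np.zeros(read_len))
    return simulate_read_pairs(chain_seq, cfg, coverage, rng)


def _rand_seq(rng, n):
    return np.frombuffer(b"ACGT", dtype=np.uint8)[rng.integers(0, 4, n)].tobytes().decode()


class TestFillGap:
    def _setup(self, junction, seed=1, v_len=320, c_len=420, gap_mean=None):
        rng = np.random.default_rng(seed)
        v, c = _rand_seq(rng, v_len), _rand_seq(rng, c_len)
        chain = v + junction + c
        v_contig = _contig(v, "Vx", "TRBV")
        c_contig = _contig(c, "Cx", "TRBC")
        mean = gap_mean if gap_mean is not None else max(len(junction), 1)
        gap = GapEstimate.from_mean(mean)
        (sc,) = build_scaffolds([v_contig], [c_contig], "TRB", gap)
        return sc, chain, v, c

    def test_recovers_known_junction_exactly(self):
        rng = np.random.default_rng(2)
        junction = _rand_seq(rng, 60)
        sc, chain, v, c = self._setup(junction, seed=3)
        pairs = _chain_reads(chain, coverage=50)
        cfg = GapFillConfig(insert_size_mean=300)
        out = fill_gap(sc, pairs, cfg)
        assert isinstance(out, ClosedChain)
        assert out.sequence == chain
        assert out.junction_nt == v[-3:] + junction + c[:3]

    def test_degenerate_zero_gap(self):
        """Flanks directly adjacent in truth: the closed junction is exactly
        the six trimmed bases."""
        sc, chain, v, c = self._setup("", seed=4, gap_mean=0)
        assert "N" not in sc.sequence
        pairs = _chain_reads(chain, coverage=60)
        out = fill_gap(sc, pairs, GapFillConfig(insert_size_mean=300))
        assert isinstance(out, ClosedChain)
        assert out.junction_nt == v[-3:] + c[:3]

    def test_no_pairs_is_no_candidates(self):
        sc, *_ = self._setup("ACGTACGTAA")
        out = fill_gap(sc, [], GapFillConfig(insert_size_mean=300))
        assert isinstance(out, Rejection)
        assert out.reason == "no_candidates"

    def test_junction_outside_band_rejected(self):
        rng = np.random.default_rng(5)
        junction = _rand_seq(rng, 55)
        # estimate says ~20 bp: realized 61 >> 1.5*20 + 6
        sc, chain, *_ = self._setup(junction, seed=6, gap_mean=20)
        pairs = _chain_reads(chain, coverage=60)
        out = fill_gap(sc, pairs, GapFillConfig(insert_size_mean=300))
        assert isinstance(out, Rejection)
        assert out.reason in ("gap_length_out_of_tolerance", "no_closure")

    def test_rejection_reasons_are_exhaustive(self):
        sc, chain, *_ = self._setup("ACGTACGTACGTACGTAC")
        for pairs in ([], _chain_reads(chain, coverage=3)):
            out = fill_gap(sc, pairs, GapFillConfig(insert_size_mean=300))
            if isinstance(out, Rejection):
                assert out.reason in REJECTION_REASONS

    def test_chain_contains_trimmed_contig_flanks(self):
        rng = np.random.default_rng(7)
        junction = _rand_seq(rng, 58)
        sc, chain, v, c = self._setup(junction, seed=8)
        out = fill_gap(sc, _chain_reads(chain, coverage=50), GapFillConfig(insert_size_mean=300))
        assert isinstance(out, ClosedChain)
        assert out.sequence.startswith(v[:-3])
        assert out.sequence.endswith(c[3:])

    def test_relaxing_thresholds_preserves_closure(self):
        """Lowering base_agreement_ratio or min_overlap never turns a closed
        gap into a rejection on identical input."""
        rng = np.random.default_rng(9)
        junction = _rand_seq(rng, 60)
        sc, chain, *_ = self._setup(junction, seed=10)
        pairs = _chain_reads(chain, coverage=50)
        strict = GapFillConfig(insert_size_mean=300)
        out = fill_gap(sc, pairs, strict)
        assert isinstance(out, ClosedChain)
        for relaxed in (
            GapFillConfig(insert_size_mean=300, base_agreement_ratio=0.6),
            GapFillConfig(insert_size_mean=300, min_overlap=14),
        ):
            out2 = fill_gap(sc, pairs, relaxed)
            assert isinstance(out2, ClosedChain)
            assert out2.sequence == out.sequence


class TestAnnotation:
    def _chain_from_parts(self, refset, locus, ins, v_i=0, j_i=0):
        v = refset.genes(locus, "V")[v_i]
        j = refset.genes(locus, "J")[j_i]
        c = refset.genes(locus, "C")[0]
        seq = v.sequence + ins + j.sequence + c.sequence
        j0 = len(v.sequence) - 3
        j1 = len(seq) - len(c.sequence) + 3
        chain = ClosedChain(locus, seq, v.gene_name, c.gene_name, (j0, j1), 20.0)
        return chain, v, j, c

    def test_synthetic_vjc_with_insertion(self, refset):
        chain, v, j, c = self._chain_from_parts(refset, "TRA", "GGG")
        ann = annotate_chain(chain, refset)
        assert ann.j_gene == j.gene_name
        assert ann.inserted_vj == "GGG"
        assert ann.deletions == {"v3": 0, "c5": 0, "j5": 0, "j3": 0}

    def test_frameshift_insertion_unproductive(self, refset):
        chain, *_ = self._chain_from_parts(refset, "TRA", "GGGG")
        ann = annotate_chain(chain, refset)
        assert ann.productive is False
        assert ann.frame_offset == 1

    def test_in_frame_stop_codon_unproductive(self, refset):
        chain, *_ = self._chain_from_parts(refset, "TRA", "TAA")
        ann = annotate_chain(chain, refset)
        assert ann.frame_offset == 0
        assert ann.productive is False

    def test_in_frame_insertion_productive(self, refset):
        chain, *_ = self._chain_from_parts(refset, "TRA", "GGGGGG")
        ann = annotate_chain(chain, refset)
        assert ann.productive is True

    def test_beta_d_gene_detected(self, refset):
        v = refset.genes("TRB", "V")[0]
        d = refset.genes("TRB", "D")[0]
        j = refset.genes("TRB", "J")[0]
        c = refset.genes("TRB", "C")[0]
        seq = v.sequence + "GGG" + d.sequence + "AAA" + j.sequence + c.sequence
        j0 = len(v.sequence) - 3
        j1 = len(seq) - len(c.sequence) + 3
        chain = ClosedChain("TRB", seq, v.gene_name, c.gene_name, (j0, j1), 20.0)
        ann = annotate_chain(chain, refset)
        assert ann.j_gene == j.gene_name
        assert ann.d_gene == d.gene_name
        assert ann.inserted_vd == "GGG"
        assert ann.inserted_dj == "AAA"

    def test_unannotatable_junction_reports_undetermined(self, refset):
        v = refset.genes("TRA", "V")[0]
        c = refset.genes("TRA", "C")[0]
        seq = v.sequence + c.sequence
        chain = ClosedChain(
            "TRA", seq, v.gene_name, c.gene_name,
            (len(v.sequence) - 3, len(v.sequence) + 3), 20.0,
        )
        ann = annotate_chain(chain, refset)
        assert ann.j_gene == "undetermined"
        assert ann.productive is False


class TestOutputs:
    def test_empty_outputs_are_valid_files(self, tmp_path):
        paths = write_chain_outputs([], [], [], tmp_path)
        for p in paths.values():
            assert p.exists()
        assert (tmp_path / "annotation.tsv").read_text().startswith("locus\t")

    def test_chain_fasta_roundtrip_and_order(self, tmp_path, refset):
        from Bio import SeqIO

        chains = []
        anns = []
        for v_i in (1, 0):
            v = refset.genes("TRA", "V")[v_i]
            c = refset.genes("TRA", "C")[0]
            seq = v.sequence + "GGG" + refset.genes("TRA", "J")[0].sequence + c.sequence
            chains.append(
                ClosedChain(
                    "TRA", seq, v.gene_name, c.gene_name,
                    (len(v.sequence) - 3, len(seq) - len(c.sequence) + 3), 9.0,
                )
            )
            anns.append(annotate_chain(chains[-1], refset))
        paths = write_chain_outputs(chains, [], anns, tmp_path)
        records = list(SeqIO.parse(str(paths["chains"]), "fasta"))
        assert len(records) == 2
        # ordered by V gene name
        assert [r.id.split("|")[1] for r in records] == sorted(
            c.v_gene for c in chains
        )
        assert {str(r.seq) for r in records} == {c.sequence for c in chains}
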