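"""V-C scaffolding, read-pair-anchored gap filling, and chain annotation.

Each V consensus is concatenated to each C consensus of its locus across an
N-run sized by the germline J (or D+J) mean length, with 3 nt trimmed from
the junction-facing ends of both consensi (consensus edges are the least
reliable bases; the junction-adjacent truth is regrown from reads).  The gap
is then closed by an overlap-consensus extension assembler: read pairs with
one mate anchored in a flank and oriented toward the gap contribute their
partner as a junction candidate; extension appends a base only when enough
candidates agree; the two extensions are spliced at an exact overlap.  A
closure is accepted only if the realized junction length falls inside the
tolerance band around the estimated gap size.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import edlib
import numpy as np
from Bio.Seq import Seq

from .consensus import ConsensusContig
from .mapping import ReadPair, encode_seq, make_aligner, revcomp
from .reference import GapEstimate, ReferenceSet

REJECTION_REASONS = (
    "no_candidates",
    "extension_stalled",
    "no_closure",
    "gap_length_out_of_tolerance",
)


@dataclass
class GappedScaffold:
    locus: str
    v_contig: ConsensusContig
    c_contig: ConsensusContig
    end_trim: int
    gap_len: int
    sequence: str
    v_flank_interval: tuple[int, int]
    gap_interval: tuple[int, int]
    c_flank_interval: tuple[int, int]

    @property
    def v_flank(self) -> str:
        return self.sequence[self.v_flank_interval[0] : self.v_flank_interval[1]]

    @property
    def c_flank(self) -> str:
        return self.sequence[self.c_flank_interval[0] : self.c_flank_interval[1]]

    @property
    def scaffold_id(self) -> str:
        return f"{self.v_contig.gene_name}~{self.c_contig.gene_name}"


@dataclass(frozen=True)
class GapFillConfig:
    """Native gap-filler settings.

    min_overlap mirrors the 20 nt candidate/closure overlap (reduce it for
    very short reads); min_reads_per_base mirrors the pileup minimum
    coverage; base_agreement_ratio is the majority fraction required to call
    an extension base; gap_tolerance is the +-50% band on the realized
    junction length; insert_size_mean (dataset-specific: 148 Jurkat-like,
    175 C1-mouse-like) bounds, together with recruit_deviation, how far from
    the gap edge an anchored mate may sit.
    """

    min_overlap: int = 20
    min_reads_per_base: int = 5
    base_agreement_ratio: float = 0.7
    gap_tolerance: float = 0.5
    insert_size_mean: int = 175
    recruit_deviation: int = 50
    max_mismatch: int = 2
    max_rounds: int = 12
    # Exact overlap required to splice the two consensus walks.  Each walk is
    # already validated per base by min_reads_per_base and the agreement
    # ratio, and the realized junction must land in the gap-size band, so the
    # splice can be shorter than the raw-read overlap: paired-end geometry
    # leaves a read-start desert between the two mate windows, and demanding
    # a 20-base overlap of the walks there costs real closures.
    closure_min_overlap: int = 8

    def __post_init__(self):
        if not 0.5 <= self.base_agreement_ratio <= 1:
            raise ValueError("base_agreement_ratio must be in [0.5, 1]")
        if self.min_overlap < 5:
            raise ValueError("min_overlap must be >= 5")


@dataclass
class ClosedChain:
    locus: str
    sequence: str
    v_gene: str
    c_gene: str
    junction_interval: tuple[int, int]
    junction_mean_coverage: float

    @property
    def junction_nt(self) -> str:
        return self.sequence[self.junction_interval[0] : self.junction_interval[1]]


@dataclass
class Rejection:
    scaffold_id: str
    reason: str
    detail: str = ""


@dataclass
class ChainAnnotation:
    locus: str
    v_gene: str
    d_gene: str | None
    j_gene: str
    c_gene: str
    junction_nt: str
    inserted_vj: str | None
    inserted_vd: str | None
    inserted_dj: str | None
    deletions: dict[str, int]
    productive: bool
    frame_offset: int


def build_scaffold(
    v_contig: ConsensusContig,
    c_contig: ConsensusContig,
    locus: str,
    gap: GapEstimate,
    end_trim: int = 3,
) -> GappedScaffold:
    v_seq = v_contig.sequence[: len(v_contig.sequence) - end_trim]
    c_seq = c_contig.sequence[end_trim:]
    gap_len = gap.mean_gap
    seq = v_seq + "N" * gap_len + c_seq
    return GappedScaffold(
        locus=locus,
        v_contig=v_contig,
        c_contig=c_contig,
        end_trim=end_trim,
        gap_len=gap_len,
        sequence=seq,
        v_flank_interval=(0, len(v_seq)),
        gap_interval=(len(v_seq), len(v_seq) + gap_len),
        c_flank_interval=(len(v_seq) + gap_len, len(seq)),
    )


def build_scaffolds(
    v_contigs: Sequence[ConsensusContig],
    c_contigs: Sequence[ConsensusContig],
    locus: str,
    gap: GapEstimate,
    end_trim: int = 3,
) -> list[GappedScaffold]:
    """Cross-product of V and C consensi for one locus, ordered by V then C
    gene name.  Empty V or C list gives an empty result."""
    out = []
    for v in sorted(v_contigs, key=lambda c: c.gene_name):
        for c in sorted(c_contigs, key=lambda c: c.gene_name):
            out.append(build_scaffold(v, c, locus, gap, end_trim))
    return out


# ---------------------------------------------------------------------------
# Gap filling

def _locate_in_flank(seq: str, flank: str, max_ed: int) -> int | None:
    """End position (exclusive) of the best infix alignment of seq in flank,
    or None if seq does not occur within max_ed edits."""
    if len(seq) < 10 or len(flank) < 10:
        return None
    res = edlib.align(seq, flank, mode="HW", task="locations", k=max_ed)
    if res["editDistance"] < 0:
        return None
    return res["locations"][0][1] + 1


def _recruit(
    scaffold: GappedScaffold, pairs: Sequence[ReadPair], cfg: GapFillConfig
) -> list[str]:
    """Junction candidate pool: reads of pairs with a mate anchored in a
    flank within reach of the gap.

    A candidate is any mate of such a pair — the partner of a deeply
    anchored mate may fall wholly within the gap, and a near-edge mate may
    itself straddle the gap edge (its own partner then anchors in the
    opposite flank when fragments are longer than flank + junction).  Both
    orientations of each read enter the pool; a wrongly oriented candidate
    simply never places against a growing edge.  One pool serves both
    extension directions.
    """
    vf = scaffold.v_flank
    cf_rc = revcomp(scaffold.c_flank)
    window = cfg.insert_size_mean + cfg.recruit_deviation
    out: dict[tuple, str] = {}
    for pi, pair in enumerate(pairs):
        anchored = False
        for mate_seq in (pair.seq1, pair.seq2):
            max_ed = max(2, len(mate_seq) // 10)
            for flank in (vf, cf_rc):
                end = _locate_in_flank(mate_seq, flank, max_ed)
                if end is not None and len(flank) - end <= window:
                    anchored = True
                    break
            if anchored:
                break
        if not anchored:
            continue
        for mate, seq in enumerate((pair.seq1, pair.seq2), start=1):
            out[(pi, mate, "f")] = seq
            out[(pi, mate, "r")] = revcomp(seq)
    return list(out.values())


def _place_candidate(
    s_arr: np.ndarray, c_arr: np.ndarray, cfg: GapFillConfig
) -> tuple[int, int] | None:
    """Best placement of candidate c against the growing sequence s such that
    the candidate overlaps the 3' end by >= min_overlap with <= max_mismatch
    mismatches and overhangs it; returns (start position, mismatches)."""
    n, m = len(s_arr), len(c_arr)
    best: tuple[int, int] | None = None
    lo = max(0, n - m + 1)  # placements with p < lo leave no overhang
    hi = n - cfg.min_overlap
    for p in range(lo, hi + 1):
        ov = n - p
        window = s_arr[p:]
        cand = c_arr[:ov]
        mism = int(np.count_nonzero(window != cand))
        if mism > cfg.max_mismatch:
            continue
        if best is None or (mism, -ov) < (best[1], -(n - best[0])):
            best = (p, mism)
    return best


_TAIL_K = 10


def _extend(
    flank: str, candidates: Sequence[str], cfg: GapFillConfig, cap: int
) -> tuple[str, list[int]]:
    """Consensus extension of flank rightward from its gap edge.

    Repeated rounds: place candidates against the current 3' end, vote per
    overhang column, and append bases while >= min_reads_per_base candidates
    cover the column and the majority base reaches base_agreement_ratio.
    Only candidates sharing an exact 10-mer with the current edge region are
    placed (cheap prefilter over the orientation-expanded pool).  Growth is
    capped so extension cannot run away past the plausible junction plus
    closure overlap.
    """
    s = flank
    support: list[int] = []
    cands = [c for c in candidates if len(c) >= cfg.min_overlap]
    cand_arrs = {c: encode_seq(c) for c in cands}
    max_cand = max((len(c) for c in cands), default=0)
    for _ in range(cfg.max_rounds):
        if len(s) - len(flank) >= cap:
            break
        tail = s[-(max_cand + cfg.min_overlap) :]
        tail_kmers = {tail[i : i + _TAIL_K] for i in range(len(tail) - _TAIL_K + 1)}
        live = [
            c
            for c in cands
            if any(
                c[i : i + _TAIL_K] in tail_kmers
                for i in range(0, len(c) - _TAIL_K + 1, 3)
            )
        ]
        if not live:
            break
        s_arr = encode_seq(s)
        votes = np.zeros((4, cap + max_cand), np.int32)
        any_vote = False
        for c in live:
            placed = _place_candidate(s_arr, cand_arrs[c], cfg)
            if placed is None:
                continue
            p, _ = placed
            overhang = cand_arrs[c][len(s) - p :]
            if overhang.size == 0:
                continue
            valid = overhang <= 3
            cols = np.arange(overhang.size)[valid]
            votes[overhang[valid], cols] += 1
            any_vote = True
        if not any_vote:
            break
        grown = 0
        depth = votes.sum(axis=0)
        ext_chars = []
        for j in range(votes.shape[1]):
            if len(s) - len(flank) + grown >= cap:
                break
            tot = int(depth[j])
            if tot < cfg.min_reads_per_base:
                break
            top = int(votes[:, j].max())
            if top / tot < cfg.base_agreement_ratio:
                break
            ext_chars.append("ACGT"[int(votes[:, j].argmax())])
            support.append(tot)
            grown += 1
        if grown == 0:
            break
        s = s + "".join(ext_chars)
    return s[len(flank) :], support


def _merge_exact(a: str, b: str, min_overlap: int) -> int | None:
    """Largest k >= min_overlap with a's suffix equal to b's prefix."""
    for k in range(min(len(a), len(b)), min_overlap - 1, -1):
        if a[-k:] == b[:k]:
            return k
    return None


def fill_gap(
    scaffold: GappedScaffold, pairs: Sequence[ReadPair], cfg: GapFillConfig
) -> ClosedChain | Rejection:
    """Close the scaffold's N-gap from read pairs, or reject with a reason.

    The junction (including the regrown 2 x end_trim trimmed bases) must land
    within the gap-size tolerance band for the closure to be accepted.
    """
    if "N" not in scaffold.sequence and scaffold.gap_len > 0:
        raise ValueError("malformed scaffold: no N-run")
    vf, cf = scaffold.v_flank, scaffold.c_flank
    if len(vf) < cfg.min_overlap or len(cf) < cfg.min_overlap:
        return Rejection(scaffold.scaffold_id, "no_closure", "flank shorter than min_overlap")
    pool = _recruit(scaffold, pairs, cfg)
    if not pool:
        return Rejection(scaffold.scaffold_id, "no_candidates")

    band_lo = max(
        0,
        round(scaffold.gap_len * (1 - cfg.gap_tolerance)) - 2 * scaffold.end_trim,
    )
    band_hi = round(scaffold.gap_len * (1 + cfg.gap_tolerance)) + 2 * scaffold.end_trim
    cap = band_hi + cfg.min_overlap + 10

    ext_v, sup_v = _extend(vf, pool, cfg, cap)
    ext_c_rc, sup_c = _extend(revcomp(cf), pool, cfg, cap)
    ext_c = revcomp(ext_c_rc)

    if not ext_v and not ext_c:
        return Rejection(scaffold.scaffold_id, "extension_stalled")

    a = vf + ext_v
    b = ext_c + cf
    k = _merge_exact(a, b, min(cfg.min_overlap, cfg.closure_min_overlap))
    if k is None:
        return Rejection(scaffold.scaffold_id, "no_closure")
    merged = a + b[k:]
    j0, j1 = len(vf), len(merged) - len(cf)
    junction_len = j1 - j0
    if not band_lo <= junction_len <= band_hi:
        return Rejection(
            scaffold.scaffold_id,
            "gap_length_out_of_tolerance",
            f"junction {junction_len} outside [{band_lo}, {band_hi}]",
        )
    # Junction support: V-side votes cover positions j0..; C-side votes cover
    # positions counted from the right.  Take the max of the two per column.
    depth = np.zeros(max(junction_len, 1), dtype=np.int64)
    for i, d in enumerate(sup_v[:junction_len]):
        depth[i] = max(depth[i], d)
    for i, d in enumerate(sup_c[:junction_len]):
        depth[junction_len - 1 - i] = max(depth[junction_len - 1 - i], d)
    return ClosedChain(
        locus=scaffold.locus,
        sequence=merged,
        v_gene=scaffold.v_contig.gene_name,
        c_gene=scaffold.c_contig.gene_name,
        junction_interval=(j0, j1),
        junction_mean_coverage=float(depth.mean()) if junction_len else float(depth[0]),
    )


# ---------------------------------------------------------------------------
# Annotation

def _match_run(a: str, b: str) -> int:
    """Length of the common prefix of a and b."""
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def _best_segment_alignment(aligner, region: str, genes) -> tuple | None:
    """Best (gene, score, matches, region_interval, gene_interval) of any
    gene locally aligned into the region; ties by score then name."""
    best = None
    for gene in sorted(genes, key=lambda g: g.gene_name):
        if not region:
            continue
        alns = aligner.align(region, gene.sequence)
        score = alns.score
        if score <= 0:
            continue
        aln = alns[0]
        t_blocks, q_blocks = aln.aligned
        matches = 0
        for (t0, t1), (q0, q1) in zip(t_blocks, q_blocks):
            matches += sum(
                1
                for a_ch, b_ch in zip(region[t0:t1], gene.sequence[q0:q1])
                if a_ch == b_ch
            )
        entry = (
            -score,
            gene.gene_name,
            matches,
            (int(t_blocks[0][0]), int(t_blocks[-1][1])),
            (int(q_blocks[0][0]), int(q_blocks[-1][1])),
        )
        if best is None or entry < best:
            best = entry
    if best is None:
        return None
    neg_score, name, matches, region_iv, gene_iv = best
    return name, -neg_score, matches, region_iv, gene_iv


def annotate_chain(chain: ClosedChain, refset: ReferenceSet) -> ChainAnnotation:
    """Light native V(D)J annotation of a closed chain.

    The J gene is the best local alignment of any germline J into the
    junction region; for TRB the D gene is sought in the V-J interspace and
    reported "undetermined" below 8 exactly matching bases.  Inserted
    nucleotides are the bases between aligned germline boundaries; deletions
    are germline edge bases absent from the chain.  Productivity is a native
    frame/stop approximation: the net junction indel must preserve the V
    reading frame (anchored at chain position 0) and the translation across
    the junction window must be stop-free.
    """
    j0, j1 = chain.junction_interval
    # Extend the germline V/C match into the regrown junction bases.
    v_contig_tail = _v_tail_bases(chain, refset)
    c_contig_head = _c_head_bases(chain, refset)
    v_ext = _match_run(chain.sequence[j0:], v_contig_tail)
    c_ext = _match_run(chain.sequence[:j1][::-1], c_contig_head[::-1])
    bio_j0, bio_j1 = j0 + v_ext, j1 - c_ext
    junction = chain.sequence[bio_j0:bio_j1]
    deletions = {
        "v3": len(v_contig_tail) - v_ext,
        "c5": len(c_contig_head) - c_ext,
    }

    aligner = make_aligner()
    locus = chain.locus
    j_res = _best_segment_alignment(aligner, junction, refset.require(locus, "J"))
    if j_res is None or j_res[2] < 8:
        return ChainAnnotation(
            locus=locus,
            v_gene=chain.v_gene,
            d_gene=None,
            j_gene="undetermined",
            c_gene=chain.c_gene,
            junction_nt=junction,
            inserted_vj=None,
            inserted_vd=None,
            inserted_dj=None,
            deletions=deletions,
            productive=False,
            frame_offset=0,
        )
    j_name, _, _, j_region_iv, j_gene_iv = j_res
    j_gene = refset.get(locus, "J", j_name)
    deletions["j5"] = j_gene_iv[0]
    deletions["j3"] = len(j_gene.sequence) - j_gene_iv[1]

    inserted_vj = inserted_vd = inserted_dj = None
    d_name = None
    inserted_total = 0
    if locus == "TRB":
        interspace = junction[: j_region_iv[0]]
        d_res = _best_segment_alignment(aligner, interspace, refset.genes(locus, "D"))
        if d_res is not None and d_res[2] >= 8:
            d_name, _, _, d_region_iv, d_gene_iv = d_res
            d_gene = refset.get(locus, "D", d_name)
            deletions["d5"] = d_gene_iv[0]
            deletions["d3"] = len(d_gene.sequence) - d_gene_iv[1]
            inserted_vd = interspace[: d_region_iv[0]]
            inserted_dj = junction[d_region_iv[1] : j_region_iv[0]]
            inserted_total = len(inserted_vd) + len(inserted_dj)
        else:
            d_name = "undetermined"
            inserted_vd = interspace
            inserted_dj = ""
            inserted_total = len(interspace)
    else:
        inserted_vj = junction[: j_region_iv[0]]
        inserted_total = len(inserted_vj)

    deleted_total = sum(deletions.values())
    frame_offset = (inserted_total - deleted_total) % 3
    productive = frame_offset == 0
    if productive:
        # Translate from the last complete codon inside V through the
        # junction into the first complete codon of C, in the V frame.
        start = max(0, 3 * (bio_j0 // 3) - 3)
        end = min(len(chain.sequence), 3 * ((bio_j1 + 2) // 3) + 3)
        end = start + 3 * ((end - start) // 3)
        window = chain.sequence[start:end]
        if "*" in str(Seq(window).translate()):
            productive = False
    return ChainAnnotation(
        locus=locus,
        v_gene=chain.v_gene,
        d_gene=d_name,
        j_gene=j_name,
        c_gene=chain.c_gene,
        junction_nt=junction,
        inserted_vj=inserted_vj,
        inserted_vd=inserted_vd,
        inserted_dj=inserted_dj,
        deletions=deletions,
        productive=productive,
        frame_offset=frame_offset,
    )


def _v_tail_bases(chain: ClosedChain, refset: ReferenceSet, n: int = 3) -> str:
    gene = refset.get(chain.locus, "V", chain.v_gene)
    return gene.sequence[-n:]


def _c_head_bases(chain: ClosedChain, refset: ReferenceSet, n: int = 3) -> str:
    gene = refset.get(chain.locus, "C", chain.c_gene)
    return gene.sequence[:n]


# ---------------------------------------------------------------------------
# Outputs

def write_chain_outputs(
    chains: Sequence[ClosedChain],
    contigs: Sequence[ConsensusContig],
    annotations: Sequence[ChainAnnotation],
    out_dir,
    rejections: Sequence[Rejection] = (),
) -> dict[str, Path]:
    """chains.fasta, contigs.fasta, annotation.tsv, rejects.tsv in out_dir."""
    from .consensus import write_contigs_fasta

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "chains": out_dir / "chains.fasta",
        "contigs": out_dir / "contigs.fasta",
        "annotation": out_dir / "annotation.tsv",
        "rejects": out_dir / "rejects.tsv",
    }
    order = sorted(range(len(chains)), key=lambda i: (chains[i].v_gene, chains[i].c_gene))
    with open(paths["chains"], "w") as fh:
        for i in order:
            ch = chains[i]
            fh.write(
                f">{ch.locus}|{ch.v_gene}|{ch.c_gene}|junction="
                f"{ch.junction_interval[0]}-{ch.junction_interval[1]}"
                f"|junction_cov={ch.junction_mean_coverage:.2f}\n"
            )
            for p in range(0, len(ch.sequence), 60):
                fh.write(ch.sequence[p : p + 60] + "\n")
    write_contigs_fasta(contigs, paths["contigs"])
    with open(paths["annotation"], "w") as fh:
        fh.write(
            "locus\tv_gene\td_gene\tj_gene\tc_gene\tjunction_nt\t"
            "inserted_vj\tinserted_vd\tinserted_dj\tdeletions\t"
            "productive\tframe_offset\n"
        )
        for i in order:
            if i >= len(annotations):
                continue
            a = annotations[i]
            dels = ";".join(f"{k}={v}" for k, v in sorted(a.deletions.items()))
            fh.write(
                f"{a.locus}\t{a.v_gene}\t{a.d_gene or ''}\t{a.j_gene}\t{a.c_gene}\t"
                f"{a.junction_nt}\t{a.inserted_vj or ''}\t{a.inserted_vd or ''}\t"
                f"{a.inserted_dj or ''}\t{dels}\t{a.productive}\t{a.frame_offset}\n"
            )
    with open(paths["rejects"], "w") as fh:
        fh.write("scaffold_id\treason\tdetail\n")
        for r in rejections:
            fh.write(f"{r.scaffold_id}\t{r.reason}\t{r.detail}\n")
    return paths
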