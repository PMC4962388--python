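"""Read trimming and germline V/C class assignment.

Each mate of a pair is assigned independently to germline gene classes
(TRAV, TRBV, TRAC, TRBC) by seeded local alignment: exact 11-mer seeds
select candidate genes, a gapped Smith-Waterman extension scores them, and
significance follows the Karlin-Altschul expectation
E = K * m * n * exp(-lambda * S), with m the query length, n the total class
database length and (K, lambda) fitted to the scoring scheme.  A hit is kept
iff E <= evalue_max (default 1e-8, the threshold that empirically cuts off
spurious mappings against the small TCR gene databases).  The per-gene read
counts form the sample's V/C usage counts table.

Reads can be supplied as ``ReadPair`` objects or, for large simulated
samples, as an encoded ``PairBatch`` matrix that avoids materialising
millions of Python strings for background reads that never seed.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
from scipy.optimize import brentq
from Bio import Align

from .reference import ReferenceSet

# Gene classes queried by the pipeline: locus + segment.
PIPELINE_CLASSES = ("TRAV", "TRAC", "TRBV", "TRBC")

SEED_K = 11
# A single isolated exact 11-mer scores 22, far below any score that can
# reach E <= 1e-8, so requiring two seed hits per (gene, strand) loses
# essentially nothing while suppressing chance background candidates.
MIN_SEED_HITS = 2

# blastn-style scoring: match +2, mismatch -3, gap of length g costs 5 + 2g.
MATCH = 2
MISMATCH = -3
GAP_OPEN = 5
GAP_EXTEND = 2


class ReadPair(NamedTuple):
    """A paired-end read; qualities are Phred+33 strings of mate length."""

    read_id: str
    seq1: str
    seq2: str
    qual1: str
    qual2: str


@dataclass(frozen=True)
class TrimConfig:
    """Trim Galore-equivalent settings (-q 20, -stringency 5)."""

    quality_cutoff: int = 20
    adapter_min_overlap: int = 5
    adapter_sequence: str = ""
    min_length_after_trim: int = 20

    def __post_init__(self):
        if self.quality_cutoff < 0:
            raise ValueError("quality_cutoff must be >= 0")
        if self.adapter_min_overlap < 1:
            raise ValueError("adapter_min_overlap must be >= 1")


@dataclass
class AlignmentHit:
    read_id: str
    mate: int
    gene_name: str
    class_key: str
    score: float
    evalue: float
    read_interval: tuple[int, int]
    gene_interval: tuple[int, int]
    strand: str
    # Oriented query (reverse-complemented for '-' hits) plus aligned blocks
    # in (gene, oriented-read) coordinates; consumed by the pileup stage.
    query_seq: str = ""
    blocks: tuple = ()


@dataclass
class HitTable:
    """Per-gene read counts and per-(read, class) best assignments."""

    evalue_max: float
    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    assignments: dict[tuple[tuple[str, int], str], AlignmentHit] = field(
        default_factory=dict
    )

    def class_total(self, class_key: str) -> int:
        return sum(n for (ck, _), n in self.counts.items() if ck == class_key)

    def class_counts(self, class_key: str) -> dict[str, int]:
        return {g: n for (ck, g), n in self.counts.items() if ck == class_key}

    def hits_for_gene(self, class_key: str, gene_name: str) -> list[AlignmentHit]:
        """Best-hit assignments whose assigned gene is the one requested."""
        return [
            h
            for (_, ck), h in self.assignments.items()
            if ck == class_key and h.gene_name == gene_name
        ]


@dataclass
class UsageSummary:
    class_key: str
    counts: dict[str, int]
    percentages: dict[str, float]
    top_gene: str | None
    top_percentage: float


# ---------------------------------------------------------------------------
# Sequence encoding

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
    _ENC[_b + 32] = _i

_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def encode_seq(seq: str) -> np.ndarray:
    """ACGT -> 0..3, anything else -> 4."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_codes(codes: np.ndarray) -> str:
    return _DEC[codes].tobytes().decode("ascii")


class PairBatch:
    """Column-oriented read pairs: an (n, 2, read_len) base-code matrix.

    Used by the simulator for background-heavy samples; individual pairs are
    materialised to strings only on demand.
    """

    def __init__(self, ids: list[str], codes: np.ndarray, quals: list[str]):
        if codes.ndim != 3 or codes.shape[1] != 2:
            raise ValueError("codes must have shape (n, 2, read_len)")
        if len(ids) != codes.shape[0] or len(quals) != codes.shape[0]:
            raise ValueError("ids/quals length mismatch")
        self.ids = ids
        self.codes = codes
        self.quals = quals  # one Phred+33 string per pair, shared by mates

    def __len__(self) -> int:
        return self.codes.shape[0]

    @property
    def read_len(self) -> int:
        return self.codes.shape[2]

    def pair(self, i: int) -> ReadPair:
        q = self.quals[i]
        return ReadPair(
            self.ids[i],
            decode_codes(self.codes[i, 0]),
            decode_codes(self.codes[i, 1]),
            q,
            q,
        )

    def to_list(self) -> list[ReadPair]:
        return [self.pair(i) for i in range(len(self))]

    def min_quality(self) -> int:
        return min(ord(min(q)) for q in set(self.quals)) - 33 if self.quals else 0


# ---------------------------------------------------------------------------
# Trimming

def _quality_trim_cut(qual: str, cutoff: int) -> int:
    """BWA-style 3' quality trimming: running sum of (cutoff - q) from the
    3' end; cut where the sum is maximal and positive."""
    # Common case: the terminal base is above the cutoff, so the running sum
    # goes negative immediately and nothing is trimmed.
    if not qual or ord(qual[-1]) - 33 > cutoff:
        return len(qual)
    q = qual.encode("ascii")
    s = 0
    max_s = 0
    cut = len(q)
    for i in range(len(q) - 1, -1, -1):
        s += cutoff - (q[i] - 33)
        if s < 0:
            break
        if s > max_s:
            max_s = s
            cut = i
    return cut


def _adapter_cut(seq: str, adapter: str, min_overlap: int) -> int:
    """Longest suffix of seq that exactly matches a prefix of the adapter,
    if at least min_overlap long; returns the cut position (len(seq) if none)."""
    if not adapter:
        return len(seq)
    for l in range(min(len(seq), len(adapter)), min_overlap - 1, -1):
        if seq[-l:] == adapter[:l]:
            return len(seq) - l
    return len(seq)


def _trim_mate(seq: str, qual: str, cfg: TrimConfig) -> tuple[str, str]:
    if len(seq) != len(qual):
        raise ValueError("sequence/quality length mismatch")
    cut = _quality_trim_cut(qual, cfg.quality_cutoff)
    seq, qual = seq[:cut], qual[:cut]
    cut = _adapter_cut(seq, cfg.adapter_sequence, cfg.adapter_min_overlap)
    return seq[:cut], qual[:cut]


def trim_reads(pairs: Iterable[ReadPair], cfg: TrimConfig) -> Iterator[ReadPair]:
    """3' quality + adapter trimming; pairs with a too-short mate are dropped
    as a pair."""
    for pair in pairs:
        s1, q1 = _trim_mate(pair.seq1, pair.qual1, cfg)
        s2, q2 = _trim_mate(pair.seq2, pair.qual2, cfg)
        if len(s1) < cfg.min_length_after_trim or len(s2) < cfg.min_length_after_trim:
            continue
        if (s1, s2) == (pair.seq1, pair.seq2):
            yield pair
        else:
            yield ReadPair(pair.read_id, s1, s2, q1, q2)


def trim_is_noop(batch: PairBatch, cfg: TrimConfig) -> bool:
    """True when trimming provably changes nothing: no adapter configured and
    every base quality at or above the cutoff (the running trim sum then
    never becomes positive)."""
    return not cfg.adapter_sequence and batch.min_quality() >= cfg.quality_cutoff


# ---------------------------------------------------------------------------
# Karlin-Altschul statistics

def karlin_altschul_params(match: int = MATCH, mismatch: int = MISMATCH) -> tuple[float, float]:
    """(K, lambda) for an ungapped match/mismatch scheme at uniform base
    composition: lambda solves sum_ij p_i p_j exp(lambda * s_ij) = 1; K is a
    fixed blastn-magnitude constant (threshold semantics, not bit-exactness)."""
    f = lambda lam: 0.25 * math.exp(match * lam) + 0.75 * math.exp(mismatch * lam) - 1.0
    lam = brentq(f, 1e-9, 10.0)
    return 0.41, lam


_KA_K, _KA_LAMBDA = karlin_altschul_params()


def evalue(score: float, query_len: int, db_len: int) -> float:
    return _KA_K * query_len * db_len * math.exp(-_KA_LAMBDA * score)


# ---------------------------------------------------------------------------
# k-mer seeding

class KmerIndex:
    """Exact k-mer seed index over the V/C germline classes, both strands."""

    def __init__(self, refset: ReferenceSet, k: int = SEED_K):
        self.k = k
        self.gene_seqs: dict[tuple[str, str], str] = {}
        self.class_db_len: dict[str, int] = {}
        table: dict[int, set[tuple[str, str, str]]] = {}
        for class_key in PIPELINE_CLASSES:
            locus, segment = class_key[:3], class_key[3]
            genes = refset.require(locus, segment)
            self.class_db_len[class_key] = sum(len(g) for g in genes)
            for g in genes:
                self.gene_seqs[(class_key, g.gene_name)] = g.sequence
                for strand, seq in (("+", g.sequence), ("-", revcomp(g.sequence))):
                    codes = encode_seq(seq)
                    n = len(codes) - k + 1
                    val = 0
                    run = 0  # valid bases in the current window
                    for i in range(len(codes)):
                        c = int(codes[i])
                        if c > 3:
                            run = 0
                            val = 0
                            continue
                        val = (val * 4 + c) % (4**k)
                        run += 1
                        if run >= k:
                            table.setdefault(val, set()).add(
                                (class_key, g.gene_name, strand)
                            )
        self.table = {code: tuple(sorted(entries)) for code, entries in table.items()}
        self.lut = np.zeros(4**k, dtype=bool)
        self.lut[list(self.table)] = True

    def screen_codes(
        self, mat: np.ndarray, chunk_rows: int = 1 << 16
    ) -> dict[int, dict[tuple[str, str, str], tuple[int, int, int]]]:
        """Row index -> {(class, gene, strand): (hit count, first window,
        last window)} for every row of an encoded (rows, L) matrix sharing a
        k-mer with the index."""
        k = self.k
        rows, L = mat.shape
        n = L - k + 1
        out: dict[int, dict[tuple[str, str, str], tuple[int, int, int]]] = {}
        if n <= 0:
            return out
        for r0 in range(0, rows, chunk_rows):
            sub = mat[r0 : r0 + chunk_rows]
            clean = int(sub.max(initial=0)) <= 3  # no N/padding in this chunk
            vals = np.zeros((sub.shape[0], n), dtype=np.int32)
            bad = None if clean else np.zeros((sub.shape[0], n), dtype=bool)
            for i in range(k):
                np.multiply(vals, 4, out=vals)
                sl = sub[:, i : i + n]
                np.add(vals, sl, out=vals, casting="unsafe")
                if bad is not None:
                    np.logical_or(bad, sl > 3, out=bad)
            np.clip(vals, 0, self.lut.size - 1, out=vals)
            hits = self.lut[vals]
            if bad is not None:
                np.logical_and(hits, ~bad, out=hits)
            rows_idx, cols_idx = np.nonzero(hits)
            for r, c in zip(rows_idx.tolist(), cols_idx.tolist()):
                counts = out.setdefault(r0 + r, {})
                for entry in self.table[int(vals[r, c])]:
                    cur = counts.get(entry)
                    if cur is None:
                        counts[entry] = (1, c, c)
                    else:
                        counts[entry] = (cur[0] + 1, cur[1], c)
        return out

    def screen(
        self, seqs: Sequence[str]
    ) -> dict[int, dict[tuple[str, str, str], tuple[int, int, int]]]:
        """Screen arbitrary-length sequences (padded into one matrix)."""
        if not seqs:
            return {}
        max_len = max(len(s) for s in seqs)
        mat = np.full((len(seqs), max_len), 4, dtype=np.uint8)
        for i, s in enumerate(seqs):
            if s:
                mat[i, : len(s)] = encode_seq(s)
        return self.screen_codes(mat)


# ---------------------------------------------------------------------------
# Mapping

def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    # gap of length g costs GAP_OPEN + GAP_EXTEND * g
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


import re as _re

_CIGAR_RE = _re.compile(r"(\d+)([=XIDM])")


def _edlib_blocks(gene_seq: str, query: str):
    """Aligned blocks for a read lying fully inside the gene, via edlib's
    infix alignment; None when the read overhangs the gene ends or aligns
    poorly (the caller falls back to full Smith-Waterman)."""
    import edlib

    res = edlib.align(query, gene_seq, mode="HW", task="path",
                      k=max(3, len(query) // 8))
    if res["editDistance"] < 0 or not res.get("cigar"):
        return None
    t0 = res["locations"][0][0]
    t1 = res["locations"][0][1] + 1
    if t0 == 0 or t1 == len(gene_seq):
        return None  # potential clipping: infix and local semantics diverge
    blocks = []
    t, q = t0, 0
    for num, op in _CIGAR_RE.findall(res["cigar"]):
        num = int(num)
        if op in ("=", "X", "M"):
            blocks.append(((t, t + num), (q, q + num)))
            t += num
            q += num
        elif op == "I":  # insertion in the read: consumes query only
            q += num
        else:  # deletion: consumes target only
            t += num
    # merge adjacent match/mismatch runs into maximal blocks
    merged = [blocks[0]]
    for (ts, te), (qs, qe) in blocks[1:]:
        (pts, pte), (pqs, pqe) = merged[-1]
        if ts == pte and qs == pqe:
            merged[-1] = ((pts, te), (pqs, qe))
        else:
            merged.append(((ts, te), (qs, qe)))
    return (t0, t1), (0, len(query)), tuple(merged)


def _best_alignment_blocks(aligner, gene_seq: str, query: str):
    fast = _edlib_blocks(gene_seq, query)
    if fast is not None:
        return fast
    aln = aligner.align(gene_seq, query)[0]
    t_blocks, q_blocks = aln.aligned
    gene_iv = (int(t_blocks[0][0]), int(t_blocks[-1][1]))
    read_iv = (int(q_blocks[0][0]), int(q_blocks[-1][1]))
    blocks = tuple(
        ((int(tb[0]), int(tb[1])), (int(qb[0]), int(qb[1])))
        for tb, qb in zip(t_blocks, q_blocks)
    )
    return gene_iv, read_iv, blocks


def _validate_read(read_id: str, seq: str) -> None:
    if seq and not set(seq) <= set("ACGTN"):
        raise ValueError(f"non-DNA characters in read {read_id}")


def map_reads(
    pairs: "Iterable[ReadPair] | PairBatch",
    refset: ReferenceSet,
    evalue_max: float = 1e-8,
    index: KmerIndex | None = None,
    min_seed_hits: int = MIN_SEED_HITS,
) -> HitTable:
    """Assign each mate to its best gene per class; count one read per class.

    Mates are mapped independently (a pair may legitimately contribute one
    mate to a V class and the other to a C class; the gap-filler exploits
    exactly such pairs).  Ties for the best hit are broken by lowest E-value,
    then highest score, then gene name, so runs are reproducible.
    """
    if index is None:
        index = KmerIndex(refset)
    aligner = make_aligner()
    table = HitTable(evalue_max=evalue_max)

    if isinstance(pairs, PairBatch):
        n = len(pairs)
        candidates = index.screen_codes(pairs.codes.reshape(n * 2, pairs.read_len))

        def seq_of(si: int) -> str:
            return decode_codes(pairs.codes[si // 2, si % 2])

        def meta_of(si: int) -> tuple[str, int]:
            return pairs.ids[si // 2], si % 2 + 1

    else:
        pair_list = pairs if isinstance(pairs, list) else list(pairs)
        seqs: list[str] = []
        meta: list[tuple[str, int]] = []
        for pair in pair_list:
            for mate, seq in ((1, pair.seq1), (2, pair.seq2)):
                _validate_read(pair.read_id, seq)
                seqs.append(seq)
                meta.append((pair.read_id, mate))
        candidates = index.screen(seqs)

        def seq_of(si: int) -> str:
            return seqs[si]

        def meta_of(si: int) -> tuple[str, int]:
            return meta[si]

    k = index.k
    for si in sorted(candidates):
        # Two seeds spanning >= k windows imply >= 2k aligned matches; any
        # hit passing a 1e-8 E-value necessarily satisfies this, while chance
        # single-run seed clusters in background reads do not.
        entries = [
            e
            for e, (count, first, last) in candidates[si].items()
            if count >= min_seed_hits and last - first >= k
        ]
        if not entries:
            continue
        read_id, mate = meta_of(si)
        seq = seq_of(si)
        rc = None
        best_per_class: dict[str, AlignmentHit] = {}
        for class_key, gene_name, strand in sorted(entries):
            gene_seq = index.gene_seqs[(class_key, gene_name)]
            if strand == "-":
                if rc is None:
                    rc = revcomp(seq)
                query = rc
            else:
                query = seq
            score = aligner.score(gene_seq, query)
            ev = evalue(score, len(seq), index.class_db_len[class_key])
            if ev > evalue_max:
                continue
            hit = AlignmentHit(
                read_id=read_id,
                mate=mate,
                gene_name=gene_name,
                class_key=class_key,
                score=score,
                evalue=ev,
                read_interval=(0, 0),
                gene_interval=(0, 0),
                strand=strand,
                query_seq=query,
            )
            cur = best_per_class.get(class_key)
            if cur is None or (hit.evalue, -hit.score, hit.gene_name) < (
                cur.evalue,
                -cur.score,
                cur.gene_name,
            ):
                best_per_class[class_key] = hit
        for class_key, hit in best_per_class.items():
            gene_seq = index.gene_seqs[(class_key, hit.gene_name)]
            gene_iv, read_iv, blocks = _best_alignment_blocks(
                aligner, gene_seq, hit.query_seq
            )
            hit.gene_interval = gene_iv
            hit.read_interval = read_iv
            hit.blocks = blocks
            table.assignments[((read_id, mate), class_key)] = hit
            key = (class_key, hit.gene_name)
            table.counts[key] = table.counts.get(key, 0) + 1
    return table


def tally_usage(table: HitTable, class_key: str) -> UsageSummary:
    """Per-gene counts and percentages of the class total; empty class gives
    an empty summary."""
    counts = table.class_counts(class_key)
    total = sum(counts.values())
    if total == 0:
        return UsageSummary(class_key, {}, {}, None, 0.0)
    percentages = {g: 100.0 * n / total for g, n in counts.items()}
    top_gene = max(counts, key=lambda g: (counts[g], g))
    return UsageSummary(class_key, counts, percentages, top_gene, percentages[top_gene])


# ---------------------------------------------------------------------------
# FASTQ I/O

def _open_maybe_gzip(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fastq_pairs(r1_path, r2_path) -> Iterator[ReadPair]:
    """Stream paired FASTQ files (gzip-transparent)."""
    with _open_maybe_gzip(r1_path) as f1, _open_maybe_gzip(r2_path) as f2:
        while True:
            h1 = f1.readline().strip()
            h2 = f2.readline().strip()
            if not h1:
                if h2:
                    raise ValueError("R1/R2 record count mismatch")
                return
            s1 = f1.readline().strip()
            f1.readline()
            q1 = f1.readline().strip()
            s2 = f2.readline().strip()
            f2.readline()
            q2 = f2.readline().strip()
            rid = h1.lstrip("@").split()[0]
            for suffix in ("/1", "/2", ".1", ".2"):
                if rid.endswith(suffix):
                    rid = rid[: -len(suffix)]
                    break
            yield ReadPair(rid, s1.upper(), s2.upper(), q1, q2)


def write_fastq_pairs(pairs: "Iterable[ReadPair] | PairBatch", r1_path, r2_path) -> None:
    if isinstance(pairs, PairBatch):
        pairs = pairs.to_list()
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.read_id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.read_id}/2\n{p.seq2}\n+\n{p.qual2}\n")


def write_counts_tsv(table: HitTable, path) -> None:
    """The per-sample counts table: class, gene_name, read_count."""
    with open(path, "w") as fh:
        fh.write("class\tgene_name\tread_count\n")
        for (class_key, gene), n in sorted(table.counts.items()):
            fh.write(f"{class_key}\t{gene}\t{n}\n")


def write_assignments_tsv(table: HitTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tmate\tclass\tgene_name\tscore\tevalue\tstrand\n")
        for ((read_id, mate), class_key), hit in sorted(table.assignments.items()):
            fh.write(
                f"{read_id}\t{mate}\t{class_key}\t{hit.gene_name}\t"
                f"{hit.score:g}\t{hit.evalue:.3g}\t{hit.strand}\n"
            )
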