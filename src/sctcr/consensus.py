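"""Candidate gene selection, pileups, the coverage gate, and consensus calls.

Genes attracting more than 10% of their class's mapped reads are candidates.
A candidate is a false positive when reads pile only onto its regions of
similarity to the truly expressed gene, so candidates must show >= 5x depth
across the (edge-trimmed) gene body; survivors get a majority-vote consensus
that recovers the cell's actual allele from the first-allele reference, and
candidates whose consensus is contained in another's are dropped as
duplicate signals of one gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .mapping import AlignmentHit, HitTable, encode_seq
from .reference import GermlineGene

_BASE_ORDER = "ACGT"


@dataclass(frozen=True)
class CandidateConfig:
    candidate_fraction: float = 0.10
    min_coverage: int = 5
    # Positions within edge_trim of either gene end are exempt from the depth
    # gate: under uniform fragment sampling the terminal bases of a transcript
    # are structurally under-covered (expected depth at offset x from an end
    # is ~x * start-density, independent of the mean depth), so a strictly
    # full-length gate rejects every true gene.  30 bp covers the droop of
    # reads up to ~100 bp at the coverages the gate is meant for, while
    # remaining far smaller than any V or C gene.  Set 0 for strict gating.
    edge_trim: int = 30

    def __post_init__(self):
        if not 0 < self.candidate_fraction <= 1:
            raise ValueError("candidate_fraction must be in (0, 1]")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if self.edge_trim < 0:
            raise ValueError("edge_trim must be >= 0")


class Pileup:
    """Per-position base counts of reads assigned to one gene."""

    def __init__(self, gene_name: str, length: int):
        self.gene_name = gene_name
        self.length = length
        self.base_counts = np.zeros((4, length), dtype=np.int32)

    @property
    def depth(self) -> np.ndarray:
        return self.base_counts.sum(axis=0)


@dataclass
class ConsensusContig:
    gene_name: str
    class_key: str
    sequence: str
    mean_coverage: float
    min_depth: int

    def __len__(self) -> int:
        return len(self.sequence)


def select_candidates(
    table: HitTable, class_key: str, cfg: CandidateConfig
) -> list[str]:
    """Genes with strictly more than candidate_fraction of the class's reads,
    ordered by descending count then name."""
    counts = table.class_counts(class_key)
    total = sum(counts.values())
    if total == 0:
        return []
    threshold = cfg.candidate_fraction * total
    selected = [g for g, n in counts.items() if n > threshold]
    return sorted(selected, key=lambda g: (-counts[g], g))


def build_pileup(hits: Sequence[AlignmentHit], gene: GermlineGene) -> Pileup:
    """Place assigned read bases at reference coordinates via their alignment
    blocks.  Read-only columns (insertions) are skipped and reference-only
    columns (deletions) add no count; '-' strand hits contribute the
    reverse-complemented bases (already oriented in the stored query)."""
    pileup = Pileup(gene.gene_name, len(gene.sequence))
    L = pileup.length
    for hit in hits:
        if hit.gene_interval[0] < 0 or hit.gene_interval[1] > L:
            raise ValueError(
                f"hit interval {hit.gene_interval} outside gene {gene.gene_name}"
            )
        q = encode_seq(hit.query_seq)
        for (t0, t1), (q0, q1) in hit.blocks:
            codes = q[q0:q1]
            valid = codes <= 3
            pos = np.arange(t0, t1)[valid]
            np.add.at(pileup.base_counts, (codes[valid], pos), 1)
    return pileup


def coverage_gate(pileup: Pileup, cfg: CandidateConfig) -> bool:
    """Accept iff depth >= min_coverage at every position of the gene body
    (positions within edge_trim of an end exempted)."""
    depth = pileup.depth
    t = cfg.edge_trim
    body = depth[t : len(depth) - t] if len(depth) > 2 * t else depth
    return bool((body >= cfg.min_coverage).all())


def call_consensus(
    pileup: Pileup,
    class_key: str,
    reference: GermlineGene | None = None,
) -> ConsensusContig:
    """Majority base per position (ties broken A<C<G<T); a zero-depth
    position falls back to the reference base when one is supplied."""
    counts = pileup.base_counts
    depth = pileup.depth
    best = counts.argmax(axis=0)  # argmax returns the first max: A<C<G<T order
    seq = np.frombuffer(b"ACGT", dtype=np.uint8)[best].copy()
    zero = depth == 0
    if zero.any():
        if reference is None:
            seq[zero] = ord("N")
        else:
            ref = np.frombuffer(reference.sequence.encode("ascii"), dtype=np.uint8)
            seq[zero] = ref[zero]
    return ConsensusContig(
        gene_name=pileup.gene_name,
        class_key=class_key,
        sequence=seq.tobytes().decode("ascii"),
        mean_coverage=float(depth.mean()),
        min_depth=int(depth.min()),
    )


def dedupe_subsequences(contigs: Sequence[ConsensusContig]) -> list[ConsensusContig]:
    """Drop contigs whose sequence is a contiguous substring of a surviving
    contig (two read sets mapping to the same gene); exact duplicates collapse
    to the highest-coverage one.  Input order of survivors is preserved."""
    order = {id(c): i for i, c in enumerate(contigs)}
    # Longest first (highest coverage breaks length ties) so containers survive.
    ranked = sorted(contigs, key=lambda c: (-len(c.sequence), -c.mean_coverage))
    kept: list[ConsensusContig] = []
    for c in ranked:
        if any(c.sequence in k.sequence for k in kept):
            continue
        kept.append(c)
    return sorted(kept, key=lambda c: order[id(c)])


def write_pileup_tsv(pileup: Pileup, path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tA\tC\tG\tT\tdepth\n")
        depth = pileup.depth
        for i in range(pileup.length):
            a, c, g, t = pileup.base_counts[:, i]
            fh.write(f"{i}\t{a}\t{c}\t{g}\t{t}\t{depth[i]}\n")


def write_contigs_fasta(contigs: Sequence[ConsensusContig], path) -> None:
    """Contig FASTA with ``gene|class|mean_cov=<float>`` headers."""
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.gene_name}|{c.class_key}|mean_cov={c.mean_coverage:.2f}\n")
            for i in range(0, len(c.sequence), 60):
                fh.write(c.sequence[i : i + 60] + "\n")
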