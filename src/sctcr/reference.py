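"""Germline TRA/TRB gene references.

Loads IMGT-dialect FASTA files of V/D/J/C gene segments (one allele kept per
gene), synthesizes reproducible reference sets for download-free testing, and
derives the junction gap-size estimate used when scaffolding a V consensus to
a C consensus.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

LOCI = ("TRA", "TRB")
SEGMENTS = ("V", "D", "J", "C")

_DNA_OK = re.compile(r"^[ACGTN]+$")

STOP_CODONS = {"TAA", "TAG", "TGA"}


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (0.5 -> 1)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class GermlineGene:
    """One germline gene segment on the coding strand.

    Only the first allele of each gene is retained at load time; the true
    allele carried by a cell is recovered later from the read consensus.
    """

    locus: str
    segment: str
    gene_name: str
    allele_id: str
    sequence: str
    functionality: str = ""

    def __post_init__(self):
        if self.locus not in LOCI:
            raise ValueError(f"unknown locus {self.locus!r}")
        if self.segment not in SEGMENTS:
            raise ValueError(f"unknown segment {self.segment!r}")
        if self.locus == "TRA" and self.segment == "D":
            raise ValueError("TRA has no D segments")
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.gene_name}")
        if not _DNA_OK.match(self.sequence):
            raise ValueError(f"non-DNA characters in {self.gene_name}")

    def __len__(self) -> int:
        return len(self.sequence)


class ReferenceSet:
    """Germline genes indexed by (locus, segment), one allele per gene."""

    def __init__(self, provenance: str = ""):
        self.provenance = provenance
        # (locus, segment) -> {gene_name: GermlineGene}, insertion-ordered
        self._genes: dict[tuple[str, str], dict[str, GermlineGene]] = {}

    def add(self, gene: GermlineGene, *, replace: bool = False) -> bool:
        """Add a gene; returns False (and keeps the existing entry) if the
        gene name is already present, implementing the first-allele rule."""
        key = (gene.locus, gene.segment)
        bucket = self._genes.setdefault(key, {})
        if gene.gene_name in bucket and not replace:
            return False
        bucket[gene.gene_name] = gene
        return True

    def genes(self, locus: str, segment: str) -> list[GermlineGene]:
        return list(self._genes.get((locus, segment), {}).values())

    def require(self, locus: str, segment: str) -> list[GermlineGene]:
        genes = self.genes(locus, segment)
        if not genes:
            raise ValueError(f"reference set has no {locus} {segment} genes")
        return genes

    def get(self, locus: str, segment: str, gene_name: str) -> GermlineGene:
        return self._genes[(locus, segment)][gene_name]

    def classes(self) -> list[tuple[str, str]]:
        return list(self._genes)

    def __len__(self) -> int:
        return sum(len(b) for b in self._genes.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, ReferenceSet):
            return NotImplemented
        return self._genes == other._genes

    def update(self, other: "ReferenceSet") -> "ReferenceSet":
        for bucket in other._genes.values():
            for gene in bucket.values():
                self.add(gene)
        return self

    def validate_pipeline_classes(self) -> None:
        """The mapper queries V and C for both loci; fail loudly if absent."""
        for locus in LOCI:
            for segment in ("V", "C"):
                self.require(locus, segment)


@dataclass(frozen=True)
class GapEstimate:
    """Expected junction size between the V and C consensus, +-50%."""

    mean_gap: int
    lower: int
    upper: int

    @classmethod
    def from_mean(cls, mean_gap: int) -> "GapEstimate":
        return cls(
            mean_gap=mean_gap,
            lower=round_half_up(0.5 * mean_gap),
            upper=round_half_up(1.5 * mean_gap),
        )


def parse_header(header: str) -> tuple[str, str, str]:
    """Parse a FASTA header into (gene_name, allele_id, functionality).

    Accepts the raw IMGT pipe-delimited dialect (gene*allele in field 2,
    functionality in field 4 when present) and plain ``GENE*ALLELE ...``
    headers, so fixtures and real downloads share one loader.
    """
    header = header.strip().lstrip(">")
    functionality = ""
    if "|" in header:
        fields = header.split("|")
        token = fields[1].strip() if len(fields) > 1 else ""
        if len(fields) > 3:
            functionality = fields[3].strip()
    else:
        token = header.split()[0] if header.split() else ""
    if "*" in token:
        gene_name, _, allele_id = token.partition("*")
        allele_id = allele_id.split()[0] if allele_id else ""
    else:
        gene_name, allele_id = token, ""
    if not gene_name:
        raise ValueError(f"header without a parsable gene token: {header!r}")
    return gene_name, allele_id, functionality


def load_germline_fasta(path, locus: str, segment: str) -> ReferenceSet:
    """Load one segment class from FASTA, keeping the first allele per gene.

    Sequences are uppercased and IMGT gap characters ('.') stripped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    refset = ReferenceSet(provenance=str(path))
    for record in SeqIO.parse(str(path), "fasta"):
        gene_name, allele_id, functionality = parse_header(record.description)
        seq = str(record.seq).upper().replace(".", "")
        refset.add(
            GermlineGene(
                locus=locus,
                segment=segment,
                gene_name=gene_name,
                allele_id=allele_id or "01",
                sequence=seq,
                functionality=functionality,
            )
        )
    if len(refset) == 0:
        raise ValueError(f"no records parsed from {path}")
    return refset


def load_reference_dir(ref_dir) -> ReferenceSet:
    """Load a directory of ``<LOCUS><SEGMENT>.fasta`` files (e.g. TRBV.fasta)."""
    ref_dir = Path(ref_dir)
    refset = ReferenceSet(provenance=str(ref_dir))
    found = False
    for locus in LOCI:
        for segment in SEGMENTS:
            if locus == "TRA" and segment == "D":
                continue
            for ext in (".fasta", ".fa"):
                path = ref_dir / f"{locus}{segment}{ext}"
                if path.exists():
                    refset.update(load_germline_fasta(path, locus, segment))
                    found = True
                    break
    if not found:
        raise FileNotFoundError(f"no <LOCUS><SEGMENT>.fasta files in {ref_dir}")
    return refset


def estimate_gap_bounds(refset: ReferenceSet, locus: str) -> GapEstimate:
    """Junction-size estimate from mean germline J (TRA) or D+J (TRB) length.

    The alpha junction spans only the J segment between the trimmed V and C;
    the beta junction spans both D and J.  Means are rounded half-up before
    the +-50% tolerance is applied.
    """
    j_genes = refset.require(locus, "J")
    mean_len = float(np.mean([len(g) for g in j_genes]))
    if locus == "TRB":
        d_genes = refset.require(locus, "D")
        mean_len += float(np.mean([len(g) for g in d_genes]))
    return GapEstimate.from_mean(round_half_up(mean_len))


# ---------------------------------------------------------------------------
# Synthetic references

_DEFAULT_N = {"V": 6, "D": 2, "J": 4, "C": 1}
# IMGT-scale segment lengths: V-regions ~300 bp, J ~50-60 bp, D 12-16 bp and
# C regions ~450 bp.  Full-length chains (~800 bp) must comfortably exceed
# the ~300 bp sequencing fragments, otherwise fragment placement is
# artificially constrained around the junction.
_DEFAULT_LENGTHS = {"V": (288, 330), "D": (12, 15), "J": (51, 60), "C": (420, 480)}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_orf_sequence(rng: np.random.Generator, length: int) -> str:
    """Random DNA of the given length (a multiple of 3), stop-free in frame 0."""
    assert length % 3 == 0
    codons = []
    while len(codons) < length // 3:
        codon = bytes(_BASES[rng.integers(0, 4, size=3)]).decode()
        if codon not in STOP_CODONS:
            codons.append(codon)
    return "".join(codons)


def _edit_distance(a: str, b: str) -> int:
    import edlib

    return edlib.align(a, b)["editDistance"]


def make_synthetic_reference(
    seed: int,
    n_per_segment: Mapping[str, int] | None = None,
    length_ranges: Mapping[str, tuple[int, int]] | None = None,
    loci: Sequence[str] = LOCI,
) -> ReferenceSet:
    """Reproducible synthetic germline set for both loci.

    Emulates the shape of an IMGT download: a handful of V/J/C (and TRB D)
    segments per locus at realistic-ish lengths.  Segment lengths are
    multiples of 3 and segments carry no frame-0 stop codon, so productivity
    of a simulated chain is determined by its junction alone.  Same-segment
    genes are kept >= 20% edit distance apart so candidates are
    distinguishable by alignment.
    """
    n_per_segment = dict(_DEFAULT_N, **(n_per_segment or {}))
    length_ranges = dict(_DEFAULT_LENGTHS, **(length_ranges or {}))
    for seg in ("V", "J", "C"):
        if n_per_segment[seg] < 1:
            raise ValueError(f"need at least one {seg} gene")
    rng = np.random.default_rng(seed)
    refset = ReferenceSet(provenance=f"synthetic(seed={seed})")
    for locus in loci:
        for segment in SEGMENTS:
            if locus == "TRA" and segment == "D":
                continue
            lo, hi = length_ranges[segment]
            if lo < 1:
                raise ValueError("min length must be >= 1")
            accepted: list[str] = []
            attempts = 0
            while len(accepted) < n_per_segment[segment]:
                attempts += 1
                if attempts > 200 * n_per_segment[segment]:
                    raise ValueError(
                        f"cannot generate {n_per_segment[segment]} divergent "
                        f"{segment} genes in length range {lo}-{hi}"
                    )
                length = 3 * int(rng.integers(lo // 3, hi // 3 + 1))
                seq = _random_orf_sequence(rng, length)
                if all(
                    _edit_distance(seq, other) >= 0.2 * min(len(seq), len(other))
                    for other in accepted
                ):
                    accepted.append(seq)
            for i, seq in enumerate(accepted, start=1):
                refset.add(
                    GermlineGene(
                        locus=locus,
                        segment=segment,
                        gene_name=f"{locus}{segment}s{i}",
                        allele_id="01",
                        sequence=seq,
                        functionality="F",
                    )
                )
    return refset


# ---------------------------------------------------------------------------
# Serialization

def write_reference_fasta(refset: ReferenceSet, path, locus: str, segment: str) -> None:
    """Write one segment class as 60-column FASTA with GENE*ALLELE headers."""
    records = [
        SeqRecord(Seq(g.sequence), id=f"{g.gene_name}*{g.allele_id}", description="")
        for g in refset.genes(locus, segment)
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def write_reference_dir(refset: ReferenceSet, ref_dir) -> list[Path]:
    """Serialize every non-empty class as ``<LOCUS><SEGMENT>.fasta``."""
    ref_dir = Path(ref_dir)
    ref_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for locus, segment in refset.classes():
        path = ref_dir / f"{locus}{segment}.fasta"
        write_reference_fasta(refset, path, locus, segment)
        written.append(path)
    return written


def write_manifest_tsv(refset: ReferenceSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("locus\tsegment\tgene_name\tallele_id\tlength\n")
        for locus, segment in refset.classes():
            for g in refset.genes(locus, segment):
                fh.write(f"{locus}\t{segment}\t{g.gene_name}\t{g.allele_id}\t{len(g)}\n")
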