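"""Per-cell orchestration, cohort runs, and the sample QC gate.

The QC gate consumes a precomputed per-sample metrics table (total reads,
exonic fraction, genes detected, ERCC spike-in ratio) — the upstream genome
alignment that produces those numbers is routine external tooling and out of
scope here.  A cell passes only if all four thresholds hold strictly.

Stage order per cell: trim -> map -> candidate selection -> pileup/gate ->
consensus -> dedupe -> scaffold -> gap fill -> annotate.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import assembly, consensus as cns, mapping, reference
from .assembly import (
    ChainAnnotation,
    ClosedChain,
    GapFillConfig,
    Rejection,
    annotate_chain,
    build_scaffolds,
    fill_gap,
    write_chain_outputs,
)
from .consensus import CandidateConfig, ConsensusContig
from .mapping import (
    HitTable,
    KmerIndex,
    PairBatch,
    ReadPair,
    TrimConfig,
    UsageSummary,
    map_reads,
    read_fastq_pairs,
    tally_usage,
    trim_is_noop,
    trim_reads,
)
from .reference import ReferenceSet, estimate_gap_bounds


# ---------------------------------------------------------------------------
# QC gate

@dataclass(frozen=True)
class SampleMetrics:
    sample_id: str
    total_reads: int
    pct_exonic: float
    genes_detected: int
    ercc_ratio: float

    def __post_init__(self):
        if min(self.total_reads, self.pct_exonic, self.genes_detected, self.ercc_ratio) < 0:
            raise ValueError(f"negative metric for {self.sample_id}")
        if self.pct_exonic > 100:
            raise ValueError(f"pct_exonic > 100 for {self.sample_id}")


@dataclass(frozen=True)
class QCThresholds:
    min_total_reads: int = 250_000
    min_pct_exonic: float = 40.0
    min_genes: int = 6000
    max_ercc_ratio: float = 0.6


def qc_filter(
    metrics: Iterable[SampleMetrics], thr: QCThresholds = QCThresholds()
) -> tuple[list[SampleMetrics], list[tuple[SampleMetrics, list[str]]]]:
    """Strict-inequality gate; failures list every violated criterion."""
    passed, failed = [], []
    for m in metrics:
        reasons = []
        if not m.total_reads > thr.min_total_reads:
            reasons.append("total_reads")
        if not m.pct_exonic > thr.min_pct_exonic:
            reasons.append("pct_exonic")
        if not m.genes_detected > thr.min_genes:
            reasons.append("genes_detected")
        if not m.ercc_ratio < thr.max_ercc_ratio:
            reasons.append("ercc_ratio")
        if reasons:
            failed.append((m, reasons))
        else:
            passed.append(m)
    return passed, failed


def read_metrics_tsv(path) -> list[SampleMetrics]:
    df = pd.read_csv(path, sep="\t")
    return [
        SampleMetrics(
            sample_id=str(r.sample_id),
            total_reads=int(r.total_reads),
            pct_exonic=float(r.pct_exonic),
            genes_detected=int(r.genes_detected),
            ercc_ratio=float(r.ercc_ratio),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Configuration

@dataclass(frozen=True)
class PipelineConfig:
    evalue_max: float = 1e-8
    end_trim: int = 3
    seed: int = 0
    candidate: CandidateConfig = field(default_factory=CandidateConfig)
    gapfill: GapFillConfig = field(default_factory=GapFillConfig)
    trim: TrimConfig = field(default_factory=TrimConfig)

    def for_simulation(self, read_len: int, frag_mean: int) -> "PipelineConfig":
        """Benchmark preset: recruit distance from the simulated fragment
        size; closure overlap auto-reduced for very short reads."""
        min_overlap = self.gapfill.min_overlap
        if read_len < 2 * min_overlap:
            min_overlap = max(8, read_len // 2 - 2)
        return replace(
            self,
            gapfill=replace(
                self.gapfill, insert_size_mean=frag_mean, min_overlap=min_overlap
            ),
            trim=replace(
                self.trim, min_length_after_trim=min(self.trim.min_length_after_trim, read_len)
            ),
        )

    def to_flat(self) -> str:
        lines = []
        for group, obj in (
            ("", self),
            ("candidate", self.candidate),
            ("gapfill", self.gapfill),
            ("trim", self.trim),
        ):
            for f in dataclasses.fields(obj):
                if f.name in ("candidate", "gapfill", "trim"):
                    continue
                key = f"{group}.{f.name}" if group else f.name
                lines.append(f"{key}={getattr(obj, f.name)!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_flat(cls, text: str) -> "PipelineConfig":
        import ast

        values: dict[str, dict] = {"": {}, "candidate": {}, "gapfill": {}, "trim": {}}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            group, _, name = key.partition(".")
            if not name:
                group, name = "", key
            values[group][name] = ast.literal_eval(raw)
        return cls(
            **values[""],
            candidate=CandidateConfig(**values["candidate"]),
            gapfill=GapFillConfig(**values["gapfill"]),
            trim=TrimConfig(**values["trim"]),
        )

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_flat().encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Per-cell pipeline

@dataclass
class CellResult:
    n_pairs_input: int
    n_pairs_trimmed: int
    hit_table: HitTable
    usage: dict[str, UsageSummary]
    contigs: list[ConsensusContig]
    chains: list[ClosedChain]
    annotations: list[ChainAnnotation]
    rejections: list[Rejection]
    errors: list[str] = field(default_factory=list)

    @property
    def productive(self) -> dict[str, int]:
        out = {"TRA": 0, "TRB": 0}
        for ann in self.annotations:
            if ann.productive:
                out[ann.locus] += 1
        return out


def process_pairs(
    pairs: Iterable[ReadPair],
    refset: ReferenceSet,
    cfg: PipelineConfig = PipelineConfig(),
    index: KmerIndex | None = None,
) -> CellResult:
    """Run the full per-cell pipeline on in-memory read pairs."""
    if isinstance(pairs, PairBatch) and not trim_is_noop(pairs, cfg.trim):
        pairs = pairs.to_list()
    if isinstance(pairs, PairBatch):
        trimmed = pairs
    else:
        pairs = pairs if isinstance(pairs, list) else list(pairs)
        trimmed = list(trim_reads(pairs, cfg.trim))
    n_input = len(pairs)

    if index is None:
        index = getattr(refset, "_sctcr_kmer_index", None)
        if index is None:
            index = KmerIndex(refset)
            refset._sctcr_kmer_index = index
    table = map_reads(trimmed, refset, evalue_max=cfg.evalue_max, index=index)

    usage = {ck: tally_usage(table, ck) for ck in mapping.PIPELINE_CLASSES}

    # Pairs with at least one significantly mapped mate anchor the gap-filler.
    assigned_ids = {rid for ((rid, _mate), _ck) in table.assignments}
    if isinstance(trimmed, PairBatch):
        anchored_pairs = [
            trimmed.pair(i) for i, rid in enumerate(trimmed.ids) if rid in assigned_ids
        ]
    else:
        anchored_pairs = [p for p in trimmed if p.read_id in assigned_ids]

    contigs: list[ConsensusContig] = []
    chains: list[ClosedChain] = []
    annotations: list[ChainAnnotation] = []
    rejections: list[Rejection] = []
    errors: list[str] = []

    per_locus_contigs: dict[tuple[str, str], list[ConsensusContig]] = {}
    for class_key in mapping.PIPELINE_CLASSES:
        locus, segment = class_key[:3], class_key[3]
        selected = cns.select_candidates(table, class_key, cfg.candidate)
        accepted: list[ConsensusContig] = []
        for gene_name in selected:
            gene = refset.get(locus, segment, gene_name)
            pileup = cns.build_pileup(table.hits_for_gene(class_key, gene_name), gene)
            if not cns.coverage_gate(pileup, cfg.candidate):
                rejections.append(
                    Rejection(f"{gene_name}", "coverage_gate", "below min coverage")
                )
                continue
            accepted.append(cns.call_consensus(pileup, class_key, reference=gene))
        accepted = cns.dedupe_subsequences(accepted)
        per_locus_contigs[(locus, segment)] = accepted
        contigs.extend(accepted)

    for locus in reference.LOCI:
        v_contigs = per_locus_contigs.get((locus, "V"), [])
        c_contigs = per_locus_contigs.get((locus, "C"), [])
        if not v_contigs or not c_contigs:
            continue
        try:
            gap = estimate_gap_bounds(refset, locus)
        except ValueError as exc:
            errors.append(str(exc))
            continue
        seen_sequences: set[str] = set()
        for scaffold in build_scaffolds(v_contigs, c_contigs, locus, gap, cfg.end_trim):
            outcome = fill_gap(scaffold, anchored_pairs, cfg.gapfill)
            if isinstance(outcome, Rejection):
                rejections.append(outcome)
                continue
            if outcome.sequence in seen_sequences:
                continue
            seen_sequences.add(outcome.sequence)
            chains.append(outcome)
            annotations.append(annotate_chain(outcome, refset))

    return CellResult(
        n_pairs_input=n_input,
        n_pairs_trimmed=len(trimmed),
        hit_table=table,
        usage=usage,
        contigs=contigs,
        chains=chains,
        annotations=annotations,
        rejections=rejections,
        errors=errors,
    )


def run_cell(
    fastq_r1,
    fastq_r2,
    refset: ReferenceSet,
    cfg: PipelineConfig = PipelineConfig(),
    out_dir=None,
) -> CellResult:
    """File-based per-cell run; writes all intermediate artifacts when an
    output directory is given."""
    pairs = list(read_fastq_pairs(fastq_r1, fastq_r2))
    result = process_pairs(pairs, refset, cfg)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        mapping.write_counts_tsv(result.hit_table, out_dir / "counts.tsv")
        mapping.write_assignments_tsv(result.hit_table, out_dir / "assignments.tsv")
        write_chain_outputs(
            result.chains,
            result.contigs,
            result.annotations,
            out_dir,
            result.rejections,
        )
        (out_dir / "config.txt").write_text(cfg.to_flat())
        with open(out_dir / "run.log", "w") as fh:
            fh.write(f"[config] hash={cfg.config_hash()}\n")
            fh.write(f"[trim] pairs_in={result.n_pairs_input} pairs_kept={result.n_pairs_trimmed}\n")
            fh.write(f"[map] assignments={len(result.hit_table.assignments)}\n")
            fh.write(f"[consensus] contigs={len(result.contigs)}\n")
            fh.write(f"[gapfill] chains={len(result.chains)} rejects={len(result.rejections)}\n")
            for err in result.errors:
                fh.write(f"[error] {err}\n")
    return result


# ---------------------------------------------------------------------------
# Cohort runs

def run_cohort(
    manifest: pd.DataFrame,
    refset: ReferenceSet,
    cfg: PipelineConfig = PipelineConfig(),
    thresholds: QCThresholds = QCThresholds(),
    metrics: Sequence[SampleMetrics] | None = None,
    out_dir=None,
) -> dict[str, pd.DataFrame]:
    """QC-gate then run every sample; returns cohort summary tables.

    manifest columns: sample_id, r1, r2.  When a metrics table is supplied
    the QC gate is applied first; otherwise all samples run.  Missing files
    are reported per sample and the cohort continues.
    """
    if metrics is not None:
        passed, failed = qc_filter(metrics, thresholds)
        passed_ids = {m.sample_id for m in passed}
        qc_rows = [
            {"sample_id": m.sample_id, "qc_pass": True, "reasons": ""} for m in passed
        ] + [
            {"sample_id": m.sample_id, "qc_pass": False, "reasons": ";".join(r)}
            for m, r in failed
        ]
    else:
        passed_ids = set(manifest["sample_id"].astype(str))
        qc_rows = [
            {"sample_id": s, "qc_pass": True, "reasons": ""} for s in passed_ids
        ]

    usage_rows, total_rows, paired_rows, recovery_rows, error_rows = [], [], [], [], []
    for row in manifest.itertuples():
        sample_id = str(row.sample_id)
        if sample_id not in passed_ids:
            continue
        try:
            sample_out = Path(out_dir) / sample_id if out_dir is not None else None
            result = run_cell(row.r1, row.r2, refset, cfg, sample_out)
        except (OSError, ValueError) as exc:
            error_rows.append({"sample_id": sample_id, "error": str(exc)})
            continue
        for class_key in ("TRAV", "TRBV"):
            summary = result.usage[class_key]
            for gene, pct in summary.percentages.items():
                usage_rows.append(
                    {"sample_id": sample_id, "class": class_key, "gene": gene, "pct": pct}
                )
        total_rows.append(
            {
                "sample_id": sample_id,
                "TRAV_total": result.hit_table.class_total("TRAV"),
                "TRBV_total": result.hit_table.class_total("TRBV"),
            }
        )
        paired_rows.append(
            {
                "sample_id": sample_id,
                "top_TRBV": result.usage["TRBV"].top_gene or "",
                "top_TRAV": result.usage["TRAV"].top_gene or "",
            }
        )
        productive = result.productive
        has_c = {
            locus: any(c.class_key == f"{locus}C" for c in result.contigs)
            for locus in ("TRA", "TRB")
        }
        recovery_rows.append(
            {
                "sample_id": sample_id,
                "n_chains": len(result.chains),
                "productive_alpha": productive["TRA"],
                "productive_beta": productive["TRB"],
                "alpha_status": "ok" if has_c["TRA"] else "no_c_contig",
                "beta_status": "ok" if has_c["TRB"] else "no_c_contig",
            }
        )

    recovery = pd.DataFrame(
        recovery_rows,
        columns=[
            "sample_id", "n_chains", "productive_alpha", "productive_beta",
            "alpha_status", "beta_status",
        ],
    )
    summary_row = {
        "n_samples": len(recovery),
        "frac_ge1_productive_alpha": (
            float((recovery["productive_alpha"] >= 1).mean()) if len(recovery) else 0.0
        ),
        "frac_ge1_productive_beta": (
            float((recovery["productive_beta"] >= 1).mean()) if len(recovery) else 0.0
        ),
        "n_multi_chain": int((recovery["n_chains"] > 2).sum()) if len(recovery) else 0,
    }
    tables = {
        "qc": pd.DataFrame(qc_rows, columns=["sample_id", "qc_pass", "reasons"]),
        "usage": pd.DataFrame(usage_rows, columns=["sample_id", "class", "gene", "pct"]),
        "totals": pd.DataFrame(total_rows, columns=["sample_id", "TRAV_total", "TRBV_total"]),
        "paired": pd.DataFrame(paired_rows, columns=["sample_id", "top_TRBV", "top_TRAV"]),
        "recovery": recovery,
        "recovery_summary": pd.DataFrame([summary_row]),
        "errors": pd.DataFrame(error_rows, columns=["sample_id", "error"]),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out_dir / f"cohort_{name}.tsv", sep="\t", index=False)
    return tables
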