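"""In-silico TCR read simulation and the recovery benchmark.

Synthetic receptor chains are built by randomly concatenating germline
segments (V-J-C for alpha, V-D-J-C for beta) with uniform random bases
inserted at the junctions (0/3/6/9 bp), read pairs are sampled from
300+-30 bp fragments with a parametric per-cycle substitution error model,
and mixed with background reads at 3 TCR : 997 background — the empirical
fraction of reads mapping to the TCR loci in whole-transcript scRNA-seq.
A chain counts as recovered only when the pipeline output contains the true
junction with 10 germline bases of flank on each side and the V, J and C
gene calls match the truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .mapping import PairBatch, ReadPair, encode_seq, revcomp
from .reference import ReferenceSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def ramp_error_profile(
    read_len: int, start: float = 0.001, end: float = 0.01, mean: float | None = None
) -> np.ndarray:
    """Per-cycle substitution probabilities rising linearly from start to end
    (Illumina-like 3' degradation).  If mean is given the ramp is rescaled to
    that mean rate."""
    profile = np.linspace(start, end, read_len)
    if mean is not None:
        profile = profile * (mean / profile.mean())
    if not ((0 <= profile) & (profile < 1)).all():
        raise ValueError("error probabilities must lie in [0, 1)")
    return profile


@dataclass
class SimConfig:
    """Study conditions of the in-silico benchmark."""

    read_len: int = 100
    frag_mean: int = 300
    frag_sd: int = 30
    coverages: tuple[int, ...] = (10, 50, 100)
    insertion_lengths: tuple[int, ...] = (0, 3, 6, 9)
    tcr_background_ratio: tuple[int, int] = (3, 997)
    error_profile: np.ndarray | None = None  # None -> default ramp
    n_chain_pairs: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.frag_mean < self.read_len:
            raise ValueError("frag_mean must be >= read_len")
        if min(self.tcr_background_ratio) <= 0:
            raise ValueError("ratio components must be positive")

    def profile(self) -> np.ndarray:
        if self.error_profile is None:
            return ramp_error_profile(self.read_len)
        p = np.asarray(self.error_profile, dtype=float)
        if p.size != self.read_len:
            raise ValueError("error profile length must equal read_len")
        return p


@dataclass
class SimulatedChain:
    locus: str
    v_gene: str
    d_gene: str | None
    j_gene: str
    c_gene: str
    inserted_vj: str | None
    inserted_vd: str | None
    inserted_dj: str | None
    sequence: str
    v_len: int
    c_len: int


@dataclass
class TruthRecord:
    chain_id: str
    chain: SimulatedChain

    @property
    def junction_nt(self) -> str:
        """Bases between the last V base and the first C base."""
        s = self.chain.sequence
        return s[self.chain.v_len : len(s) - self.chain.c_len]

    @property
    def junction_interval(self) -> tuple[int, int]:
        return (self.chain.v_len, len(self.chain.sequence) - self.chain.c_len)


def _random_bases(rng: np.random.Generator, n: int) -> str:
    if n == 0:
        return ""
    return bytes(_BASES[rng.integers(0, 4, size=n)]).decode()


def simulate_chain(
    refset: ReferenceSet, locus: str, ins_len: int, rng: np.random.Generator
) -> SimulatedChain:
    """Uniformly random V(/D)/J/C draw with ins_len inserted bases at the V-J
    junction (alpha) or at both the V-D and D-J junctions (beta)."""
    v = refset.require(locus, "V")
    j = refset.require(locus, "J")
    c = refset.require(locus, "C")
    vg = v[rng.integers(0, len(v))]
    jg = j[rng.integers(0, len(j))]
    cg = c[rng.integers(0, len(c))]
    if locus == "TRB":
        d = refset.require(locus, "D")
        dg = d[rng.integers(0, len(d))]
        ins_vd = _random_bases(rng, ins_len)
        ins_dj = _random_bases(rng, ins_len)
        seq = vg.sequence + ins_vd + dg.sequence + ins_dj + jg.sequence + cg.sequence
        return SimulatedChain(
            locus, vg.gene_name, dg.gene_name, jg.gene_name, cg.gene_name,
            None, ins_vd, ins_dj, seq, len(vg.sequence), len(cg.sequence),
        )
    ins_vj = _random_bases(rng, ins_len)
    seq = vg.sequence + ins_vj + jg.sequence + cg.sequence
    return SimulatedChain(
        locus, vg.gene_name, None, jg.gene_name, cg.gene_name,
        ins_vj, None, None, seq, len(vg.sequence), len(cg.sequence),
    )


def _phred_string(profile: np.ndarray) -> str:
    q = np.clip(np.round(-10 * np.log10(np.maximum(profile, 1e-4))), 2, 41)
    return "".join(chr(int(v) + 33) for v in q)


def _apply_errors(codes: np.ndarray, profile: np.ndarray, rng) -> np.ndarray:
    err = rng.random(codes.shape) < profile
    if err.any():
        codes = codes.copy()
        shift = rng.integers(1, 4, size=int(err.sum()))
        codes[err] = (codes[err] + shift) % 4
    return codes


def simulate_read_pairs(
    template: str,
    cfg: SimConfig,
    coverage: float,
    rng: np.random.Generator,
    id_prefix: str = "tcr",
    placements: list | None = None,
) -> list[ReadPair]:
    """Paired reads from Normal(frag_mean, frag_sd) fragments placed uniformly
    on the template; mate1 reads the fragment 5' end forward, mate2 the 3'
    end reverse-complemented; substitutions per the per-cycle profile.

    When a list is passed as ``placements`` it receives one
    (fragment_start, fragment_length) tuple per pair, for truth-tracking.
    """
    L = len(template)
    rl = cfg.read_len
    if L < rl:
        raise ValueError("template shorter than read_len")
    n_pairs = math.ceil(coverage * L / (2 * rl))
    profile = cfg.profile()
    qual = _phred_string(profile)
    tcodes = _BASES.searchsorted(
        np.frombuffer(template.encode("ascii"), dtype=np.uint8)
    )  # template is ACGT-only by construction
    frags = np.clip(
        np.rint(rng.normal(cfg.frag_mean, cfg.frag_sd, size=n_pairs)), rl, L
    ).astype(int)
    pairs = []
    for i in range(n_pairs):
        f = frags[i]
        s = int(rng.integers(0, L - f + 1))
        if placements is not None:
            placements.append((s, int(f)))
        m1 = _apply_errors(tcodes[s : s + rl], profile, rng)
        m2_src = tcodes[s + f - rl : s + f][::-1]
        m2 = _apply_errors((3 - m2_src) % 4, profile, rng)  # reverse complement
        pairs.append(
            ReadPair(
                f"{id_prefix}_{i}",
                bytes(_BASES[m1]).decode(),
                bytes(_BASES[m2]).decode(),
                qual,
                qual,
            )
        )
    return pairs


def simulate_background_pairs(
    n_pairs: int,
    cfg: SimConfig,
    rng: np.random.Generator,
    background_fasta: str | None = None,
    id_prefix: str = "bg",
) -> list[ReadPair]:
    """Background read pairs: fragments of a supplied genome FASTA, or i.i.d.
    uniform DNA when none is given (download-free default)."""
    rl = cfg.read_len
    qual = "I" * rl
    if background_fasta is not None:
        from Bio import SeqIO

        seqs = [
            str(r.seq).upper()
            for r in SeqIO.parse(str(background_fasta), "fasta")
            if len(r.seq) >= cfg.frag_mean + 4 * cfg.frag_sd
        ]
        if not seqs:
            raise ValueError("background FASTA shorter than fragment length")
        pairs = []
        for i in range(n_pairs):
            src = seqs[rng.integers(0, len(seqs))]
            f = int(np.clip(round(rng.normal(cfg.frag_mean, cfg.frag_sd)), rl, len(src)))
            s = int(rng.integers(0, len(src) - f + 1))
            frag = src[s : s + f]
            pairs.append(
                ReadPair(f"{id_prefix}_{i}", frag[:rl], revcomp(frag[-rl:]), qual, qual)
            )
        return pairs
    codes = rng.integers(0, 4, size=(n_pairs, 2, rl), dtype=np.int8)
    raw = _BASES[codes]
    return [
        ReadPair(
            f"{id_prefix}_{i}",
            raw[i, 0].tobytes().decode(),
            raw[i, 1].tobytes().decode(),
            qual,
            qual,
        )
        for i in range(n_pairs)
    ]


def mix_with_background(
    tcr_pairs: Sequence[ReadPair],
    cfg: SimConfig,
    rng: np.random.Generator,
    background_fasta: str | None = None,
    as_batch: bool = False,
) -> "tuple[list[ReadPair] | PairBatch, dict[str, str]]":
    """Shuffle TCR pairs into background at the configured ratio; the
    manifest labels every read id with its origin.

    With as_batch=True the mixture is returned as an encoded PairBatch
    (uniform read length required), which keeps samples with hundreds of
    thousands of background pairs cheap to screen.
    """
    n_tcr = len(tcr_pairs)
    a, b = cfg.tcr_background_ratio
    n_bg = round(n_tcr * b / a)
    if as_batch:
        rl = cfg.read_len
        if any(len(p.seq1) != rl or len(p.seq2) != rl for p in tcr_pairs):
            raise ValueError("as_batch requires uniform read length")
        if background_fasta is not None:
            bg_pairs = simulate_background_pairs(n_bg, cfg, rng, background_fasta)
            bg_codes = np.stack(
                [
                    np.stack([encode_seq(p.seq1), encode_seq(p.seq2)])
                    for p in bg_pairs
                ]
            ) if bg_pairs else np.empty((0, 2, rl), np.uint8)
        else:
            bg_codes = rng.integers(0, 4, size=(n_bg, 2, rl), dtype=np.uint8)
        codes = np.empty((n_tcr + n_bg, 2, rl), dtype=np.uint8)
        ids = [p.read_id for p in tcr_pairs] + [f"bg_{i}" for i in range(n_bg)]
        quals = [p.qual1 for p in tcr_pairs] + ["I" * rl] * n_bg
        for i, p in enumerate(tcr_pairs):
            codes[i, 0] = encode_seq(p.seq1)
            codes[i, 1] = encode_seq(p.seq2)
        codes[n_tcr:] = bg_codes
        manifest = {
            rid: ("tcr" if i < n_tcr else "background") for i, rid in enumerate(ids)
        }
        perm = rng.permutation(n_tcr + n_bg)
        batch = PairBatch(
            [ids[i] for i in perm], codes[perm], [quals[i] for i in perm]
        )
        return batch, manifest
    bg = simulate_background_pairs(n_bg, cfg, rng, background_fasta)
    combined = list(tcr_pairs) + bg
    manifest = {p.read_id: ("tcr" if i < n_tcr else "background")
                for i, p in enumerate(combined)}
    perm = rng.permutation(len(combined))
    return [combined[i] for i in perm], manifest


# ---------------------------------------------------------------------------
# Recovery scoring

@dataclass
class RecoveryResult:
    recovered: bool
    reasons: list[str] = field(default_factory=list)


def evaluate_recovery(
    chains, annotations, truth: TruthRecord, refset: ReferenceSet
) -> RecoveryResult:
    """Recovered iff some closed chain contains the true junction plus 10
    germline flanking bases on each side, and its V/J/C calls are the truth."""
    ch = truth.chain
    v_seq = refset.get(ch.locus, "V", ch.v_gene).sequence
    c_seq = refset.get(ch.locus, "C", ch.c_gene).sequence
    needle = v_seq[-10:] + truth.junction_nt + c_seq[:10]
    if not chains:
        return RecoveryResult(False, ["no_chain"])
    reasons = set()
    for chain, ann in zip(chains, annotations):
        if chain.locus != ch.locus:
            continue
        if needle not in chain.sequence:
            reasons.add("junction_mismatch")
            continue
        if (chain.v_gene, ann.j_gene, chain.c_gene) != (
            ch.v_gene,
            ch.j_gene,
            ch.c_gene,
        ):
            reasons.add("wrong_genes")
            continue
        return RecoveryResult(True)
    return RecoveryResult(False, sorted(reasons) or ["no_chain_for_locus"])


def run_benchmark(
    refset: ReferenceSet,
    cfg: SimConfig,
    read_lens: Sequence[int] = (25, 50, 75, 100),
    coverages: Sequence[int] | None = None,
    n_chain_pairs: int | None = None,
    background_fasta: str | None = None,
    pipeline_config=None,
) -> pd.DataFrame:
    """Recovery fractions over the read-length x coverage grid.

    Each synthetic "cell" carries one alpha and one beta chain; for every
    grid point, n_chain_pairs cells are simulated per junction-insertion
    length, mixed with background, and pushed through the full pipeline.
    Pipeline errors score as non-recovery without aborting the grid.
    """
    from . import pipeline as pl

    coverages = tuple(coverages if coverages is not None else cfg.coverages)
    n_chain_pairs = n_chain_pairs if n_chain_pairs is not None else cfg.n_chain_pairs
    base_cfg = pipeline_config if pipeline_config is not None else pl.PipelineConfig()
    ss = np.random.SeedSequence(cfg.seed)
    rows = []
    for read_len in read_lens:
        for coverage in coverages:
            if cfg.error_profile is None:
                profile = None
            else:
                # Resample the supplied per-cycle profile to this read length,
                # preserving its shape (a flat profile stays flat).
                src = np.asarray(cfg.error_profile, dtype=float)
                profile = np.interp(
                    np.linspace(0, 1, read_len), np.linspace(0, 1, src.size), src
                )
            cell_cfg = replace(cfg, read_len=read_len, error_profile=profile)
            pcfg = base_cfg.for_simulation(read_len, cfg.frag_mean)
            n_rec = {"TRA": 0, "TRB": 0}
            n_tot = {"TRA": 0, "TRB": 0}
            for ins_len in cfg.insertion_lengths:
                for _ in range(n_chain_pairs):
                    (child,) = ss.spawn(1)
                    rng = np.random.default_rng(child)
                    truths = {}
                    tcr_pairs: list[ReadPair] = []
                    for locus in ("TRA", "TRB"):
                        chain = simulate_chain(refset, locus, ins_len, rng)
                        truths[locus] = TruthRecord(f"{locus}_{ins_len}", chain)
                        tcr_pairs.extend(
                            simulate_read_pairs(
                                chain.sequence,
                                cell_cfg,
                                coverage,
                                rng,
                                id_prefix=f"{locus.lower()}",
                            )
                        )
                    pairs, _ = mix_with_background(
                        tcr_pairs, cell_cfg, rng, background_fasta, as_batch=True
                    )
                    try:
                        result = pl.process_pairs(pairs, refset, pcfg)
                        chains, anns = result.chains, result.annotations
                    except Exception:
                        chains, anns = [], []
                    for locus in ("TRA", "TRB"):
                        n_tot[locus] += 1
                        rec = evaluate_recovery(chains, anns, truths[locus], refset)
                        if rec.recovered:
                            n_rec[locus] += 1
            for locus in ("TRA", "TRB"):
                rows.append(
                    {
                        "read_len": read_len,
                        "coverage": coverage,
                        "locus": locus,
                        "n": n_tot[locus],
                        "n_recovered": n_rec[locus],
                        "fraction": n_rec[locus] / n_tot[locus] if n_tot[locus] else 0.0,
                    }
                )
    return pd.DataFrame(rows)


def write_truth_tsv(truths: Sequence[TruthRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chain_id\tlocus\tv_gene\td_gene\tj_gene\tc_gene\t"
            "inserted_vj\tinserted_vd\tinserted_dj\tjunction_nt\n"
        )
        for t in truths:
            c = t.chain
            fh.write(
                f"{t.chain_id}\t{c.locus}\t{c.v_gene}\t{c.d_gene or ''}\t"
                f"{c.j_gene}\t{c.c_gene}\t{c.inserted_vj or ''}\t"
                f"{c.inserted_vd or ''}\t{c.inserted_dj or ''}\t{t.junction_nt}\n"
            )


def write_manifest_tsv(manifest: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\torigin\n")
        for read_id, origin in manifest.items():
            fh.write(f"{read_id}\t{origin}\n")
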