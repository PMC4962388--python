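# Reproduction recipes (network required)

The desk test-suite and `scripts/acceptance.py` run entirely on synthetic
references and reads.  The recipes in this directory reproduce the analyses
on the original public data; they download reference and sequencing data and
are therefore **not** run by the test suite.

Prerequisites: `curl`, `seqtk`, the `sctcr` CLI on PATH, and (for the cohort
recipe) an SRA/ENA download tool.

| Recipe | What it reproduces | Data |
| --- | --- | --- |
| `imgt_simulation_benchmark.sh` | In-silico recovery benchmark on human germline genes with genomic background (read lengths 25/50/75/100 bp, coverages 10/50/100x, insertions 0/3/6/9 bp, 3:997 mixing) | IMGT/GENE-DB human TRA/TRB V, D, J, C; hg19 |
| `jurkat_subsampling.sh` | Full-chain recovery from bulk RNA-seq of Jurkat replicates, with seqtk subsampling at 50 k - 5 M read pairs x 6 seeds (insert-size preset 148) | GEO GSE45428 |
| `mouse_cohort.sh` | Per-cell QC gating and paired alpha/beta reconstruction across the 91 mouse T helper cells (insert-size preset 175) | ArrayExpress E-MTAB-2512 |

Each recipe writes its outputs under `repro_out/<recipe>/`.  The IMGT
germline FASTA files must be saved as `<LOCUS><SEGMENT>.fasta`
(e.g. `TRBV.fasta`) in the reference directory; the loader accepts raw IMGT
pipe-delimited headers and keeps the first allele of each gene.
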