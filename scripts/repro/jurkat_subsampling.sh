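#!/usr/bin/env bash
# Jurkat replicate recovery and read-depth subsampling (GEO GSE45428).
# Expected: one productive alpha (TRAV8-4/TRAJ3/TRAC) and one productive
# beta (TRBV12-3/TRBD1/TRBJ1-2/TRBC2) chain per replicate; the beta chain
# recovered at >= 100k pairs, the alpha at >= 500k pairs, in all seeds.
set -euo pipefail

OUT=repro_out/jurkat
REF=repro_out/imgt_benchmark/imgt_human   # from imgt_simulation_benchmark.sh
mkdir -p "$OUT"

# 1. Fetch the three replicate FASTQ pairs of GSE45428 (via SRA; accessions
#    resolvable from the GEO series page) into $OUT/rep{1,2,3}_R{1,2}.fastq.gz
echo ">> download GSE45428 replicates into $OUT before continuing" >&2

for rep in 1 2 3; do
    R1="$OUT/rep${rep}_R1.fastq.gz"; R2="$OUT/rep${rep}_R2.fastq.gz"
    [ -f "$R1" ] || continue

    # full-depth run, Jurkat-like insert preset (mean 148)
    sctcr run --r1 "$R1" --r2 "$R2" --ref-dir "$REF" \
        --insert-preset jurkat-like --out "$OUT/rep${rep}_full"

    # subsampling grid: 50k/100k/500k/1M/5M pairs x 6 seeds
    for depth in 50000 100000 500000 1000000 5000000; do
        for seed in 11 12 13 14 15 16; do
            seqtk sample -s"$seed" "$R1" "$depth" > "$OUT/tmp_R1.fastq"
            seqtk sample -s"$seed" "$R2" "$depth" > "$OUT/tmp_R2.fastq"
            sctcr run --r1 "$OUT/tmp_R1.fastq" --r2 "$OUT/tmp_R2.fastq" \
                --ref-dir "$REF" --insert-preset jurkat-like \
                --out "$OUT/rep${rep}_d${depth}_s${seed}"
        done
    done
done
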