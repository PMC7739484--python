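#!/usr/bin/env bash
# Run the whole pipeline from the shell: simulate every input table with
# planted truth, then re-analyze the simulated tables stage by stage.
set -euo pipefail

out=scratch/example_run
mkdir -p "$out"

nichepart simulate --out "$out/sim" --seed 1

nichepart detect  --out "$out/detect" \
    --coverage "$out/sim/detection.tsv" --samples "$out/sim/samples.tsv"
nichepart derep   --out "$out/derep" \
    --genomes "$out/sim/genomes.tsv" --ani "$out/sim/ani.tsv"
nichepart enrich  --out "$out/enrich" \
    --gene-clusters "$out/sim/gene_clusters.tsv" \
    --annotations "$out/sim/annotations.tsv" \
    --groups "$out/sim/genome_groups.tsv"
nichepart snv     --out "$out/snv" \
    --snv "$out/sim/snv.tsv" --snv-groups "$out/sim/snv_groups.tsv"

echo "--- specificity calls ---"
head -5 "$out/detect/specificity_calls.tsv"
echo "--- SNV group summary ---"
cat "$out/snv/group_summary.tsv"
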