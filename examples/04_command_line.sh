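#!/usr/bin/env bash
# The same pipeline from the shell: simulate reads with a YAML spec,
# index them, assemble, and score against the truth genome.
set -euo pipefail
workdir=$(mktemp -d)

cat > "$workdir/spec.yaml" <<EOF
genome_len: 10000
depth: 30
read_len: 100
insert_mean: 300
insert_sd: 30
EOF

adaseed simulate --spec "$workdir/spec.yaml" -o "$workdir/sim" --seed 11
adaseed index "$workdir/sim_1.fastq" "$workdir/sim_2.fastq" -o "$workdir/idx"
adaseed assemble "$workdir/idx" -o "$workdir/contigs.fa" \
    --depth 30 --insert 300,30
adaseed eval "$workdir/contigs.fa" "$workdir/sim_genome.fa"

rm -rf "$workdir"
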