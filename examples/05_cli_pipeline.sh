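#!/bin/sh
# Full shell pipeline: simulate a genome with planted ground truth, then
# run scan -> date -> classify -> synteny -> ksdist -> report on it.
# All outputs are plain text (FASTA/GFF3/TSV/JSON) under out/.
set -e

paleoevo simulate --seed 7 --genome-size 1000000 --n-elements 20 \
    --ages 0.5,2,5 --ks 0.3 --n-genes 80 --out out/sim

paleoevo pipeline --in out/sim --out out/run

echo "--- duplication report ---"
cat out/run/report/report.json
echo "--- age histogram (first lines) ---"
head -5 out/run/date/age_histogram.tsv
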