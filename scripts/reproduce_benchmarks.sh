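#!/usr/bin/env sh
# Optional: run the pipeline on the published plant 6mA benchmark datasets.
#
# The datasets are NOT bundled with this package; obtain the positive and
# negative FASTA files for rice-Lv (154,000 + 154,000 windows), F. vesca
# (1,966 + 1,966), R. chinensis (813 + 813) and A. thaliana
# (31,873 + 31,873) from their public repositories and place them under
# $DATA. Every window must be 41 bp. Expect several CPU-hours for the
# full rice-Lv cross-validation.
set -eu

DATA=${DATA:-data}
OUT=${OUT:-benchmark_runs}
SEED=${SEED:-1}

# Five-fold cross-validation on rice-Lv (within-species benchmark).
sixmanet cv --pos "$DATA/rice_lv_pos.fasta" --neg "$DATA/rice_lv_neg.fasta" \
    --k 5 --seed "$SEED" --out "$OUT/rice_cv"

# Train once on rice-Lv; apply the frozen selector + network cross-species.
sixmanet train --pos "$DATA/rice_lv_pos.fasta" --neg "$DATA/rice_lv_neg.fasta" \
    --seed "$SEED" --out "$OUT/rice_model"

for species in f_vesca r_chinensis a_thaliana; do
    sixmanet evaluate --model "$OUT/rice_model" \
        --pos "$DATA/${species}_pos.fasta" --neg "$DATA/${species}_neg.fasta" \
        --out "$OUT/${species}_balanced"
    # Imbalanced variants: keep all negatives, downsample positives.
    for ratio in 5 10; do
        sixmanet subsample --pos "$DATA/${species}_pos.fasta" \
            --neg "$DATA/${species}_neg.fasta" --ratio "$ratio" \
            --seed "$SEED" --out "$OUT/${species}_1to${ratio}"
        sixmanet evaluate --model "$OUT/rice_model" \
            --pos "$OUT/${species}_1to${ratio}"/*_1to${ratio}_pos.fasta \
            --neg "$OUT/${species}_1to${ratio}"/*_1to${ratio}_neg.fasta \
            --out "$OUT/${species}_1to${ratio}_eval"
    done
done
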