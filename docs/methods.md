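# Methods

## Problem and pipeline

`sixmanet` classifies 41-bp DNA windows, centered on a candidate adenine,
as N6-methyladenine (6mA) sites or not. The pipeline is:

1. **Encoding.** Each base maps to an 8-vector: its one-hot indicator
   (order A, T, C, G), its three nucleotide-chemical-property coordinates
   (ring structure, hydrogen-bond strength, amino/keto group), and its
   electron–ion interaction potential (A 0.1260, T 0.1335, C 0.1340,
   G 0.0806, stored exactly at the tabulated four decimals, unscaled).
   The 41×8 matrix is flattened row-major, so the 8 features of position
   *i* occupy slots 8i…8i+7 of the 328-vector. The column order within a
   block (one-hot, then NCP, then EIIP) is a frozen convention; any fixed
   order is equivalent for the model, but it must be stable for saved
   selectors to transfer.

2. **Feature selection.** A linear elastic net regresses the 0/1 labels
   on the 328 features: min‖y−Xβ‖² + λ₁‖β‖₁ + λ₂‖β‖₂². Features with
   exactly nonzero fitted coefficients are retained — the solver's native
   sparsity, with no magnitude threshold (a `select_top_k` /
   `--select-k` compatibility mode exists for users who want a fixed
   dimensionality). The retained count is data- and penalty-dependent and
   is therefore *reported*, never asserted. The fit sees the training
   partition only; in cross-validation the selector is refit inside each
   fold and the per-fold index sets recorded.

3. **Classifier.** A small 1-D CNN on the reduced vector (length D):
   conv(64 filters, kernel 7, stride 1, valid padding) → batch
   normalization → ELU → flatten ((D−6)·64 units) → dense(16, ELU) →
   dense(8, ELU) → dense(1, sigmoid). Training: SGD with momentum 0.9,
   learning rate 10⁻³, binary cross-entropy, batch size 256, at most 100
   epochs, early stopping when validation accuracy has not improved for
   10 epochs, best-epoch weights restored. Scores ≥ 0.5 are called 6mA
   (the tie at exactly 0.5 is called positive by convention).

4. **Evaluation.** Acc, Sn, Sp, MCC from the confusion counts; trapezoid
   ROC AUC; AUPRC in the average-precision (step-interpolation)
   convention. Stratified, seeded five-fold cross-validation reports
   mean ± standard deviation per metric. Cross-species evaluation applies
   a trained selector + network unchanged to another labeled dataset.
   Imbalanced test sets are built by keeping **all** negatives and
   drawing ⌊n_neg/r⌋ positives uniformly without replacement — the rule
   consistent with the benchmark ratio counts (e.g. 1966 negatives at
   1:10 → 196 positives; 31,873 at 1:5 → 6,374).

## Parameters that matter

| parameter | default | role |
|---|---|---|
| window length | 41 bp | fixes all downstream shapes (41×8 → 328); configurable |
| λ₁, λ₂ | data-driven (see below) | selection sparsity; both ≥ 0, exposed everywhere |
| conv filters / kernel / stride | 64 / 7 / 1 | the single convolutional layer |
| batch-norm momentum / ε | 0.8 / 10⁻⁵ | 0.8 weighs the *running* statistic: new = 0.8·old + 0.2·batch |
| ELU α | 1.0 | canonical slope for the negative branch |
| learning rate / SGD momentum | 0.001 / 0.9 | optimizer |
| patience / max epochs / batch | 10 / 100 / 256 | early-stopping regime |
| validation fraction | 0.1 | stratified, seeded split used only to monitor early stopping |
| decision threshold | 0.5 | score ≥ threshold → 6mA |
| imbalance ratio r | 5 or 10 | negatives per positive in subsampled sets |

**Default penalties.** No canonical single (λ₁, λ₂) exists for this
problem. The default uses an equal L1/L2 mix and overall strength
0.05·α_max, where α_max is the smallest penalty that zeroes every
coefficient on the standardized training data (the anchor of the usual
regularization path). This keeps strongly informative columns while
zeroing isotropic noise at desk-scale sample sizes, and adapts to sample
size and feature scale; both λs are configurable for users who want a
specific operating point.

**Standardization.** Features are standardized (zero mean, unit variance,
training statistics only) before the elastic-net fit, because the design
mixes binary indicator columns with EIIP values an order of magnitude
smaller and penalized regression is scale-sensitive. The transform is
stored in the selector sidecar and replayed at apply time, so the
train-only protocol is preserved end-to-end. Whether to standardize was a
genuinely open design point; unstandardized fitting is recoverable by
pre-scaling inputs. The classical elastic-net rescaling factor (1+λ₂/n)
on the fitted coefficients is omitted: it rescales coefficients uniformly
and cannot change the nonzero set, which is all the selector consumes.

## Numerical choices

- Elastic-net solver: coordinate descent (scikit-learn), tolerance 10⁻⁶,
  max 10,000 iterations; non-convergence logs a warning. λ₁ = λ₂ = 0
  falls back to ordinary least squares (all features retained on generic
  full-rank designs).
- The CNN is implemented in NumPy with hand-written backpropagation;
  gradient correctness is pinned by central-difference checks (tolerance
  10⁻⁶ absolute) in the test suite. Weight init is seeded He-normal;
  shuffling and the validation split flow from the same training seed, so
  runs are bit-reproducible on one machine.
- Batch-norm uses batch statistics in training and the running averages
  at inference; predictions are therefore deterministic functions of the
  saved weights (save/load round-trips scores to 10⁻⁶).
- MCC with a zero denominator, and Sn/Sp with an empty class, are defined
  as 0.
- Convolution padding is "valid": the layer sees the reduced vector as a
  single-channel signal and no synthetic boundary values are introduced.
  Dense-layer ELU activations (after conv and on the 16- and 8-unit
  layers) are a design choice; without a nonlinearity the two hidden
  dense layers would collapse into one linear map.
- AUPRC uses average precision (step interpolation), avoiding the known
  optimism of linear interpolation between precision–recall points;
  trapezoidal ROC AUC equals the all-pairs Mann–Whitney statistic with
  ties counted ½.

## Synthetic data: what it does and does not show

The generator plants a short motif (default GAGG, a context enriched near
rice 6mA sites) at a fixed offset by substitution into an i.i.d. uniform
background, forcing the central adenine; positives carry the motif with
probability `signal_strength`, negatives with the complement, and a
sequence assigned "no motif" is guaranteed not to match it at the
planting offset. `signal_strength = 1` gives a perfectly separable
dataset; `0.5` makes the classes exchangeable — a clean chance-level null.

This exercises every pipeline stage with known ground truth: the selector
should concentrate on the one-hot columns of the motif positions, the
CNN should reach ≥ 0.95 held-out accuracy at full strength and ~0.5 on
the null. It does **not** emulate real 6mA context statistics —
positional nucleotide biases, dispersed and degenerate motifs, genomic
composition, label noise — so passing these tests demonstrates that the
machinery is correct and leakage-free, not that real-data accuracies will
match published figures. Runs on the real benchmarks go through
`scripts/reproduce_benchmarks.sh` (external download, hours of CPU).

Test and acceptance problem sizes are deliberately desk-scale: 300–1,000
windows per class for end-to-end checks, n = 500 designs for selector
properties, 10,000 samples × 100 seeds for the AUPRC-baseline property.

## Known limitations

- The linear elastic net screens features marginally; motifs visible only
  through higher-order interactions could be discarded before the CNN
  sees them.
- Training is single-threaded NumPy; the full 308,000-window rice
  benchmark is hours of CPU, not minutes.
- Inputs must be pre-windowed 41-bp (configurable) sequences; no genome
  scanning or window extraction is provided.
- Only {A,C,G,T} windows are scored; ambiguity codes are rejected (or
  dropped and counted under `--skip-invalid`), and a non-adenine central
  base warns rather than errors, since negative-set construction
  conventions vary between benchmark releases.
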