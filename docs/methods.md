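# Methods

## The model

`peakvar` links genome sequence to quantitative chromatin accessibility with
convolutional neural networks and uses those networks for in silico
mutagenesis of non-coding variants.

**Sequence-to-signal regression.** Each open-chromatin peak contributes one
training example: a fixed-length window (1000 bp for bulk DNase/ATAC models,
500 bp for scATAC pseudobulk models) centred on the peak summit, one-hot
encoded as an L x 4 matrix (columns A, C, G, T; unknown bases are all-zero
rows). The label is the peak's signal value — the pipeline signalValue for
bulk data, or the natural log of the MACS2 score for scATAC pseudobulk
peaks. The network is a stack of convolution blocks with ReLU activations,
max pooling, dropout, an optional dense sigmoid layer and a single linear
output unit, trained with SGD to minimise mean squared error. For scATAC
labels a threshold-weighted MSE (weight `factor` on examples with signal
above `threshold`; defaults 3 and 4) keeps the strongest peaks from being
neglected, and a triangular cyclic learning rate can replace the constant
one. Model selection is always the epoch with the lowest validation loss.

**Classification.** The classifier variant uses the same trunk with a
sigmoid output and cross-entropy loss. Its negatives are background windows
sampled to match the G+C content of the peak windows (tolerance 0.02, two
negatives per positive by default) with any window overlapping a peak
removed — without GC matching the model largely learns base composition.

**Chromosome-holdout splits.** Train/validation/test sets are partitioned by
whole chromosome (bulk default: chr4 validation, chr8+9 test; the MPRA
models hold out chr3+7 for validation and twelve chromosomes for test), so
no test sequence shares local context with training data.

**Variant scoring.** For an SNV at 1-based position p, two windows are built
on the forward reference strand — 499 bp left / 500 bp right of the variant
for 1000 bp models, 249/250 for 500 bp models — one carrying the reference
allele, one the alternate. The predicted allelic skew is

    delta = s(ref) - s(alt),

so positive delta means the reference allele is predicted more active.
Classifier outputs are logit-transformed (eps = 1e-7) before differencing.
By default both strands are scored and averaged, which cancels
strand-specific prediction noise and preserves the exact antisymmetry of
delta under allele swap.

**The empirical null and outlier calling.** A large background variant set
restricted to open-chromatin regions is scored through the same model; the
sample standard deviation (n-1 denominator) of those deltas scales disease
variant deltas into z-scores. No mean is subtracted: the null is treated as
centred at zero, because most variants have no regulatory effect. Two-sided
Gaussian p-values `2(1 - Phi(|z|))`, Benjamini-Hochberg q-values computed
over exactly the in-OCR disease variants for that model, and an outlier flag
(`|z| >= 2` and in-OCR) follow. Variants outside OCRs may still be scored
for cross-cell-type comparison but are never flagged and carry no q-value.
The 2 s.d. cutoff keeps roughly 95% of a Gaussian inside; because the
empirical null is heavier-tailed than Gaussian the cutoff is conservative.
`normality_diagnostics` quantifies this with a Shapiro-Wilk test and
matched-moment Gaussian and Laplace reference samples (a Laplace with the
null's sd puts the 2 s.d. cutoff at 2*sqrt(2) ~ 2.82 scale units; its excess
kurtosis is 3).

**MPRA evaluation.** Reporter-assay oligo records (150 bp span, reverse-
complement flag, co-variant substitutions, measured log2(RNA/DNA) activity,
allelic skew and FDR q-value) are re-embedded in model-length windows: the
oligo span is centred (odd padding puts the extra base on the right), the
focal allele substituted, every co-variant's alternate allele substituted
identically in both members of a ref/alt pair, and the whole window
reverse-complemented when the assayed oligo was. Variants are categorised as
skew-positive emVars (skew >= 0.2 at q below the threshold), skew-negative
emVars, neutral (|skew| < 0.2, q above threshold), or unclassified (the two
rules cover neither large-skew/poor-q nor small-skew/confident-q
records; those are excluded from evaluation). Direction-of-effect accuracy
is the fraction of emVars whose predicted skew sign matches the measured
sign, reported against the always-majority-class baseline across a ladder of
q cutoffs; group-level shifts use one-sample t-tests (one-sided for the two
emVar classes, two-sided for neutral; groups under 3 members are NA).

**Transfer learning.** Phase 1 trains a regression on accessibility windows
(peaks with their signal, GC-matched negatives with signal 0) at the oligo
length (150 bp); phase 2 continues training all weights on measured MPRA
activity with its own learning rate. The benchmark compares, on a held-out
MPRA test chromosome set, (a) the fine-tuned-on-a-quarter model, (b) a model
trained on the same quarter only, and (c) the accessibility model without
fine-tuning, as the median Spearman correlation over 3 seeds.

**Contribution scores.** Attributions use rescale-rule multiplier
propagation (the DeepLIFT rule that DeepSHAP builds on) against an all-zero
reference input — a sequence of unknown bases. Linear layers propagate
multipliers like gradients; ReLU and sigmoid units use the finite-difference
slope between actual and reference activations (local derivative when the
difference underflows 1e-9); max-pool windows route their pooled difference
through the forward-pass argmax. The scores therefore satisfy completeness —
they sum to f(x) - f(reference) — exactly up to float round-off, which the
test suite checks at 1e-3 relative tolerance.

## The numpy network engine

No deep-learning framework is a dependency: `peakvar.nn` implements the
1-D convolution (im2col + GEMM), max pooling, inverted dropout, dense
layers, SGD with momentum, constant/triangular-cyclic learning rates and the
three losses directly on numpy, with reverse-mode gradients verified against
numerical differentiation in the test suite. Training is bit-reproducible
given a seed: weight initialisation (He scaling), batch shuffling and
dropout masks all flow from one `numpy.random.Generator`. Two numerical
safeguards matter in the small-data regime: the output unit's bias starts at
the training-label mean (base-rate logit for classifiers), which prevents
the large constant error at the start of training from silencing ReLU
features, and gradients are clipped to a global norm of 5 by default.

## The synthetic data generator

The generator fabricates the complete input universe so the whole framework
is testable without downloads. Background sequence is i.i.d. at 41% G+C
(human-like). Two position-weight-matrix motifs are planted: an 8 bp
CEBP-like activator (consensus weight 0.85 per column) and a 12 bp CTCF-like
architectural factor (0.80). Each peak receives 1-3 motif instances sampled
from the PWMs near its summit, and its signal is

    signal = 1 + sum_m weight_m * best_log_odds_m + Normal(0, 0.25),

truncated at zero, with accessibility weights 0.45 (CEBP-like) and 0.20
(CTCF-like); the summit is the centre of the strongest instance. This is the
simplest generative model under which a CNN regression is well specified:
signal is linear in max-pooled motif match strength. Reporter activity uses
its own weights — 0.45 for the activator and 0 for the CTCF-like factor,
reflecting that an architectural chromatin factor does not drive an episomal
reporter — which is exactly what makes fine-tuning on reporter data
informative beyond accessibility pre-training.

Variants come in three flavours. Motif-disrupting variants sit at the most
informative PWM column of a planted instance whose planted base is strong
(probability >= 0.5) with the least-likely base as alternate, guaranteeing a
log-odds loss above 1 bit; their true effect is weight * delta-log-odds, and
positive effect means the reference allele is more active. Neutral
disease-like variants and the 2000-variant background set are uniform over
peak bases outside every motif footprint, so their true regulatory effect is
exactly zero — mirroring that common background variation is depleted from
strongly constrained binding sites, and giving the empirical null a
ground-truth-neutral base. The MPRA table covers all disease-like variants
plus background fill to 600 oligos; measured activity and skew are the
reporter-weighted truths plus Normal(0, 0.25) noise, q-values come from
two-sample t-tests on 5 simulated replicate measurements per allele
(BH-corrected across oligos), ~20% of records are reverse-complemented, ~10%
carry one non-motif co-variant, and the top 40% by activity are flagged
active.

Default scale: 4 chromosomes x 250 kb, 400 peaks of 500 bp, 200 disease-like
variants (half disrupting), 2000 background variants, 600 oligos. Four
chromosomes (rather than fewer, longer ones) are needed because splits are
assigned by whole chromosome: chr1+2 train, chr3 validation, chr4 test.
Everything is byte-reproducible from the spec's single seed.

**What the generator does not emulate:** linkage disequilibrium, repeat
structure and mappability artifacts, saturating or cooperative enhancer
grammar, allele-frequency spectra, assay-specific bias (Tn5/DNase cut
preference), and realistic peak-calling noise. Passing the synthetic
benchmark therefore shows the machinery recovers planted effects under its
own generative assumptions — not that models trained on real data will reach
any particular accuracy.

## Benchmark problem sizes and training settings

The desk-scale presets are sized for a single CPU. The synthetic regression
uses one 64-filter convolution (kernel 8), max pooling 61/61, and a direct
linear readout (no dense layer), trained 60 epochs at learning rate 5e-3,
momentum 0.9, batch 64 on summit-shift (0, ±50, ±100, ±150) and
reverse-complement augmented training windows — roughly 2800 examples from
200 training peaks. The global-ish pooling plus linear readout mirrors the
generator's max-match structure; the full-size bulk architectures (e.g.
1000 + 2x200 filters, pool 13/13, dense 100 sigmoid) are available as
presets but are GPU-scale when trained on real peak sets. The transfer
benchmark uses a 150 bp model with one 32-filter convolution, pooling 13/13
and a 32-unit dense sigmoid layer for both phases. Training-time
augmentation and strand-averaged variant scoring are both standard practice
for sequence-to-activity CNNs and markedly reduce seed-to-seed variance at
this data scale.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open internally; VCF positions convert on
  ingest. Even-length windows place the focal position at index L/2 - 1
  (499 for 1000 bp), one convention for summits, variants and oligo spans.
- Windows that would run off a chromosome end are dropped and counted in a
  log message, never N-padded.
- narrowPeak summit offset -1 falls back to the floor midpoint.
- `logit` clips to [eps, 1-eps] (default 1e-7) so boundary probabilities
  stay finite.
- Correlations on constant vectors return NaN rather than raising;
  classifier metrics require both classes.
- The Shapiro-Wilk test subsamples to 5000 scores (seeded) when the null is
  larger, and the subsample size and seed are reported.
- BH q-values exist only for the in-OCR family; non-OCR variants carry NaN.
- Ties in ranks are mid-ranked (scipy defaults) throughout.

## Known limitations

- The engine is CPU-bound numpy; the full-size architectures train
  only at reduced scale here. Nothing about the statistical procedures
  changes with scale.
- The empirical null is heavy-tailed, so Gaussian p-values are conservative
  near the 2 s.d. cutoff and anti-conservative deep in the tails; Cauchy or
  Student-t alternatives are a documented extension point, off by default.
- emVar categorisation leaves genuinely ambiguous records unclassified;
  direction-of-effect accuracy excludes them.
- The GC matcher samples genome background without a repeat model; a repeat
  tolerance is only enforced when a repeat mask is supplied (synthetic
  genomes have none).
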