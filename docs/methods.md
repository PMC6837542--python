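# Methods

## Scope and design

`crisprattn` models two prediction problems for CRISPR-Cas guide design:

1. **Off-target specificity** — given an sgRNA aligned to a same-length
   genomic site, classify the pair as active (cleaved at appreciable
   frequency) or inactive. Real datasets of this kind are extremely
   imbalanced (hundreds of validated off-targets against ~10^5 mined
   candidate sites with ≤6 mismatches).
2. **On-target efficiency** — given a guide(+context) sequence, regress its
   editing activity: indel frequency for synthesis-library screens, or
   normalised log2 fold change of guide abundance for negative-selection
   fitness screens.

Both are sequence problems with a twist: the *cellular response* to an edit
is cell-specific, so the package also computes a network-derived,
expression-weighted gene covariate (NetExpress) that injects cellular
context into the regression models.

## Tokenisation

Two vocabularies, both of exactly 16 types, with 0-based positions oriented
5′→3′ of the sgRNA:

* **Base-pair tokens** (off-target): position *k* of an aligned pair maps to
  the ordered pair (sgRNA base, DNA base), indexed lexicographically over
  (A, C, G, T) × (A, C, G, T), i.e. (A,A) = 0 … (T,T) = 15. A length-L pair
  yields L tokens (Cas9 spacer: 20; Cas12a window incl. 5′ PAM: 27). Four of
  the 16 types are perfect matches.
* **Dimer tokens** (on-target): a length-2 sliding window; token *k* encodes
  bases (k, k+1) with the same 4×4 indexing; L−1 tokens per sequence
  (19 for 20-base Cas9 guides, 33 for 34-base Cas12a windows).

The canonical worked example holds: `AUGCU → AU, UG, GC, CU`. Internally
sequences are stored in the DNA alphabet (U→T on ingest, single canonical
form); decoders can render RNA. Ambiguity codes are rejected rather than
imputed. The index bijection is arbitrary but fixed and documented so that
token streams are portable across runs and machines.

## Model architectures

All three models share hyperparameter defaults chosen for CPU training
(`ModelConfig`): embedding dimension 32, 4 attention heads, 2 transformer
blocks, Conv2d channels (32, 64) with 3×3 kernels over the 1-channel
(L, d) embedding image, 2×2 max pooling, fully connected sizes (128, 32),
dropout 0.2, LSTM hidden size 32, Adam at learning rate 1e-3 with early
stopping (patience 10) on a held-aside validation split. The
`ModelConfig.compact()` profile (embed 16, 1 block, conv 8/16, FC 64,
dropout 0.1) is the desk-scale variant used by the bundled benchmarks; it
trains in seconds per epoch on one core and is ample for the planted-signal
tasks.

* **AttnToMismatchCNN**: embedding + learned positional embedding
  (elementwise sum) → transformer encoder stack (shape-preserving, asserted
  at runtime) → Conv/Pool ×2 → flatten → FC → 2-way log-softmax. Loss:
  negative log-likelihood. Sinusoidal positional tables are available as an
  option.
* **AttnToCrisprCNN**: the same trunk over dimer tokens; per-guide
  covariates are concatenated after the CNN flatten; linear output head;
  mean squared error loss.
* **SeqCrispr**: embedding → CNN branch and single-layer LSTM branch in
  parallel; flattened CNN output, final LSTM hidden state and covariates
  concatenated into the FC head; linear output.

The transformer is **encoder-only by default**. A decoder option exists
(self-attention over the embedded sequence plus cross-attention against the
encoder output) for fidelity to the original encoder–decoder description,
but in this task there is no separate target sequence for a decoder to
consume, so the encoder-only form is the defensible default.

The layers run on a small reverse-mode autodiff engine (`crisprattn.nn`)
written on numpy: broadcast arithmetic, batched matmul, im2col convolution,
max pooling, embedding lookup, layer norm, multi-head scaled dot-product
attention, LSTM, Adam. Every primitive's gradient is checked against
central finite differences in the test suite; models are deterministic in
eval mode and training is reproducible from a single integer seed.

## NetExpress

For gene *g*, network neighbours *N(g)*, edge confidence *w* and expression
profile *e*: `NetExpress(g) = Σ_{j∈N(g)} w(g,j)·e(j)`. Exactly the one-hop
weighted sum — no diffusion, no propagation, no normalisation beyond it.
Decisions where the inputs are messy in practice:

* Neighbours absent from the expression table contribute 0 (the common
  STRING/CCLE gene-set mismatch); `strict=True` raises instead.
* Raw STRING combined scores (0–1000) are auto-rescaled to (0, 1] on file
  ingest when the maximum exceeds 1; disable via argument.
* Duplicate edges (either orientation) collapse to the maximum confidence;
  self-loops are dropped.
* Expression is used as provided; a `--log2` ingest flag applies
  log2(x+1) when counts-scale data demand it.
* When fed to a model, the covariate is z-scored on training-fold statistics
  only, never on held-out data.

An isolated gene scores 0; a gene absent from the network raises a lookup
error — the two cases are deliberately distinct.

## Training protocols

* **Top-fraction labelling**: the `round(f·n)` highest-activity samples are
  positive (default f = 0.2). Ties at the cutoff are broken by stable input
  order — deterministic and documented, since any rule is arbitrary.
* **Class-balanced minibatches**: each batch takes ~half of its size from a
  random permutation of the negatives (each negative visited exactly once
  per epoch) and matches it with positives drawn with replacement, keeping
  the positive fraction within [0.4, 0.6]. Evaluation always happens on
  unresampled data.
* **Splitters**: shuffled k-fold partitions with fold sizes differing by at
  most one; group-wise holdout (leave-3-sgRNAs-out, leave-cell-line-out)
  with train/test group disjointness asserted.
* **Metrics**: AUC-ROC (trapezoid over the ROC), PR-AUC (area under the
  precision–recall curve; the metric of record for imbalanced tasks),
  Spearman, Pearson, MSE. Fold aggregation is mean ± standard deviation.
* Divergent training (non-finite loss) raises immediately with diagnostics
  rather than producing silent NaN metrics.

## Feature importance

For each input feature (a token position, or a named covariate), the
feature's column is permuted across samples, the dataset loss recomputed,
and the procedure repeated 40 times with independent permutations; the
average post-shuffle loss is the feature's raw importance, and raw scores
are normalised by their sum. Two deliberate choices:

* The score is the **raw post-shuffle loss, not the increase over the
  baseline** — conventional permutation importance uses the delta, but the
  raw-loss form is the procedure implemented here; it preserves ranking
  (all features share the same baseline) while making the normalised scores
  of uninformative features converge to a common positive value rather
  than zero.
* The shuffled unit is the **extracted token**, not the underlying base:
  for dimer models a single overlapping dimer position is permuted even
  though its neighbours then disagree about the shared base. The model
  consumes tokens, so this perturbs exactly one model input.

Shuffling is column-wise across samples, never within a sequence; on a
1-sample dataset every permutation is the identity, so scores degenerate to
uniform (a tested contract).

## Synthetic data: what it emulates, and what it does not

* **Off-target generator**: random guides; decoys carry 0–6 substitutions
  at uniform positions (matching the ≤6-mismatch candidate-mining
  convention); latent activity `100·exp(−Σ penalties at mismatched
  positions)` plus Gaussian noise (s.d. 2 on the percent scale), clipped to
  [0, 100]; labels by top-fraction. Default penalties ramp from 0.05 (5′)
  to 0.5 (3′), encoding the seed-region intolerance of PAM-proximal
  mismatches. Default size 50 guides × 80 decoys = 4000 pairs.
* **On-target generator**: an Erdős–Rényi gene network (60 genes, density
  0.08, confidences U(0.2, 1)); independent lognormal expression per cell
  line (two lines by default); guide efficiency = per-position dimer
  effects (N(0, 0.3) each, sequence-term s.d. ≈ 1.7 at 34 bases) + 1.0 ×
  across-gene-standardised NetExpress of the guide's gene + N(0, 0.5)
  noise. Each guide appears once per cell line, so the same sequence
  receives discordant efficiencies across lines — the cell-specificity
  phenomenon the NetExpress covariate exists to capture.

Passing the planted-signal tests demonstrates that the architectures,
training loop, covariate plumbing and importance machinery can recover
known structure of realistic shape. It does **not** demonstrate performance
on real screens: the generators have no chromatin context, no copy-number
confounding, no guide-synthesis artefacts, no batch effects, and their
noise is homoscedastic Gaussian. Benchmark numbers on these data
characterise the software, not the biology.

## Problem sizes and runtime choices

The bundled experiments are sized for a single CPU core: 4000 pairs /
5000 guide records for the recovery benchmarks (8 and 12 epochs), 2000
records per arm for the NetExpress ablation (16 epochs, paired
with/without across 5 seeds, at planted effect 1.0 and 0.0), and a
1200-record training with 40-repeat importance over 34 features evaluated
on 300 held-aside samples for the importance-recovery experiment. The
ablation uses a paired t-test across seeds; at smaller training sizes the
extra covariate acts as a mild regulariser and can produce a spurious
positive gap even with no planted effect, which is why the ablation's
default sample size is the larger one.

## Known limitations

* The autodiff engine is float64, CPU-only, and deliberately minimal; it is
  not a general deep-learning framework and large-scale training is out of
  scope.
* Epigenomic covariates (DNase, ChIP, methylation) are not modelled.
* Genome-wide candidate mining and sequence alignment are out of scope —
  inputs are pre-aligned, equal-length pairs.
* The positional-embedding default is learned; the sinusoidal option exists
  but the benchmarks do not exercise it beyond unit tests.
* Normalisation of screen log2 fold changes is the caller's responsibility;
  when needed, z-scoring within cell line is the documented convention.
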