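# crisprattn

Attention-boosted deep sequence models for CRISPR sgRNA activity prediction,
combined with a cell-specific, network-based gene feature.

## The problem

Designing a good single-guide RNA (sgRNA) means balancing two risks: the
guide must cut efficiently at its intended site (**on-target efficiency**)
and must not cut at genomic sites that merely resemble the spacer
(**off-target specificity**). Both depend on sequence, but the *cellular
consequence* of an edit also depends on the cell: knocking out the same gene
depletes cells in one line and barely registers in another. `crisprattn` is
for computational biologists who want trainable, inspectable models of all
three ingredients — sequence, class imbalance, and cellular context — plus a
synthetic benchmark suite that exercises every component without external
downloads.

## What is in the box

**Sequence encodings.** An aligned sgRNA–DNA pair of length L becomes L
base-pair tokens, one per position: the ordered pair (sgRNA base, DNA base),
16 possible types. A guide sequence becomes L−1 overlapping dimer tokens via
a length-2 sliding window, also 16 types (e.g. `AUGCU → AU, UG, GC, CU`).
Positions are 0-based, oriented 5′→3′ of the sgRNA; 20-base Cas9 spacers
yield 20 base-pair / 19 dimer tokens, Cas12a windows (27 and 34 bases,
including the 4-base 5′ PAM) yield 27 and 33.

**Models** (built on a compact numpy autodiff engine, `crisprattn.nn`):

* `AttnToMismatchCNN` — off-target classifier: token + positional embedding
  (elementwise sum) → transformer blocks → two Conv2d/MaxPool stages over the
  (L, d) embedding image → fully connected → log-softmax over
  {active, inactive}. Trained with negative log-likelihood and per-batch
  positive oversampling for heavily imbalanced screens.
* `AttnToCrisprCNN` — on-target regressor: same trunk over dimer tokens,
  biological covariates (NetExpress, copy number) concatenated before the
  fully connected head, linear output, mean-squared-error loss.
* `SeqCrispr` — on-target regressor with parallel CNN and LSTM branches over
  the embedded dimers.

**NetExpress.** For gene *g* with network neighbours *N(g)*, edge
confidences *w* and cell-line expression *e*:

```
NetExpress(g) = Σ_{j ∈ N(g)} w(g, j) · e(j)
```

a one-hop, confidence-weighted summary of how strongly a gene's interaction
partners are expressed in a given cell line — the cell-specific covariate
that lets one model produce different predictions for the same guide in
different cells.

**Feature importance.** Shuffle one input feature across samples, recompute
the loss, repeat 40 times, average; the mean post-shuffle loss is the raw
importance, normalised over features to sum to 1.

**Synthetic benchmarks** (`crisprattn.synthetic`, `crisprattn.benchmarks`)
plant recoverable structure — position-weighted mismatch penalties,
per-position dimer effects, a gene effect transmitted through a random
interaction network — so recovery is a testable claim, not an anecdote.

## Worked example

```python
import numpy as np
from crisprattn import (
    AlignedPair, encode_base_pairs, encode_dimers,
    GeneNetwork, ExpressionProfile, compute_netexpress,
)
from crisprattn.benchmarks import run_offtarget_benchmark

ts = encode_dimers("AUGCU")
print(ts.tokens)                      # [ 3 14  9  7] -> AU, UG, GC, CU

pair = AlignedPair("ACGTACGTACGTACGTACGT", "ACGAACGTACGTACGTACGT")
print(pair.n_mismatches)              # 1
print(len(encode_base_pairs(pair)))   # 20

net = GeneNetwork.from_edges([("A", "B", 0.5), ("A", "C", 1.0)])
expr = ExpressionProfile("K562", {"B": 2.0, "C": 3.0})
print(compute_netexpress("A", net, expr).score)   # 4.0

report = run_offtarget_benchmark(seed=11)   # 4000 pairs, ~1 min on one core
print(round(report.auc_roc, 3), round(report.pr_auc, 3))   # 0.999 0.996
```

The last two numbers are held-out AUC-ROC and PR-AUC of the off-target
classifier on the planted-penalty benchmark: near-perfect recovery, because
the generator's activity is an exact function of mismatch positions plus
small noise.

The same workflows are available from the shell:

```bash
crisprattn simulate ontarget --out sim/
crisprattn netexpress --network sim/network.tsv --expr sim/expression_CL1.tsv \
    --cell-line CL1 --out scores.tsv
crisprattn --seed 3 train --task ontarget --model attn_crispr \
    --data sim/guides.tsv --use-netexpress --out run/
crisprattn --seed 3 importance --model run/checkpoint.npz --task ontarget \
    --data sim/guides.tsv --use-netexpress --out importance.json
```

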