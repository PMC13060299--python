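# cytoset

Permutation-invariant transformer modelling of flow-cytometry samples across
heterogeneous marker panels — with self-supervised pretraining and per-cell
attention attribution.

## The problem

Flow cytometry measures a handful of protein markers on each of thousands of
cells per sample.  Predicting a *sample-level* label (disease status,
genotype, biological sex, ...) from the raw cell set is awkward for standard
machine learning: a sample is an unordered set of cells, different
experiments measure different marker panels, labelled samples are scarce,
and batch effects shift intensities between runs.  `cytoset` is for
computational immunologists who want an end-to-end, interpretable model that
handles all four problems without manual gating.

## The model

A sample is a set $s=\{v_1,\dots,v_{n_s}\}$ of cells over a global marker
vocabulary $M$; each panel measures $M_s \subseteq M$.

1. **Availability-augmented embedding** — each cell becomes
   $c_i = [a_i; e_i] \in \mathbb{R}^{2|M|}$: a binary availability indicator
   ($a_i(j)=1$ iff marker $j$ measured and unmasked) concatenated with an
   expression vector holding the measured value where available and a
   learnable per-marker value $\mu_j$ elsewhere.  Any panel maps into one
   shared space, and a measured zero is never confused with an unmeasured
   marker.  A position-wise feed-forward layer projects $c_i$ to the hidden
   size $h$.
2. **Encoder** — Pre-LN self-attention blocks over cells, no positional
   encoding; exactly permutation-equivariant.
3. **Decoder** — a learnable task-specific query token pools the encoded
   cells through iterative cross-attention; its final state feeds the
   prediction head.  Predictions are permutation-invariant, and the softmax
   attention weights (per cell, head, and layer; head-averaged weights sum
   to one per layer) quantify each cell's contribution — for a 7000-cell
   sample the uniform expectation is $1/7000 \approx 1.4\times10^{-4}$, so
   cells far above that are the ones driving the decision.

Training has two stages.  **Pretraining** (no labels): two complementary
masked views per sample — i.i.d. per-entry masking after an optional
sample-wide marker dropout, and whole-marker masking — and three per-cell
regression targets per measured marker: the expression value, its percentile
rank within the sample ($P_{ij}=\mathrm{rank}(X_{ij}\mid X_{:j})/n$), and its
log Gaussian-KDE density ($\sigma = 0.05$).  Heteroscedastic heads are
trained with a Gaussian negative log-likelihood; masked entries carry full
weight, observed ones weight $\beta<1$, unmeasured slots none.
**Downstream**: the embedding and encoder are frozen, and the decoder + head
are trained with cross-entropy (or MSE) under fixed-rate marker-wise input
dropout.  See `docs/methods.md` for every formula, default and design
choice.

## Worked example

The built-in generator draws corpora from a Gaussian mixture of cell
populations with configurable panels, batch effects, and a planted class
signal (here: an NK-like population at 15% frequency in class 0 versus 25%
in class 1), recording every cell's true population:

```python
import numpy as np
from cytoset import CytometrySetClassifier, MaskedCytometryPretrainer
from cytoset.synthetic import default_spec, generate_corpus
from cytoset.train import compute_metrics

spec = default_spec(n_samples_per_class=50, cells_per_sample=(1000, 1000), seed=101)
samples, truth = generate_corpus(spec)
train, test = samples[::2], samples[1::2]
y_train = np.array([s.label for s in train])
y_test = np.array([s.label for s in test])

pre = MaskedCytometryPretrainer(hidden_size=32, encoder_layers=2, heads=4,
                                epochs=8, cells_per_step=256, random_state=0)
pre.fit(train)                                   # self-supervised, no labels

clf = CytometrySetClassifier(pretrainer=pre, decoder_layers=2, epochs=150,
                             lr=3e-3, cells_per_step=512,
                             validation_fraction=0.0, random_state=0)
clf.fit(train, y_train)
metrics = compute_metrics(np.searchsorted(clf.classes_, y_test),
                          clf.predict_proba(test))
print(f"test accuracy {metrics['accuracy']:.2f}  AUC {metrics['auc']:.2f}")

record = clf.attention(test[0])                  # per-cell attribution
pops = test[0].extra["population"]
top = np.argsort(record.per_layer_weights[0])[-50:]
print(f"max attention per decoder layer: {np.round(record.max_weight_per_layer, 4)}")
print(f"NK fraction overall {np.mean(pops == 3):.2f}, "
      f"among top-50 attended cells {np.mean(pops[top] == 3):.2f}")
```

Output (a few minutes on one CPU):

```
test accuracy 0.76  AUC 0.96
max attention per decoder layer: [0.0117 0.0016]
NK fraction overall 0.11, among top-50 attended cells 1.00
```

The classifier separates the classes (AUC 0.96), and the decoder's first
attention layer concentrates on exactly the planted population: its top-50
attended cells are 100% NK against an 11% base rate, with a maximum
per-cell weight of 0.0117 — about 12× the uniform 1/1000 expectation.
(Which layer sharpens varies between runs; the other layer here stays near
uniform.)

Both estimators follow the scikit-learn contract (`get_params`/`set_params`,
`fit`/`predict`/`predict_proba`, fitted attributes with trailing
underscores) with `X` a list of `CytometrySample` objects.  Real data enters
through `cytoset.io`: an FCS 3.0/3.1 reader with logicle transformation and
channel-to-marker resolution, or plain CSV/TSV matrices, plus an on-disk
sample store with a TSV manifest.  A `cytoset` command-line tool wires the
stages together (`simulate` / `prepare` / `pretrain` / `finetune` /
`evaluate` / `attribute`); grouped, stratified cross-validation utilities
live in `cytoset.train`.

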