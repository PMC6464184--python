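# hyperelm

Hypercomplex extreme learning machines for multichannel image recognition.

## The problem

Biometric sensors often capture several registered images of the same
surface — e.g. multispectral palmprint scanners record blue, green, red and
near-infrared bands of one palm.  The classical ways to classify such
multisource data with an extreme learning machine (ELM) either concatenate
the channel vectors into one wide feature (feature-level fusion, costly and
high-dimensional) or train one classifier per channel and merge their
scores (matching-score-level fusion, which discards cross-channel
structure).  The hypercomplex ELM (HELM) takes a third route: the d+1
channels become the d+1 components of a hypercomplex number, and the whole
network is trained in that number system, so no explicit fusion rule has to
be designed for the features at all.

## The model

An ELM is a single-hidden-layer feedforward network whose input weights
are random and frozen; only the output weights are learned, in closed form.
For inputs `X` (one row per sample), hidden width `Ñ` and one-hot targets
`T`:

    H = g([X, 1] α),        β = (HᵀH + λI)⁻¹ Hᵀ T

with `α` uniform on [−1, 1], activation `g` ∈ {sigmoid, sin, atan} and
ridge parameter `λ ≥ 0`.

HELM extends this to d+1 registered channels.  Each channel j has its own
random input weights and hidden matrix `H⁽ʲ⁾ = g([X⁽ʲ⁾, 1] α⁽ʲ⁾)`.  The
hidden matrices become the components of one matrix over a commutative
(d+1)-component hypercomplex system (channel 1 → real part, channel j+1 →
imaginary unit e_j, every unit squaring to −1, distinct units
annihilating), targets are one-hot in every component (the winning entry
is `1 + e₁ + … + e_d`), and the output weights solve the hypercomplex
ridge system

    (𝓗ᴴ𝓗 + λ𝓘) ∘ β = 𝓗ᴴ𝓣 .

At test time the d+1 real components of the network output are min-max
rescaled by their training extrema and summed (a sum-rule over channels);
the argmax of the fused score is the predicted identity.  With a single
channel (d = 0) everything reduces exactly to the plain ELM, and at d = 1
to complex-valued ridge regression.

Two solvers are provided: the default embeds the hypercomplex system into
one real linear system (exact for every d), while the `blockwise` solver
follows the recursive Schur-complement hypercomplex inverse (exact for
d ≤ 1; an approximation for d ≥ 2, where the algebra is non-associative —
see `docs/methods.md`).

## Worked example

`examples/train_helm_synthetic.py` builds the standard synthetic
benchmark — 20 identities × 10 acquisitions × 4 registered 32×32
ridge-texture channels, emulating registered multispectral palmprint
regions of interest — splits it half/half per class and trains a HELM with
500 hidden nodes:

```
$ python examples/train_helm_synthetic.py
classes: 20, channels: 4, train/test: 100/100
test recognition accuracy: 99.00%
misrecognized samples: 1 of 100
```

The accuracy line is the recognition accuracy RA = 100·N_c/N: of the 100
held-out acquisitions, 99 were assigned to the correct identity.  The
other example scripts each show one capability:

* `hypercomplex_basics.py` — the number system and the exact linear solver;
* `compare_fusion_strategies.py` — HELM vs feature-level and score-level
  ELM fusion vs each single channel;
* `noise_robustness.py` — test-time Gaussian / salt & pepper / speckle
  corruptions;
* `activation_significance.py` — pooled one-sided t-tests between
  activation functions on the bundled published accuracy tables.

A `hyperelm` command-line tool wraps the same library for shell use
(`hyperelm synth | train | predict | eval | ttest | bench`; see
`hyperelm --help`).

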