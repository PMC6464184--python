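# Methods

## The hypercomplex number system

A scalar is `y = y⁽¹⁾ + y⁽²⁾e₁ + … + y⁽ᵈ⁺¹⁾e_d` with real coefficients.
The conjugate negates every imaginary coefficient and the norm is the
Euclidean norm of the coefficient vector.  The defining relations of the
units — every `e_k² = −1` — do not determine the products of *distinct*
units, and no choice of real values for `e_i e_j` can satisfy all the
constraints consistently once d ≥ 2 (for d = 2, demanding
`e₁e₂ = −1 = e₁²` would force `e₂ = e₁`).  The package therefore fixes the
product rule

    a ∘ b = (a₀b₀ − Σₖ aₖbₖ) + Σₖ (a₀bₖ + aₖb₀) e_k ,

i.e. cross-unit products vanish.  This is the unique bilinear commutative
(d+1)-component rule under which `y ∘ y* = |y|²` holds exactly with the
conjugate and norm above, and it coincides with real arithmetic at d = 0
and complex arithmetic at d = 1.  The cost is associativity: for d ≥ 2,
`(e₁e₁)e₂ = −e₂` but `e₁(e₁e₂) = 0`.  All consequences below flow from
that trade-off.

Matrices are stored as d+1 stacked real component matrices; the matrix
product reduces to `C₀ = A₀B₀ − Σₖ AₖBₖ`, `Cₖ = A₀Bₖ + AₖB₀`, a handful
of real BLAS calls.

## Solving linear systems: two routes

**Real embedding (default).**  Left-multiplication by a fixed matrix A is
a genuine real-linear map on the stacked components, with operator matrix

    [ A₀  −A₁ … −A_d ]
    [ A₁   A₀      0 ]
    [ …        ⋱     ]
    [ A_d  0      A₀ ]

so `A ∘ X = B` is one real `(d+1)n × (d+1)n` system: one LU factorization,
all right-hand-side columns solved together.  The result is exact to
solver precision for every d, non-associativity notwithstanding, because
the equation itself only involves one product.  Residual checks
(`‖A∘X − B‖_F / ‖B‖_F ≤ 1e−8`) are part of the test suite for d = 0…4.

**Blockwise recursive inverse.**  The alternative inverts the matrix by
2×2-block recursion with a Schur complement (`S − R P⁻¹ Q`), splitting at
`⌊n/2⌋`, bottoming out at 1×1 blocks where the scalar inverse
`y* / |y|²` is exact.  Products inside the block formulas are evaluated
left-to-right to make the result well-defined under non-associativity.
For d ≤ 1 the algebra is associative and the recursion reproduces the
real/complex inverse to numerical precision.  For d ≥ 2 it is an
approximation *by construction*: the cancellations the block-inverse
identity relies on need associativity.  Measured on the ridge-regularized
Gram matrices the model actually produces (24×24, four channels, sigmoid
activation), the relative residual `‖A A⁻¹ − I‖_F / √n` is of order
10¹–10², roughly quadratic in the ratio of imaginary to real component
magnitudes, and no practical ridge value changes that regime.  The
package therefore reports the residual to the caller
(`block_inverse_residual`), regression-bounds it on fixed-seed fixtures,
and uses the real-embedding solver by default; the blockwise path is kept
as a selectable, faithful implementation of the recursive scheme.

Numerical guards: scalar inversion refuses norms ≤ 1e−12 (configurable);
the embedded solve refuses zero pivots; `λ = 0` adds a 1e−8 diagonal
jitter so the unregularized normal equations stay solvable.  Argmax ties
resolve to the lowest class index throughout.

## ELM and HELM

The baseline ELM draws input weights i.i.d. uniform on [−1, 1] from a
seeded generator (weights depend only on the dimensions and the seed),
forms `H = g([X,1]α)` and solves the ridge normal equations.  Requesting
more hidden nodes than training samples warns but proceeds — the ridge
solution remains defined.  The one-hot convention puts 1 in the target
class column and 0 elsewhere.

HELM draws one independent weight stream per channel from a master seed
(stream j for channel j, via seed-sequence spawning), so the d = 0 model
is bit-identical to a plain ELM trained with the same seed.  The dataset's
channel order fixes the channel→unit mapping (first channel → real slot)
and is recorded in the model.  Targets are one-hot in *every* component.
After solving for β, the training outputs' per-component, per-node minima
and maxima are stored; a test sample's fused score is

    f(j) = Σₖ (ntₖ(j) − min_tₖ(j)) / (max_tₖ(j) − min_tₖ(j)) ,

with a zero contribution whenever `max = min` (the limit of an
uninformative node) and no clipping of out-of-range test values — the
rescaling uses training extrema only.  Note the per-node rescaling is
monotone within a node but not order-preserving across nodes, so d = 0
fused decisions can differ from raw-output argmax on weakly separated
samples; β itself is identical.

The conventional baselines: feature-level fusion concatenates the channel
rows and trains one ELM; score-level fusion trains one ELM per channel
(same seed — weights depend only on dimensions, so duplicated channels
contribute equal terms) and sums per-node min-max-normalized scores,
mirroring the fusion rule above.

## Synthetic data

The generator emulates registered multispectral palmprint ROIs.  Per
identity it draws a base texture (six oriented sinusoids, 2–6 cycles per
image, random orientation/phase/amplitude); per channel it blends that
base with a channel-specific texture (`coupling γ = 0.65` — each band
shares most of the identity's structure but has its own appearance) and
maps the template linearly to [0, 255]; per acquisition all channels shift
together by up to ±1 pixel (registration holds across channels) and each
pixel gets N(0, 20²) jitter on the 8-bit scale.  Defaults: 20 classes ×
10 samples × 4 channels at 32×32.  The ±1-pixel limit reflects pre-cut,
registered ROIs; larger misalignment would call for feature extraction,
which is out of scope for a raw-pixel classifier, and the benchmark is
deliberately calibrated to be learnable to ≥ 95% so that qualitative
comparisons (multichannel vs single channel, wide vs narrow hidden layer,
clean vs noisy) are not masked by a floor effect.

What the generator does *not* model: real spectral reflectance physics,
illumination fields, skin deformation, sensor noise correlations, or
between-session drift.  Passing benchmarks here show the pipeline's
machinery is correct and its qualitative orderings hold on controlled
data; they say nothing quantitative about real palmprint databases.

Noise corruptions act on the raw [0, 255] images *before* per-image
min-max intensity normalization (their conventional parameters are 8-bit
quantities): additive Gaussian (mean 0, std 36, clipped), salt & pepper
(10% of pixels forced to 0 or 255, equal probability), and multiplicative
speckle `I·(1+u)` with `u` uniform, zero-mean, variance 0.05 — the
uniform convention of the common imaging toolboxes; swapping in Gaussian
`u` is a one-line change.  By default only test images are corrupted
(robustness probing); training-time corruption is available by applying
the noise functions before dataset assembly.

## Evaluation protocol

Recognition accuracy is reported in percent.  Randomized experiments are
repeated over seeds derived from one master seed (kept below 2³¹) and
summarised mean±std.  Series are compared with the classical pooled
one-sided two-sample t-test, `df = n₁ + n₂ − 2`, right-sided p from the
t distribution, rejecting at α = 0.05.  The statistic is computed from the
explicit pooled formula and cross-checked in the tests against an
independent library implementation.  Degenerate zero-variance input yields
t = 0 (equal means) or ±∞.

The standard benchmark protocol (10 repetitions; each repetition re-draws
dataset, half/half stratified split, model weights and noise fields from
its own derived seed) trains HELM at 500 and at 50 hidden nodes, one ELM
per channel at 500, and evaluates the trained HELM on clean and corrupted
test images.  Problem sizes (100 training rows of 1024 pixels, four
channels) keep a full 10-repetition run in the tens of seconds on one CPU
while leaving clear margins between the compared conditions.

## Known limitations

* The blockwise inverse is not a correct inverse for d ≥ 2 (see above);
  use the default solver unless fidelity to the recursive scheme is the
  point.
* Raw-pixel classification has no translation invariance; the model
  tolerates only the small registered shifts the generator produces.
* Min-max score fusion is sensitive to training-output outliers (extrema,
  not quantiles).
* The bundled published accuracy tables are inputs for the significance
  utilities; reproducing the underlying image-database accuracies would
  require the license-gated PolyU/CASIA data and is intentionally not
  attempted.
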