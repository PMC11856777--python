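# Methods

## Problem

A classifier deployed for clinical decision support will meet inputs unlike
anything it was trained on. Its predicted probability captures *stochastic*
(aleatoric) uncertainty — irreducible noise such as class overlap — but says
nothing about *knowledge* (epistemic) uncertainty (KU): whether the prediction
is supported by training evidence at all. This package implements and compares
two KU estimators on binary-classification tasks, together with the synthetic
data and the threshold-based out-of-distribution (OoD) detection protocol used
to evaluate them.

## Estimators

**Deep ensemble (ENN).** K networks differing only in initialization and
data-order seed are trained independently. The pooled prediction is the mean
of the member sigmoid outputs; the KU measure is sigma(L), the population
(1/K) standard deviation of the member *logits*. Logits are used rather than
probabilities because probability-space spread saturates once members are
confident, while logit spread keeps resolving disagreement; this choice is
ours — the estimator is often described ambiguously as the spread of "member
outputs".

**SNGP.** A spectral-normalized neural Gaussian process is a single network
whose hidden layers are constrained to be approximately distance preserving
and whose output layer is a GP approximated in finite dimensions:

* *Spectral normalization.* After every optimizer step each constrained
  weight matrix W is rescaled to W·min(1, c/σ_max(W)) with σ_max estimated by
  power iteration (warm-started between steps; 3 iterations per step, more in
  the standalone operation). Bound c = 0.95.
* *Bi-Lipschitz MLP backbone.* The toy backbone is an input projection
  followed by residual blocks h + ReLU(Wh + b) with ‖W‖₂ ≤ c < 1. The
  residual form gives a positive lower Lipschitz constant, so hidden distances
  can neither explode nor collapse — plain (non-residual) spectral-normalized
  stacks can still collapse directions, which destroys distance awareness.
  The transformer backbone spectral-normalizes its feed-forward sublayers and
  the input projection; attention is left standard, as no established
  bi-Lipschitz attention mechanism exists — a known gap, discussed under
  limitations.
* *RFF head.* The hidden vector h feeds a random Fourier feature map
  Φ = sqrt(2/D)·cos(Wh + b), W ~ N(0, 1/ℓ²), b ~ U[0, 2π), whose inner
  products approximate the RBF kernel exp(−‖h−h′‖²/2ℓ²). Only the output
  weights β (and a scalar bias) on top of Φ are trained.
* *Laplace covariance.* After training, one pass over the training split
  accumulates the precision P = I + Σᵢ pᵢ(1−pᵢ) ΦᵢΦᵢᵀ. A query's posterior is
  N(μ, σ) with μ = βᵀΦ(x), σ² = Φ(x)ᵀP⁻¹Φ(x) (Cholesky solve). The class
  probability uses the mean-field adjustment sigmoid(μ/√(1+λσ²)), λ = π/8.
* *Pooling.* A pool of SNGPs averages member μ and member σ (averaging σ²
  instead is available behind `var_mode="sigma2"`; with similar member scales
  the two differ negligibly).

KU for the SNGP is the pooled σ. With P = I (no data) σ ≈ 1 for every query,
which is the far-field ceiling.

**Kernel scale and hidden normalization.** The kernel length scale ℓ is
expressed in hidden-space units. We deliberately do *not* normalize the
hidden vector onto the unit sphere before the RFF map: sphere projection
discards the radial component of the representation and, empirically,
collapses the ID/OoD σ contrast on the toy datasets (undetected fractions of
50–70% instead of 0%). With the raw residual-backbone representation the
random input projection expands coordinates by roughly √width, so ℓ = 5 in
hidden units corresponds to ≈ 0.4 input units on 2-D data; this value gives
both a clean separation of OoD σ from the ID test σ distribution and a smooth
σ-vs-distance gradient (Spearman > 0.9 on the two-moons far field). Sphere
normalization remains available (`hidden_norm="sphere"`).

## Toy datasets

*Two moons*: n = 1500, isotropic Gaussian noise 0.1, balanced classes.
*Stripes*: four vertical stripes over x1 ∈ [0, 8] with intervals
(0, 0.8), (1.6, 2.8), (4, 5), (6, 7), density weights 3:1:2:1, x2 uniform on
[0, 6], class-1 probabilities (0.97, 0.65, 0.03, 0.9). The stripe geometry
mixes dense and sparse stripes, gaps of different widths, and class mixtures
from near-pure to noisy, and is constant in x2 — any uncertainty gradient
along x2 is an artifact of the estimator. The class probabilities were chosen
so the Bayes AUROC (~0.95) stays above the 0.90 performance bar the study
expects of all models; heavier class mixing (e.g. probabilities 0.9/0.5/0.2/
0.7) caps the attainable AUROC near 0.84 and would conflate predictive noise
with estimator quality.

**Synthetic OoD sets.** Uniform proposals over the source bounding box padded
by 3× the length scale are accepted iff their exact nearest-neighbor distance
to the source is at least the length scale: 0.2 for moons, 0.5 for stripes
(about half the minimum width of the respective structures, taken as given
constants). The acceptance set size defaults to the test-split size; a
proposal budget of 1000× m bounds the runtime with an explicit
generation-exhausted error.

## Synthetic EHR cohort

Each patient is a 48-hour token stream over 17 concepts (12 continuous
"value" channels with clinically plausible placeholder baselines, 5 boolean
event channels). A latent severity s ~ N(0,1) drives everything:

* each value concept's mean shifts by `value_effect`·sd·s (default 0.5 sd per
  unit severity); observations occur per hour with a probability derived from
  the total token rate (default 1.5 tokens/patient-hour);
* each boolean concept's hourly occurrence log-odds shift by
  `bool_effect`·s (default 0.5);
* the mortality label is Bernoulli(sigmoid(α + βs)), β = 2.0, with α
  calibrated by Gauss–Hermite quadrature so the marginal prevalence equals the
  configured base rate (default 0.13, a typical ICU in-hospital mortality
  benchmark prevalence).

Timestamps are the hour indices (hourly discretization); tokens are sorted by
(t, concept index); an empty stream is patched with a single baseline token so
every episode is non-empty. The generator reproduces heterogeneous token
kinds, variable episode lengths, class imbalance and a learnable
severity→outcome pathway. It does **not** emulate temporal autocorrelation
within channels, inter-channel correlation beyond the shared severity factor,
missing-not-at-random patterns, or any real clinical semantics — so passing
tests demonstrate correct mechanics and a detectable signal, not clinical
realism. An adapter (`read_benchmark_episode`) ingests per-episode hourly
tables in the layout of the public ICU mortality benchmark for users with
access to the real data.

**Corruptions.** *RTR* flags ⌊fraction·n⌋ uniformly chosen token positions;
at embedding time each flagged row of the input matrix is replaced by an
i.i.d. standard-normal vector of the full embedding width (a random "token"
cannot be expressed as a valid concept index, so the replacement lives in
embedding space; the time-embedding block is randomized together with the
concept block). *PTS* replaces whole tokens — concept, value and timestamp —
drawn uniformly from the pooled tokens of the donor episodes, then re-sorts
the stream by time, since models consume time-ordered input. Both report
d_proxy = n_changed/n_total exactly. The evaluation schedule assigns test
episodes round-robin to d_proxy ∈ {0.1, …, 1.0}, giving equal numbers of
corrupted episodes per level.

## Token encoding

Concepts are one-hot over the 17-concept vocabulary; value tokens scale the
one-hot by the measurement after per-concept z-scoring with training-split
statistics (raw magnitudes such as 88 bpm would otherwise dominate the
unit-scale one-hot entries; the z-scoring choice is flagged as a sensitivity
knob). Timestamps enter through the sinusoidal embedding: pair i carries
(sin, cos) of t/base^(2i/width), base 10⁴, width 16, t in hours since episode
start. Concept block and time block are concatenated (not added) so value
magnitudes cannot mix with phase information. The transformer consumes the
resulting (tokens × 33) matrices, zero-padded per batch with a validity mask.

## Models and training

* Toy ENN: 27 ReLU MLPs, depths 1–3 × widths {100, 106, …, 150}, each with
  its own seed. Adam lr 2·10⁻³, minibatch 128, ≤150 epochs.
* Toy SNGP pool: 9 residual backbones, depths 1–3 × widths {100, 125, 150},
  D = 256 random features. Adam lr 10⁻³, full batch, ≤80 epochs. The GP head
  converges quickly, and long minibatch schedules keep deforming the backbone
  geometry after the decision boundary is settled, which measurably erodes
  the OoD detection margin — hence the shorter schedule.
* EHR ENN: 8 encoder-only transformers (pre-norm blocks, mean-over-valid-
  tokens pooling), depths 2–4, widths 64–512 with the wide-and-deep corner
  excluded. EHR SNGP: 4 such backbones with spectral-normalized feed-forward
  sublayers and the RFF-Laplace head (D = 256). Adam lr 10⁻⁴ (2·10⁻⁴ at smoke
  scale), batch 32, early stopping on validation loss (patience 5 full /
  3 smoke).
* All training is binary cross-entropy with early stopping and
  best-validation parameter restoration; every run is deterministic given the
  global seed, which fans out additively to member seeds.

Networks, backpropagation, Adam and spectral normalization are implemented on
a small in-package reverse-mode autodiff engine over numpy arrays; its
gradients are verified against central differences in the test suite.

## Evaluation protocol

KU values are transformed by ln(10σ) (toy) or ln(10σ+1) (EHR) — strictly
monotone maps chosen for readable densities; thresholding commutes with them.
The detection threshold is the q-th percentile of the *ID test* KU only,
lower-nearest-rank convention: the largest value that leaves
⌈(1−q/100)·n⌉ samples strictly above (exactly ⌈0.1n⌉ above at q = 90 for
distinct values). q = 90 for toy, 70 for EHR (a stricter screen for a
safety-critical setting). An OoD sample is *undetected* if its KU is ≤ the
threshold (the boundary counts as undetected; ties have measure zero for
continuous KU). Undetected fractions are reported overall and per d_proxy bin
of width 0.1. Predictive quality is AUROC (rank statistic) and AUPRC
(precision-recall step integration) of the pooled prediction, with (min, max)
ranges across ensemble members / pooled models.

## Problem sizes used by the test suite

The suite runs the toy study at full size (n = 1500, both datasets, both
estimators, five seeds) and the EHR study at the smoke scale the package
defines for quick iteration: a 300-patient cohort, a 55/15/30 split (the
larger test share keeps undetected-fraction estimates stable at this cohort
size), width-64 transformers with 2 heads, sequences capped at 48 tokens, and
≤15 epochs. Learnability is additionally checked on a fresh 500-episode
evaluation cohort. The full-scale configuration (n = 2000, widths up to 256,
4 heads, uncapped sequences) runs through the same `EhrRunConfig` with
`smoke=False`.

## Numerical and degenerate-case choices

* Power iteration warm-starts from the previous left vector; an all-zero
  matrix reports σ_max = 0 and is returned unchanged.
* The Laplace precision starts at the identity (unit prior), so it is always
  positive definite; predictions use a Cholesky factorization.
* σ² values are clipped at 0 before the square root (they can go ~1e−16
  negative through round-off).
* The toy transform ln(10σ) rejects σ = 0; pooled SNGP σ is strictly positive
  by construction (identity prior), and ENN σ(L) = 0 only for bitwise-equal
  members.
* `percentile_threshold` on an all-tied sample returns that value, leaving
  zero samples strictly above.
* Token-sort ties at equal timestamps break by vocabulary index; PTS without
  a vocabulary falls back to lexicographic concept order.
* Corruption with fraction 0 is the identity and d_proxy = 0 exactly.

## Known limitations

* The ensemble and SNGP comparison at EHR scale uses standard attention; the
  SNGP's distance-preservation guarantee therefore holds only for the
  feed-forward path, and mean-token pooling is itself not distance
  preserving. Both weaken σ's distance fidelity on sequences relative to the
  toy MLP setting — visible as substantial undetected PTS fractions.
* d_proxy is a proxy: the fraction of corrupted tokens, not a true
  data-manifold distance.
* The synthetic cohort's single-factor severity model makes the mortality
  signal easier to learn than real ICU data; absolute AUROC/AUPRC values on
  it are not comparable to published benchmark values.
* The autodiff engine implements exactly the operations these models need; it
  is not a general deep-learning framework (no GPU, no convolutions, float64
  only — which also makes runs bit-reproducible on one platform).
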