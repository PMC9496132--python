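# Methods

`enose` implements a complete machine-olfaction classification pipeline for
fruit spoilage detection: an array of cross-sensitive gas sensors samples the
headspace above a fruit sample once per second for 350 s, and the joint
transient response is used to decide whether the fruit is fresh or infected
with one of three moulds (*Aspergillus niger*, *Penicillium expansum*,
*Penicillium crustosum*). This note records the models, the defaults, the
numerical choices, and what the synthetic experiments do and do not show.

## Synthetic acquisition model

Each sample yields one response curve per sensor channel on the grid
t = 0, 1, …, 350 s. Live channels follow a first-order rise to a class- and
channel-specific plateau:

    y(t) = p_{c,j} · (1 − exp(−t/τ)) + ε(t),   ε(t) ~ N(0, σ²),  y clipped at 0

* **Plateau matrix** `p` (4 classes × 8 channels, mg/L): rows differ by a few
  percent per live channel, emulating the subtle headspace shifts different
  fungal species induce. Channels 0 and 4 share a profile because they model
  a duplicated indicator sensor pair; channels 2 and 6 are dead (permanently
  below their detection floor, exactly 0), mirroring arrays in which some
  sensors never respond to the analyte mixture. The entries are declared
  defaults, not fitted to any measured gas concentrations.
* **Rise constant** τ = 7 s. The curve has saturated to within ~5 × 10⁻¹⁰
  relative by 150 s, so the 150–300 s region is a genuine plateau and its
  class-conditional mean recovers the plateau matrix exactly in the
  noise-free limit.
* **Noise** σ = 0.6 mg/L. Calibrated once so that the default end-to-end
  classifier lands near 0.9 mean cross-validated accuracy — high enough that
  the task is non-trivial, low enough that the class structure is
  recoverable — then frozen.
* **Outlier injection**: a `floor(n · fraction)` subset of records, chosen
  without replacement, has all live-channel values multiplied by
  `outlier_scale` (default 5). Whole-record multiplicative inflation makes
  outliers extreme in feature space without changing curve morphology, which
  is exactly what the Mahalanobis screen should catch.

What the generator does **not** model: sensor drift and hysteresis,
temperature/humidity coupling, cross-talk chemistry, non-Gaussian spike
noise, and biological variability beyond the class plateau shifts. Passing
tests on synthetic data therefore demonstrate the pipeline's statistical
machinery (feature contracts, screening power, optimizer behaviour), not
field performance on real e-nose measurements.

## Preprocessing

* **k-point linear smoothing** (k ∈ {3,5,7,9,11}, default 7): unweighted
  moving average; near the ends the symmetric window shrinks, preserving
  series length and avoiding phase shift. The window choice trades noise
  suppression against transient detail; 7 points is the default working
  point.
* **Pair-anomaly rule**: the duplicated sensors (channels 0 and 4) are
  compared over 150–300 s; a record is discarded when max |a−b| exceeds
  1.2 mg/L, strictly. Max is the strictest aggregator of the window
  disagreement; mean is available by configuration.
* **Dead-channel exclusion**: a channel is dropped only if *every* value of
  *every* record is within ε = 10⁻⁶ mg/L of zero — a strict rule so a single
  genuine reading retains the channel.
* **Mahalanobis screening**: distances are computed per class (each class's
  own mean and unbiased covariance) in the 36-dimensional feature space, with
  cutoff √χ²₁₋α(d), α = 0.025 by default. Two numerical points matter:
  * With n ≈ 40 samples per class and d = 36 features the sample covariance
    is near-singular; when its condition number exceeds 10¹⁰ a ridge
    λ = 10⁻⁶·tr(S)/d is added. Note also that in-sample distances are bounded
    by (n−1)/√n, so very small classes cannot exceed the χ² cutoff at all —
    screening experiments should use enough samples per class (the recovery
    experiment uses 100).
  * The screen **iterates to a fixpoint** by default: gross outliers inflate
    the covariance they are judged against (masking), so statistics are refit
    on the survivors and the screen reapplied until no distance exceeds the
    cutoff. `max_iter=1` recovers the single pass. At the fixpoint a second
    application removes nothing, so repeated screening cannot oscillate.

## Features

Six descriptors per channel over the 30–300 s window (271 points at 1 s):
trapezoidal integral, population variance, average differential
((v_m−v_1)/((m−1)Δt) by telescoping), signed maximum one-step gradient,
relatively-stable average (mean of the final 50 % of the window, i.e. the
165–300 s plateau), and energy (Σv²Δt). Eight channels give 48 features;
excluding the two dead channels leaves 36. The descriptor definitions are
the standard transient-response readings, each pinned by a unit test so any
reinterpretation is a visible diff. Scaling laws (linear descriptors scale
with the curve, variance and energy quadratically) are asserted as
properties.

## Dimensionality reduction

PCA (eigendecomposition of the covariance, components sign-fixed so the
largest-magnitude entry is positive), LDA (generalized eigenproblem
S_B w = λ S_W w with the within-class scatter ridge-regularized like the
covariance above; at most classes − 1 components), and FA by iterated
principal-factor extraction on the correlation matrix (communalities
re-estimated from the loadings until the maximum change falls below 10⁻³,
at most 500 iterations; variables whose communality drifts above 1 are
rescaled to the bound — the usual Heywood guard). Defaults: LDA k = 3,
FA k = 3, PCA k chosen to reach 95 % explained variance. Inside
cross-validation every projection is fit on the training fold only; a
`global_fit` flag reproduces whole-dataset fitting for comparison with
protocols that reduce before splitting.

## Classifier

A from-scratch multilayer perceptron: sigmoid hidden layers (ReLU by flag),
softmax output, cross-entropy loss, full-batch gradient descent, fan-in
scaled symmetric uniform initialization (half-range 1/√fan-in), zero biases.
Inputs are standardized with training-fold statistics stored on the model.
Analytic gradients are verified against central finite differences to
better than 10⁻⁵ relative error. The library-level defaults
(two hidden layers of 10, learning rate 0.01, 500 epochs) are conservative;
the pipeline configuration uses learning rate 0.3 and 800 epochs, which
full-batch descent on the standardized 3-D LDA features needs to converge.
All of these are declared settings — nothing here is tuned to any external
dataset.

## Swarm optimizers

All three algorithms minimize over a box with population 15 and 100
iterations by default, track the best-so-far fitness per iteration
(monotone by construction), clip to bounds after every move, and round
integer-constrained dimensions after each update (round-after-update rather
than relaxation, since hidden node counts are the search space).

* **SSA**: the population is ranked each iteration; the best 20 % are
  producers, updated by x·exp(−i/(αT)) (α ~ U(0,1]) while the alarm value
  R₂ ~ U(0,1) stays below the safety threshold ST = 0.8, else by a Gaussian
  step. The remaining scroungers move toward the best producer via the
  ±1-vector pseudo-inverse step; the worse half instead jump relative to the
  worst position by Q·exp((x_worst−x)/i²). A random 10 % act as forewarners:
  β·|x−x_best| around the best if not already best, else a bounded jump
  scaled by 1/((f−f_worst)+10⁻⁸). Constants (fractions, ST, β ~ N(0,1),
  K ~ U(−1,1), ε) are configurable.
* **PSO**: canonical inertia-weight form, w = 0.7, c₁ = c₂ = 1.5, velocities
  clamped to 20 % of each dimension's span.
* **GWO**: canonical α/β/δ encircling update with the exploration
  coefficient decreasing linearly 2 → 0.

The architecture-search harness negates the mean validation accuracy of a
BPNN with the candidate integer hidden sizes and caches fitness per rounded
architecture so identical candidates are never retrained. The library-level
default estimator is an inner stratified 3-fold on the supplied training
data (fixed seed). The pipeline runner instead uses the evaluation's own
stratified 10-fold cross-validation as the fitness function — accuracy
under k-fold CV is the classical fitness choice for this kind of
architecture search — and warm-starts the search with the configured
default architecture as an incumbent, so the selected architecture is never
worse than the default under that objective. Two consequences are worth
stating plainly: the reported tuned accuracy is the maximum of the CV
accuracies the search visited and therefore carries selection (winner's
curse) optimism, and tuning-does-not-hurt holds by construction under the
shared objective. The `per_fold` option re-tunes inside every training fold
(with an inner 3-fold estimator) when strict leakage avoidance of the
tuning step itself is wanted.

## Evaluation

Stratified 10-fold cross-validation (per-class fold counts differ by at most
one; classes smaller than k trigger a warning and an unstratified fallback).
Reported metrics: per-fold accuracies, their mean and sample standard
deviation (fold-level, ddof = 1), macro-averaged true-positive rate and F1
from the pooled confusion matrix (zero-support classes excluded with a
warning; classes are balanced by design so macro averaging is natural), and
wall-clock training time (recorded, never asserted — hardware dependent).
Within each fold the outlier screen, the projection and the classifier see
training rows only; fold disjointness is asserted and any overlap is a hard
error.

## Experiment sizes

The recovery experiment uses 100 samples per class (see the distance bound
above), 20 generator seeds, 10 % injected outliers at scale 5, α = 0.025.
The chance-level null uses 20 samples per class with shuffled labels over
10 seeds; the separability limit uses σ = 0 with a nearest-neighbour
classifier. The tuned-vs-default comparison runs SSA at population 8 /
15 iterations over node bounds [2, 64]² on the study-sized dataset for
5 generator seeds. These sizes keep every experiment's Monte-Carlo error
well inside the asserted margins.

## Known limitations

* The synthetic generator's class structure lives almost entirely in plateau
  levels; real fungal headspace dynamics also change curve shape over days
  of incubation.
* Iterated Mahalanobis screening assumes roughly elliptical clean classes;
  heavy-tailed clean data would lose more than the ~0.6 % observed here.
* FA uses principal-factor extraction, not maximum likelihood; loadings are
  reported on the correlation scale.
* The BPNN trains by plain gradient descent; it is deliberately simple and
  auditable rather than fast.
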