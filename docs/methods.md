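# Methods

This note documents the models, the synthetic benchmark, the numerical
choices, and the limitations of `survite`.

## Data model

A record is `(x, t, γ, δ)`: an m-vector of numeric baseline covariates, a
binary treatment, a positive observed time, and an event indicator with
δ = 1 meaning the death was observed and δ = 0 meaning the time is a
censoring time (a lower bound on survival).  Categorical covariates must be
encoded numerically *before* loading: knowledge regions address covariates
by index/name in clinical units, so silent re-encoding (e.g., automatic
one-hot) would corrupt region thresholds.  Train/validation/test splitting
uses a seeded permutation with `floor(N·ratio)` rows for each holdout and
the remainder in the training share (for N = 2139 at 70/15/15 this gives
1499/320/320).

Continuous covariates are standardized by training-set mean/sd before
entering the encoder (binary ones pass through); this is an off-switchable
default — the method itself does not require it, but the encoder's
initialization assumes roughly unit-scale inputs.  Region membership is
always evaluated on raw covariates.

## Prior-knowledge regions

A region is a weighted sum of closed-interval indicators with an admissible
value set `V`; a knowledge base is a set of regions labelled *positive*
(members are known to have ΔY > 0; their union is Ω) or *zero* (ΔY = 0;
union Γ).  Membership uses an absolute tolerance of 1e-9 on the sum because
graded encodings use half-integer coefficients; a patient matching both Ω
and Γ raises an inconsistency error (the alternative — downgrading to
unknown — would silently hide a malformed knowledge base).

Boundary convention: clinical score tables assign rows like "34~51 → score
2, >51 → score 3".  Shared boundaries take the middle score, and the
indicator encodings realize the resulting open endpoints by shaving one
float ulp (`nextafter`) off the adjacent closed interval.  The equivalence
of the graded Child-Pugh region encoding and direct scoring is verified on
10,000 random covariate tuples in the test suite.

The hepatectomy study regions are shipped exactly as printed — five unit
indicators with admissible set {4}, i.e., any four of five criteria — with
an `all_criteria` flag switching to {5}, because the printed source is
internally inconsistent with its own earlier small-tumor criterion ({5}
over the same five indicators) and never reconciles the two.

## Semi-synthetic benchmark

Covariates emulate an HIV trial cohort: AGE truncated-normal(35, 8²) on
[18, 70] years; CD4/CD8 counts lognormal with medians 350 and 800
cells/mm³; four binary covariates (Z30, RACE, GENDER, STE) with marginal
rates 0.40/0.40/0.50/0.35 sharing a latent Gaussian factor (correlation
0.45) — real demographic/history indicators cluster, and the correlation
widens the graded indicator-sum distribution so that the region mix at
n = 2139 lands near the reference cohort split (about 460 positive-effect,
690 zero-effect, 990 unconstrained).  These rates were fixed once from that
region-mix calibration and are config-overridable.

Treatment is Bernoulli with `p = (1/d1)(d2 + sigmoid(AGE − mean(AGE) +
λ·CD40 − μ·mean(CD40)))`, clipped to [0, 1] with a warning (the affine
transform can exit the unit interval); defaults d1 = 2, d2 = 0.5 give
propensities in [0.25, 0.75], strong but overlapping confounding by age.

Potential outcomes come from the Gompertz proportional-hazards model by
inverse transform, `Y = (1/κ)·log(1 − κ·log z / (χ·e^{x'η}))` with
z ~ U(0, 1); for |κ| < 1e-10 the exponential limit `−log z / (χ e^{x'η})`
is used (the two branches agree to 1e-8 in the tests).  The *same* z feeds
both arms of one patient.  That sharing is what makes exact sign control
possible: in Γ the treated arm reuses the control parameters, so Y¹ = Y⁰
exactly; in Ω the treated arm's hazard scale is χ¹ = ρ·χ⁰ with ρ = 0.5,
and since the survival time is strictly decreasing in χ at fixed z, Y¹ > Y⁰
for every draw.  Outside the regions the arms use independent parameter
sets (κ¹ = 0.08 vs κ⁰ = 0.05, different η), giving a wide, signed effect
distribution.  Censoring is lognormal, `log y_cen ~ N(μ_c = 4.0,
σ²_c = 0.6)` (natural log), producing ≈ 20% censoring; γ = min(y, y_cen)
and δ = 1 iff y < y_cen.  Ground truth (Y¹, Y⁰, ΔY, region) is returned in
a separate table and never enters the observational dataset.

What the generator does *not* emulate: informative (covariate-dependent)
censoring, time-varying covariates, competing risks, and the heavy-tailed
lab-value distributions of real cohorts.  Passing benchmark tests therefore
says nothing about those regimes.

## Network and objective

Eight fully connected networks: encoder φ (two hidden layers, default 100
units, leaky-ReLU, batch norm, dropout 0.2), per-arm g_j like φ, per-arm
noise transforms u_j (tanh, one hidden layer, output of the noise
dimension, default 10), per-arm output heads h_j (one affine layer with
exponential activation — predictions strictly positive), and a one-layer
softmax treatment head ψ.  ε-noise is standard normal, drawn fresh per
forward pass in training; at inference the ITE is the average of
`ŷ(x, 1, ε_s) − ŷ(x, 0, ε_s)` over S = 100 *paired* seeded draws (pairing
makes the estimate exactly zero for identical arm parameters and removes
the shared-noise variance component).

The objective per batch is

    factual + α·IPM(φ-sample₁, φ-sample₀) + β·CE(ψ, t)  [+ knowledge terms]

with defaults α = 1000, β = 100.  The factual term normalizes each arm by
its own batch count; the treatment cross-entropy is a batch mean (so β's
meaning is batch-size independent).  The IPM defaults to squared
RBF-kernel MMD (biased V-statistic; bandwidth by median heuristic on the
pooled sample, overridable) — deterministic and exactly matched against a
brute-force double kernel sum in the tests.  An entropic Sinkhorn
Wasserstein-1 is available; its transport plan is computed by Sinkhorn
iteration and held constant in the gradient (envelope approximation).

Knowledge terms act on counterfactual predictions `ŷ^{1−t}` obtained by
routing a patient's representation through the opposite arm's branch, *in
the same forward pass* as the factual rows of that branch, so batch-norm
statistics and dropout masks are shared by the combined flow.  Cases: Ω
control (observed or censored) — hinge `max(0, γ − ŷ^{T=1})` (observed
time is a lower bound on the counterfactual treated time); Ω treated,
observed — hinge `max(0, ŷ^{T=0} − γ)`; Ω treated, censored — no
information; Γ observed — absolute error with γ as the label; Γ censored —
lower-bound hinge.  The Γ terms are inner-normalized per arm and scaled by
N_Γ/N.  For the Ω terms the printed source scales bare sums by N_Ω/N with
no inner mean; `prior_losses` reproduces that form verbatim, but the
trainer defaults to an inner-normalized variant (`normalized_omega=True`):
a bare sum grows linearly with batch size while every other objective term
is a mean, which makes the printed fixed α, β inconsistent across batch
sizes, and in our benchmark the bare-sum form dominates the factual
gradient ~30:1 per record and visibly destabilizes training.  Both
behaviors are exposed.

## Training

Adam (lr 3e-3), 80 epochs, seeded reshuffling each epoch, `ceil(N/b)`
batches with the short final batch kept, one step per batch.  Batches with
a single arm skip the IPM with a warning; non-finite losses abort with the
component breakdown.  Model selection: the parameters (including batch-norm
running statistics, which are part of model state) from the epoch with the
lowest validation factual loss, evaluated in inference mode with fixed
noise draws.  The test fold is not an argument of the training routine.

Numerical choices that mattered: both output heads' biases initialize at
`log(mean observed time)` — with the exponential output the network
otherwise starts predicting ≈ 1 in time units where observed times are in
the tens, and the resulting one-sided hinge "catch-up" phase pushes the
arms apart asymmetrically; gradient clipping is off by default; with an
empty knowledge base the knowledge branch is skipped entirely, so
`cdnepk` training is bit-identical to `csa_dragonnet` under the same seed
(verified in the tests).

## Evaluation

PEHE is reported as the mean *squared* effect-estimation error (no square
root — the convention of the benchmark reproduced here; `sqrt_pehe` is
provided for comparison with literature using the root) and the ATE error
as the absolute difference of mean effects.  Both require simulated ground
truth; the harness refuses real data, where one potential outcome is always
counterfactual.  The comparison harness trains every mode on identical
splits per seed and reports mean ± sd over seeds on the held-out test fold.

An important property of this benchmark: inverse-transform hazard sampling
gives per-patient survival noise with a coefficient of variation near one,
so at n = 2000 the test-fold PEHE of *all* three modes (≈ 40–60) exceeds
that of a constant zero predictor (≈ 35), and differences between modes
are within the across-seed spread (sd ≈ 10–40).  Mode rankings on this
benchmark at this size are therefore unstable seed-to-seed and should not
be read as evidence about the methods' relative merit on real cohorts; the
comparison harness exists to make exactly that variability visible.

## Interpretation module

The lasso of estimated effects on standardized covariates minimizes
`(1/2N)·Σ(ΔŶ − ϖ₀ − x'ϖ)² + ι·‖ϖ‖₁` with an unpenalized intercept by
cyclic coordinate descent with soft-thresholding (convergence when the
largest coefficient change in a sweep is below 1e-8); the solution is
checked against the one-dimensional closed form, the OLS limit at ι = 0,
and a brute-force grid.  The penalty is chosen by k-fold cross-validation
with ties going to the larger (sparser) value.  Covariates are ranked by
absolute coefficient with index-order tie-breaks.  Binned effect summaries
use linear-interpolation quantiles (the convention behind the box-plot
displays is otherwise arbitrary).

## Known limitations

* The estimators are not calibrated for real-data deployment: no
  uncertainty quantification on ΔŶ, no competing risks, no time-varying
  covariates or treatments.
* Counterfactual bounds are one-sided for Ω; under weak factual signal the
  unconstrained side can drift, and occasional training runs show inflated
  positive effect estimates (visible in the benchmark spread).
* The Sinkhorn IPM's envelope gradient ignores the plan's dependence on
  the representations; it is provided for experimentation, not as the
  default.
* Checkpoints store weights, batch-norm statistics, the architecture and
  the covariate-name manifest; optimizer state is not persisted, so
  training cannot be resumed mid-run.
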