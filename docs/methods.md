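# Methods

`dfcmamba` classifies disease stage from resting-state fMRI by modelling the
*trajectory* of a subject's functional connectivity over a scan, and it is
built to be interpretable at three levels: which scan periods mattered, which
latent features drove the decision, and which region pairs carried the
evidence.

## Pipeline

**Windowed connectivity.** Each scan session is an `N x T` matrix of
regional BOLD time series. Every region's series is z-scored over time using
the population standard deviation (divisor `T`) — the z-score is a
definition here, not an estimator — and flat regions are rejected as failed
extractions. Overlapping windows of `Lw = 30` time points advanced by
`s = 2` (93% overlap) give `K = floor((T - Lw)/s) + 1` windows; with the
reference 116-region atlas and 137 retained volumes, `K = 54`. Each window's
pairwise Pearson correlation matrix is clamped to `[-1, 1]` against
floating-point overshoot and vectorised into its `D = N(N-1)/2` upper
triangle (row-major, `i < j`). A degenerate window (a region with zero
within-window variance) contributes zero correlations for that region with a
warning rather than NaNs, so pipelines stay runnable on pathological inputs.
Before entering the autoencoder, correlations are mapped affinely to
`[0, 1]` via `(r + 1)/2` — the minimal invertible map matching the sigmoid
output of the decoder.

**Per-window VAE.** Each window vector is compressed independently by a ReLU
MLP encoder into a diagonal-Gaussian posterior (two parallel affine heads
for the mean and log-variance), sampled with the reparameterization trick,
and reconstructed by the mirror decoder with a sigmoid output. The loss is
the batch-mean squared reconstruction error plus `beta * KL` to the standard
normal prior. Per-sample KL (summed over latent dimensions) is averaged over
the batch so the joint-objective weighting is batch-size invariant. The
reference stack is `[6670, 2048, 1024, 512, 256] -> 128`; all contracts are
width-agnostic.

Two numerical choices matter at small scale and are deliberate:

* *Log-variance head bias starts at −4* (`sigma ~ 0.14`). With `sigma ~ 1`
  at initialisation the reparameterization noise swamps the posterior mean,
  the decoder learns to ignore the latent entirely, and the model settles
  into posterior collapse it escapes only very slowly. Starting tight breaks
  the deadlock; the KL term re-inflates `sigma` wherever a dimension remains
  uninformative.
* *The desk preset scales the KL weight by `D / 6670`.* The reconstruction
  term sums squared error over `D` features, so its magnitude scales with
  `D` while the KL does not; a fixed weight of 1.0 at `D = 190` is
  effectively a ~35x stronger prior than in the reference configuration and
  collapses the posterior. Scaling preserves the reference balance;
  `beta = 1.0` remains the full-scale default.

**Selective state-space temporal encoder.** The `K x L` latent sequence is
processed by a stack of two gated Mamba blocks. Each block: layer norm, a
projection pair (conv path and SiLU gate) to `d_inner = 2 * d_model`, a
causal depthwise convolution (kernel 4, left-padded), SiLU, the S6 selective
scan, multiplicative gating, an output projection and a residual connection.
Dropout (p = 0.15) is applied after the depthwise convolution in training
mode only. The scan discretises a per-channel diagonal linear system with
input-dependent step sizes: `Delta = softplus(w * u + b)` from the
post-convolution activation, `B` and `C` as per-channel linear maps of the
normalised block input (a literal reading of the defining recurrences; a
`bc_source` switch derives them from the conv output instead). The default
update is the simplified rule `A_bar = exp(Delta A)`, `B_bar = Delta * B`;
exact zero-order hold is selectable and agrees to first order in `Delta`.
The state matrix is real-diagonal, initialised `A[n] = -(n + 1)` and stored
as `log(-A)`; the `Delta` bias is initialised so `softplus(bias)` is
log-uniform in `[0.001, 0.1]`. The scan is a sequential recurrence —
sequence lengths are tens of windows, so no parallel-scan kernel is needed.
Mean pooling over windows yields the temporal context vector.

**Temporal importance.** The per-window, per-channel `Delta` values recorded
during the scan measure how strongly the model refreshes its state on each
window; their channel mean `s_k` is the window-importance score. By default
the trace is taken from the *first* block: measured across trained models,
the first block's profile tracks planted informative windows consistently
(it reads the latent content directly), while the final block's profile —
which mixes propagated state — has unstable sign. `final` and `mean`
remain selectable. Class profiles average `s_k` over a class's sessions and
are z-scored across windows by default.

**KAN head.** A two-layer Kolmogorov-Arnold network maps the context vector
to class logits. Every edge carries `phi(x) = w_b * SiLU(x) + sum c_m
B_m(x)` with a cubic B-spline on a uniform grid of `G = 5` intervals
(`G + p = 8` coefficients per edge, evaluated by the Cox-de Boor recursion);
node outputs are plain sums of edge activations, so the learned univariate
curves are directly inspectable parameters. Spline coefficients start at
`N(0, 0.1^2)` and base weights at 1, so the head begins close to a SiLU
additive model. Outside the knot span the basis decays to zero and the SiLU
term keeps gradients alive. Every 10 epochs during the first half of joint
training the grid is re-spanned to the observed activation range (1%
margin) and the coefficients are refitted by least squares; refreshes stop
at mid-training because a late re-parameterisation invalidates the
optimiser's moment estimates and can destabilise an already-converged head.
When the domain grows, the refit is the least-squares optimum over the new
basis but cannot be exact — re-representing a spline at half the knot
density leaves a residual of a few percent of the curve scale. No dropout
is used inside the head, keeping individual curves interpretable.

**Two-phase training.** Phase 1 trains the VAE alone on training-partition
windows (labels unused; validation and test windows never enter), Adam at
1e-3, batch 32, restoring the lowest validation-reconstruction checkpoint.
Phase 2 optimises `alpha * L_vae + beta_cls * L_cls` (`alpha = 0.1`,
`beta_cls = 1.0`) end to end with differential learning rates — VAE 1e-5,
temporal encoder and head 1e-3 — and keeps the VAE bit-frozen for the first
15 epochs. The best checkpoint is the highest validation subject-level
accuracy, ties broken by lower validation cross-entropy, considering only
post-warmup epochs: a warmup-phase checkpoint is not the trained
configuration, and on few-subject validation sets whose accuracy saturates
early the tie-break would otherwise lock onto an underfit early epoch.
Phase 2 feeds the
temporal encoder *posterior means* rather than reparameterized samples: the
KL anchors `sigma ~ 1` on uninformative latent dimensions, so sampled
inputs are noise-dominated at desk scale and differ systematically from the
evaluation path (which is deterministic posterior-mean by design). Phase 1
still samples, as the ELBO requires.

**Evaluation.** Strictly subject-level: session probability vectors are
averaged per subject (ties in the argmax go to the lower class index), and
a subject's sessions never span partitions — the split generator allocates
whole subjects 70/10/20 per class by largest remainder, and `evaluate`
re-asserts disjointness. Metrics: accuracy, macro precision/recall/F1
(empty-class precision counted as 0 with a warning), and AUC for binary
tasks. Multi-seed runs report mean ± sd and a two-sided paired t-test on
run-level accuracies; zero-variance difference vectors are flagged as
degenerate instead of crashing.

**Attribution.** The Jacobian of a class logit with respect to every
window's input features — computed by reverse-mode differentiation through
head, encoder stack and VAE encoder — is averaged over windows and mapped
back to a symmetric zero-diagonal `N x N` matrix. Class-level maps average
the session maps of that class's (test) sessions. Attributions are reported
on the model's `[0, 1]` input scale; a flag applies the chain-rule factor
1/2 to convert to correlation units. Thresholding keeps the
`ceil(percent/100 * D)` largest-|a| unique pairs (ties broken
lexicographically); region scores are node strengths (sum of incident
absolute attributions).

## Autodiff and optimisation

The models run on a small tape-based reverse-mode engine over numpy
(float64) with exact vector-Jacobian products for every primitive,
including a custom differentiable B-spline evaluation (derivative via the
standard basis-derivative identity). Finite-difference tests pin gradients
through the full pipeline to ~1e-6 relative error. Adam follows the usual
bias-corrected form with per-group learning rates and a freeze flag.

## What the synthetic cohorts emulate

Real cohorts of this kind are access-controlled, so all testing runs on
simulated data with known ground truth. Sessions are piecewise-stationary
multivariate normal draws: a block-structured base correlation template
(modular networks), per-subject low-rank deviations (rank 4, per-edge sd
0.06) shared across a subject's sessions (stable individual connectivity),
class effects on named edges, and window-indexed temporal effects, plus
independent observation noise (sd 0.2). Edits are made in correlation space
and projected back to the SPD cone by eigenvalue clipping with diagonal
renormalisation. Everything is a pure function of
`(cohort seed, class, subject, session)`.

The desk preset (N = 20 regions, T = 137, K = 54, 20 subjects per class,
1-2 sessions each) plants a diffuse stationary signature per class — one
primary discriminative edge at `delta_r = 0.4` plus six weaker satellites
at `0.45 * delta_r` — and gives class 1 a transient episode: a five-edge
network couples more strongly in windows 10-20. The diffuse stationary
part is what real disease signatures look like and is what an unsupervised
bottleneck can encode (a signature confined to literally one edge
contributes too little reconstruction variance to survive compression);
the primary edge stays the single strongest effect, so the attribution
probe has a known target, and the episode gives the temporal probe a known
window range. The nuisance magnitude (subject deviations) is set
comparable to the class-signal norm: large enough that the autoencoder
must learn subject structure, small enough that the task stays separable.

What the generator does **not** emulate: hemodynamic response shapes and
BOLD spectra, motion artifacts, scanner/site effects, heavy-tailed noise,
and continuously varying coupling. Passing recovery tests therefore shows
the pipeline recovers the *kind* of structure it assumes — stationary
discriminative edges, transient network episodes, subject-level
heterogeneity — not that it handles real acquisition artifacts.

## Reduced ("desk") configuration

Single-CPU runs use a scaled stack chosen once: encoder `[190, 96] -> 32`
latents, temporal encoder `d_model 32 / d_state 4 / 2 blocks`, KAN hidden
width 8, phase schedules 40 + 60 epochs with batch 8 (the desk cohort has
~45 training sessions, so batch 8 keeps a useful number of optimiser steps
per epoch). All contracts are width-agnostic; the reference widths remain
the defaults for full-scale use.

## Known limitations

* The sequential scan and the pure-Python autodiff are desk-scale tools; the
  full 6670-feature architecture constructs but is not practical to train in
  this implementation.
* Total-parameter-count reproduction against external reports is not a
  target; `DFCClassifier.parameter_count()` itemises counts per component
  (spline coefficients and base weights separately) instead.
* Subject-level accuracy on small cohorts is quantised (8 test subjects =
  12.5% steps); multi-seed dispersion should be read with that granularity
  in mind.
* The temporal-importance score is a measure of the trained model's
  selectivity, not a causal localiser; its sign convention depends on which
  block is read (see above) and is reported z-scored within class.
* Window overlap smears temporal localisation: with `Lw = 30` and `s = 2`
  an episode spanning windows 10-20 in time touches every window whose
  span intersects it — windows 0 through 34 at varying fractions — so
  only far-away windows are clean controls, and contrasts of "inside vs
  outside the planted range" are diluted by construction. The planted
  episode is still detected in the seed-averaged class profile, but
  individual seeds can invert the response (a model may "attend" to an
  informative window by lowering its time step and holding state rather
  than raising it), so single-run profiles should be read cautiously. The
  first few windows additionally carry a cold-start artifact of the zero
  initial scan state.
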