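# Methods

This note documents the models, estimators, and design choices behind
`mesochoice`, and what the synthetic data can and cannot establish.

## Synthetic sessions

A session is a per-trial dF/F tensor (trials × x × y × t) on a 10-region
atlas, plus a behavior table. The atlas is a jittered Voronoi partition of
a circular imaging window (default 64×64 pixels, 65 µm/pixel); regions are
convex, disjoint, and nonempty by construction. Trials run 1 s pre-stimulus,
1.5 s open-loop and (by default) 1 s closed-loop at 30 frames/s.

Each task variable contributes a separable planted signal
`spatial map × temporal kernel × (signed amplitude + trial jitter)`:

| variable  | carrier areas        | kernel                     | amplitude (dF/F) | trial jitter SD |
|-----------|----------------------|----------------------------|------------------|-----------------|
| stimulus  | V1, L, AL            | 200 ms alpha transient     | 0.020            | 0.020           |
| wheel     | A, AM, RL, PM        | step at movement time      | 0.015            | 0.012           |
| saccade   | AM, A                | transient at saccade time  | 0.015            | 0.010           |
| attention | AM, A, RS, PM        | constant over the trial    | 0.008 × latent   | 0.004           |
| choice    | all 10 (20% sparsity)| 0.3 s pre-movement ramp    | 0.004 × sign     | 0.008           |

The per-trial jitter acts along the same spatial pattern as the signal, so
it — not the independent per-pixel sensor noise (SD 0.01) — limits
single-trial discriminability: the expected two-sided d′ after spatial
pooling is roughly `2·amplitude / jitter SD`. No published amplitudes exist
for these quantities; the ratios above were chosen once so that
cross-validated d′ of each variable lands in the 0.5–1.5 range typical of
mesoscale task variables, with the choice amplitude fixed at one fifth of
the stimulus and sparsely distributed. Attention is a latent per-trial
state z ~ N(0,1) that drives the pupil change (plus measurement noise),
selects the psychometric slope (high for z > 0), and scales the sustained
cortical offset; attention labels are the top/bottom tertiles of the
z-scored pupil change, as in the analysis itself.

Choices are drawn from the lapse-logistic psychometric curve
`P_left(θ) = σ(αθ)(1−λ) + λ/2` with λ = 0.2, α = 2/90 (low attention) or
5/90 (high attention) per degree. A trial is correct when the choice
matches sign(θ); at θ = 0 the rewarded side is a fair virtual coin, so
those trials are correct with probability 1/2. Over 13 difficulty levels
uniform on [−90°, +90°] the closed-form expected accuracies are 68.3%
(low) and 79.6% (high); under a continuous-uniform difficulty distribution
they are 67.4% and 79.0%.

What the generator does **not** emulate: hemodynamic physiology (the
correction is tested on a parametric shared artifact), eye video (saccades
are event lists), realistic spatial correlation structure of cortical
noise, session-to-session nonstationarity, and the closed-loop coupling of
wheel to stimulus position. Passing tests therefore demonstrate estimator
correctness under the declared statistical model, not performance on real
recordings.

## Preprocessing

dF/F uses a scalar grand-average F0 per session. All temporal filters are
zero-phase (forward–backward Butterworth) so filter delay cannot bias d′
timing claims; the band-pass is 0.1–8 Hz (order 2 per pass), binning is
130 µm mean pooling with 50% overlap (edge windows truncated), and 50 fps
data is polyphase-resampled to 30 fps. Wheel events are flagged at
velocity zero-crossings whose following excursion exceeds a threshold
(default 20 trace units; the threshold's physical unit is left
configurable). Saccade candidates come from a velocity threshold at
k·MAD (k = 6 by default, replacing a camera-specific adaptive scheme);
events lasting ≤ 60 ms or smaller than 1.5° are rejected. The pupil
attention metric is the open-loop maximum minus the 1-s pre-stimulus mean,
z-scored within session. Hemodynamic correction detrends each channel by a
per-pixel linear fit normalized by its intercept, low-passes the
calcium-independent channel at 5 Hz (6th-order Butterworth — the filter
family is unstated upstream, Butterworth assumed), regresses it onto the
signal channel per pixel, subtracts the fit, low-passes at 8 Hz, and
downsamples toward 50 µm pixels. A constant violet channel yields c = 0
with a warning.

## Localized factorization

The data matrix (pixels × concatenated time) is SVD-compressed; rank is
the smallest r whose reconstruction retains 99% of the summed per-pixel
*temporal variance* (mean-removed — a DC offset costs no rank budget; an
energy criterion would retain offset dimensions and drop variance-carrying
ones). The factorization runs entirely in the compressed basis: with
X ≈ U S Vᵀ and V orthonormal, fitting A·W to U·S is equivalent to fitting
A·(W Vᵀ) to the reconstruction.

Seed masks set a distance field D = 1 inside each region, decaying as
exp(−d/ℓ) outside (ℓ ≈ 15% of the typical area diameter by default); the
per-pixel penalty is 1 − D and localization is scored on the D > 0.5
support. Fitting alternates unconstrained least squares for the temporal
factors with HALS updates for the non-negative spatial maps under a
per-pixel quadratic penalty; components failing the 75% localization
threshold are re-fit with the penalty strengthened (×4, up to four
rounds). The rank line search starts with one component per region and
greedily adds a component to the region whose seed support holds the
largest residual variance until the explained-variance target (0.99) is
met or every region reaches its cap; an unreachable target returns the
best fit with `converged=False` and a warning. This greedy scheme is a
simplification of the reference solver's line search. After convergence,
near-duplicate spatial maps within an area (cosine > 0.95) are dropped and
the model re-fit: collinear spatial columns make the temporal unmixing
ill-conditioned, injecting large anti-correlated noise into the duplicated
components that a diagonal (per-component standardized) state-axis readout
cannot cancel.

Explained variance of a component subset follows the reconstruction
convention: per-pixel temporal variance of the partial reconstruction,
summed over pixels, divided by the summed variance of the original — note
this can slightly exceed 1 for an overcomplete fit, and is not 1 minus the
residual variance.

## State axes and d′

For two balanced trial groups A and B, the axis is the per-component
difference of means divided by the pooled SD `sqrt((σ_A²+σ_B²)/2)`,
normalized to unit length (the normalization resolves an ambiguity in the
upstream notation); window-mode axes average the per-component ratio over
the window before normalizing. Zero-variance components get weight 0 with
a warning. Projections are plain dot products with no mean-centering in
time. Cross-validation uses 5 folds; each fold's axis comes from a 20%
split and d′ is computed on the held-out 80%, the curve being the fold
mean. Because both the axis and its sign are re-estimated, the reported
curve is swap-invariant across group relabeling (the d′ statistic itself,
at fixed axis, is antisymmetric).

Group rules per variable: stimulus uses the same trials at two alignments
(around onset vs the preceding second — the one deliberate exception to
group disjointness); wheel/choice require the first movement ≥ 0.5 s after
onset with no saccade in the preceding 0.5 s, aligned to movement, with
the no-movement group aligned to a random frame in (0.5 s, 5 s] (clipped
to the trial); saccades mirror the wheel rule; attention splits the top
vs bottom pupil tertiles. The larger group is randomly subsampled for
balance. The attention d′ curve is reported relative to its value at the
window start (an imposed zero at trial onset). Axis stability smooths
S(t) with a 3-frame backward window and reports the cosine-similarity
matrix; time-independent axes take t* at the center of the longest run
whose mean off-diagonal stability exceeds 0.8.

For the Gaussian-oracle tests, two clouds separated by δ along one
component with unit isotropic noise have closed-form population d′ = δ;
the cross-validated estimate carries a small attenuation (≈ 1% at the
test's n) from axis-estimation noise, which the 3-SE tolerance absorbs.

## Geometry statistics

Angles use |cos| (axes are directionless), folded to [0°, 90°]. The
independence null resamples axis entries with replacement (2000
surrogates), renormalizes, and takes the 2.5/97.5 percentiles of the angle
to the original axis; this entry-bootstrap differs from a rotation null
when the weights have nonzero mean, and is the convention implemented.
Clustering is average-linkage on the angle matrix. The SDI formula is
`(d′_global / max_i d′_i − 1)·100`; under independent noise the pooled d′
of N equal contributors grows as √N, so the attainable SDI scales like
(√N−1)·100 — the nominal (N−1)·100 ceiling is treated as descriptive and
never asserted. The five-area-group d′ space uses dorsal (PM, AM),
ventral (L), parietal (A, AL, RL), somatosensory (SSt, SSb), and
retrosplenial (RS) groups; V1 is excluded because it contributes a
near-uniform d′ to every separation. Piecewise fits are continuous
two-segment least squares with one free knot, scanned at sample
resolution and refined by a bounded scalar search; the fit window runs
from −1 s to the earliest time the curve reaches 95% of its post-movement
maximum, and flat curves are flagged degenerate rather than fit.

The pixel-vs-axis contrast uses a dedicated construction
(`synth.planted_sparse_choice_session`): 400 carrier pixels spread across
all areas, per-pixel d′ = 0.12, with a small per-area *independent*
background fluctuation on the carrier population. The background makes
each area's carrier fragment a compressible, localized activity mode (so
the factorization retains it) while pooling across the 10 independent
areas still averages it away; the resulting component-space axis d′ is
≈ 1.1–1.2 while no single pixel exceeds ≈ 0.27. A construction with only
iid pixel noise cannot achieve both at this grid size: either the pattern
carries too little variance for any decomposition to retain, or a shared
fluctuation floors the pooled statistic at the per-pixel level.

## Recurrent decision model

The model is a 50-unit Elman RNN with ReLU activations, three inputs
(left stimulus, right stimulus, binary attention), batch normalization
over the recurrent output sequence (placement is unstated upstream; this
is the recorded choice), and a 3-class softmax head. Inputs run 25 frames
with the stimulus appearing at frame 10, orientation mapped to [−1, 1]
with Gaussian noise of SD 0.1 on the stimulus channels ("amplitude 0.1"
interpreted as an SD); the attention channel is a noiseless constant.
Loss is cross entropy at the stimulus frame (target no-choice) plus cross
entropy at the final frame (target the drawn choice); training uses Adam
(learning rate 1e-3, the common framework default) for 25 epochs at batch
640. The entire network, batch-norm backward pass, backpropagation
through time, and optimizer are in numpy; gradients are verified against
finite differences to ~1e-9 relative error.

Because the labels are stochastic draws from the psychometric curve,
end-of-trial accuracy converges to the generator's label consistency
(the mean of max(P_left, 1−P_left)): ≈ 0.68 on low-attention trials and
≈ 0.80 on high-attention trials, and the final-frame softmax probability
P(L)/(P(L)+P(R)) converges to the psychometric probability itself — the
psychometric readout and the lapse-recovery check use this output
probability, while the argmax response is a much steeper near-step
function of θ. For representational analyses the model's "choice" on a
trial is its own argmax response, in the same way an animal's choice is
its recorded response. At zero difficulty the generated labels are
independent of the stimulus by construction, so no stimulus-linked choice
axis exists there; per-difficulty choice-axis comparisons use the nonzero
levels (the behavioral task's smallest orientation difference was
likewise never zero). Trained networks represent choice along nearly the
same hidden direction at every nonzero difficulty; the angle between the
easiest- and hardest-level axes is typically 10–20° for a single training
run at 640 trials per level, with occasional runs reaching ~30°, and
concentrates well below 20° at larger training sizes.

## Pipeline and problem sizes

`run_pipeline` executes simulate → decompose → axes → geometry (→ RNN)
from one config; every analysis constant (0.99 variance targets, 0.75
localization, 20% training fraction, 5 folds, tertile split, 2000
surrogates, 25 epochs, batch 640, λ = 0.2, α = 2/90 and 5/90, 13 levels)
is a config field echoed in the report header. Reports are deterministic
for a fixed (config, seed). Stage caching was considered and dropped:
runs are deterministic and desk-scale runtimes are tens of seconds, so a
content-addressed cache would add complexity without benefit.

Default problem sizes are chosen for routine desk use: 32–64 pixel grids,
200–400 trials per session, 640 RNN trials per difficulty level and
attention state (the full-scale generator setting is 6400 per level), and
the component cap of 2–4 per region. All are configurable upward.

## Known limitations

- The greedy rank search and HALS solver are simplifications of the
  reference localized-NMF algorithm; on data with hundreds of genuine
  components per region their component counts may differ.
- The diagonal state-axis estimator ignores component covariance; it is
  the estimator under study, not an optimal linear decoder, and the
  duplicate-component pruning above exists precisely because it cannot
  exploit anti-correlated noise.
- Single-seed RNN training at the desk-scale size leaves noticeable
  run-to-run variance in representational statistics; claims about the
  model family should be checked across several seeds.
- The synthetic noise model is white in space and time; real widefield
  noise is spatially correlated and hemodynamically structured, so
  absolute d′ values here do not predict real-data effect sizes.
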