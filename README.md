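# mesochoice

State-axis analysis of distributed choice signals in mesoscale cortical
imaging, on fully synthetic data.

## The problem

During a two-alternative orientation-discrimination task, widefield calcium
imaging of the mouse posterior cortex records a superposition of variables:
stimulus-evoked responses, wheel- and eye-movement activations, slow
attention-state shifts, and — much weaker and sparsely distributed across
areas — signals that correlate with the animal's left/right *choice*.
Pixel-by-pixel decoding cannot see the choice signal; it becomes readable
only after spatial integration: a localized non-negative matrix
factorization (one set of components anchored to each of 10 cortical
areas) followed by a linear discriminant ("state axis") in component
space.

This package implements that analysis chain end to end, together with a
synthetic-session generator that plants each variable with controllable
amplitude, so every stage can be validated against planted ground truth:

- `mesochoice.synth` — 10-area atlas, per-trial dF/F tensors with planted
  stimulus / movement / saccade / attention / choice signals, behavior
  tables, psychometric choice generation, and RNN training data;
- `mesochoice.preprocess` — grand-mean dF/F, zero-phase band-pass and
  overlapping spatial binning, wheel/saccade event detection, the
  pupil-based attention metric, dual-wavelength hemodynamic correction;
- `mesochoice.decompose` — SVD compression and seeded,
  localization-penalized NMF with a greedy rank line search
  (`F[x,y,t] ≈ Σ_k A[x,y,k] · C_k(t)`, spatial maps non-negative and
  anchored to their seeding region);
- `mesochoice.axes` — trial-group construction per task variable, state
  axes `S ∝ (⟨A⟩−⟨B⟩)/σ_AB` (pooled SD, unit norm), projections
  `P_i(t) = S·C_i(t)`, and 5-fold cross-validated discriminability
  `d′(t) = (⟨P_A⟩−⟨P_B⟩)/σ_pooled` with axes fit on 20% of trials;
- `mesochoice.geometry` — pairwise axis angles (folded to [0°, 90°]), a
  bootstrap surrogate null for independent axes, hierarchical clustering,
  the Spatial-Distribution Index `SDI(%) = (d′_global/max_i d′_i − 1)·100`,
  five-area-group d′ coordinates, two-segment piecewise fits of d′ ramps,
  and pixel-wise d′ maps (the negative control);
- `mesochoice.rnn` — a 50-unit ReLU Elman network with batch normalization
  and a 3-way softmax head, trained with Adam on choices drawn from the
  lapse-logistic psychometric curve
  `P_left(θ) = σ(αθ)(1−λ) + λ/2` (λ = 0.2; α = 2/90 low / 5/90 high
  attention), then analyzed with the same state-axis machinery on its
  hidden units. The network and its training loop are implemented directly
  in numpy (the model has ~3,000 parameters; gradients are verified against
  finite differences in the test suite);
- `mesochoice.pipeline` / `mesochoice.cli` — one-config orchestration and a
  `mesochoice` command-line entry point.

## Worked example

```python
import numpy as np
from mesochoice import synth, decompose, axes

atlas = synth.make_atlas(shape=(32, 32), seed=0)
params = synth.SessionParams()                  # 30 fps, 1 s pre-stim, 1.5 s open loop
tensor, trials = synth.simulate_session(
    atlas, synth.default_signal_spec(), params, n_trials=200, seed=1
)

x = np.moveaxis(
    tensor.data.reshape(200, -1, tensor.n_frames), 0, 1
).reshape(np.prod(atlas.shape), -1)
masks = decompose.make_seed_masks(atlas)
decomp = decompose.loca_nmf(x, masks, atlas, n_trials=200, seed=0)

pair = axes.build_group_pair(trials, "choice", params.frame_rate, seed=0)
ga = axes.extract_aligned(decomp.temporal, pair.trials_a, pair.align_a, (-0.5, 0.5), 30.0)
gb = axes.extract_aligned(decomp.temporal, pair.trials_b, pair.align_b, (-0.5, 0.5), 30.0)
curve = axes.dprime_curve(ga, gb, 30.0, (-0.5, 0.5), seed=0)
print(f"components: {decomp.n_components},  peak |d'| choice: {curve.peak:.2f}")
```

Output from this exact script:

```
components: 38,  peak |d'| choice: 0.87
```

38 spatial-temporal components were retained across the 10 areas, and the
held-out discriminability of left- vs right-choice trials along the choice
state axis peaks at d′ ≈ 0.9 — the planted choice amplitude is one fifth
of the stimulus amplitude and spread over 20% of pixels, so no single
pixel or area reaches this value on its own.

The full pipeline (all five variables, geometry statistics, optional RNN)
runs from the command line:

```bash
mesochoice run-all --seed 1 report.json
mesochoice rnn-train --seed 1 --trials-per-level 640 rnn_report.json
```

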