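# Methods

## Problem and labels

A plot's maturity day is the day (counted from September 1 = day 1) when it
reaches growth stage R8, scored visually.  Each drone flight over a trial
yields one sample per plot with the seven vegetation-index features and the
label

    rmd = imaging_day − maturity_day   (days),

negative when the plot matures after the flight, positive when it had
already matured.  Because flights happen in a 100–121 days-after-planting
window, plots maturing far outside it cannot be resolved from imagery;
samples with `rmd ≤ −15` or `rmd ≥ 20` are excluded before modelling (both
bounds excluded).

## Imaging features

Plot rasters carry five reflectance bands (blue, green, red, rededge, nir).
Canopy is segmented from soil on the NDVI channel, either by threshold or by
a two-phase Chan–Vese active contour (scikit-image, 200 iterations,
initialised from the NDVI > 0.3 mask; the phase with higher mean NDVI is
foreground).  Foreground components smaller than `min_area` (default 25 px,
8-connected) are removed as noise.  Per-pixel indices are then averaged over
the mask (configurable to median):

| index | formula |
|---|---|
| CCCI  | ((nir−re)/(nir+re)) / NDVI, NDVI = (nir−red)/(nir+red) |
| MTVI2 | 1.5·(1.2·(nir−green) − 2.5·(red−green)) / √((2·nir+1)² − (6·nir − 5·√red) − 0.5) |
| BNDVI | (nir−blue)/(nir+blue) |
| GLI   | (2·green−red−blue)/(2·green+red+blue) |
| CI    | (red−blue)/red |
| H     | atan2(2·red−green−blue, √3·(green−blue)) |
| V     | max(red, green, blue), clipped to [0, 1] |

Numerical conventions: any index whose denominator magnitude falls below
1e-9 is flagged missing (NaN) rather than returned as ±inf, and flagged
pixels are skipped in that index's plot aggregate; hue uses the two-argument
arctangent so the quadrant is defined, with H = 0 and a flag at the 0/0
point; an empty mask yields an all-flagged feature vector, never silent
zeros.  The MTVI2 denominator follows the index's canonical definition.
Whether indices should be averaged per pixel (as here) or computed on
per-plot band means is ambiguous in the field; the difference only touches
the nonlinear indices and is far below the feature noise.

## Networks

All techniques share a feed-forward extractor 7→64→64→64→32, a linear
predictor 32→1, and (for adaptation) one or more classifiers 32→16→2
emitting log-probabilities over {source, target}.  Prediction loss is the
MSE in days²; classification loss is the mean negative log-likelihood.
Parameters use fan-in-scaled uniform initialisation; inputs are
standardized with statistics of the source training data only, and the
scaler is part of the saved model.

The activation is tanh throughout.  A bounded latent space turned out to be
the decisive conditioning choice for the adversarial game: with unbounded
ReLU features the domain classifier chases a drifting, badly scaled
representation and the extractor can "fool" it without ever aligning the
domains, whereas with tanh latents the same optimisation aligns them
reliably.  ReLU remains available (`activation="relu"`).

The gradient reversal layer is the identity on the forward pass; during
backpropagation the classification loss's gradient with respect to
everything upstream of the connector is multiplied by −λ (default λ = 1,
optionally ramped from 0 to λ over training with the logistic schedule
2/(1+e^(−10p))−1).  The classifier itself always receives unreversed
gradients, so it learns to discriminate while the extractor learns to
defeat it.

## Training procedures

Optimisation is Adam (β = 0.9/0.999, ε = 1e-8) on minibatches.  Defaults,
chosen where the study protocol fixes them and by small-scale calibration
otherwise:

| constant | default | note |
|---|---|---|
| pre-training epochs | 50 | study protocol |
| fine-tuning epochs | 20 | observed balance point; sweeps use 50 |
| adaptation epochs | 100 (max 500) | study protocol |
| target batch size | 100 | fixed by protocol; epoch = ⌈n_target/100⌉ paired batches |
| source batch size | 100 | swept 40–200 in the batch experiment |
| lr (pretrain / adaptation) | 1e-3 | |
| lr (fine-tune) | 3e-4 | lower than pre-training to preserve representations |
| lr (domain classifier) | 1e-2 | stronger adversary; see below |
| classifier steps per batch | 5 | see below |

*Fine-tuning* copies the pretrained parameters, freezes the first three
extractor layers exactly (they are never touched by the optimiser, hence
bitwise unchanged), and updates the remaining extractor layer and the
predictor on the labelled target subset.

*Single-source adaptation* pairs each target batch (each target sample
exactly once per epoch) with a full source batch drawn by reshuffled
cycling.  Per paired batch the objective is `L_y(source) + L_d(source ∪
target)`, with `L_d` reaching the extractor only through the reversal.
Target labels are never read.  Because one optimiser step per batch leaves
the classifier far behind a representation that moves every step, the
classifier takes several extra steps per batch on the current latents
(default 5) at its own higher learning rate — without this the adversary
stays at chance while the features remain separable by any converged probe.

*Multi-source adaptation* keeps one classifier per source domain, each
discriminating its source batch against the target batch; the aggregate
classification loss is the unweighted mean over classifiers.  With a single
source the procedure reduces exactly — same RNG streams, same arithmetic —
to the single-source procedure, which the tests verify bit for bit.

Every procedure is a pure function of (data, architecture, config, seed).

## Synthetic trial generator

The generator emulates the study's data structure, not any real field:

* **Maturity days** — integer draws from a truncated normal per trial
  (rejection sampling; inclusive bounds).  The five canned trial designs
  (progeny trial 433 plots, preliminary yield trial 1,265, and three
  advanced yield trials of 885–1,500 plots; check fractions 5–25%; two
  flights each in 2018–2020 layouts, one in the 2021 layouts) follow the
  published trial descriptions; their distribution parameters are
  illustrative.
* **Reflectance** — per band b, ρ_b(r) = ρ_green_b + (ρ_senesced_b −
  ρ_green_b)·logistic(r/τ) with τ = 6 days, between a green canopy spectrum
  (0.04, 0.08, 0.05, 0.30, 0.50) and a senesced one
  (0.09, 0.16, 0.20, 0.28, 0.32).
* **Features** — the analytic indices of that spectrum, per-domain affine
  shift `slope·x + intercept`, plus Gaussian noise.  Default noise is ~10%
  of each index's dynamic range, calibrated so a source-trained network
  reaches a realistic 1.6–1.9-day test RMSE; at lower noise the synthetic
  task is implausibly easy and every data-volume effect disappears into a
  sub-day floor.
* **Domain shift** — the affine feature map is the single knob standing in
  for genotype-by-environment, sensor and season effects.  The `moderate`
  level degrades a source-only model on the target by roughly a quarter to
  a third (comparable to published cross-year degradations); `strong` is
  2.5× the moderate deviations.
* **Plot rasters** — canopy drawn as crop-row strips over a fixed dry-soil
  spectrum (0.08, 0.10, 0.12, 0.18, 0.22), with optional pixel noise; the
  returned mask marks canopy pixels exactly, which closes the loop between
  the imaging pipeline and the tabular generator (zero-noise rendered plots
  reproduce the analytic features to 1e-6).
* **Reproducibility** — one RNG stream per domain keyed by (scenario seed,
  CRC32 of the domain id), so adding a domain never perturbs the others.

What the generator does *not* emulate: spatial autocorrelation within a
field, weather and lodging, genotype structure, orthomosaic stitching
artefacts, or reflectance-calibration error.  Passing tests therefore show
that the procedures behave as designed under the assumed shift structure,
not that they reach any particular accuracy on real trials.

Two canned scenarios serve different questions.  `standard_scenario`
mirrors the study layout (two labelled source trials, one shifted target
trial) and drives the ratio/batch sweeps and the directional-improvement
checks.  `covariate_shift_scenario` uses two *identical* trial designs so
the label (RMD) marginals coincide and the affine feature shift is the only
domain signal; feature-alignment experiments must use it, because under
mismatched label marginals even perfectly adapted features remain
domain-separable (the latent encodes the label) — with matched designs the
separability floor is chance.

## Evaluation

R² is the coefficient of determination 1 − SS_res/SS_tot (can be negative);
RMSE is in days.  Grouped reports (per domain, per flight) always compute
pooled rows on concatenated residuals, never by averaging group metrics.
Epoch curves are smoothed with a forward 10-point mean (tail elements
average the remainder); the turning point of a target-accuracy curve is the
first index after which the smoothed series strictly decreases for ≥ 3
consecutive evaluations and never regains its value — `None` when no such
index exists.  The fine-tuning-ratio sweep pre-trains once, fine-tunes for
50 epochs on each fraction of the target-training split, and evaluates on
the remaining target data (or a supplied fixed set).  The independent-trial
harness fine-tunes per target trial on its check lines only and reports on
breeding lines; adversarial arms use all target features unlabelled and
report on all target samples.

Feature alignment is measured by a logistic-regression domain probe
(held-out 70/30 split) on the latent features — near 0.5 means aligned
representations, near 1.0 means the domains remain separable.

## Known limitations

* The adversarial equilibrium is sensitive to optimisation balance; the
  classifier-steps and classifier-learning-rate defaults were chosen on the
  synthetic bench and may need retuning for other feature sets.
* Uncertainties are residual-based (bootstrap RMSE intervals on request);
  no calibration of per-plot predictive intervals is attempted.
* Checkpoints store plain arrays (npz + JSON header, format version 1);
  optimiser state is not persisted, so training cannot be resumed
  mid-epoch.
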