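# Methods

This note documents the models, numerical choices, and limitations behind
`erkdyn`. Everything stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is quoted from external measurements.

## Biosensor calibration

The EKAR-family FRET reporter is read out as the *associated fraction*

    f_A = 1 − (I_CFP / I_YFP) / R_P,

the fraction of reporter molecules in the high-FRET conformation, where
`R_P` is the imaging power ratio between donor and acceptor channels
(supplied as a constant; we do not model filter/fluorophore physics).
Phos-tag anchors — (phospho fraction `p`, mean `f_A`) pairs measured under
graded stimulation — are fit by ordinary least squares to the affine line

    f_A = K_AU + (K_AP − K_AU) · p,

whose endpoints `K_AU`, `K_AP` are the associated fractions of the fully
unphosphorylated and fully phosphorylated reporter. This affine form is the
unique line consistent with the activity map below at `p = 0` and `p = 1`;
a multiplicative form `(K_AU + K_AP)·p`, which sends `f_A → 0` at `p = 0`,
is algebraically incompatible with that map and is not used. Activity is

    x = ERK_active / phosphatase_active = (f_A − K_AU) / (K_AP − f_A),

with the exact inverse `f_A = (K_AU + x·K_AP)/(1 + x)`. Measurement noise
inevitably produces `f_A` outside `[K_AU, K_AP)`; by default such values
are clamped to `[K_AU, K_AP − 1e-6·span]` (a per-cell flag is available via
`clamp_fa`), because the accepted range used for cell exclusion in the
original experiments is not published. The clamp threshold is configurable
and is a package default, not a measured value.

## Batch correction

Endpoint stain intensities are long-tailed, so replicate alignment happens
in log space: per target, matched-condition medians are computed per
replicate in log10, the reference replicate's medians are regressed on each
source replicate's (`reference = β1·source + β0`, requiring at least two
shared conditions), every single-cell log10 value of the source is mapped
through the fit, and values are exponentiated back. The map is affine in
log space, hence monotone: within-replicate rank order is preserved, and
re-applying the correction is idempotent up to fit residual. A
`pool_groups` mode computes medians pooled over co-plated groups (e.g.
multiple cell lines) so each replicate receives a single scaling per
antibody and between-group differences are preserved.

## Trace featurization

Pulses are interior local maxima with topographic prominence at least a
threshold, by default 10% of the dataset's activity interquartile range.
Pulse *duration* is the width at half prominence with linearly interpolated
crossings (a standard, parameter-free definition; the source experiments do
not define one). Nine features summarize each trace: mean, max, summed and
average pulse duration (min), summed and average pulse height (activity at
the peak), average absolute first difference per minute, average inter-pulse
interval (min), and frequency. *Average derivative* uses the absolute
difference because a signed mean would cancel on pulsatile traces — the
shape this feature is meant to detect. Cells with fewer than two pulses get
the observation window as their inter-pulse interval (a defined upper bound
rather than a missing value, so downstream regressions keep all cells); an
`interval_imputed` flag records this.

*Frequency* is the power-weighted mean frequency of the one-sided
periodogram of the mean-subtracted trace, in cycles/hour, computed with a
Hann taper. A rectangular window biases the power-weighted mean by up to
~10% when the window holds a non-integer number of cycles (measured on
pure sinusoids at 4–5 h periods); the Hann taper keeps the recovery of a
known oscillation within 0.2% across 1–6 h periods. The estimator is
invariant to additive offsets and positive scaling.

Quality control drops cells with under 15 hours of finite data or any
sample outside configurable plausibility bounds; on the fixed 19-hour
sampling grid this retains exactly the cells with complete finite traces.

## Delay-ODE model of ERK-driven gene expression

A hypothetical ERK target gene follows four coupled equations driven by an
activity input `E(t)`: TF phosphorylation, delayed transcription with
negative feedback of total protein on its own production (Hill term with
half-max `K_D` and exponent `v`), delayed translation, and ERK-dependent
protein phosphorylation. The phosphorylation flux `k_pP·E·P` leaves the
unphosphorylated pool and enters the phosphorylated pool with the same
magnitude, so total protein is conserved when all degradation rates vanish
(verified to integration tolerance). The endpoint readout is total protein
`P + P^P` (a total-protein antibody analog); a phospho-only readout is a
switch.

Integration is classical fixed-step RK4 (default step 1 min), vectorized
over cells, with delayed states read from the stored solution history by
linear interpolation; pre-history equals the initial condition, which is
the steady state under the pre-stimulus ERK level. Steady states solve the
closed-form linear chain when feedback is off, and otherwise a scalar
monotone fixed-point equation for total protein by bracketed root finding
on `[0, no-feedback total]` (the bracket always contains exactly one
root). RK4 preserves equilibria exactly, so long-horizon endpoints converge
to the analytic fixed point independent of step size, and halving the step
changes endpoints on reference inputs by under 0.1%. The gene survey runs
at a 2-minute step, justified by that convergence measurement.

Parameter sampling varies six quantities: the mRNA, protein and
phospho-protein degradation rates and the protein dephosphorylation rate
(log-uniform over two decades around unit-scale per-minute rates:
`k_dm ∈ [1e-3, 1e-1]`, `k_dp, k_dpp ∈ [1e-4, 1e-2]`, `k_deph ∈ [1e-3,
1e-1]` min⁻¹), the feedback half-max `K_D ∈ [10, 1000]`, and the
fractional expression at baseline, uniform in [0, 1] with `k_b + k_m`
fixed at 1 so the fraction itself is the sampled quantity. The remaining
rates are fixed defaults. These ranges are package defaults chosen to span
half-lives from minutes to days against the 19-hour observation window;
they are not published values, so published survey fractions are not
comparable targets. A gene's regulation sign compares endpoints under a
sustained high-ERK step versus zero ERK; ties are labeled positive with a
degeneracy flag. Under the default ranges both signs occur.

## Synthetic data generator

The generator emulates a 96-well live-cell experiment followed by endpoint
staining. Per-cell activity is: an Ornstein–Uhlenbeck baseline (mean 0.1,
sd 0.02, correlation time 30 min, exact AR(1) discretization); an acute
media-addition transient at treatment time in every well including dose-0
controls (amplitude 0.15, decay 90 min) — this is what gives the "low"
history class a shared shape that survives the prototype-correlation
filter, as vehicle responses do in real imaging; a dose-scaled initial
transient relaxing to a sustained plateau (saturating with half-max 2
ng/ml); and a Poisson pulse train (rate saturating at 1.5/h) with per-cell
lognormal amplitude and duration. MEK inhibition relaxes activity
exponentially (time constant 6 min) to a floor at 30% of baseline and
stops pulsing. Per-cell lognormal multipliers (log-sd 0.3) provide
heterogeneity. Mean activity is non-decreasing in dose by construction,
and post-inhibition activity is below pre-inhibition activity for every
stimulated cell.

Coordinates are uniform in a 702 × 785 µm field with a configurable
fraction (default 25%) grouped into spatial clusters of 5–30 cells
(Gaussian spread 25 µm); each cluster of non-inhibited cells shares a
synchronized activity burst in the final two hours. Stains come from the
delay-ODE model applied to each cell's trace through a named eight-target
panel whose parameters span fast phospho-trackers to slow integrators,
multiplied by unit-mean lognormal noise (default CV 10%) and
replicate-specific batch factors (log10-normal, sd 0.15, reference
replicate at 1). Ground truth (class per treatment archetype, burst
cluster, batch factors) is stored losslessly.

Five treatment archetypes define history classes: moderate-then-off (EGF
then mid-experiment inhibitor), low (no or sub-threshold dose, or
immediate inhibition), recent-on (EGF in the final five hours), mid-term
(delayed EGF, inhibited late), and long-high (sustained high dose). All
archetype trace parameters are free defaults: no quantitative pulse-shape
parameters exist to fit.

What the generator does *not* emulate: optics and photobleaching,
segmentation/tracking errors, cell division and migration, receptor-level
adaptation, or correlated antibody cross-talk. Passing tests therefore
demonstrate internal consistency of the inference machinery under a known
generative model, not performance on microscopy data.

## Forward models

Targets are log10 stain intensities. Evaluation uses stratified folds (by
well/treatment): 20% of cells held out as test, the rest split 64/16 into
train/validation. The time-series linear model regresses the target on all
trace timepoints (minimum-norm least squares; collinearity resolved by the
pseudoinverse). The featurized linear model uses the nine dynamic features.
The convolutional model is two same-padding 1-D convolutions (16 channels,
kernel 16) feeding dense layers of 192, 64 and 64 rectified units and a
linear output; the 192-unit layer width is fixed regardless of input length
(same-padding keeps the conv output at the input length, so a "match the
input" rule would be ill-defined after truncation). Inputs and targets are
z-scored with dataset-level statistics. Training is Adam (learning rate
1e-3) on mean-squared error with an L2 penalty (default 1e-3, with 1e-2 and
the grid {1e-1, 1e-2, 1e-3} as the documented alternatives), 100 epochs
default, batch size 256. The network, backpropagation and Adam are
implemented in NumPy (`erkdyn._nn`) and run single-threaded CPU; fixed
seeds reproduce training exactly.

Attribution uses integrated gradients along the straight path from an
all-zeros standardized trace (or the dataset mean) with a midpoint Riemann
sum. For a linear model the attribution is exactly `w ∘ (x − baseline)` at
any step count. For the rectified network the path integral converges at
rate 1/n_steps because of activation kinks; 1024 steps bring the
completeness residual below 1e-3 on trained models. Truncated-window
training (`keep_last_n`, default 150 of 190 samples) re-fits on the
trailing window with the offset recorded.

## Reverse models

Stains enter regressions in log10 (configurable), z-scored; coefficients
are reported in both scales. Cross-validation is 10-fold; following the
source procedure, the fold with the lowest test RMSE selects the model
form, which is then refit on the full data and its R² reported. Nesting
guarantees the full multiple regression never scores below the best single
predictor in-sample. Incremental predictor addition ranks stains by
single-predictor R² and reports the cumulative curve. Condition-average
models regress per-condition means on per-condition means; with
independent per-cell noise this bounds single-cell R² from above.
Condition exclusion filters all tables consistently through a predicate on
the condition label.

## History classes and classification

Activity traces are clustered by k-means (k = 5, best of 10 restarts) on
raw calibrated activity without per-cell normalization (a z-scoring switch
exists). Each cell's Pearson correlation to its class centroid gates
training membership at r ≥ 0.7; a class losing all members is an error
naming the class. The stain-based classifier is multiclass boosting (SAMME)
over depth-2 decision trees, 500 rounds, with 10-fold stratified
cross-validation; the fold model with the lowest test error is reported
with per-class accuracy and the confusion matrix. Cells dropped by the
correlation filter still receive predictions at annotation time. Predictor
importance is the ensemble's accumulated split-gain per stain.

Spatial aggregation uses a pointy-top hexagonal lattice (circumradius
default 50 µm) anchored at the field origin, with exact axial-coordinate
rounding for nearest-center assignment, so region identifiers are
reproducible; an optional group key keeps separate imaging fields from
sharing regions. The regional pipeline repeats clustering, filtering and
classification on region means computed over filter-surviving cells.
Whole-image models use one sample per image and a single decision tree
(appropriate to the sample size), with as much cross-validation as the
image count permits.

## Statistics

Endpoint comparisons model two error scales, cell-to-cell and
experiment-to-experiment (`ε_i = ε_cell + ε_exp`). The test statistic uses
the variance of replicate means divided by the replicate count as each
group's squared standard error: the expectation of that variance is
`σ_exp² + σ_cell²/n`, i.e. it already composes both scales without double
counting (adding the cell term again would, and measurably drives the null
rejection rate to ~0.016). Groups combine Welch-style with Satterthwaite
degrees of freedom on replicate counts; with three replicates per group the
null rejection rate at α = 0.05 is ~0.035 (measured at 100,000 null
draws), the familiar mild conservatism of Satterthwaite at tiny group
counts. The floored decomposition (`max(s_b − s_w/n, 0)` as the experiment
component) is reported for interpretation. False discovery control is
Benjamini–Hochberg step-up. Spatial heatmap ordering is average-linkage
hierarchical clustering of pairwise Euclidean distances with exact optimal
leaf ordering (branch flips minimizing summed adjacent-leaf distance
without splitting clusters).

## Problem sizes

Default analyses run on synthetic plates of 10 treatments × 3 replicates.
The shipped checks use 60 cells/well (1,800 cells) for classification,
35 cells/well (1,050 cells) for reverse inference, 5,000 cells for the
forward-model comparison (60 training epochs, where the non-linear margin
is already stable), a 200-gene × 1,000-cell survey at a 2-minute ODE step,
and 4,000–10,000 Monte-Carlo draws for statistical calibration. These sizes
were chosen so every property of interest is measured with comfortable
margin on a single CPU core.

## Known limitations

- The delay-ODE model is deterministic; transcriptional bursting and
  intrinsic expression noise are represented only as endpoint lognormal
  measurement noise.
- The boosted classifier's importance scores inherit CART's column-order
  tie-breaking; scores are stable only up to small perturbations.
- Calibration assumes a single reporter population per cell; mixed
  expression states would bias `K_AU`/`K_AP`.
- The generator's archetype parameters are plausibility defaults, so
  absolute accuracies on synthetic data say nothing about accuracies on
  microscopy data; only the relative/structural claims transfer.
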