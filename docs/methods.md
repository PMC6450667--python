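# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## Behavioral model

Responses on the color wheel and panorama are reduced to wrapped errors
e = response − target in (−180°, 180°], with 180° (not −180°) on the
boundary. Angles are kept in degrees throughout; radians appear only inside
density evaluation. The error distribution is a two-component mixture

p(e) = (1 − γ)·φ_k(e) + γ/2π,

where φ_k is the zero-mean von Mises density (evaluated with the
exponentially scaled Bessel function `i0e`, so concentrations up to the
k = 500 bound do not overflow) and γ is the guess rate. There is no swap
(misbinding) component and no bias parameter.

**Fitting.** The log-likelihood surface is multimodal for small samples, so
the MLE restarts a bounded L-BFGS-B search from the grid
k ∈ {1, 4, 16, 64} × γ ∈ {0.1, 0.5, 0.9}, with k ∈ [0.01, 500],
γ ∈ [0, 1], and keeps the best optimum; the procedure is deterministic
given the data. A fit pinned at the k bounds (e.g. all-identical errors) is
flagged `converged=False`. Group-level ("aggregate") fits pool wrapped
errors across all included subjects, after exclusion.

**Success threshold.** The posterior probability that an error belongs to
the memory component is (1−γ)φ_k(e) / [(1−γ)φ_k(e) + γ/2π]; it crosses 0.5
at cos e\* = [ln(γ/(1−γ)) + ln I₀(k)] / k. Ties at exactly 0.5 classify as
correct. Degenerate cases return 180° (posterior never falls below 0.5) or
0° (never reaches it). In the two regimes the behavioral generator uses by
default — (k = 5.4, γ = 0.33) for color, (k = 27, γ = 0.36) for scene —
the closed form gives ≈ 56.8° and ≈ 27.9°; the scoring defaults round these
to the conventional 57° and 30° cutoffs but can derive thresholds from an
aggregate fit instead (`thresholds="derive"` in `RunConfig`).

**Scores.** Precision of a correct trial is 180 − |e| (undefined on
incorrect trials). The composite quality score is emotion (0 / 0.5 / 1 for
incorrect / low-confidence correct / high-confidence correct) plus, per
visual feature, 1 − |e|/threshold on correct trials and 0 otherwise, giving
a total in [0, 3]. Threshold-relative scaling keeps the score continuous at
the classification boundary; a `scaling="range180"` switch provides the
180°-relative alternative, which is discontinuous there. Missing responses
count as incorrect rather than being dropped, preserving trial counts for
modulator construction. Subjects with mean |e| ≥ 75° on either visual
feature are excluded (uniform guessing gives an expected 90°).

## Dependency statistics

For binary success outcomes A, B over a subject's trials, corrected
dependency is (P_AB + P_A′B′) − (P_A·P_B + P_A′·P_B′); it is symmetric
under jointly relabelling correct/incorrect and needs no special-casing at
degenerate margins (observed equals expected when a feature is always
correct). Emotion counts as successful on any correct response, collapsing
confidence. Precision–success and precision–precision Pearson correlations
are Fisher-z transformed with r clipped to ±(1 − 1e−7); the
precision–precision correlation is restricted to trials where both
features were correct. Group inference is a one-sample t with df = n − 1.

## Synthetic-data generator

The generator is first-class, tested code: it defines the conditions under
which every downstream claim is verified.

**Design.** The full profile mirrors the emulated study: 28 subjects,
6 study–test blocks of 24 trials (144 object–scene–sound events), 6
panoramas shown 4× per block, valence balanced 12/12 within block, and any
two same-panorama trials within a block at least 45° apart in both color
and location (rejection sampling with an even-spacing fallback; infeasible
constraints raise before sampling). One scan run per block, 466 volumes at
TR 1.5 s, 6 s events; encoding trials every 7 s from t = 10 s, remember
trials every 20 s after a 20 s gap. A small profile (4 subjects, 2 runs ×
120 scans, 6 trials per block, compressed spacing) exists for fast tests.

**Behavior.** Each trial draws a Bernoulli(0.5) latent memory state that
shifts every feature's in-memory probability by ±`dependency_strength`
(default 0.15): color and scene responses are von Mises around the target
when in memory and uniform otherwise, emotion is correct with a shifted
probability around `p_emotion_correct` = 0.76. This plants success
dependency while leaving precision (k) uncoupled across features, so the
dependency stage is falsifiable in both directions. Marginal guess rates
equal γ as long as the shift does not clip. High confidence is an
independent Bernoulli(0.70); the confidence split is a generator choice —
only the overall emotion accuracy has an empirical anchor.

**Neural.** Per run, the latent ROI signal is white-in-time Gaussian noise
with covariance 1 on the diagonal, `within_cov` = 0.6 inside a network
(PM, AT, HIPP over the canonical 12 ROIs) and `between_cov` = 0.1 across
networks; during remember windows (onset to onset + 6 s + 5 s hemodynamic
lag) the between-network covariance is raised by
`retrieval_between_boost` = 0.2. These levels were chosen once so the
thresholded matrices land in a realistic regime (within r ≈ 0.5, between
r ≈ 0.1 at encoding after 0.5-SD white noise). Events add an HRF-convolved
boxcar (canonical double-gamma, "glover": ~6 s peak, ~16 s undershoot) of
amplitude 1 to every ROI. Planted gPPI couplings add
β · seed(t) · m(t) to a target, where m(t) is the convolved, centered
modulator (quality or feature precision, computed from the generated
behavior at the 57°/30° thresholds) and seed(t) is the *noisy* seed signal
— the estimator being tested forms its interaction in BOLD space from the
observed seed, so planting on the noise-free latent would build an
errors-in-variables attenuation into the ground truth. Random-walk nuisance
signals (6 per run) contaminate all ROIs with Gaussian loadings and are
returned for denoising. All generation flows from explicit integer seeds
through `numpy.random.default_rng`; no global RNG state is touched, and
output is bit-reproducible.

**What the generator does not emulate.** No volumetric images, no motion
or physiological noise structure, no autocorrelated BOLD noise (the latent
process is white in time), no hemodynamic variability across regions, and
no response-time dynamics. Passing tests therefore demonstrate the
correctness and calibration of the estimators under the stated generative
model, not their robustness to real-data artifacts such as head motion or
serially correlated noise.

## Background connectivity

Event models build, per condition (encoding, remember) and per run, a 6 s
boxcar and five parametric modulators — emotion memory (0/0.5/1), color
and scene success (mean-centered over all trials of the condition), color
and scene precision (centered within correct trials of that feature, zero
elsewhere) — all convolved with the canonical HRF at TR (16× oversampled
impulse grid via nilearn).

Denoising runs per run in one least-squares projection: intercept, linear
trend, discrete-cosine high-pass basis with cutoff 128 s (K = ⌊2·T·TR/128⌋
functions — regression on this basis implements the 1/128 Hz high-pass and
composes with the rest of the projection), nuisance regressors, and — for
background connectivity — all task and memory regressors. Residuals are
concatenated across runs. A rank-deficient design raises an error naming
the dependent columns; the pipeline passes `on_collinear="drop"`, because
in short runs a modulator that happens to be constant within the run
exactly duplicates the event boxcar and carries no information.

Condition-weighted correlations use nonnegative weights from the
HRF-convolved condition boxcar, negative lobes clipped at zero and
normalized to sum 1 (normalization does not affect the correlation);
weighted Pearson reduces exactly to ordinary Pearson under equal weights.
Matrices are thresholded by zeroing entries **below** the cut (default
0.25; entries at the cut survive), keeping surviving weights. Negative
correlations are zeroed at any nonnegative cut; there is no absolute-value
option.

Louvain community detection (networkx implementation, resolution 1.0) is
stochastic, so Q is the maximum over 100 seeded restarts; an empty graph
defines Q = 0 with singleton communities. Network density is the mean
connection strength over within- or between-network ROI pairs, counting
thresholded-out zeros (an `include_zeros=False` switch averages surviving
edges only). Encoding-vs-retrieval comparisons use the paired t on Q and
1-df repeated-measures F tests computed as squared paired t statistics of
the within-subject contrasts (task main effect, network main effect, and
the task × network interaction that captures a disproportionate
between-network change). Group-average matrices are Fisher-z averaged and
transformed back.

## Memory-modulated gPPI

The quality modulator places each remember trial's 0–3 score on its 6 s
event, mean-centers across remember events, zeroes other time points and
convolves with the HRF. For each ordered (seed, target) pair, the target
series is regressed on run intercepts, the seed series, the psychological
regressors, and the elementwise product of the observed seed with each
psychological regressor; interactions are formed in BOLD space with no
neural-level deconvolution (under-determined at TR 1.5 s). The quality
model includes the remember-event main effect alongside the quality
modulator, conditioning the interaction on the task. In the five-feature
model all five modulators and their five interactions enter one model, so
each beta is that modulator's unique contribution. gPPI fits run on
nuisance-denoised (not task-denoised) series, so task structure remains
available to the model itself.

Network summaries average interaction betas over each ordered
seed-network → target-network cell (9 cells over PM/AT/HIPP; HIPP→HIPP is
the anterior↔posterior hippocampus coupling). Group inference is a
one-tailed one-sample t per cell (the directional hypothesis: better
memory, stronger coupling) with Benjamini–Hochberg FDR across the tested
family; the univariate activity GLM reports the quality-modulator beta per
ROI with the same group machinery.

**Specificity is evaluated against gPPI's real leakage pathways.** Three
mechanisms spread a planted seed × modulator coupling beyond its pair, all
properties of the estimator rather than implementation artifacts: the
product term is symmetric in seed and target, so the reverse-direction
pair carries the effect; a region that is both a planted target and a
planted seed chains second-order effects; and any signal that correlates
two seeds (shared evoked responses, between-network covariance) lets a
correlated seed's interaction regressor absorb part of the effect. The
specificity test therefore plants on disjoint ROI pairs with the shared
evoked response and between-network covariance switched off, treats all
four hippocampus↔cortex network cells as on-target, and requires the five
remaining cells to be individually within 3 SE of zero and to show no
pooled systematic effect within 2 SE — a per-cell 2-SE rule over five null
cells would fail by design about a quarter of the time under any seed.

## Problem sizes and tolerances

Simulation-based checks use sizes chosen to make their tolerances
comfortable: mixture recovery uses 20 replicates of n = 3000 (k within
10%, γ within 0.03 on the replicate mean); threshold closed form vs 0.01°
grid search agrees within 0.02° over 50 random (k, γ); dependency null
calibration uses 200 cohorts of 28 subjects (grand mean within 0.02,
false-positive rate 0.05 ± 0.03); the retrieval signature uses 20 cohorts
of 8 subjects on the small profile, requiring the correct direction in at
least 18 at every threshold in {0, 0.1, 0.2, 0.25, 0.3}; gPPI recovery
averages 20 full-scale single-subject runs (planted 0.5 recovered within
0.1 — the small remaining attenuation comes from the denoising projection
touching the seed). The full 28-subject pipeline runs end to end in well
under a minute on one CPU, and identical seeds reproduce the results
bundle byte for byte (content hashes recorded in the bundle manifest).

## Known limitations

- The mixture model has no misbinding component; swap errors in real data
  would inflate γ.
- Density "mean strength" counts sub-threshold pairs as zero by default;
  the surviving-edges-only alternative changes absolute levels (not the
  direction of the retrieval effect in the simulations run here).
- The condition-weighting kernel (convolved boxcar, clipped, normalized)
  follows a common toolbox convention; other kernels would change weighted
  correlations slightly.
- Emotion confidence is generated as an independent binary attribute; in
  real data confidence and accuracy correlate.
- The 2 × 2 repeated-measures F tests are exact only for 1-df contrasts,
  which is all this design needs.
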