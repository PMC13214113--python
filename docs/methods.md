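# Methods

`vigorcoh` implements a complete analysis chain for asking whether local
beta-band (β) power or seed-based β imaginary coherence (iCoh) is the more
reliable trial-level predictor of movement vigor, together with a synthetic
cohort generator that plants the statistical structure the analysis assumes.
This note documents the models, the estimators, the parameters that matter,
and the design decisions taken where more than one defensible choice existed.

## The scientific setting

Participants perform instructed Fast and Slow hand openings. Vigor is
summarized behaviorally by RT + MT (reaction time plus movement time), an
inverse proxy: larger values mean less vigorous movement. Two neural
candidate predictors are compared per trial:

- **β power** — local band power (sensor-space Morlet, or source-space
  analytic envelope), the classical movement-related desynchronization
  marker;
- **β iCoh** — the magnitude of the imaginary part of the normalized
  cross-spectrum between a seed parcel (left precentral gyrus, the motor
  cortex contralateral to the moving hand) and every other cortical parcel.
  Because purely instantaneous (zero-lag) mixing contributes only to the
  real part of the cross-spectrum, iCoh discounts volume conduction and
  residual source leakage.

The package's claim structure mirrors the study design: both metrics can
decode Fast vs Slow above chance within subjects, but only iCoh shows a
*consistent direction* (lower in Fast) across subjects, and only the
iCoh-based model coefficients correlate (negatively) with the per-subject
Slow−Fast difference in RT + MT.

## Synthetic cohort generator (`synth`)

The generator is first-class, tested code; it defines the study conditions
for every downstream test.

**Parcel signals.** Per subject, trial and β sub-band, the seed parcel
carries unit-variance band-limited Gaussian noise (FFT shaping with 1 Hz
raised-cosine edges). Each *coupled* parcel receives
`κ_cond · shift(seed, π/2) + (1−κ_cond) · independent band noise`, where the
quarter-cycle shift is applied through the analytic signal (constant π/2
across the band) so the planted interaction is invisible to zero-lag
measures but maximal for iCoh. `κ` depends on the trial condition:
`kappa_slow = 0.8`, `kappa_fast = 0.2` by default (coupling gap 0.6), with a
per-subject spread `kappa_sd = 0.08` on the gap. Band carriers are chosen
over pure sinusoids deliberately: nonzero spectral width makes the
coherence estimator non-trivial (finite-sample bias, fluctuating
single-trial estimates) while keeping Monte-Carlo expectations easy to
obtain. The default coupled set is four fronto-parietal parcels
(bilateral precuneus, right superior parietal, left postcentral); the
default simulated parcel universe is the seed plus the 21 candidate
fronto-parietal parcels — a desk-scale choice; the full 68-parcel
Desikan-Killiany universe is supported and covered by a count-contract
test.

**Power effect.** Each subject draws a Fast−Slow power offset in dB from
N(0, `power_effect_sd` = 2 dB) — random sign across subjects by design,
reproducing the empirical ~50/50 split of power-coefficient signs. The
offset is applied as a per-condition amplitude gain on all parcel signals
(a global amplitude state), so the candidate parcels carry a decodable
power effect while iCoh, being scale-invariant, is untouched. A small side
effect is accepted: the gain changes the signal-to-background ratio and
thereby the finite-sample bias of iCoh on uncoupled parcels by a small,
sign-varying amount.

**Behavioral coupling.** RT and MT condition means are drawn per subject
(across-subject sds as configured; defaults: Fast RT 300±40 ms, Slow RT
450±60 ms, Fast MT 220±25 ms, Slow MT 600±70 ms — values chosen once as
realistic for an instructed-speed hand-opening task), with additional
trial-level jitter (40/30 ms). The per-subject coherence effect (expressed
on the Fast−Slow scale, i.e. negative when Slow coupling exceeds Fast) and
the per-subject Slow−Fast RT+MT difference are tied by a Gaussian copula
targeting `rho_behavior = −0.6`: subjects with a larger planted
connectivity effect also slow down more between conditions.

**Sensors and traces.** Sensor epochs are a fixed full-rank random mixing
(32 channels on a 0.012-spaced grid montage) of the summed parcel signals
plus 1/f noise (exponent 1.0). This linear mixing replaces anatomical
source modeling: it preserves exactly known connectivity ground truth
without head geometry. Kinematic traces are rectified-cosine luminosity
bumps (five peaks: RT anchor plus four movement repetitions) and
acceleration bursts whose magnitude scales with amplitude/MT, so Fast
trials have higher mean |acc| — as observed empirically.

**What the generator does not emulate:** eye/muscle artifacts, realistic
forward fields, non-stationary baselines, electrode drift, or any
neurofeedback dynamics. Passing tests therefore certify the *statistical
machinery* (calibration, leakage safety, recovery of planted effects), not
robustness to real-world EEG artifacts.

**Determinism.** One `rng_seed` feeds a `SeedSequence` that fans out to
the mixing matrix, the cohort effect draw, and per-subject streams;
identical seeds give bit-identical cohorts.

## Feature extraction (`spectral`, `connectivity`)

- **Windows.** Seven 0.5 s analysis windows spanning [−1, +1] s around the
  go cue with 50 % overlap; three 0.5 s baseline windows, as printed, for
  dB correction ([−1.50,−1.00], [−0.75,−0.25], [−0.50,0.00] — the gap in
  that listing is reproduced as printed).
- **Sensor power.** Morlet wavelets at 1 Hz steps across the band, 7
  cycles per frequency. Per-frequency power is averaged across
  frequencies and then within windows. Averaging *complex* coefficients
  across frequencies before squaring (a literal reading of the processing
  description) cancels phase across frequencies; it is available behind
  `complex_average=True` but is not the default. dB correction:
  `10·log10(power / baseline)`, baseline pooled over conditions and its
  three windows, time-invariant across the seven analysis windows.
- **Source path.** Zero-phase (forward-backward) windowed-sinc FIR
  band-pass with 2 Hz transitions (~53 dB stop-band), anti-aliased
  decimation to 128 Hz, **per-trial symmetric orthogonalization of the
  real filtered courses**, then Hilbert analytic signal and trimming of
  the 0.2 s edge margins to [−1.5, +1.5] s. The filter→orthogonalize→
  Hilbert ordering follows the described pipeline; per-trial (rather than
  concatenated-session) fitting is the default and configurable.
- **Orthogonalization.** The closest set of mutually zero-lag-orthogonal
  time courses (least total squared change): alternate the Procrustes
  solution for an orthonormal basis with a diagonal magnitude refit
  (tolerance 1e−10, max 50 iterations). Orthogonality is exact at every
  iteration; `converged` refers to the optimality refit, and strongly
  collinear trials occasionally report `converged=False` at the iteration
  cap with orthogonality still at machine precision. Known limitation:
  the transformation cannot exactly undo a shared component in finite
  samples — it strictly *reduces* the leakage-induced bias (tested), not
  to zero.
- **iCoh.** Per trial and window: `|Im(Sxy)| / sqrt(Sxx·Syy)` with
  within-window sample averages; no across-trial averaging, because the
  decoder consumes trial-resolved tensors. The estimator's positive
  small-sample bias under independence (≈0.2 at 64 samples of 15–25 Hz
  signal) is accepted and characterized by a Monte-Carlo test; windows
  with zero power yield NaN (flagged, excluded downstream), never a
  silent 0.

## Group statistics (`group_stats`)

- **Trial screening.** |x − median| > 3·MAD per condition, unit and
  window (raw MAD, no 1.4826 constant; MAD = 0 flags any nonzero
  deviation). Cell-wise masking is the default (a trial can be excluded
  for one unit-window but not another); whole-trial removal is available.
  Masking never alters retained values.
- **Cluster test.** Per-unit paired t across subjects; units with |t|
  above the two-sided critical value (α = 0.05, df = n−1) are clustered
  by spatial adjacency (edges between positions closer than 0.02) and
  sign; cluster mass = Σt; the null is the maximum |mass| under random
  per-subject sign flips (the standard paired scheme), 1000 permutations,
  with the +1-corrected p-value for validity. The implementation is
  original and agrees exactly (t-maps, cluster memberships) with MNE's
  cluster permutation test on shared instances; MNE serves only as an
  independent oracle in tests. Windows are tested separately; there is no
  across-window cluster dimension.
- **Sign-proportion test.** Over the 21 fronto-parietal parcels: the
  proportion with a negative across-subject mean Fast−Slow difference,
  against a null built by flipping whole subjects' difference maps;
  one-sided for the Fast < Slow direction. Caveat (documented in tests):
  when the effect is perfectly parcel-common this null is bimodal and the
  test cannot reject; parcel-level heterogeneity is required for power.

## Decoding (`decoding`)

L1-regularized logistic regression (liblinear, C = 1.0 on z-scored
features — no inner hyperparameter search, as none is described), inside
stratified 5-fold CV. All preprocessing is leakage-safe: per-class 3×MAD
trial rejection and z-scoring are fit on the training fold only. For the
fold-level MAD rule a trial is dropped when **more than half** of its
feature columns flag it: per-column flag rates of ~5 % mean an "any
column" rule would empty the classes once tens of columns are stacked,
whereas a genuinely artifactual trial is extreme nearly everywhere.
Columns with MAD = 0 (majority-duplicated values, which occur under
bootstrap resampling) are skipped.

**Grouped SFS.** Candidates are spatial groups (one channel/parcel × its
7 windows). Greedy forward selection adds the best group while the mean
CV AUC improves by ≥ 0.002, at most 3 groups; at the first step the best
single group must beat 0.5 by the same margin; ties break by candidate
order. An empty selection is a flagged, valid outcome carrying the best
rejected model's score.

**Nested performance estimate.** Selecting the best of 21 candidate
groups by CV AUC inflates that same AUC (winner's curse ≈ +0.18 under the
null, measured). The reported `mean_auc` therefore comes from a nested
cross-validation — SFS re-run inside each outer training fold, scored on
the untouched outer test fold — which is chance-calibrated (group mean
ΔAUC within ±0.03 on label-permuted cohorts, an acceptance property).
The reported `selected_groups` come from SFS on the full data, as the
selection-frequency maps require.

**Bootstrap CI.** 1000 class-stratified bootstrap samples; 5-fold CV per
sample with folds grouped by original trial index, so a resampled
duplicate never sits in training and test simultaneously (plain
resample-then-split CIs are optimistically biased above chance — null
coverage 15/20 vs 20/20 with grouping, measured). 95 % percentile CI;
subjects whose CI overlaps 0.5 are excluded from the group-level
coefficient-consistency analysis.

**Sign convention.** The positive class is Fast, so a negative
standardized coefficient means the feature is lower in Fast trials. The
printed outcome coding in the source description (0 = Fast, 1 = Slow)
contradicts its own interpretation of negative coefficients; both codings
are available (`positive_class`), and the default is the one under which
"negative ⇔ lower in Fast" holds.

## Inference (`inference`)

One-sample t of subject mean AUCs vs 0.5 (reported as ΔAUC with dz and
95 % CI); two-sided one-sample t of mean coefficients vs 0 with sign
proportions (above-chance subjects only, configurable); Pearson
correlations of coefficients with Slow−Fast differences in RT+MT (and MT,
RT separately), one-sided for the expected negative direction; partial
correlation by double residualization on the power coefficients with
df = n−3; and the artifact control (trial-wise |acc| vs trial-mean β
feature, per-subject r, group t vs 0). All group tests consume
per-subject summaries only.

## Pipeline and problem sizes

`run_end_to_end` wires behavior → features → group stats → decoding →
inference, seeds every stochastic stage from one master seed via
`SeedSequence` fan-out, embeds the config hash in the report, and records
a JSON-lines log with per-stage durations and decision flags. A stage
failure produces a machine-readable failure record and a partial bundle.
The CLI (`vigorcoh simulate / run-all / behavior / features / group-stats
/ decode / infer / report`) is a thin layer over the library; exit codes
are 0 / 2 (config error) / 3 (stage failure).

Default problem sizes are the package's own desk-scale choices: 12
subjects × 60 trials per condition for the planted cohort, 32 sensors, 22
simulated parcels, 1000 bootstrap samples and 1000 permutations in the
full protocol; calibration suites use 50 label-permuted subjects at 40
trials per condition and 100-replicate permutation nulls. The behavioral,
spectral and connectivity stages are exact or near-exact recoveries by
construction; the decoding and inference stages are statistical and are
tested as calibration/recovery properties at these sizes.

## Known limitations

- **Coefficient saturation inversion.** With the default coupling gap of
  0.6 the iCoh decoders operate near separability (AUC ≈ 0.95–1.0). For
  separable data the L1-logistic weight norm needed to achieve a given
  loss *shrinks* as class separation grows, so across subjects the mean
  coefficient magnitude anti-correlates with the planted coupling gap
  (measured r ≈ −0.6). The coefficient–vigor correlation therefore only
  carries the planted (negative) sign in weakly-coupled regimes, where
  logistic coefficients grow with effect size — the regime of real
  recordings (ΔAUC ≈ 0.15). The pipeline additionally reports the
  correlation of the *measured* per-subject Fast−Slow iCoh difference
  with the vigor difference (`icoh_diff_vigor_corr`), which tracks the
  planted effect monotonically at any coupling strength.
- The generator's linear mixing sidesteps head-model realism; sensor-space
  results should not be read as spatially realistic topographies.
- The iCoh estimator's small-sample bias is condition-independent only
  when signal-to-background ratios match across conditions; the global
  power gain introduces a second-order violation (documented above).
- The bootstrap CI conditions on the full-data selection; it quantifies
  stability of the selected model, not of the selection process.
- `paired_compare` applies the Shapiro gate to the paired differences
  (the description says only "data distribution"); configurable via
  `force_test`.
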