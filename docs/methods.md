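# Methods

## The problem

Resting-state functional connectivity is normally computed from dedicated
rest scans, but many datasets contain only task runs. Several strategies
exist for recovering rest-like signal from block-design task fMRI:

* **ORIG** — treat the task run as if it were rest.
* **BLOCK** — cut out the baseline (crosshair) blocks and concatenate
  them, with conservative fixed cuts: everything within ~15 s of a task
  block's end is discarded (the hemodynamic response has not settled),
  while the first 5 s of the following task block still count as rest
  (the response has not yet risen).
* **BLOCKVAR** — the same concatenation, but the cutting windows are
  shifted by a per-subject hemodynamic delay estimated from the data, so
  each retained window is simply `[baseline onset + delay, baseline
  onset + delay + baseline duration)`. This keeps far more data than the
  fixed cuts.
* **REG** — regress HRF-convolved task regressors (one per condition,
  plus intercept) out of every voxel and keep the residuals.
* **BLOCKREG** — REG first, then BLOCKVAR-style concatenation of the
  residuals.

The package implements all five, the seed-based connectivity stage that
consumes their output, and the similarity evaluation against
continuously acquired rest — exercised end to end on synthetic
multi-subject BOLD data with known ground truth.

## Paradigms

Two block designs ship as templates (TR = 1.4 s throughout):

* **RFT** (right finger tapping): 6 × 10 s task blocks interleaved with
  7 × 10 s baselines, 130 s. The fixed cutting rule retains a single
  14 s window here (the untouched leading baseline plus the 5 s
  pre-extension; every interior baseline dies to the 15 s post-gap), so
  BLOCK falls below the 30 s minimum and is excluded for this paradigm.
* **EDT** (emotion discrimination): 4 emotion + 4 object 20 s blocks,
  alternating, interleaved with 20 s baselines plus a final baseline.
  The block list sums to 340 s. (The printed total duration of the
  original paradigm is 320 s, which is inconsistent with its own block
  list of 8 × 20 s task + 9 × 20 s baseline; the template uses the block
  list verbatim rather than silently reconciling the two.)

Volume `i` is assigned acquisition time `i·TR`; block membership uses
half-open `[onset, onset + duration)` intervals. Second-to-volume
conversion of cutting windows is conservative: the start index rounds
up, the end index rounds down (with a 1e-9 relative guard against float
division artifacts).

## Hemodynamic delay estimation

The task boxcar (union over task conditions) is delayed in whole-TR
steps `s = 0..7` (front-padded with zeros, truncated at the run end) and
Pearson-correlated with the mean time course of an occipital ROI; the
argmax is the subject's delay, ties resolving to the smaller shift. The
7-TR cap equals 9.8 s at TR 1.4 s. Shifting is applied to the *raw*
boxcar, so the estimate absorbs the subject's whole hemodynamic delay;
a response-model variant (convolving each shifted boxcar with a kernel
first) is available through the `kernel` argument but is not the
default, and the two are not equivalent.

## Connectivity

Fixed stage order: (1) nuisance regression of the six motion parameters,
white-matter and ventricular series, and optionally the global mean
(GSR on/off), always with an intercept; (2) zero-phase band-pass,
order-2 Butterworth applied forward and backward, 0.009–0.08 Hz; (3)
mean time course of a 3×3×3 voxel seed cube, voxelwise Pearson
correlation, Fisher z (`atanh`), with r clipped to ±(1 − 1e-7) so the
seed's own voxels stay finite. For concatenated inputs the filter runs
on the concatenated series, not per segment: extraction happens before
the preprocessing stages it feeds, and filtering short fragments of
~10–20 s would be meaningless against a 111 s low-frequency cutoff.
Seed coordinates in synthetic mode are network-mask centroids; the five
standard MNI seed coordinates (default mode, cuneus, thalamus,
sensorimotor, auditory) ship as a preset for real-data use, converted
through the volume affine.

## Similarity metrics and group statistics

Each method's z-map is compared with the map from the continuous rest
run trimmed to the same number of volumes (the first `k` volumes), so
that both maps rest on equal amounts of data.

* **ICC**: two-way, absolute-agreement, single-measures coefficient
  (voxels as random targets, the two maps as k = 2 raters):
  `(MSR − MSE) / (MSR + MSE + (2/n)(MSC − MSE))`. This form penalises
  mean offsets between maps; the offset-invariant consistency form is
  selectable (`form="consistency"`). The offset sensitivity is why ICC
  and R² can disagree.
* **Dice**: overlap of the suprathreshold voxel sets at z ≥ 0.3
  (positive tail only); returns 0, flagged, when both sets are empty.
  The threshold is applied to raw z values; whether maps should be
  variance-normalised first is an open question inherited from the
  measure's usage, and no normalisation is applied.
* **R²**: squared Pearson correlation across masked voxels.

For group statistics, correlation-type metrics are variance-stabilised
(`atanh` of ICC; `atanh` of the signed map correlation for R²; Dice
untransformed), then a one-way repeated-measures ANOVA across the
method factor (statsmodels `AnovaRM`; subjects are the repeated factor)
and Welch two-sample t-tests of each method against the test-retest
condition are computed, two-sided and uncorrected. This is a deliberate
simplification of a full mixed factorial model; a Bonferroni option
exists but defaults off. The test-retest ceiling is realised as two
independently simulated rest runs per subject.

## The synthetic generator

A 20×20×10 voxel grid (4 000 voxels, all brain) carries six rectangular
parcels: five scored networks (default mode, cuneus, thalamus,
sensorimotor, auditory) and an "occipital" parcel that hosts the task
activation and the delay-estimation ROI. Components, per run:

* **Network latents** — per parcel, Gaussian white noise band-passed to
  0.009–0.08 Hz and rescaled to unit variance, shared by the parcel's
  voxels through per-voxel loadings U(0.8, 1.2). This matches the
  analysis band so connectivity is identifiable by construction.
* **Task response** (task runs only) — the condition boxcars delayed by
  the subject's true hemodynamic delay and convolved with a *zero-lag*
  Gaussian dispersion kernel (sd 2 s). Modelling delay and dispersion
  separately makes `true_delay` the subject's total hemodynamic delay,
  which is precisely the quantity the raw-boxcar shift search measures;
  convolving with the canonical double-gamma instead (available as
  `task_response="hrf"`) adds that kernel's own ~4-TR lag on top of the
  recorded delay, making the recorded ground truth unrecoverable by the
  method under test and pushing 5-TR delays past the 7-TR cap. True
  delays are drawn uniformly on {2..5} TRs (2.8–7.0 s, mean 4.9 s),
  bracketing typical whole-response delays below the cap. The response
  has amplitude 2.0 (in units of the unit-sd latents) on the activated
  parcels — occipital and sensorimotor, since block paradigms with
  visual stimulation and motor responses activate both — reflecting
  that primary visual/motor block responses are typically several times
  stronger than spontaneous fluctuations; a weak whole-brain response
  rides on a fixed per-voxel gain field (sd 0.3 of the focal amplitude),
  the way real evoked activity is focal plus distributed.
* **Task-state modulation** — ongoing network fluctuations are
  fractionally suppressed while the task is on (peak suppression 0.3,
  following the evoked profile), emulating task-related variability
  quenching. Being multiplicative, this component cannot be removed by
  linear task regression, which is what keeps even the best extraction
  method strictly below the test-retest ceiling.
* **Nuisance** — a global fluctuation loading on every voxel
  (N(0.6, 0.1)), six random-walk motion series leaking into a random
  20 % of voxels, and white-matter/CSF components with small loadings.
  The returned confounds are the generating motion/WM/CSF series plus
  the measured global mean of the simulated data.
* **Noise** — white Gaussian, sd 1.0.

Every draw derives from the master seed through named substreams
(subject, run label, component), so runs are bit-reproducible, and with
`task_modulation=0` a task run equals its amplitude-zero twin plus
exactly the evoked component.

**What the simulation does not model**: scanner drift, spikes,
physiological aliasing, spatial autocorrelation/smoothing, EPI
distortion, anatomy. Passing tests therefore demonstrate that the
pipeline's math recovers known statistical structure and reproduces the
qualitative method ordering under these idealised conditions — not that
it would do so at any particular effect size in real 7 T data, whose
printed similarity values are not reproduction targets here.

## Numerical choices

* Fisher-z clip constant 1e-7 (z ≈ 8.1 at r = 1).
* Band-pass: `sosfiltfilt`, pad length capped at n − 1; inputs shorter
  than 12 volumes are rejected.
* OLS via QR with column pivoting for rank diagnosis (collinear columns
  are named in the error) and `lstsq` for the fit; an intercept is
  always included.
* Shift-search ties break toward the smaller shift; shifts that push
  every event off the run score −inf.
* Degenerate group statistics (all conditions identical) short-circuit
  to F = 0 / t = 0 rather than propagating 0/0.
* Default experiment scale: 8 subjects, 20×20×10 grid, 360 s rest runs.
  These sizes make the full comparison run in well under a minute while
  leaving every effect of interest detectable.

## Known limitations

* BLOCKREG reuses the delay-adjusted (BLOCKVAR) windows by default;
  fixed windows are a config option (`blockreg_intervals="fixed"`), and
  the two variants are not interchangeable on short paradigms.
* The 5 s pre-extension of the fixed cutting rule is read as extending
  into the following task block; the alternative reading (only the head
  of the baseline itself) is available as
  `pre_extension_mode="baseline_head"`. Both retain < 30 s on the RFT
  grid.
* Real-data mode expects user-supplied tissue masks and confound tables;
  no spatial preprocessing, segmentation, scrubbing or ICA denoising is
  provided or planned.
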