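# Methods

This note documents the models, conventions and numerical choices behind
qppdyn, and what the synthetic-data tests do and do not establish.

## Synthetic scans

A synthetic scan emulates a 10-minute resting-state acquisition at
TR = 1.25 s (480 frames) over 30 parcellated regions. Each region
timecourse is the sum of three components:

1. **Global fluctuation.** One shared trace `g(t)` — Gaussian noise
   band-passed to 0.01–0.1 Hz and z-scored — enters region `r` as
   `gs_amplitude · gs_weights[r] · g(t)`. Default weights are 0.5, raised
   to 1.0 on the designated cingulate/midline set (regions 0–2), so the
   cingulate couples to the global signal at twice the strength of other
   regions.
2. **Quasi-periodic pattern.** A window of `W = 8` frames (10 s) carrying
   one raised-cosine cycle is inserted at quasi-regular onsets: a renewal
   process starting at frame 0 with intervals
   `mean_event_interval_frames ± interval_jitter_frames` (uniform,
   rounded to integer frames, clipped at `W` so events never overlap).
   The first third of regions carries the waveform with positive sign
   (group A, containing the cingulate set), the second third carries its
   negation (group B), and the rest are uninvolved — the anticorrelated
   two-network structure QPP detection assumes. Involved regions are
   given small integer phase lags cycling 0, 1, 2 frames; the lags are a
   fixed function of region index rather than random so that all scans of
   a cohort share one coherent pattern, which is what group-concatenated
   detection presumes.
3. **Noise.** Gaussian noise, band-passed to the analysis band per region
   (and per voxel at voxel level), rescaled to `noise_sd`. The
   noise-shaping filter is a zero-phase Butterworth of order 5 per pass:
   this keeps more than 95% of the noise power inside the nominal band,
   which is the operational meaning of "band-limited" here.

Default amplitudes (`gs_amplitude = 1`, `qpp_amplitude = 1`,
`noise_sd = 0.5`) are order-of-magnitude choices: the source experiments
report no empirical event rate or amplitude, so the defaults are set
where all three components are comparably visible and detection is
neither trivial nor hopeless. They are explicitly not calibrated to any
reported effect size. The default event spacing (24 ± 4 frames ≈ 30 s)
places ~20 events per scan, in the range of quasi-periodic recurrence
described for rodent BOLD patterns.

The voxel stage fills contiguous blocks of a 10 × 6 × 5 grid with each
region's timecourse plus independent white voxel noise; no anatomical
realism is attempted (recovery tests do not need it). Ground truth
(event onsets, global trace, planted template, group labels) is returned
exactly as planted.

**What passing tests show — and don't.** Recovery tests prove the
algorithms find exactly the structure they assume, with known truth.
Real data adds hemodynamic convolution, physiological confounds, motion,
non-stationary arousal states and anatomy, none of which are simulated;
green tests here say nothing about robustness to those.

## Preprocessing

Order fixed as: nuisance regression → normalization → band-pass →
spatial smoothing → ROI extraction. Nuisance regressors are a constant,
linear and quadratic trend on a [-1, 1] time axis plus optional motion
traces (zeros for synthetic data; the slot exists for real-data reuse).
Band-pass is a zero-phase forward–backward Butterworth, order 2 per pass
by default — zero phase so that event timing used by the
sliding-template detector is not shifted; family and order are exposed.
Normalization uses the sample (n−1) SD throughout the package.
Spatial smoothing is mask-normalized Gaussian convolution
(σ = FWHM/(2√(2 ln 2)) in voxel units), so background voxels never bleed
into the brain. ROI extraction is label-wise voxel averaging in ascending
label order.

A characterization test records that trend regression and band-pass do
*not* numerically commute on band-limited data (relative difference
~10%, correlation ≈ 0.98 between the two orders): zero-phase filtering
of fitted polynomial trends leaves edge transients. The pipeline
therefore fixes the order rather than treating the two as interchangeable.

## Global-signal arm

The GS is the unweighted mean over in-brain timecourses (mask voxels at
voxel level, region means at region level), z-scored — the z-scoring is
cosmetic for Pearson correlation but retained as the conventional
definition. Concatenated-group maps concatenate scans and their per-scan
z-scored GS in time. The ANOVA consumes *per-scan* region correlations
(one value per scan after cingulate averaging): this is what makes the
error degrees of freedom equal scans − cells (66 for the default
design). Zero-variance timecourses get r = 0 and are flagged; a
zero-variance mean trace (perfectly cancelling regions) is a degenerate
input and raises.

## QPP detection

The detector follows the iterative sliding-template scheme: seed the
template with an observed window, correlate, average supra-threshold
windows, repeat to convergence (template-to-template correlation above
0.9999 on two consecutive iterations). Choices the scheme leaves open:

- **Threshold schedule** 0.1 for the first 3 iterations, then 0.2 —
  the permissive early threshold follows the robust variant of the
  algorithm family; only the final 0.2 defines events.
- **Peak picking.** "Windows above threshold" are taken at local STC
  maxima with minimum separation `W` (greedy by descending STC, earliest
  frame on ties), so overlapping windows are never double-counted.
- **Starts.** 20 seed windows drawn without replacement from the valid
  window starts using `start_seed`; among converged starts the one with
  the largest sum of supra-threshold STC peaks wins, earliest start on
  ties.
- **Phase alignment.** The iteration's fixed points are indexed by an
  arbitrary time offset of the pattern inside its window (a template
  seeded k frames off a planted event converges to the same pattern
  shifted by k). After selecting the best start, the detected event
  alignment is shifted by the offset (within ±(W−1)) that maximizes the
  energy of the averaged template — coherent structure adds, noise
  cancels — which centers the pattern in the window and makes reported
  onsets comparable across runs. Ties prefer the smaller shift.
- **Concatenation.** Group-level detection runs on the temporal
  concatenation of a group's scans; windows spanning scan boundaries are
  masked and never averaged, counted, or reported as events.
- **GSR.** By default the global signal (plus intercept) is regressed
  from each scan before detection. Because the GS is the unweighted mean
  of the very regions being residualized, the residuals' mean trace is
  identically zero and each residual is exactly orthogonal to the
  removed GS — the orthogonality guarantee tests verify both facts.

Event-rate summaries report both the signed (> 0.2) and absolute
(|STC| > 0.2) conventions, since both appear in practice; the pipeline's
ANOVA uses the signed fraction. The cingulate involvement metric
averages the cingulate-mean W-frame segments over a scan's detected
events and reports max − min of that waveform; scans with zero events
yield NaN and are dropped (with a logged count) from the ANOVA.

`W` is configurable and recorded in every output; the default 8 frames
(10 s) matches rodent QPP durations reported in the literature.

## CPCA arm

Analytic signals are computed per scan (Hilbert transform never crosses
concatenation boundaries) on z-scored timecourses; the real part of the
output equals the z-scored input exactly. The complex time × region
matrix of a group is decomposed once by SVD without re-centering (the
rows are zero-mean by construction): `data ≈ scores · loadingsᴴ` with
unit-norm loadings, eigenvalue_k = σ_k²/T. "Variance explained at a
timepoint" is operationalized as the squared score magnitude
|s_{t,k}|² — each component's share of reconstructed power at that frame;
the definition is a package choice, stated here because no standard
formula exists. Incidence is computed per scan from that scan's score
rows; the first and last 5 frames of each scan are excluded
(configurable) to avoid Hilbert edge artifacts. Exact dominance ties go
to the lower component and are counted. Requests for more components
than the numerical rank are truncated with a warning, and incidence
clamps to the available components.

Fitting is per group by default (concatenate a group's analytic
matrices, decompose once, read incidence per scan) and can be done per
scan by passing single-scan inputs.

## Statistics

Type III sums of squares with sum-to-zero factor coding is the default
for the unbalanced two-way design with interaction (Type II available);
fitting is ordinary least squares via statsmodels. Repeated scans from
one animal are treated as independent units — this mirrors the design
the cohort layout implies (error df = scans − cells) and is a
faithfulness choice, not a statistical endorsement. Undefined metric
values are dropped with a logged count; an empty design cell is an
error naming the cell. Zero residual variance yields flagged sentinel
F values (0 for a zero effect sum of squares, +inf otherwise), never
silent output. Tukey HSD uses the studentized-range distribution
(scipy); with two groups it reduces to the pooled two-sided t-test,
which the tests verify to 1e-6.

## Pipeline

`run_pipeline` executes simulate/load → preprocess → the three arms →
ANOVAs. All tabular artifacts are TSV with a fixed float format
(`%.12g`), so identical configs and seeds give byte-identical tables;
volumes are NIfTI-1 with the TR in the header. At the artifact sizes
this pipeline produces (templates, loadings, STC traces), TSV doubles as
the array container — everything is diffable; no binary container is
used. Stages record a config hash in `state.json` and are skipped on
rerun when the hash matches. If one arm fails the others complete; the
failure lands in the manifest and the run exits nonzero.

## Problem sizes in the calibration suites

The statistical calibration tests use 1000 null cohorts of 24 scans
(3 per cell) for ANOVA p-value uniformity and 500 three-group
simulations (n = 10 each) for Tukey family-wise error; recovery curves
use 20 seeds per condition. These sizes give the uniformity and
binomial checks adequate resolution while keeping the default test run
short; calibration of the tests themselves does not depend on the cell
counts, and the design-degrees-of-freedom checks always use the full
74-scan layout.

## Known limitations

- No hemodynamic response model, physiological noise, motion, or
  anatomical realism in the generator; group differences planted via
  parameter overrides are additive and stationary.
- The QPP detector's phase alignment assumes a single dominant recurring
  pattern; with several competing patterns the energy criterion centers
  whichever the iteration converged to.
- CPCA incidence compares only the first K (default 3) components;
  structure outside them is invisible to the statistic.
- Treating repeated scans per animal as independent inflates the error
  degrees of freedom relative to a mixed model.
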