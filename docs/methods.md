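# Methods

`synei` quantifies the balance between excitatory and inhibitory synapses
(the E/I ratio) from five independent kinds of measurement, and ships a
synthetic-cohort generator that plants known effects so every stage can be
validated by parameter recovery.  This note documents the models, the
parameters that matter, the numerical choices, and the limits of what the
synthetic validation shows.

## 1. Anatomical E/I: 3D punctum detection (`synei.fdt`)

### Model

The input is a two-channel 3D epifluorescence stack (8-bit, default voxel
0.1 × 0.1 × 0.2 µm) in which postsynaptic densities appear as synapse-sized
immunolabeled puncta: PSD-95 marks excitatory PSDs, gephyrin inhibitory
ones.  The channels are analyzed independently.

**Background normalization.** The staining background field is estimated per
channel by a wide Gaussian filter (`background_sigma`, default 2 µm —
several punctum diameters, so puncta barely perturb the estimate) and every
voxel is rescaled so the local background maps to
`background_target_fraction × 255` (default 0.30 → 76.5).  This flattens
staining gradients; an all-zero channel passes through unchanged.  A
consequence worth knowing: after this per-voxel normalization, no object
brighter than its surroundings can measure below the normalized background
level, so at the default target the low (<75) intensity band can only be
populated by structures dimmer than ~0.26 of full scale.

**Multi-threshold detection.** The normalized channel is binarized at every
threshold of a fixed-interval series (default 20→180, step 10).  At each
threshold: one erosion + one dilation with a 1-voxel ball (removes
single-voxel noise and severs thin bridges), 3D connected-component
labeling (26-neighborhood), and per-component measurement.  Components are
filtered by

* volume inside `[min_volume, max_volume]` = [0.03, 1.0] µm³ — the size
  window of synaptic PSDs; and
* 3D eccentricity ≤ 0.95, defined from the principal axes of the
  second-moment ellipsoid as `sqrt(1 − λ_min/λ_max)`, with each voxel's own
  box moment added so single-plane objects are not degenerate.

Components **larger** than `max_volume` but smaller than
`background_component_volume` (50 µm³) are lipofuscin-scale deposits: their
entire footprint is excluded at every threshold, so a bright blob core can
never masquerade as a punctum.  Components larger still are the percolating
sub-background-threshold field (thresholds below the normalized background
select nearly the whole volume) and are skipped without masking.

**Merging across thresholds.** Thresholds are scanned in ascending order.
Instances at different thresholds whose voxel sets overlap are one punctum;
the highest-threshold instance is its geometric representative (volume,
eccentricity, centroid, accepting threshold).  Re-running a duplicated
threshold is exactly idempotent.

**Per-punctum intensity.** Measured over the punctum's full reconstructed
footprint (union of accepted voxel sets).  The default (`intensity_mode =
"max"`) is a robust peak: the maximum of the 3×3×3 locally averaged image
within the footprint.  We use the peak rather than the footprint mean
because the mean is dominated by however much faint periphery the lowest
threshold happened to capture (empirically it tracks planted amplitude with
a slope of only ~0.18 and compresses the intensity distribution ~5-fold),
whereas the local-average peak tracks amplitude at slope ~0.5 with small
residual and is insensitive to single-voxel noise.  `"mean"` and
`"integrated"` (sum × voxel volume) remain available.

### Derived statistics

Per channel, punctum intensities are binned over the 20–180 scale (bin
width 5, aligned with the 75/90 band edges) and expressed as percent of all
labeled puncta.  From the distribution: low/mid/high band proportions
(<75, 75–90, >90; they sum to 100%), the high/low ratio (flagged `inf`
when the low band is empty), and the distribution peak (maximum bin
height; ties go to the lower-intensity bin).  The **anatomical E/I ratio**
is the PSD-95 peak height divided by the gephyrin peak height; a broader
(more heterogeneous) gephyrin intensity distribution lowers its peak and
raises the ratio.  When a subject is imaged as several stacks, puncta are
pooled into one distribution per channel before taking peaks
(`subject_anatomical_ei`) — the max-bin estimator is upward-biased at small
counts, and pooling keeps that bias (and its differential effect on broad
vs narrow distributions) small.

## 2. Cellular E/I: ISH cell counting (`synei.ish`)

Label-dark 2D fields are blurred (Gaussian, σ = 3 px) to remove small
artifacts, thresholded automatically with the Yen entropic criterion
(`skimage.filters.threshold_yen`; a constant image raises), and segmented
into 8-connected components.  Objects with area **strictly greater** than
10 px are counted; densities are reported per 10,000 µm².  The cellular E/I
ratio is vGluT1+ density / GAT1+ density.  Subjects are screened for
outliers by Mahalanobis distance of the (vGluT1, GAT1) density pair from
the sample mean (sample covariance, ddof 1); the default upper control
limit is 2.56 on the distance scale (a `squared` switch is provided, since
which scale the convention refers to is ambiguous).  Automatic thresholding
is only meaningful on fields that contain label; a field with no cells at
all is degenerate (the threshold then splits noise), which is a known
limitation of the procedure, not of this implementation.

## 3. Electrophysiological E/I: voltage-clamp traces (`synei.ephys`)

Oocytes carrying microtransplanted human synaptic membranes are clamped at
−80 mV; GABA and kainate are perfused onto the same oocyte.  Per trace:

* baseline = median of the ≥0.5 s pre-application segment;
* a linear trend fitted to that segment is extrapolated and subtracted, so
  slow drift does not bias the response;
* the residual is smoothed with a 0.1 s boxcar and the amplitude is its
  extremum within [t_on, t_off + 5 s].  Smoothing matters: the raw
  extremum of a noisy trace is biased upward by ~3 noise SDs, which alone
  would exceed the 2% bias budget at 1% noise;
* noise is the MAD-scaled SD of the detrended baseline; SNR = |amplitude| / noise.

QC requires SNR ≥ 3, visible activation (excursion beyond 3× noise inside
the window), deactivation (decay back toward baseline), and repeatability —
repeat applications of one agonist must agree within a population CV of
0.3 (the repeatability tolerance is this package's operationalization of
"consistently activated").  Inward currents are negative; ratios use
magnitudes.  The per-oocyte E/I is |kainate|/|GABA|; the subject-level E/I
is the arithmetic mean over at least three QC-passing oocytes (triplicate
rule), and the subject is the unit for group statistics.
`potentiation_index` supports modulator assays (post/pre amplitude).

## 4. Synaptosome size classes (`synei.cytometry`)

Event tables carry diameter-calibrated particles.  The analysis gate keeps
1–3 µm (boundaries inclusive), optionally capped at a fixed number of
analyzed events.  Size classes partition the gate around a calibration
bin at 2 µm: medium is |∅ − 2| ≤ δ (δ = 0.1 µm, configurable — flow gates
are bead-anchored intervals, and a measure-zero "exactly 2 µm" class would
be empty), small is below, large above.  The large/small proportion ratio
summarizes the distribution; `percent_reduction` expresses group mean
count loss relative to control.

## 5. Transcriptional E/I: FPKM screening (`synei.transcriptome`)

The transcriptional E/I ratio is the raw FPKM ratio DLG4/GPHN per subject —
deliberately untransformed.  Around it:

* `filter_expressed`: keep genes with FPKM strictly > 2 in ≥ 3 subjects;
* `response_screen`: per-gene simple linear regression of expression on the
  ratio (vectorized Pearson r, two-sided t test with n−2 df); positive-slope
  genes below a **required** raw-p cutoff are selected, with
  Benjamini–Hochberg FDR reported alongside.  Both 0.001 and 0.01 are
  defensible cutoffs; the choice is the caller's, never silent;
* `diagnosis_log2fc`: slope of log2(FPKM + 0.1) on a 0/1 diagnosis code,
  which for a binary regressor equals the difference of group means of
  log2(FPKM + 0.1);
* `module_fold_changes`: applies the fold change over user-supplied
  excitatory/inhibitory gene lists (the lists are inputs, not computed) and
  reports genes missing from the filtered matrix explicitly.

## 6. Statistics layer (`synei.stats`)

All modalities reduce to per-subject values entering one decision pipeline:
Bartlett's test at α = 0.05 gates variance homogeneity (the gate level is
our choice; the gating itself is the procedure).  Homogeneous → one-way
ANOVA + two-sided Dunnett versus control (scipy).  Heterogeneous → Welch
ANOVA (pingouin; Kruskal–Wallis available by configuration) + two-sided
Dunn rank tests versus control with Bonferroni adjustment over the
comparisons (the adjustment choice is ours; none is named by convention).
Reported df are always the design df (k−1, N−k); the Welch-corrected
denominator df travels in the decision trail.  Degenerate all-identical
input returns F = 0, p = 1 rather than NaN.  The group × intensity-bin
interaction of binned distributions uses a two-way mixed
(repeated-measures) ANOVA (pingouin `mixed_anova`); when the interaction
carries no variance the same F = 0, p = 1 convention applies.
`wilcoxon_ranksum` uses the exact null for small tie-free samples and
otherwise the tie-corrected normal approximation *without* continuity
correction, so identical samples give p = 1 exactly.  Pearson correlations
report R² alongside.

## 7. Synthetic cohorts (`synei.synthetic`) and what they do (not) show

All generators draw from one root `SeedSequence`, spawned per
object/subject in a fixed order: identical (spec, seed) → byte-identical
output.

**FDT scenes.** Puncta are isotropic Gaussians (σ = radius/2, truncated at
the radius, i.e. 2σ) at non-overlapping centers (distance > sum of radii);
lipofuscin-like blobs are larger than the size window and co-located in
both channels (autofluorescence).  Defaults: 120 puncta/channel in a
16 × 16 × 2.4 µm (160 × 160 × 12 voxel) field ≈ 0.2 puncta/µm³ per channel
— a few-fold sparser than real cortical PSD density (~0.6/µm³), so the
hard-sphere non-overlap placement rule stays satisfiable — background 100,
noise SD 6, blob radius 0.8–1.1 µm.  Radii default to 0.40–0.46 µm: the per-punctum peak-intensity
slope depends on punctum size (a fixed smoothing kernel captures a larger
fraction of a broader profile), so a wide size dispersion acts as intensity
noise; a tight, realistic PSD size distribution keeps the planted intensity
contrast recoverable.  The intensity model default (mode 170, spread 16 on
the raw scale) keeps the ±3σ population above the detection floor (puncta
dimmer than ~16 counts over background do not survive thresholding +
morphology) and below the 8-bit ceiling — the synthetic analogue of
correct exposure.  The planted anatomical peak ratio is the ratio of
channel intensity spreads (peak height of a binned unimodal distribution
scales as 1/spread).

The truncation choice (2σ, not 3σ) is deliberate: with a 3σ-truncated
profile of the same radius, the above-threshold cores are so small that
the 1-voxel opening at a 0.2 µm z-step erases them, and nothing in the
synapse volume window is detectable.

**Known gaps between synthetic and real data.** No optical PSF or
deconvolution artifacts; no spatially correlated noise; no layer structure
within a stack (layers are separate stacks); lipofuscin morphology is a
free knob, not calibrated to real deposits; ISH fields have flat
background and disk-shaped cells; FPKM matrices are log-normal without
count noise or gene–gene correlation beyond the planted postsynaptic
block.  Passing recovery tests therefore shows the pipelines are
*self-consistent and unbiased under their stated assumptions*, not that
they are robust to every pathology of real tissue.

**Recovery experiments** (`synei.pipelines`) at the problem sizes used in
the test suite:

* anatomical: planted peak-ratio factor 1.4, 5 subjects/group, 3 stacks ×
  120 puncta/channel per subject (real-tissue stacks carry 25–30k puncta
  each; this is a deliberate desk-scale reduction), 20 seeds.  The
  recovered group ratio carries a known mild attenuation (~3–5%) from the
  residual intensity-measurement noise and the small-sample bias of the
  max-bin peak estimator; both are documented above and bounded well
  inside the ±10% recovery criterion.
* electrophysiology: planted E/I 0.5, noise 1% of amplitude; the mean
  subject E/I is unbiased within 2%.
* transcriptome: GPHN ×0.6 at n = 8 vs 12, log-normal σ 0.25; Wilcoxon
  p < 0.05 in ≥80% of 100 seeds.

**Planted-shift band test.** Because the default normalization floor sits
above the low band (Section 1), the leftward-shift monotonicity check runs
the detector at `background_target_fraction = 0.22`, which moves the floor
to ~65 so the low band is reachable; the planted shift then monotonically
lowers the measured high/low ratio.  This is an analysis configuration for
that scenario, not a change to any default.

## 8. Numerical conventions

* Ratios with empty denominators are flagged (`inf`; `nan` when both sides
  are empty) rather than raised, except where a precondition is explicit
  (GPHN FPKM > 0, GAT1 density > 0, distribution peaks > 0).
* Histogram bands must align with bin edges; misalignment raises instead of
  interpolating.
* Eccentricity of a single-voxel object is computed with the voxel's own
  box moment (anisotropy of the voxel itself, ~0.87 at 0.1/0.2 µm spacing,
  below the 0.95 cut).
* Seeds derived inside the acceptance script stay below 2³¹.
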