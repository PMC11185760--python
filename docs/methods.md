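# Methods

This note documents the models, conventions and design choices behind
`octocage`, in the order the pipeline runs.

## Assay timeline

The assay is a 22-h session discretized into 132 ten-minute periods
(1-based). Phases are day (6 h, white background), night (6 h, red
background), night with stimuli (6 h), and day (4 h). Three stimuli —
a rotating moth and two sets of moving lines — onset at elapsed 12, 14
and 16 h, i.e. at the start of periods 73, 85 and 97, each 2 h apart.
Hour labels are 1-based ("hour 13" denotes the window starting at
12 h elapsed); this is the only reading under which the stimulus
periods are exactly 12 periods apart. `AssaySchedule.scaled(s)`
shrinks every duration by `s` while keeping the 132-period grid, so
period arithmetic is scale-invariant; scaled schedules are used
wherever a test does not need 79,200 frames. The frame interval must
divide the period length.

## Tracking

Frames are segmented on the red channel, where the dark mouse contrasts
with both the white day background and the red night background. The
threshold is fixed (default 90 of 255) with a per-frame Otsu fallback
(`threshold=None`) for footage with drifting illumination; the largest
connected component above 40 px² inside the cage bounds is the mouse.
Elongation is the ratio of the blob's major to minor axis. The head is
the blob-boundary pixel farthest along the motion direction (the
blob's major axis, sign-continuous with previous travel, while
stationary). Runs of missing detections of at least `hut_dwell` frames
(default 2) are attributed to the hut; on clean synthetic footage
`hut_dwell=1` recovers the ground truth exactly.

SAP (stretch-attend posture) is operationalized as elongation ≥ 2.0
with centroid displacement ≤ 2 px/s. The thresholds are configuration
parameters: SAP has no universally fixed quantitative definition, so
the defaults are documented conventions, not measurements.

Quadrants partition the cage; boundary points resolve to the quadrant
with the nearest centroid. Occupancy percentages are over frames with
known position, and in-hut time counts as home-quadrant time (the hut
sits in the home quadrant); frames missing for any other reason are
excluded from every percentage denominator.

Coordinates are pixels, origin top-left, x rightward, y downward;
time 0 is assay start. Whether quadrant time should use the centroid
or the head is genuinely ambiguous; the centroid is the default and
both are computed.

## Pose-derived parameters

Pose tables carry 8 keypoints (nose, ears, head, neck, center, hip,
tail base) with per-sample likelihoods. Samples with likelihood
strictly below 0.90 are invalid — the comparison is strict, a sample at
exactly 0.90 is kept — and invalid samples are excluded from all
statistics; coordinates are never interpolated or smoothed.

Speed is the Euclidean displacement between consecutive valid center
samples divided by the time gap (px/s), undefined across invalid gaps.
Speed classes partition speeds at thresholds (2, 10, 40, 80) px/s into
still/scoot/move/burst/escape; "% movement" counts everything above
still. These thresholds are conventions carried from prior use of this
assay family and are exposed in configuration; the simulator's state
speeds (0, 6, 25, 60, 110 px/s) sit strictly inside the bins so class
recovery is exact on noiseless tracks.

Acclimation is the value in the last 10-min bin of hour 1 minus the
first bin (percentage points; negative = settling down) — the simplest
monotone summary of settling, in preference to a fitted slope.
Habituation is the absolute % (or mean speed) in the 10-min window
after a stimulus onset, not baseline-relative, because group
comparisons use these levels directly. Speed-family parameters are
reported in px/s (px per 1-s frame at full scale).

Location parameters: Home is % of valid frames with the center inside
the hut polygon; Peek additionally requires the nose outside; Window is
% within 40 px of the window center. Wall and Food are the mean over
frames of the minimum distance to any wall segment / food point — the
mean, not the minimum over time, is the default reading of "closest
distance" as a time-aggregated parameter; `_min` variants are also
emitted. Window Partner is conditional on the focal mouse's window
time (a `_total` variant normalized by all valid time is emitted too).

Empty denominators yield NaN, never 0, and NaN propagates to any
derived difference; downstream statistics drop NaN pairwise.

The two parameter families deliberately share raw ids (M1, MD, ...);
profile keys are namespaced `trk:`/`pose:`, and the CSV writer can emit
the published column layout (d*, f*, pose block, tracking block).

## Syllable summaries

A bout is a maximal run of one label. Frequency is the share of bout
onsets (usage), keeping frequency independent of duration; frame-share
is also computed. The transition matrix is the bout-level chain, which
by construction has no self-transitions; rows of never-left syllables
are NaN and flagged. Summaries are computed over the whole assay or
any 10-min period. The 29-id alphabet is fixed and sparse (ids 0–63
with gaps), mirroring how unsupervised segmentation software numbers
and prunes candidate states; no model fitting happens here — label
sequences are inputs.

## Gait

A compliant run is one-directional with under 10 s between first and
last initial contact; non-compliant runs are excluded, and an animal
needs ≥ 3 compliant runs (configurable) to enter the per-animal table.
Stand is mean contact duration; step cycle the mean gap between
consecutive initial contacts of a paw; swing their difference; cadence
is steps per duration, where duration spans first-to-last initial
contact (a run-bounds variant exists). Support percentages partition
the run window by the exact set of paws in contact, with two-paw sets
classed girdle (RF-LF, RH-LH), lateral (RF-RH, LF-LH) or diagonal
(RF-LH, LF-RH).

NSSP is computed over sliding 4-step windows: a window is normal when
it matches one of the six canonical patterns (cruciate Ca/Cb, alternate
Aa/Ab, rotary Ra/Rb) under cyclic continuation. Step-window share is
used rather than a literal time weighting — the standard regularity
treatment — and a duration-weighted variant is emitted alongside. The
six patterns cover every cyclic order of the four paws, so a window is
normal exactly when it uses each paw once; the explicit pattern table
is kept for transparency. The body axis for the paw-angle parameter is
the local direction of travel (neighbouring same-paw contacts, falling
back to the overall run direction), since footfall logs carry no spine
landmarks; angles are signed acute, in (−90°, 90°].

## Profiles, PCA and clustering

A profile is the named 125-vector: 15 tracking + 52 pose parameters,
29 syllable frequencies, 29 syllable durations. Undefined entries
(typically durations of unexpressed syllables) are imputed by the
group mean and flagged. Group profiles are per-parameter means over a
group's mice.

The pipeline z-scores parameters (sample SD), computes PCA, sign-fixes
each component so its largest-magnitude loading is positive, and
weights each parameter by |PC1 loading| / max |PC1 loading|. Absolute
values are used because loading signs are arbitrary; raw and squared
variants are options. Order of operations is z-score → weight →
Euclidean distance → Ward (Ward.D2 on squared increments, stated
because R dialects differ). With unit weights the procedure reduces
exactly to plain Ward on z-scores (tested). Zero-variance parameters
are dropped from PCA with a warning and receive weight 0. PCA and
clustering default to group-level profiles — the unit at which
dendrograms are reported — with per-mouse mode used for the screening
and recovery checks. Whether standardization should precede or follow
weight computation is not externally fixed; standardize-first is the
default and both orders are reachable through the estimator options.

## Statistics

The screening layer compares untreated model mice to controls per
parameter and per age timepoint with the unpaired two-sample Wilcoxon
(Mann–Whitney) rank-sum test, two-sided: exact null for small tie-free
samples, tie-corrected normal approximation otherwise. p-values are
compared to α = 0.05 raw — the screen counts "parameters significant in
≥ 1 timepoint" without multiplicity correction, matching the screening
convention; Benjamini–Hochberg is available but off by default.
Direction is the median difference (model − control). Kruskal–Wallis
(tie-corrected) with Dunn's two-sided z-tests on mean ranks serves the
syllable statistics; Dunn's test is implemented directly (tie-corrected
mean-rank formula, unadjusted two-sided p) and verified against hand
computation. Gait uses two-way ANOVA (type-II sums of squares) with
Tukey HSD on the crossed cell means run only when the interaction is
significant, and recorded as skipped otherwise.

## What the simulator emulates — and what it does not

The generators plant, per group, a behavioral state: movement fractions
by phase, an hour-1 acclimation ramp, hut and window occupancy, a peek
fraction, post-stimulus activity, SAP fraction, partner co-occurrence,
motion-state mix, and a syllable repertoire-narrowing bias. Occupancy
quantities are scheduled per 10-min period with exact frame counts
(contiguous hut/window visits), so planted fractions are recoverable by
counting; roaming avoids the hut footprint and window zone so those
occupancies stay scheduled quantities. Group effects follow the study
design — activity falls and hut time rises with age; the disease
genotype further lowers activity, habituation and sociability and
narrows the syllable repertoire (most strongly at the old timepoint);
treatments leave a residual fraction of the genotype effect (0.10
cyclosporine, 0.45 nebivolol, 0.55 cabozantinib). Where the study
conditions fix no value (baseline fractions, effect magnitudes,
per-mouse SD 0.02), values were chosen once as field-plausible and are
documented in `simulate.py`.

Deliberately not emulated: video-codec artifacts, photorealistic
appearance (the mouse is an ellipse, the hut a polygon), pose-estimator
failure modes beyond i.i.d. low-likelihood samples, multi-animal
occlusion, circadian drift, and any syllable-discovery process. A
passing suite therefore demonstrates that the pipeline's computations
are correct and that planted effects of realistic size are recovered —
not that the assay's biological effect sizes are reproduced. In
particular, on synthetic cohorts the planted effects touch most
parameter families, so the Wilcoxon screen flags most parameters;
the published per-parameter counts are a property of the real data
and are only checked when the real per-mouse table is available
(`tests/data/supplementary_profiles.csv`).

Segment boundaries (hut entries, window exits) produce a handful of
teleport frames per period whose measured speed is arbitrary; ground
truth reports realized kinematics, so oracle comparisons remain exact,
and the boundary frames are ≲ 0.5 % of the assay.

## Numerical conventions

NaN is the undefined sentinel throughout. Z-scores use sample SD
(ddof 1). Quadrant boundary ties break to the nearest quadrant
centroid. Exact Wilcoxon p-values are two-sided doubled tail
probabilities. Support percentages are computed on the exact event
partition (no discretization); the tests cross-check against a
per-millisecond oracle. Determinism: every generator is a pure
function of its integer seed; cohort seeds derive from
`SeedSequence([seed, group, mouse])` and stay below 2³¹.

## Problem sizes

The test suite runs scaled assays (1/60 scale, 1,320 frames) for
anything involving frame rendering, full 79,200-frame assays for
generator-fidelity and parameter-recovery checks, a 16-mouse recovery
cohort, and 1,000-replicate null simulations for calibration. The
acceptance script simulates the full 12-group design at 8 mice per
group (96 mice, full-length assays). These sizes were chosen so the
whole pipeline, including every statistical check, runs comfortably on
one CPU.

## Known limitations

* The tracking stage assumes one mouse per cage; overlapping animals
  or reflections are out of scope.
* Likelihood filtering is the only pose cleaning; no smoothing or gap
  imputation, by design.
* The head heuristic degrades when the mouse is stationary for long
  stretches (axis sign ambiguity), which does not affect any of the
  125 parameters (the head enters only Peek, via the nose keypoint in
  pose data).
* Gait print geometry/intensity values are acquisition-side quantities:
  they are carried through and aggregated, never re-derived from
  images.
* The published summary-table reproduction checks require the original
  per-mouse table, which cannot be redistributed here.
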