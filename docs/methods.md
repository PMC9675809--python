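# Methods

`meg_seqmem` re-implements, on fully synthetic data, a complete MEG analysis
of auditory sequence recognition: an old/new paradigm in which listeners
memorize a tonal musical piece and an atonal counterpart and then judge
five-tone excerpts (250 ms per tone, 1250 ms per excerpt) as memorized or
novel. The package covers stimulus construction and complexity, cohort
simulation with a physical forward model, event-related-field preprocessing,
sensor- and source-level mass-univariate statistics with cluster-based
Monte-Carlo correction, and behavioral analysis. Everything below is the
package's own account of what is computed and why.

## Stimulus model

Tone sequences are lists of MIDI pitches. The atonal counterpart of a tonal
sequence applies an injective pitch-class map in which every class is
displaced by exactly 1 or 2 semitones (uniformly across octaves). This
preserves length, rhythm, approximate contour, and the positional recurrence
structure — if a pitch occupied positions 1, 7 and 8, its image occupies the
same positions — while destroying the tonal center. The preset map
`C→C♯, E→F♯, G→F` is available; random valid maps are drawn by randomized
backtracking so that a full 12-class injective map always exists.

Per-tone predictability uses a bounded-order n-gram model with additive
smoothing,

    p(e | ctx) = (count(ctx, e) + γ) / (count(ctx) + γ·|A|),

with information content `IC(e|ctx) = log2(1/p(e|ctx))` (bits) and entropy
`H(ctx) = Σ_e p(e|ctx)·IC(e|ctx)`, bounded by `0 ≤ H ≤ log2|A|`. Defaults:
order 2, γ = 1. Contexts shorter than the order (sequence starts) back off
to the longest observed context; all context lengths up to the order are
counted during training. A full multiple-viewpoint variable-order model and
a curated Western training corpus are out of scope; instead a *toy corpus*
of diatonic random walks (two octaves of a major scale, step-biased moves)
gives the model tonal-looking statistics, so remapped (atonal) sequences
score reliably higher IC. Consequently the absolute IC/H values are not
comparable to values from corpus-trained variable-order models — only the
tonal/atonal contrast and the formal identities are meaningful, and that is
what the tests assert.

## Synthetic cohort

**Geometry.** Sources live on a regular cubic grid (paper-scale 8 mm,
analysis default 12 mm) strictly inside a sphere of 76 mm; sensors sit on a
Fibonacci spiral covering the upper hemisphere of a 102-mm shell. Each of
the (default 102, desk-scale 64) positions carries two orthogonal planar
gradiometers and one radial magnetometer — 306 channels at full scale. A 2D
sensor layout is built by azimuthal-equidistant projection snapped to the
smallest regular grid with one channel per cell (used by the sensor-level
cluster statistics).

**Forward model.** The analytic current-dipole solution for a homogeneous
conducting sphere (closed form, independent of conductor radius). Radial
dipole moments are externally silent, so the lead field keeps only the two
tangential columns per dipole. Magnetometers read the radial field
component; planar gradiometers read its finite difference over a 17-mm
tangential baseline. An overlapping-spheres or BEM variant can be swapped in
behind the same `LeadField` contract; the single sphere needs no anatomy and
is exact for the geometry simulated here.

**Regions.** Named spherical patches stand in for anatomy: bilateral
auditory patches (lateral), bilateral hippocampal patches (deep), and a
midline cingulate patch. Effects are *placed* in these compact patches. For
cluster labelling the grid additionally carries an atlas-style exhaustive
partition (every dipole labelled by its nearest ROI center), mirroring how
an anatomical-atlas lookup labels any voxel a cluster touches.

**Ground truth.** Every condition evokes bilateral auditory activity: a
~5 Hz damped burst per tone (fast band) and a smoothed boxcar envelope over
the five tone windows (slow band), sustained 250 ms past the last tone
(recognition-related activity does not switch off with the final tone).
On top of this baseline, the simulated dissociation is: memorized-tonal
adds a slow-band effect in hippocampus + cingulate at tone windows 3–5;
memorized-atonal adds a slow-band effect in right auditory cortex at all
windows. Default effect amplitude 30 nA·m per dipole over a 15–25 nA·m
baseline — ordinary event-related dipole strengths.

**Variability.** Per subject, the simulator draws (i) random tangential
dipole orientations (cortical folding differs across heads), (ii) a
response-latency offset per (ROI, band) up to ±80 ms and a gain per
(ROI, band), and (iii) a global subject gain (sd 0.2); per trial, a
multiplicative amplitude jitter (sd 0.1). Items (i)–(ii) matter beyond
realism: with perfectly coherent sources in all regions, a minimum-variance
beamformer cancels correlated sources and the group contrast degenerates.
No real cohort is perfectly coherent, and neither is this one.

**Noise.** Two components per channel type: white Gaussian noise (2 pT/m
per sample for gradiometers, 100 fT for magnetometers at 150 Hz) and a
dominant 1/f "pink" component (RMS 20 pT/m and 1 pT respectively, spectrum
flattening below 0.03 Hz). The pink component is essential, not cosmetic:
MEG background is strongly colored, and with white-only noise the 0.1–1 Hz
band would be evoked-dominated, yielding a covariance no real recording has
(and, again, pathological beamformer behavior). With these defaults
single-trial sensor SNR is below one and the ~35-trial condition average
reaches roughly 10 dB on the best channels — ordinary ERF territory.

**Trials and behavior.** 160 trials per subject (two 80-trial blocks, tonal
then atonal, each 40 memorized + 40 novel, shuffled), onsets every 1.6 s
starting 0.5 s in. Correctness is Bernoulli per trial with a per-subject
probability drawn around the condition means 34.34 / 34.41 / 30.98 / 34.51
of 40 (memorized-tonal, novel-tonal, memorized-atonal, novel-atonal) with
between-subject SDs 5.95 / 6.04 / 5.46 / 4.26 — memorized-atonal is the
hard condition. Reaction times are lognormal around per-subject condition
means (1735.17 / 1799.52 / 1879.44 / 1873.78 ms, SDs ≈ 250–267 ms, within-
subject sd 300 ms). Familiarity with the tonal piece is a 1–7 rating drawn
from a fixed distribution concentrated on low values; by default familiarity
does not couple to brain amplitudes (no effect size is available to
calibrate such a coupling), so correlation-map recovery is tested on
explicitly constructed coupled fixtures instead.

## Preprocessing

Zero-phase band-pass filtering (4th-order Butterworth, forward–backward,
reflection padding ≥ 3 time constants of the low edge) into the analysis
bands: slow 0.1–1 Hz, faster 2–8 Hz, plus delta 1–4 Hz and theta 5–8 Hz.
Epochs run −100…+1250 ms around onset with the convention
`floor((tmax−tmin)·rate)+1` samples and the onset sample at t = 0 (203
samples at 150 Hz); baseline correction subtracts the per-channel mean of
the 100-ms pre-onset window, per trial, before averaging. Analyses use
correctly answered trials only; losing all trials of a condition is an
error naming that condition. Condition averages are combined across planar-
gradiometer pairs by root-sum-square (output non-negative, magnetometers
dropped).

## Cluster-based Monte-Carlo significance

Cell-level tests are binarized (1 = significant at the cell alpha, split by
contrast direction) on their native geometry — 2D sensor layout × time, or
the 3D voxel grid — restricted to valid cells. Connected clusters use
orthogonal-neighbor adjacency (4-connectivity in 2D, 6 in 3D; time counts
as one orthogonal axis). The null distribution re-places the observed
number of 1s uniformly over the valid cells (whole-matrix permutation of
the binarized map, *not* subject-level sign flipping) and records the
maximum cluster size, 1000 times by default. A cluster is significant when
its size strictly exceeds the (1−α) empirical quantile of the null — the
"larger than 99.9% of permuted maxima" rule at α = 0.001 — and its p-value
is `(1 + #{null ≥ k}) / (1 + n_perm)`, which cannot be zero. This
conditional-on-count null corrects for spatial multiplicity; exactness on
small lattices is verified against exhaustive enumeration of all
placements, and family-wise error on Bernoulli-thresholded null maps is
verified to stay at or below the nominal level.

## Sensor-level statistics

Per combined gradiometer and timepoint, a paired t-test across subjects
contrasts the memorized and novel condition averages (two-sided, α = 0.01;
direction split afterwards by the sign of t). The nominal 0–2500 ms
analysis window exceeds the 1350-ms epoch and is clipped to the available
data with a logged warning. Binary maps are embedded into the 2D layout per
timepoint (a lossless bijection) and corrected by the space-time cluster
MCS at α = 0.001 with 1000 permutations. Output tables report size,
distinct channels, time interval and Monte-Carlo p per cluster.

## Source-level statistics

**Inverse model.** Scalar LCMV beamformer. The sensor covariance comes from
the band-passed epochs plus Tikhonov loading (λ = 0.05 × mean diagonal;
positive-definiteness is verified, and a rank-deficient covariance at λ = 0
raises). Per dipole the scalar orientation minimizes `uᵀ(LᵀC⁻¹L)u` (the
generalized-eigenvector, power-maximizing choice), and the unit-gain filter
is `w = C⁻¹l / (lᵀC⁻¹l)`, so `w·l = 1` holds exactly; dipoles with
vanishing lead field (sphere center) are flagged inactive rather than
inverted. Noiseless round trips recover a dipole's amplitude to < 1% at the
true grid point; at 20 dB SNR localization stays within two grid steps.

**Two-level GLM.** First level: per subject, the memorized − novel
difference of condition-mean source time courses. The beamformer sign
ambiguity is resolved per dipole by flipping both conditions together so
that the largest-magnitude sample of their sum is positive; |contrast| is
invariant to arbitrary orientation flips. Group level: one-sample t across
subjects per dipole (α = 0.05, split by sign; zero-variance cells are
degenerate, not ±inf). For the tone-window analysis the first-level maps
are sub-averaged within each 250-ms window *before* the group test
(sub-average-then-test), binarized, and corrected by 3D spatial cluster MCS
per window and direction at the family-adjusted α = 0.01/(5 windows × 2
bands) = 0.001. Cluster tables carry the majority atlas label of their
member voxels.

**Contrasts.** The piece contrast compares window means of |activity| for
memorized-tonal vs memorized-atonal (paired across subjects; magnitudes
sidestep the per-piece sign convention), with the same ten-MCS family. The
band contrast z-scores window means within subject and band before
differencing, making it invariant to global band gain. The familiarity
analysis computes per-dipole, per-window Pearson correlations between the
1–7 ratings and windowed activity across subjects, binarizes at α = 0.05 by
the sign of r, and applies the spatial cluster MCS with the 95%
maximum-cluster rule.

## Behavioral statistics

Two one-way ANOVAs (α = 0.05) on accuracy and mean RT treat the four
condition cells as independent groups — at 71 subjects this yields the
printed df (3, 280), although the design is repeated-measures; the package
follows the printed convention and notes the caveat here. Post-hoc pairwise
t-tests (all six pairs) are judged against the Bonferroni-adjusted
α = 0.05/4 = 0.0125; the divisor 4 follows the published analysis even
though six pairs exist (a textbook Bonferroni would use 6).

## Problem sizes and defaults

The desk-scale configuration — 12 subjects, 64 sensor positions (192
channels), 12-mm grid (~1000 dipoles), 1000 permutations — was chosen so a
complete pipeline run finishes in well under a minute on one CPU while
keeping every statistical mechanism intact; the 71-subject / 102-position /
8-mm configuration is available via `paper_scale_config`. Calibration
checks use further-reduced grids (24-mm spacing) where only the statistical
engine, not the physics, is under test.

## What passing tests do and do not show

The simulator emulates condition structure, band-specific regional effects,
realistic colored noise, and behavioral distributions. It does not emulate
individual anatomy, extended cortical patches with constrained
orientations, eye/cardiac artifacts, head movement, or environmental
interference (removed upstream in real pipelines); recordings are
artifact-free by construction, so trial rejection beyond correctness never
occurs. Recovery results therefore validate the *analysis machinery* —
filters, beamformer, GLM, permutation correction — under a known ground
truth, not the anatomical claims one could draw from real recordings.
Beamformer point spread is real and visible: clusters extend beyond the
generating patches, and correlated-source cancellation can produce genuine
opposite-direction side lobes (e.g. a left-auditory novel>memorized blob
mirroring a right-auditory effect); the recovery criteria are therefore
stated in terms of majority labels and expected windows/directions, not
voxel-exact maps.

## Known limitations

* The n-gram toy corpus produces IC/H on its own scale; no comparison with
  corpus-trained variable-order model outputs is meaningful.
* The binarized-map permutation null is conditional on the number of
  suprathreshold cells and ignores their spatial autocorrelation; it is the
  procedure specified, and it is anticonservative in principle for smooth
  fields at the cell level, but family-wise calibration on the simulated
  nulls holds (verified).
* The ANOVA's independent-groups treatment of repeated measures inflates
  df; kept deliberately for fidelity to the published convention.
* HDF5 recordings store float32 data; statistics are computed in float64.
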