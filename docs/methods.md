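# Methods

## Viewing geometry

All angular quantities use the exact per-axis arctangent
`θ = atan(d_cm / D)` where `d_cm` is the pixel offset from the screen
center scaled by the panel's cm-per-pixel factor and `D` the viewing
distance. Pixels are 0-based with centers at integer coordinates; degrees
are measured from the screen center, rightward/downward positive. The
small-angle linear form would be accurate to ~0.5 % at 10° eccentricity,
but the exact form costs nothing and makes `deg_to_px ∘ px_to_deg` an
identity to better than 1e-9 px. The default fixture geometry is a 24-inch
16:9 panel (1920×1080 px, 53.1×29.9 cm) at 60 cm; all five geometry
numbers are configuration, not constants. Anisotropic pixels are supported
(per-axis scales); a >5 % pixel/physical aspect mismatch warns.

## Binocular compositing

When both eyes are valid the composite position is the per-axis arithmetic
mean; when exactly one is valid, that eye is used unchanged — monocular
recordings are first-class because strabismic participants may be tracked
from the fixating eye only. Samples with neither eye valid stay in the
stream flagged invalid so that gaps are visible to event detection.

## Event detection

Two stated definitions must compose: a velocity/acceleration/amplitude
saccade picker and a dispersion/duration fixation definition. We detect
saccades first: candidate runs are maximal stretches where instantaneous
speed exceeds the velocity threshold (30 °/s default), and a run is a
saccade only if its peak absolute acceleration (> 8 000 °/s² default) and
start-to-end amplitude (> 0.1° default) also qualify. The acceleration
criterion is applied at run level, not per sample, because acceleration
necessarily crosses zero at the velocity peak of every saccade — a
per-sample conjunction would split each saccade in two. Fixations are then
carved from inter-saccade segments by greedy left-to-right dispersion
clustering (I-DT style): a window grows while the maximum sample distance
from the running centroid stays within 0.1°, closes when it would not, and
is emitted if it lasts ≥ 100 ms. The greedy rule is the determinism
tie-break; dispersion is a radius from the centroid (rotation-invariant)
rather than a bounding box — whether the 0.1° stability bound is a radius
or a diameter is not fixed by convention, so the threshold is a parameter.

Speed is the norm of the central-difference velocity of the degree-space
trace (one-sided at segment ends); acceleration is the central difference
of speed. Invalid samples and timestamp gaps longer than two nominal
inter-sample intervals break both differentiation and events, so blinks
cannot be bridged. Denoising is a documented 3-sample per-axis median
filter (the vendor "heuristic filter" of commercial trackers is
unpublished; a median of three is the closest reproducible equivalent and
removes single-sample spikes exactly). It runs before detection by
default and is a pipeline flag.

## Saliency maps

Raw real-valued maps from any generator backend (the contract is: given a
stimulus image and a prompt, write a grayscale PNG) are Gaussian-smoothed
with reflective boundary (mass-conserving) and min–max rescaled to
integers 0–255 with round-half-away-from-zero. No smoothing scale is
canonical, so the default sigma is 2 % of map width — scale-free — and is
recorded in map metadata. A constant map is a degenerate 0/0
normalization; it becomes all zeros with a `constant` flag, and scoring
refuses it because it carries no feature signal. Differential maps
subtract the raw (pre-normalization) grids of two opposite prompts and
normalize the signed difference over its full range without clipping;
normalizing before subtracting would instead weight the two prompts
equally regardless of their raw dynamic range, which is the noted
alternative. 16-bit PNGs are down-converted with a warning; RGB collapses
by BT.601 luminance.

## Fixation saliency scoring

The outcome per fixation is the intensity of the map pixel under the
fixation center, by nearest-pixel lookup (intensities are defined per
pixel; interpolation would invent values). The out-of-range rule is read
per axis: a fixation is discarded iff its centroid lies farther outside
the image than 20 % of the corresponding image dimension; in-margin but
off-image centroids are clamped to the nearest boundary pixel (the
minimal-assumption rule, logged per fixation). Both readings (per-axis vs
radial; clamp vs drop) are configuration knobs for sensitivity analysis.
Fixations straddling a trial boundary belong to the trial containing
their temporal midpoint. Aggregation is the mean of per-image means —
unweighted across images — so long trials do not dominate a participant's
score; trials with zero surviving fixations are excluded, and a
participant with no valid trial is excluded for that feature.

## Statistics

*Group comparison.* Two-sided Mann–Whitney U per feature on participant
overall means. For pooled n ≤ 12 the p-value is exact by full enumeration
of group labelings over pooled midranks (`p = min(1, 2·min(P(U≤u),
P(U≥u)))`); larger samples use the normal approximation with tie-corrected
variance and 0.5 continuity correction. No multiple-testing correction is
applied across features by default (none is part of the analysis plan); a
Benjamini–Hochberg column is available as an option.

*Correlation.* Spearman's ρ (midranks, product-moment of ranks); exact
permutation p for n ≤ 8, t-approximation otherwise. The default mapping
pairs color features with the "color preference" instrument item, field
maps with "visual field preference", complexity with "difficulties with
visual complexity", luminance with "need for light", and an
adult-attention map with the instrument's two overall scores.

*Covariate adjustment.* "Multivariate regression" is implemented as
multivariable OLS (statsmodels) of participant means on age and binary
comorbidity indicators; rank-deficient designs fail loudly naming the
collinear columns.

*Sample size and power.* The closed-form two-means formula with
nearest-integer rounding is the headline convention (40.19 → 40, matching
the planned 40/group, 80 total); the ceiling convention (41) and a
rank-test size inflated by the Pitman efficiency 3/π (43) are also
reported. The Monte-Carlo power verifier draws replicate cohorts and
applies the two-sided two-sample t test — the test matching the
means-based planning formula; a Mann–Whitney option exists for checking
the rank-test power under the same conditions.

## Synthetic cohorts

The simulator emulates the study conditions: 500 Hz binocular sampling,
contiguous image-viewing trials, and viewers whose attention is a weighted
mixture over feature maps. Fixation targets are drawn with probability
`w·I/ΣI + (1−w)/N` over normalized map intensities, so the expected
fixation saliency value is `w·ΣI²/ΣI + (1−w)·mean(I)` — strictly
increasing in `w`, which is the lever the recovery tests pull. Fixation
durations are truncated normal (defaults mean 250 ms, SD 60 ms, floor
80 ms — the floor deliberately admits sub-100 ms fixations to exercise the
detector's rejection path; recovery tests use a 150 ms floor so every
scripted fixation is detectable). Saccades are minimum-jerk trajectories
whose duration follows the oculomotor main sequence (≈ 2.2·A + 21 ms,
capped by the profile's transition time), which guarantees peak velocity
and acceleration clear the detector thresholds for amplitudes ≥ 1°;
successive targets are redrawn (up to 50 times) to keep amplitudes above
that floor. Inter-trial gaze jumps are rendered as scripted saccades at
the start of the next trial so ground truth and detection agree event for
event. Trial tails shorter than a minimum fixation plus a saccade are
absorbed into the final fixation, keeping every scripted duration above
the profile floor. The two eyes are the composite position ±1 px
horizontally (exercising the averaging path without moving the composite);
optional per-sample Gaussian jitter in degrees models tracker noise.
Per-participant seeds derive deterministically from the cohort master
seed.

What the simulator does **not** model: nystagmus waveforms, smooth
pursuit, blinks and partial-validity episodes, calibration drift, or head
movement. Passing recovery tests therefore show the pipeline is correct
under clean oculomotor structure, not that it is robust to every clinical
recording artifact — saccade/fixation timing under nystagmus in particular
is known to be unreliable and is out of scope.

## Problem sizes and numerical choices

Recovery and monotonicity tests use 200×200 px maps, 5–60 s trials and
cohorts of 2–6 per group — large enough that Monte-Carlo standard errors
separate the weight grid, small enough for an interactive test cycle. The
power verification uses 10 000 replicates of the full 40 + 40 design
(vectorized, seconds of runtime). Exact-test cutoffs (pooled n ≤ 12 for
Mann–Whitney, n ≤ 8 for Spearman permutation) keep enumeration below ~10⁵
evaluations. Ties in normalization rounding, greedy window closure in
fixation carving, and sorted iteration orders are the fixed tie-breaks
that make reruns byte-identical.
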