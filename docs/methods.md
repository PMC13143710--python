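# Methods

This note documents the models, conventions and design choices behind
`gazephase`, in the spirit of a statistical package's methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and conventions

A *viewing episode* is one participant × artwork self-paced viewing:
a gaze stream (t, x, y, validity), the judgment click time, and a 1–10
rating. One set of conventions is used everywhere: origin top-left,
y increasing downward, coordinates normalised to the half-open unit
square [0,1)×[0,1) (so the image area is 1 and ROI areas are directly
fractions of it), time in seconds with 0 = stimulus onset. Episodes
store flat numpy arrays, not per-sample objects; at 300 Hz a single
episode holds thousands of samples and everything downstream is
vectorised.

Binocular recordings are reduced to a cyclopean stream on read: the
two eyes are averaged where both are valid, otherwise the valid eye is
used. Samples falling outside the unit square after normalisation are
flagged invalid but never deleted, preserving timing structure.

## Preprocessing

**Gap interpolation.** Invalid runs no longer than 75 ms (below
typical blink duration) with valid samples on both sides are linearly
interpolated; longer runs stay invalid. An episode whose valid
fraction falls below a threshold (default 0.5) is flagged rejected —
a quality flag, never an exception. These defaults are configurable;
sample-level preprocessing details vary between laboratories and the
package makes no claim that they match any particular one.

**Fixation detection.** Dispersion-threshold (I-DT) detection:
a fixation is a maximal window of consecutive valid samples whose
dispersion (x-range + y-range) stays at or below a threshold and which
spans at least 100 ms. The default threshold, 0.018 of image width, is
the 1° equivalent for a 23-inch 16:9 monitor viewed at ~52 cm.
Durations include one nominal inter-sample interval, so a 1-s
stationary stream yields exactly a 1-s fixation. The implementation is
checked against a naive quadratic window-scan oracle in the tests.

## The constrained gaze-state HMM

Each stimulus gets its own K-state Gaussian-emission HMM (default
K = 14, treated as a configuration constant) fitted by maximum-
likelihood Baum–Welch on all observers' observation sequences for that
stimulus. The default observation unit is I-DT fixation centroids —
the conventional choice for scanpath HMMs, and the one under which the
transition matrix has a natural fixation-to-fixation interpretation —
with a downsampled raw-sample mode available.

Numerical choices:

- **Initialisation**: k-means++ on the pooled observations per
  restart; spherical covariances at pooled variance / K; sticky
  transition rows (0.8 diagonal); uniform initial distribution.
  Defaults: 20 restarts, tol 1e-6 (relative log-likelihood),
  max 200 iterations, eigenvalue floor 1e-6.
- **Restart selection**: the restart with the highest log-likelihood
  wins; the fitted states are then re-indexed by descending stationary
  occupancy so repeated fits are comparable.
- **Scaling**: forward–backward uses per-step normalisation with a
  per-timepoint shift of the emission log-densities, giving exact
  log-likelihoods without underflow. If the emission density is
  exactly zero at a timepoint the decoder raises instead of silently
  renormalising.
- **Viterbi ties** break toward the lower state index
  (first-argmax), making decoded paths deterministic.

**Constraint projection.** After every M-step:

1. covariance eigenvalues are floored at 1e-6;
2. ellipse axis lengths (of the mass-defining ellipse, below) are
   clamped to mean ± Nσ across all 2K axis lengths (default N = 2 —
   the clamp strength is a free parameter with no canonical value, so
   it is surfaced in the fit log);
3. the ellipse area is projected into the band [0.1%, 5%] of image
   area by isotropic rescaling of both eigenvalues (preserving
   orientation and aspect ratio). The band is enforced *last*, so
   every returned model satisfies it exactly.

"ROI area" needs an operational definition; the package uses the area
of the ellipse containing 68% of the Gaussian's mass,
A = π·χ²₂(0.68)·√det Σ, a 1σ-equivalent convention. The mass level is
configurable (`area_definition`). Projection can in principle lower
the EM objective; per-iteration decreases beyond tolerance are
recorded in the fit's event log rather than hidden. Applying the
projection to an already-feasible model is a no-op (tested).

## Time-bin aggregation and indices

Decoded sequences are aggregated over [0, 30) s in 3-s half-open bins.
A bin's distribution p is the mean posterior over its timepoints; hit
counts are *entries* into a state on the Viterbi path (one for the
state occupied at bin start, one per transition into a state); dwell
time is path time per state. Bins with fewer than 10% of the expected
timepoints are flagged unpopulated and excluded from statistics —
self-paced episodes (mean ≈ 13 s) make partial and empty late bins the
norm, and the threshold is configurable.

All entropies use the natural log: normalisation makes the base
immaterial for Hnorm, and Neff = exp(H) requires e for
Neff(uniform) = K. TV between consecutive *populated* bins is
attributed to the earlier bin, so "TV in the 6–9 s window" means the
change from the [6,9) distribution to the [9,12) one, and an episode
with B populated bins has exactly B−1 TV values. Switch is computed
within each bin on the per-timepoint Viterbi path and is undefined
(missing, not zero) for bins with fewer than two timepoints.

## Group definition and inference

Ratings are min–max normalised within participant (participants who
used a single value map to 0.5 and are flagged — their ranking is
uninformative). Artworks are ranked by mean normalised rating and
split into equal high/low halves; boundary ties break deterministically
by artwork id and are logged.

Each populated bin × metric cell is tested with a two-sided Wilcoxon
rank-sum (Mann–Whitney) test: exact by enumeration when both samples
have ≤ 10 untied observations, otherwise the normal approximation with
tie-corrected variance. The reported z is always the uncorrected
normal deviate, positive when the high group tends larger. The effect
size is the z-based rank-biserial r = z/√N; with the artwork-level
6-vs-6 complete-separation case this convention gives the internally
consistent triple p = 2/924 ≈ 0.0022, z = 18/√39 ≈ 2.88, r ≈ 0.83
(a continuity-corrected z would give 2.80 instead, which is why the
correction is off). The U-based Cliff-style r = 2U/(n₁n₂) − 1 is
provided as a clearly labelled alternative. BH-FDR is applied over
the whole bin × metric family of the main analysis; supplementary
analyses form separate families.

**Observation unit.** The unit entering each test is configurable:
`episode` (default; pools all viewing episodes within each artwork
group), `artwork` (6 vs 6 artwork means) or `participant`. These are
genuinely different tests. Episodes within an artwork share that
artwork's ROI layout, so under artwork-level heterogeneity the pooled
episode-unit test is anticonservative — the randomisation unit of the
group split is the artwork. The calibration simulations therefore
assess type-I control at the artwork unit, while the episode unit
gives the power to resolve per-bin effects. Neither choice is claimed
to be "the" correct one; both are exposed.

## The synthetic-study generator

The generator produces the structure the analysis assumes, with
defaults matching the targeted study design: 35 participants ×
12 artworks (6 per evaluation group), 300 Hz sampling on a 1920×1080
stimulus, self-paced judgment times drawn from N(13.1, 1.21²) s
truncated to [3, 30] s (and to ≥ the artwork's convergence onset, so
every episode contains its transition), group rating levels 0.668 /
0.357 on the normalised scale with Gaussian noise (SD 0.12), and
convergence onsets τ = 6 s (high group) vs 12 s (low group).
Truncation to ≥ 3 s guarantees at least one populated bin; 30 s is
the analysis horizon.

**Mechanism.** The hidden state path runs at *fixation-event*
granularity: each event dwells for a Gamma-distributed duration
(mean 300 ms, SD 120 ms, floor 60 ms — typical fixation-duration
statistics), then transitions. Before τ the chain is in an exploration
regime (self-transition 0.15, uniform off-diagonal); from τ onward
every row places probability 0.92 on a per-episode *focus state*
(drawn from a small set of focus candidates per artwork) and spreads
the rest uniformly. This is the minimal mechanism producing the
lower-Hnorm / lower-TV middle-phase signature of earlier convergence;
no claim is made that real gaze follows it. A per-sample Markov chain
at 300 Hz was rejected because it implies physiologically impossible
switching rates and defeats fixation detection. Each event's fixation
centre is drawn from the occupied ROI's Gaussian; samples add
isotropic jitter (SD 0.0015 of image width, post-filtering tracker
precision territory), so per-state sample centroids converge to the
ROI means and I-DT sees realistic input. Ground-truth ROI models draw
means in the interior of the unit square and ellipse areas
log-uniformly inside the constraint band (margin 0.3 log-units from
the edges so emission spread cannot leak outside).

Ratings are generated on the normalised scale and inverse-mapped to
1–10 integers through per-participant affine response scales (random
floor in 1–3, ceiling in 8–10), so the normalisation stage is
exercised end to end. For the depth analysis the generator plants
depth points at the focus-candidate ROI means, coupling depth-point
fixation to convergence.

**What the generator does not emulate**: image content and saliency,
calibration drift, smooth pursuit, blink dynamics, participant-level
rating biases beyond the affine scale, or any coupling between rating
noise and gaze. Passing tests therefore demonstrate that the pipeline
recovers the *assumed* structure, not that real viewing data contain
it.

**Simulation sizes.** The effect-recovery check runs the full
35 × 12 design at 300 Hz once; the null-calibration check runs 200
compact replicates (6 participants, 12 artworks, 60 Hz, shared onset
τ = 12 s, equal rating levels) with decoding done under the
ground-truth per-artwork models — re-fitting 12 fourteen-state HMMs
per replicate would add nothing to what the dedicated fitting and
recovery tests already establish. The acceptance script fits one
artwork's K = 14 model on 35 episodes with the default 20 restarts.

## Supplementary analyses

**Depth fixations.** A fixation hits a depth point when its centroid
lies within a radius (default 0.05 normalised units — the hit
criterion has no canonical value and is configurable) of any annotated
point. Per bin: hit count, first hit time, mean dwell of hitting
fixations; cumulative hit counts are prefix sums across bins and are
compared between groups per cumulative window with the same rank-sum
machinery, as a separate FDR family. Depth annotations are
user-supplied; the generator plants synthetic ones.

**Gaze cascade.** Each 2AFC trial's timeline is rescaled to [0, 1]
with 1 = decision; per normalised-time bin (default 10) the fraction
of valid samples on the ultimately chosen option's region is averaged
across trials; samples on neither option are excluded from the
denominator with the excluded fraction logged. The last bin is the
decision-proximal estimate. The generator ramps
P(gaze on chosen) linearly from a baseline to a final probability at
decision time.

## Known limitations

- The fitted transition matrix lives at fixation granularity while
  per-timepoint decoding applies it at the sample rate; emissions
  dominate decoding for well-separated ROIs, but transition-sensitive
  quantities (Switch) should be interpreted relative to the sampling
  rate.
- K is fixed by configuration; the package deliberately does not
  select the number of states.
- Exact rank-sum p-values are only available for untied samples of
  ≤ 10 per group; elsewhere the tie-corrected normal approximation is
  used and flagged.
- The I-DT oracle equivalence is exact for uniformly sampled streams;
  with strongly non-uniform timestamps the minimal-window definition
  (first window spanning the minimum duration) is still honoured but
  1°-equivalence of the threshold degrades.
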