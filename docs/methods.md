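# Methods

This note documents the models and procedures implemented in `shoalkit`,
the choices made where the design was genuinely open, and what the bundled
simulator does and does not establish about real data.

## Trajectory preparation

Input trajectories are tidy CSV tables (`trial_id, frame, fish_id, x, y`)
with a commented header declaring units (`mm` or `px` with a scale factor)
and the frame rate (default 24 Hz). Coordinates are millimetres with the
origin at the arena centre and y up; frame indices are 0-based and every
frame interval is half-open `[start, end)`. A missing observation must be
present as an explicit blank/NaN row — absent rows, non-contiguous frame
indices and duplicated `(frame, fish)` rows are schema errors, not data.

**Gap filling.** Interior gaps are linearly interpolated between flanking
observations; leading/trailing gaps take the nearest observed position.
Runs longer than `max_gap` (default 15 frames, matched to the smoothing
window) are refused with the individual and frame span named: an automated
tool should not invent long stretches of movement that a human would have
hand-checked. The operation is idempotent.

**Smoothing.** Savitzky–Golay with a 15-frame window. The polynomial order
is not dictated by the source protocol; the default is cubic, the standard
choice for kinematics because it preserves velocity structure. At the
series ends the filter switches to shrinking-window least-squares fits over
the part of the window inside the series, so no positions are extrapolated
outside the observation interval. Smoothing is linear in the coordinates
and therefore exactly translation- and rotation-equivariant (tested at
1e-9 mm).

## Group metrics

All per-frame series are frame-aligned with the trajectory; derivative
quantities (speed, centroid velocity) repeat the preceding value at the
final frame. Undefined values are NaN throughout.

- **Headings** come from frame-to-frame displacement, not body axis — the
  tracker supplies point positions only. Displacements below `min_step`
  (default 0.2 mm) are treated as tracking jitter and the last valid
  heading is carried forward; headings are undefined before the first
  valid step.
- **Polarization** is the resultant length of the defined unit headings,
  undefined when fewer than two members have a defined heading.
- **Front/back** is the sign of the projection of a member's displacement
  from the centroid onto the centroid velocity, with a strict inequality
  (a fish exactly at the centroid is not "in front"). Frames where the
  centroid moves slower than `min_centroid_speed` (default 0.5 cm/s) are
  undefined for all members: a stationary group has no front.
- **Leadership structure** is the population (÷n) variance of the members'
  front proportions — the n tagged fish are the complete group, not a
  sample. Configurable but deliberate.
- Per-trial summaries use the median for speed and polarization (robust to
  burst-and-glide swimming) and the mean for centre distance and front
  proportion.
- **Cover occupancy** is a point-in-circle test of the smoothed position
  against a single circular refuge (a simplification of a planted area).

Foraging trials are split at the food-depletion frame into pre/post
windows `[0, d)` and `[d, n)`. The depletion frame is metadata (the
simulator logs it exactly); no attempt is made to infer it from
trajectories.

## Density maps

Relative neighbour positions are accumulated over every ordered
(focal, neighbour) pair at every frame with a defined focal heading, in
the focal frame (origin at the focal fish, heading rotated to +y), scaled
to body lengths. Defaults: 0.25 BL bins over ±5 BL; samples outside the
extent are dropped and tallied, not clamped. The speed–polarization map
bins (mean individual speed, polarization) per frame at 0.25 cm/s × 0.05.
Maps are plain histograms normalised to percent of the densest bin; the
peak count is stored so raw counts remain recoverable and maps with equal
binning can be pooled exactly. Bin widths and extents are explicit package
defaults, not claims about any published figure's binning.

## Mixed models and repeatability

The inference engine is a Gibbs sampler for the Gaussian random-intercept
model with categorical fixed effects (context, or trial number), a group
intercept and optionally an individual intercept nested within group. Full
conditionals are conjugate: multivariate normal for β (prior variance
1e8), independent normals for the random intercepts, inverse-gamma for the
variances (prior shape = scale = 0.001, a standard weakly-informative
choice; both configurable — the test suite checks on synthetic data that
results are insensitive to the realised components rather than assuming
it). Package defaults are 5 chains of 20 000 iterations, 2 000 burn-in,
thin 10 — a deliberately scaled-down default; larger runs are a config
change. Convergence is monitored by the potential scale reduction factor
across chains (reported per variance component).

Consistency repeatability `R_C = V_level / ΣV` is computed **per draw**
and summarised by the posterior mean and equal-tailed 95% CI, so the
ratio's uncertainty is propagated; the ratio of posterior-mean components
is also reported as the point estimate used in published tables.

**"CI excludes zero".** Variance draws are strictly positive, so the lower
quantile of a variance (or of R) is never literally zero. The package
flags significant repeatability when the lower 95% bound of R exceeds
`zero_tol = 0.01` (1% of total variance). Calibration tests show this rule
gives ≤10% false positives when the true group variance is zero and ≥90%
CI coverage at true R = 0.5 at the study design size (25 groups × 5
individuals × 4 contexts, 100 replicates per arm).

A method-of-moments (expected-mean-squares) estimator serves as an
independent oracle for the sampler on balanced designs: fixed effects are
removed by demeaning within fixed-factor cells, the nested ANOVA
identities are solved, and negative solutions are truncated at zero. With
one observation per individual the individual and residual components are
not separable and the result is flagged confounded. On balanced 50-group
data the Gibbs posterior means agree with the moment estimates within 10%.

**Inference by CI overlap.** Context effects are compared by whether the
95% credibility intervals of two cell means overlap; no multiple-testing
correction is applied, matching the CI-overlap convention of the
repeatability literature. This is documented rather than hidden: overlap
inference is conservative and the comparison table reports every pair.

## The synthetic-data generators

**Metric-level generator.** `generate_lmm_data` draws observations
directly from the random-intercept model and returns the generating
components and realised effects, giving exact ground truth for testing the
samplers. Note that the recoverable truth for a single dataset is the
*realised* variance of the drawn effects, which differs from the
asymptotic setting by O(√(2/q)); tests are calibrated accordingly.

**Agent-based simulator.** A zonal (metric-zone) model with disjoint
annular zones: repulsion inside 30 mm, alignment in [30, 120) mm,
attraction in [120, 400) mm — roughly repulsion within a body length
(40.6 mm) and alignment over a few body lengths. Disjoint annuli make a
perfectly aligned, noise-free group an exact fixed point of the update
(rigid translation), which anchors the polarization tests. Per frame each
agent blends its heading a quarter of the way toward the desired direction
and adds von Mises noise (SD 0.25 rad); step length is the agent's
preferred speed. The arena is a 400 mm-radius circle with a graded inward
push inside a 40 mm wall band and reflective hard containment; agents
start inside a central 50 mm release circle.

Study conditions (fixed once as the package defaults): 25 groups of 5
fish at 24 fps; trial durations 60 s open, 90 s foraging, 60 s cover —
short-trial analogues of a longer laboratory protocol, sized so the whole
experiment simulates in about a minute; one open, four foraging and two
cover trials per group. Heterogeneity enters through preferred speed:
population mean 3.2 cm/s, among-group SD 0.8 cm/s, among-individual SD
0.2 cm/s (floored at 0.5 cm/s). The foraging context places three 25 mm
patches of five food items on an equilateral triangle; agents sense a
patch strongly within 150 mm and weakly at any range (a scent term that
makes depletion reliable within a trial), slow to half speed while
approaching detected food, and stop for a 1.5 s handling time per item;
the depletion frame is logged when the fifteenth item is eaten. The cover
context adds a central 75 mm refuge which agents stochastically seek
(0.05/s), settle under (0.5/s once inside) and leave (0.1/s).

The simulator reproduces the qualitative phenomenology the pipeline must
detect — groups slow and disperse while food is present and speed up after
depletion; speed and polarization co-vary positively (an emergent
property: faster agents straighten their paths relative to the noise, it
is not imposed); cover produces partial emergence of subgroups; injected
group-level speed differences propagate into significant group-level
repeatability with near-zero individual-level speed repeatability. It is
**not** a behavioural model of real fish: there is no vision cone, body
shape, hydrodynamics, satiation, or learning, and its parameters are not
fitted to data. Passing end-to-end tests therefore demonstrates that the
pipeline recovers known heterogeneity injected under realistic geometry
and noise — not that any particular species behaves this way.

## Pipeline

`run_pipeline` is a pure function of (inputs, config, seed): every run
writes its resolved configuration next to its outputs and re-running
reproduces them bit-for-bit. Per-trial randomness derives from
deterministic substreams spawned from the root seed. The across-context
analysis uses the first trial per context with the foraging trial split
pre/post depletion (a four-level context factor); an all-trials variant
runs from the same metric table without recomputation. Within-context
analyses (foraging pre-depletion trials 1–4; cover trials 1–2) use trial
number as the fixed factor. The headline across-context output carries six rows:
group-level repeatability of speed, centre distance, polarization and
leadership structure, and individual-level repeatability of centre
distance and front proportion.

## Known limitations

- The moment estimator is exact only for balanced designs; it warns and
  approximates otherwise (the sampler itself has no such restriction).
- The `zero_tol` significance rule is a pragmatic convention; users needing
  strict decision rules should inspect the posterior directly.
- Heading-from-displacement underestimates alignment when fish hold
  position while reorienting; with point tracking this is unavoidable.
- Non-Gaussian responses, random slopes and REML are out of scope: the
  models here are Gaussian random-intercept models by design.
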