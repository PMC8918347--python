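# Methods

## Data model and conventions

Positions are stored in millimetres, one (x, y) sample per fish per frame;
tracking dropouts are explicit NaN gaps, never silently imputed. The
coordinate origin is the lower-left corner of the arena's bounding
rectangle (bounding square for the circular arena), x rightward,
y upward. Frames are indexed from 0 and all windows are half-open
`[start, end)`. Pixel data are converted at ingest via an optional
`px_per_mm` factor in the metadata sidecar, so everything downstream is a
single unit.

The preference chamber is laid out `stimulus | test | stimulus` along x.
Two sizes are standard: a 25 × 75 mm test area with 8 × 75 mm stimulus
areas (fish up to 4 weeks post-fertilization) and 50 × 75 / 16 × 75 mm
(8 wpf). The shoaling arena is a 700 mm diameter circle.

### Gap handling

Trackers lose animals for a few frames at a time. `fill_gaps`
linearly interpolates interior gaps up to `max_gap_frames` (default 5, or
about 0.17 s at 30 fps — long enough to bridge single-frame identity
drops, short enough not to invent behavior); longer and leading/trailing
gaps stay missing. Metric code then handles the remaining gaps
explicitly: speed uses only consecutive present-present frame pairs,
neighbor distances drop missing pairs pairwise, occupancy is a percentage
of *tracked* frames, and the PCA drops incomplete frames listwise rather
than fabricating covariance.

### Swim speed

Mean speed over a window is the mean consecutive-frame step length times
the frame rate, with no smoothing or outlier filtering. Speed is
translation invariant and scales linearly with frame rate for fixed
per-frame displacements.

## Social preference scoring

The test area is split at the midline perpendicular to its long axis into
two equal halves; the half adjacent to the occupied stimulus area is the
social ROI. Tie rule: a point exactly on the midline counts as social and
points on outer walls count inside, so the two ROIs exactly partition the
test area and scoring is deterministic; on continuous data the boundary
set has measure zero. The score is computed over the last 600 s of the
720 s test phase (stimulus fish need up to ~2 min to settle after
transfer), following 600 s of habituation.

### Exclusion rule

Exclusion is a two-pass batch procedure per age group: first every fish's
mean swim speed is computed and averaged per genotype group; then
0.6 × the smallest group mean is applied as the threshold. A fish exactly
at the threshold is included (≥ rule); a fish that never moved is always
excluded as frozen, regardless of the threshold value. The speed that
gates exclusion is configurable — test phase (default), habituation, or
the minimum of both — because either phase is a defensible freezing
indicator; the default uses the phase being scored.

## Shoal metrics

Per frame and focal fish, distances to all other present fish yield NND
(min), IID (mean over the other N − 1 fish) and FND (max); per-fish values
are frame means, shoal-level values are means over fish. For gap-free
data the shoal-level IID equals the mean over unordered pairs (also
reported). By construction NND ≤ IID ≤ FND pointwise, and all distances
are translation invariant and scale linearly under uniform scaling.

Cumulative shoal distance is defined as the sum of per-fish path lengths
(the standard activity proxy for a group); a centroid-path-length variant
is available behind a flag for users who want the group's net travel
instead.

### Variance explained (polarization)

The 2N × T trajectory matrix (rows fish1_x, fish1_y, fish2_x, …) is
row-centered and its 2N × 2N covariance across time eigendecomposed
(unbiased T − 1 denominator; irrelevant to the VE ratio but documented for
eigenvalue reporting). VE₂ = (λ₁ + λ₂)/Σλ. Covariance — not correlation —
is used deliberately: the statistic asks how much of the positional
variance the collective motion carries, so rows are not rescaled. The
implementation uses a symmetric eigendecomposition; tests cross-check it
against an independent singular-value route to 1e-8 relative.

Degenerate inputs: an all-stationary shoal has zero total variance and
raises an undefined-statistic error rather than returning 0/0; eigenvalues
are clipped at zero to absorb −1e-16-scale numerical noise.

### Mixed-movie control

For each `k_same`, pseudo-shoals are composed of `k_same` fish from one
focal recording plus `n_total − k_same` fish from *distinct* other
recordings, truncated to the shortest recording; VE₂ is averaged over
seeded replicates. Fish from different recordings share no common motion,
so the curve starts near 1/N and rises continuously toward the true shoal
value — the empirical justification for using VE₂ as a coordination
measure.

## Synthetic generators

### Shared-motion shoal model

Fish i sits at `center + c(t) + e_i(t)` where the shared process c and the
per-fish processes e_i are independent stationary AR(1) (discretized
Ornstein–Uhlenbeck) walks with per-coordinate stationary SDs
`sigma_shared` and `sigma_idio`. Per axis the stationary covariance is
exactly `sigma_shared² J + sigma_idio² I`, whose top eigenvalue is
`N sigma_shared² + sigma_idio²`, so the population variance explained is

&nbsp;&nbsp;&nbsp;&nbsp;VE₂ = ρ + (1 − ρ)/N,&nbsp;&nbsp;ρ = sigma_shared² / (sigma_shared² + sigma_idio²).

This closed form is the analytic target every empirical VE₂ estimate is
tested against. Parameter choices:

* `n_fish = 20`, `duration_s = 1800`, `frame_rate_hz = 30` — the shoaling
  assay's recording conditions.
* total per-coordinate SD ≈ 50 mm — keeps a 20-fish shoal spread over a
  plausible fraction of a 700 mm arena.
* `relaxation_time_s = 0.25` — the mean-reversion time constant. It does
  not affect the stationary covariance (hence not the closed form), only
  the frame-to-frame autocorrelation, and thereby the *finite-sample* bias
  of eigenvalue estimates: autocorrelated frames shrink the effective
  sample count, and at ρ = 0 the top sample eigenvalues of an
  equal-eigenvalue covariance overshoot in proportion. A bout-scale
  decorrelation of 0.25 s keeps 30 fps frames nearly independent, so the
  empirical VE₂ at T = 54,000 matches the closed form to better than 0.01
  across the whole ρ grid (measured bias at ρ = 0: +0.007; a 2 s
  relaxation time would inflate it to +0.020). The parameter is exposed
  for users who want slower, smoother centroid motion and can tolerate
  the bias.
* Boundary reflection is off by default (the closed form is exact only
  for the unconstrained process; excursions beyond the arena are ~7 σ
  events at the default SD) and available for realism.

The model is a statistical stand-in, not a kinematic one: its
frame-to-frame jitter implies unrealistically high instantaneous speeds
and no bout structure, so absolute speed- and path-length-based numbers
from this generator are only meaningful in relative comparisons. The
zonal model below is the qualitative-realism counterpart.

### Zonal (repulsion/alignment/attraction) model

The classic three-zone update: turn away from neighbors inside
`r_repulsion` (default 15 mm), otherwise average headings of neighbors
inside `r_alignment` (60 mm) and steer toward neighbors inside
`r_attraction` (250 mm); Gaussian turning noise per frame (0.25 rad),
constant speed (40 mm/s, a cruising speed of a few body lengths/s for
juvenile zebrafish), radial reflection at the circular wall. No analytic
target exists; tests assert qualitative properties (attraction contracts
a dispersed group; high turning noise lowers VE₂).

One caveat: with uniform-random headings the fish become confined random
walks whose position autocorrelation time (~R²/D) is hours, far beyond
any 30 min recording, so their *sample* VE₂ does not reach the 1/N floor
at feasible T. The 1/N limit is therefore exercised through the
shared-motion model at ρ = 0, where stationarity actually holds.

### Preference fish

A single fish performs a reflected random walk in the test area:
per-frame displacement = isotropic Gaussian step (SD 0.5 mm per
coordinate; at 20 fps this gives a mean speed of ≈ 12.5 mm/s, a realistic
larval cruising speed) plus `beta / frame_rate` of drift toward the
occupied stimulus wall. β = 0 yields 50% expected social-ROI occupancy by
symmetry; the stationary occupancy rises monotonically with β (the
stationary density of a reflected drift-diffusion is exponential with
length scale D/β). `simulate_preference_assay` chains an unbiased
habituation phase and a biased test phase continuously, mimicking
stimulus-fish introduction. The walk starts at the test-area center,
where a real test fish is released.

Seeding: one integer seed expands deterministically into independent
per-fish substreams, so simulations are reproducible and fish are
statistically independent.

## Statistical chain

All tests are two-sided (the assays have no a-priori direction). The
normality screen is a one-sample KS test against a normal with the
sample's own mean and SD; estimating parameters from the sample makes the
classical p-value anti-conservative (Lilliefors caveat), which is
acceptable for a screen whose typical outcome — non-normal behavioral
data — motivates the rank tests that follow.

Kruskal–Wallis uses mid-ranks with tie-corrected variance and a
chi-square reference (g − 1 df); for tiny totals (≤ 10) an exact
permutation p over all group assignments is available. The rank-sum test
enumerates the exact null distribution for tie-free samples with total
n ≤ 25 and otherwise uses the tie-corrected normal approximation with
continuity correction; `auto` picks for you. Post-hoc families mirror
the figure-caption comparisons (age within genotype, genotype within age,
rearing within genotype × age); each family is Benjamini–Hochberg
adjusted by default, with `none` available for raw p-values. Post-hoc
tests run only when the omnibus p clears `posthoc_alpha` (default 0.05;
pass None to disable gating).

Calibration, recomputed by the acceptance script: the omnibus type-I
error at α = 0.05 over 2,000 null replicates (3 × n = 15) and the power
of the full chain for a 1.5 SD shift (n = 15/group, 500 replicates).

## Pipelines

Batch runs are manifest-driven (one CSV row per trajectory file with
group labels) and fully seeded; result tables are byte-identical across
reruns with the same config and seed. The JSON-lines log records the
config hash, seed, per-age-group thresholds and group means, exclusion
counts, per-file failures, and empty groups, mirroring how
included/excluded n are reported alongside results. Figures are
best-effort and excluded from the determinism guarantee.

## Problem sizes used in tests

The test suite validates study-scale properties directly — 20-fish,
54,000-frame matrices for the VE₂ convergence grid and the mixed-movie
control (21 recordings), 2,000 replicates for type-I calibration, 200
seeds for the preference symmetry — and uses smaller shoals (5–12 fish,
minutes of data) for unit-level properties where size is irrelevant.

## Known limitations

* The synthetic generators plant the *statistical* structure the metrics
  measure (coordination level, social bias) but not bout-structured
  kinematics, wall-following, or inter-fish avoidance; passing tests show
  the estimators recover planted structure, not that real fish behave
  like the models.
* The shared-motion closed form holds for the unconstrained process;
  with reflection enabled it is approximate.
* VE₂ estimates from autocorrelated trajectories carry a positive
  finite-sample bias that grows with the motion's correlation time; the
  mixed-movie control inherits this at small `k_same`.
* The KS screen is anti-conservative with estimated parameters; treat it
  as a heuristic gate, not a calibrated test.
* `fill_gaps` is linear interpolation; for gaps longer than a few frames
  the listwise-drop policy of the PCA and the pairwise-drop policy of the
  distance metrics are the safer defaults.
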