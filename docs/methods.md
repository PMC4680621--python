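# Methods

This note documents the models, priors, numerical choices and
limitations behind `whaletrack`, in the order data flow through the
pipeline.

## Synthetic data: what it emulates and what it does not

The generator produces the three inputs the analysis needs: latent
two-state tracks, Argos-like fixes, and bathymetry.

**Movement truth.** Tracks are forward simulations of the same switching
first-difference correlated random walk the estimator assumes, on a
12-h step.  Defaults caricature the two behavioural modes: persistence
γ = (0.8, 0.2) (0.85/0.15 in the recovery experiments, which call for
well-separated states), mean turn angles
θ = (0, 0) — state 2 turns more because its small γ leaves the
isotropic process noise dominant — process noise 0.15° (≈ 17 km) per
step, and stay probabilities (0.95, 0.95), i.e. behavioural bouts of
about ten days.  These choices give per-step speeds around 3 km h⁻¹ in
transit and below 2 km h⁻¹ in ARS, realistic for humpback whales.
Process noise is drawn isotropically in kilometres in a local tangent
plane and converted to degrees with latitude-dependent scaling, so the
simulation is undistorted across the 20–40° S study band.  Longitudes
are emitted in [0, 360) because the study region straddles the
antimeridian.

**Observation process.** Fix times are a Poisson process (default 4
fixes/day).  Each fix draws a location class from a configurable mix
dominated by the poor classes (as real Argos data are) and a Student-t
position error with a class-specific scale.  Argos does not publish
per-class error magnitudes; the defaults (class 3 ≈ 0.3 km up to class
B ≈ 10 km, ν between 4 and 2) are literature-typical and
configuration-exposed, never asserted.  Class-Z fixes are corrupted at a
300-km scale so that the class-Z filter has real work to do.

**Bathymetry.** Rasters are a flat abyssal floor plus Gaussian
seamounts, `depth(r) = floor + (summit − floor) exp(−r²/2ρ²)`;
overlapping bumps combine by taking the shallowest.  The Gaussian form
gives closed-form isobath radii, which the tests exploit.  For habitat
experiments with a known answer, `bathymetry_for_tracks` centres one
seamount under every sustained (≥ 4-step) ARS bout, so search behaviour
happens over shallow features by construction.

What the generator does **not** emulate: tag failure and shedding
physics (tag life is just a duration), spatially structured behaviour
(states switch by a Markov chain, not in response to the environment),
fix-density dependence on behaviour, and ocean currents.  Passing tests
therefore demonstrate estimator correctness under the stated model, not
robustness to every way real tags misbehave.

## Speed filtering

Class-Z fixes are dropped, then each whale's track is filtered so no
consecutive retained pair implies more than 12 km h⁻¹ (haversine
distances on a 6371-km sphere; the ellipsoid correction is far below
Argos noise).  The committed semantics are **maximal retention**: the
filter keeps a largest subset whose consecutive speeds all satisfy the
bound, found exactly by an O(n²) dynamic program over valid
subsequences (ties resolved deterministically towards later fixes).  We
prefer this to the McConnell-style greedy deletion rules used by some
GIS packages because it is directly checkable against an exhaustive
oracle — and because greedy deletion measurably strands retainable
fixes on about 1% of Argos-like tracks.  Exact duplicate timestamps
with conflicting positions keep the more accurate class (with a
warning); a zero time gap between distinct positions implies infinite
speed and forces a removal.  Filtering is idempotent, and raising the
threshold never removes more fixes.

## The switching state-space model

Latent 12-h positions follow the first-difference correlated random
walk written in the README; the first displacement, which has no
predecessor, gets a vague N(0, 1°²) prior.  Observations enter by
linear time-interpolation between the bracketing grid positions with
per-coordinate Student-t errors at the class scales above (kilometres
converted to degrees at the track's mean latitude).  The grid is
anchored at each whale's first retained fix; a track must have ≥ 8
fixes spanning ≥ 2 grid intervals.

**Priors and identification.**  The two states are identified as
"transit = faster and straighter" through prior support, following the
established switching-DCRW practice: (γ₁, γ₂) uniform on the ordered
region 0 < γ₂ < γ₁ < 1; θ₁ ~ U(−π/4, π/4); θ₂ ~ U(π/2, 3π/2) (course
reversals); α₁, α₂ ~ Beta(1, 1); half-Cauchy(1°) on the process SDs and
U(−1, 1) on their correlation.  Two fully exchangeable states were
tried first and fail in an instructive way: on a single-behaviour track
the labels become coin flips, and an anti-persistent mode (states
alternating every 12 h with α ≈ 0.1) attains essentially the same
marginal likelihood while destroying the behavioural classification.
The support constraints remove both degeneracies without informative
densities.

**Sampler.**  Metropolis-within-Gibbs, natively implemented:

* *Latent positions* — vectorised single-site random-walk Metropolis
  over three interleaved colour groups; sites three apart are
  conditionally independent because the process dependence spans two
  steps, so a whole group updates in a handful of array operations.
* *Movement parameters and switch probabilities* — random-walk
  Metropolis (logit scale for the α's, log scale for the SDs) accepted
  against the **marginal** likelihood with states summed out by the HMM
  forward algorithm.  Conditioning on sampled labels instead lets the
  chain pin itself into degenerate label modes; collapsing is the
  standard remedy and targets the same posterior.  Under the
  half-Cauchy/uniform priors there is no conjugate update for Σ, so it
  shares the Metropolis block.
* *States* — one forward-filtering backward-sampling draw per
  iteration at the current parameters.

Proposal scales adapt towards ~30% acceptance during burn-in only.
Two chains with over-dispersed starts run by default; split-R̂ is
reported per movement parameter and a value above 1.1 warns (it does
not fail — matching how convergence is treated in applied practice).
Runs are reproducible: all randomness derives from the run seed plus a
CRC of the whale identifier, so per-whale fits are order-independent.

**Classification.**  The behaviour index of a grid point is the mean of
its state draws over all retained draws of all chains (the first two
grid points, which precede the first modelled step, carry the first
step's state).  Locations are labelled transit below 1.25 and ARS above
1.75, with the boundaries themselves classified uncertain — the
conservative reading of the strict inequalities.  Uncertain locations
are excluded from the habitat comparison.

**What to expect of state recovery.**  With well-separated modes
(γ = 0.85/0.15) on 120-day tracks at reduced MCMC (8000/4000/5),
posterior-mean γ₁ lands within ±0.05 of truth and classification
accuracy excluding uncertain is 0.8–0.95.  Individual 60-day tracks are
noticeably seed-sensitive: with ~120 grid steps the posterior can
honestly remain uncertain for most locations.  Note also that even a
noiseless observer cannot push the per-location transit probability to
1 everywhere on a pure-transit track: the process noise occasionally
produces true course reversals, and the posterior correctly assigns
those steps non-trivial ARS mass.  Aggregate summaries (fractions of
draws, pooled accuracies) are therefore the meaningful quantities.

## Metrics

Distances are sums of consecutive great-circle legs over the 12-h
locations ("minimum total distance").  Mean speed is the mean of
per-segment speeds, which on the regular grid equals total distance
over elapsed time exactly; it is "not estimated" below 10 locations.
Reported speeds round half-up to one decimal, matching the published
summary-table format.  The reconstruction used for the published worked
examples — equal 12-h meridional legs covering the printed distance in
the printed duration — reproduces every printed mean speed that is
consistent with the distance/time identity (9 of 34 rows; the others
evidently involve gap handling the publication does not specify).

Migration onset is operationalised bathymetrically: the first location
over water deeper than 1000 m whose next four locations (≈ 2 days) all
stay deeper.  The geographic "left the southern lagoon" component of
the published definition is not checkable on synthetic data and is
deliberately out of scope; both the isobath and the sustain length are
configuration-exposed.  Segments spanning the onset count as migration.

Speed comparisons use per-segment speeds as observations (a per-whale
aggregation would leave residual degrees of freedom far below those the
original analysis reports), in a fixed-effects two-way ANOVA of
reproductive category × phase with Type-II sums of squares — the
appropriate choice for the unbalanced designs tracking data produce.
Empty cells drop the interaction with a warning; a single-level factor
collapses to one-way.  Degenerate inputs with zero variation report
F = 0 by convention.  The Newman–Keuls post hoc orders group means and
steps down the studentized range, declaring ranges nested inside a
non-significant range non-significant without testing; under the
complete null its family-wise error equals the nominal level because
any rejection must pass the full-range gate (verified by simulation).

## Occupancy

The occupancy grid lives in a cylindrical equal-area projection centred
on the data (standard parallel at the median latitude), so every
10 × 10 km cell covers exactly 100 km² of sphere; implemented from the
closed form rather than a projection library.  Cells are half-open with
the lower-left edge inclusive; a whale revisiting a cell counts once in
its visitor count.  Occupancy is (positions × 12 h) / 24 / visitors, in
days/whale, and by construction the grid conserves total tracked time:
Σ days/whale × visitors = half the location count.  Residence time at a
named feature is computed from maximal runs of consecutive 12-h
locations within the association radius (default 50 km, the published
proximity radius; the original's radius for "remained associated" is
unstated), each run contributing run-length × 0.5 days.

## Habitat

Depth is bilinear interpolation of the raster; isobaths are
marching-squares level sets of the depth field, and the distance to an
isobath is the minimum over contour segments of the point-to-segment
distance in a tangent plane at the query point (adequate at the
few-hundred-km scales involved; errors stay below one raster cell near
the contour).  The nearest contour **anywhere** is used, not the
nearest within a named feature.  Depth magnitudes are reported positive
in summaries, ETOPO-style negative-down in storage.  The ARS/transit
comparison is a one-way ANOVA per covariate; with only two groups
F = t² exactly, which the tests assert.

## Pipeline

`pipeline.run` chains the stages, writes every artefact as CSV/JSON
plus a manifest with the config digest, seed and package version, and
is bit-reproducible at fixed seed (timestamps aside).  Whales are
fitted independently, so results do not depend on iteration order.
Tracks too short to fit are skipped with a logged warning rather than
aborting the fleet.

## Problem sizes used in the shipped experiments

The package's own validation experiments (test suite and acceptance
script) use fleets of 3–5 whales, 60–120-day tracks and reduced MCMC
runs of 4000–8000 iterations with two chains — enough for the
quantities asserted (signs, bookkeeping identities, recovery within
stated tolerances) while keeping a full run in minutes on one core.
The 40000/20000/10 default of `MCMCConfig` reproduces the published
analysis configuration and is what production fits should use.

## Known limitations

* The observation-error class table is fixed, not estimated; a real
  deployment could estimate scales hierarchically.
* One whale at a time: no hierarchical pooling of movement parameters
  across individuals (the published analysis also fitted per
  individual).
* The behaviour process is a homogeneous Markov chain; no covariate- or
  habitat-dependent switching.
* Isobath distances are only as good as the raster resolution, and the
  tangent-plane segment distance degrades slowly for contours thousands
  of kilometres away.
* The migration-onset rule is purely bathymetric; tracks that hug a
  shelf southwards will trigger late.
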