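# whaletrack

Analysis of Argos satellite-telemetry tracks of humpback whales
(*Megaptera novaeangliae*) on a South Pacific breeding ground and their
southbound migration: cleaning of raw satellite fixes, Bayesian
switching state-space modelling of movement with behavioural-mode
classification, migration and speed metrics, occupancy-time gridding,
and comparison of the bathymetric habitat used in the two behavioural
modes (notably residency over seamounts).

The package is aimed at movement ecologists working with Argos-tracked
marine megafauna.  Because tag data of this kind are rarely deposited,
every stage is driven by a first-class synthetic-data generator that
emulates the statistical structure the analysis assumes, so the whole
pipeline can be exercised — and its estimators validated — against known
ground truth.

## The model

Raw Argos fixes carry a location class (3, 2, 1, 0, A, B, Z in
descending accuracy; Z is invalid).  After dropping class Z and removing
fixes implying speeds above 12 km h⁻¹ (the upper bound of reported
humpback swimming speeds), the track is modelled with a two-state
switching first-difference correlated random walk.  Latent positions
x_t on a regular 12-h grid evolve as

    x_t − x_{t−1} = γ_{b_t} T(θ_{b_t}) (x_{t−1} − x_{t−2}) + e_t,
    e_t ~ N₂(0, Σ),

where T(θ) is a rotation, γ ∈ [0,1] the displacement persistence, and
the behavioural state b_t ∈ {1 = transit, 2 = area-restricted search}
follows a two-state Markov chain with stay probabilities α₁, α₂.  A fix
observed a fraction w into a grid interval satisfies

    y = (1 − w) x_t + w x_{t+1} + ε,

with ε Student-t distributed per coordinate at a fixed class-specific
scale.  Transit is identified as the faster, straighter mode (γ₂ < γ₁
by prior construction; θ₁ near 0, θ₂ centred on course reversal).
Inference is by Metropolis-within-Gibbs MCMC — by default 40 000
iterations with the first 20 000 discarded as burn-in and one of every
10 samples retained, i.e. 2000 draws per chain.  Each 12-h location is
classified from the posterior-mean state b̄: transit if b̄ < 1.25, ARS
if b̄ > 1.75, uncertain otherwise.

Downstream, the regularized locations feed: per-whale distance/speed
summaries (speeds split into breeding-ground and migratory phases, the
onset of migration being a sustained crossing of the 1000-m isobath);
10 × 10 km occupancy-time grids in days/whale
((positions × 12 h) / 24 / individuals); consecutive residence times
near named features; and one-way ANOVAs of depth and isobath distances
between ARS and transit locations.

## Worked example

```python
from whaletrack import (SimulationConfig, MCMCConfig, simulate_true_track,
                        simulate_argos_fixes, filter_fixes, fit_sssm, regularize)
from whaletrack.metrics import mean_speed_kmh, round_half_up, track_distance_km

cfg = SimulationConfig(n_whales=1, duration_days=120, gamma=(0.85, 0.15), seed=1)
track = simulate_true_track(cfg, "W1")            # ground truth
fixes = simulate_argos_fixes(track, cfg)          # noisy, irregular Argos fixes
kept, report = filter_fixes(fixes, vmax_kmh=12.0)
print(report)
# FilterReport(n_input=457, n_removed_lcz=22, n_removed_speed=62, n_retained=373)

draws = fit_sssm(kept, MCMCConfig(n_samples=8000, n_burn=4000, thin=5,
                                  n_chains=2, seed=101))
locs = regularize(draws)                          # 12-h posterior-mean locations
print(locs["mode"].value_counts().to_dict())
# {'transit': 116, 'uncertain': 84, 'ARS': 37}
print(track_distance_km(locs), round_half_up(mean_speed_kmh(locs)))
# 6980 km, 2.5 km/h
```

The fit recovers the generator's movement parameters (posterior means
γ₁ = 0.81 against a truth of 0.85, γ₂ = 0.10 against 0.15, α₁ = 0.92
against 0.95 in this run) and classifies the behavioural state of 91% of
non-uncertain locations correctly against the simulated truth.  The
`whaletrack` command exposes the same stages as `simulate`,
`preprocess`, `fit` and `run` subcommands.

## Layout

- `whaletrack.synthetic` — two-state track simulator, Argos-like fix
  generator, seamount bathymetry builder
- `whaletrack.preprocess` — class-Z removal and the 12 km/h speed filter
- `whaletrack.sssm` — the switching DCRW sampler, regularization and
  mode classification
- `whaletrack.metrics` — distances, speeds, migration onset, two-factor
  ANOVA and Newman–Keuls post hoc
- `whaletrack.occupancy` — equal-area occupancy grids and residence times
- `whaletrack.habitat` — depth/isobath covariates and the mode contrast
- `whaletrack.pipeline` / `whaletrack.cli` — one-command orchestration

See `docs/methods.md` for the modelling assumptions, priors, numerical
choices and known limitations.
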