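"""Shared fixtures.

The expensive MCMC fits are session-scoped so several tests can share
one sampler run.  All randomness is seeded; the suite is deterministic.
"""

import warnings

import numpy as np
import pandas as pd
import pytest

from whaletrack import (MCMCConfig, SimulationConfig, filter_fixes, fit_sssm,
                        simulate_argos_fixes, simulate_true_track)


def make_fixes_df(hours, lon, lat, lc="1", ptt="X1"):
    """Hand-built fixes table from arrays of hours/positions."""
    t0 = pd.Timestamp("2011-08-01T00:00:00", tz="UTC")
    n = len(hours)
    return pd.DataFrame({
        "ptt": ptt,
        "time": t0 + pd.to_timedelta(np.asarray(hours, dtype=float), unit="h"),
        "lc": [lc] * n if isinstance(lc, str) else list(lc),
        "lon": np.asarray(lon, dtype=float),
        "lat": np.asarray(lat, dtype=float),
    })


@pytest.fixture(scope="session")
def two_state_fit():
    """A 60-day two-state track with well-separated modes, fitted at
    reduced MCMC; returns (true_track, filtered_fixes, draws)."""
    cfg = SimulationConfig(n_whales=1, duration_days=60, gamma=(0.85, 0.15),
                           seed=11)
    track = simulate_true_track(cfg, "W1")
    fixes = simulate_argos_fixes(track, cfg)
    kept, _ = filter_fixes(fixes)
    mcmc = MCMCConfig(n_samples=4000, n_burn=2000, thin=5, n_chains=2, seed=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        draws = fit_sssm(kept, mcmc)
    return track, kept, draws


@pytest.fixture(scope="session")
def single_state_fit():
    """A pure-transit (absorbing chain) 60-day track, fitted at reduced MCMC."""
    cfg = SimulationConfig(n_whales=1, duration_days=60, gamma=(0.85, 0.15),
                           switch_prob=(1.0, 0.95), seed=21)
    track = simulate_true_track(cfg, "W1")
    fixes = simulate_argos_fixes(track, cfg)
    kept, _ = filter_fixes(fixes)
    mcmc = MCMCConfig(n_samples=4000, n_burn=2000, thin=5, n_chains=2, seed=9)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        draws = fit_sssm(kept, mcmc)
    return track, kept, draws
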