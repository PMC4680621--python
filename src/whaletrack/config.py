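"""Configuration objects and the Argos location-class tables.

Argos location classes, in descending order of positional accuracy, are
3, 2, 1, 0, A, B and Z; Z flags invalid fixes.  Argos does not publish a
single authoritative error magnitude per class, so the per-class error
scales below are literature-typical values (class 3 a few hundred metres,
class B around ten kilometres) and are configuration-exposed rather than
asserted anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


class ConfigError(ValueError):
    """Raised when a configuration field is invalid; names the field."""


#: Argos location classes in descending order of accuracy.
LC_CLASSES = ("3", "2", "1", "0", "A", "B", "Z")

#: Isotropic observation-error scale per class, km (Z is a corrupted fix).
DEFAULT_LC_ERROR_KM = {
    "3": 0.3, "2": 0.7, "1": 1.5, "0": 4.0, "A": 6.0, "B": 10.0, "Z": 300.0,
}

#: Student-t degrees of freedom of the observation error per class.  Heavy
#: tails for the poor classes absorb the occasional wild Argos fix.
DEFAULT_LC_DF = {
    "3": 4.0, "2": 4.0, "1": 3.0, "0": 2.5, "A": 2.5, "B": 2.0, "Z": 2.0,
}

#: Default class mix of received fixes (most Argos fixes are low quality).
DEFAULT_LC_PROBS = (0.06, 0.09, 0.13, 0.20, 0.24, 0.25, 0.03)


def _check_prob(name, value, open_interval=False):
    lo_ok = value > 0.0 if open_interval else value >= 0.0
    hi_ok = value < 1.0 if open_interval else value <= 1.0
    if not (lo_ok and hi_ok):
        raise ConfigError(f"{name} must lie in {'(0,1)' if open_interval else '[0,1]'}, got {value}")


@dataclass
class SimulationConfig:
    """Ground-truth simulation settings for a fleet of tagged whales.

    The defaults caricature the two behavioural modes the movement model
    assumes: a fast, persistent "transit" mode (index 1) and a slow,
    tortuous "area-restricted search" mode (index 2).  With the default
    process noise of 0.15 degrees (~17 km) per 12-h step this yields
    per-step speeds around 3 km/h in transit and under 2 km/h in ARS,
    realistic for humpback whales.

    Parameters
    ----------
    gamma : pair of floats in [0, 1]
        Displacement persistence per state (transit, ARS).
    theta : pair of floats, radians
        Mean turn angle per state.
    sigma_proc : float
        Process noise SD per step, in degrees-of-latitude equivalent
        (applied isotropically in km in a local tangent plane).
    switch_prob : pair of floats in (0, 1)
        Markov stay probabilities (P(stay transit), P(stay ARS)).
    argos_rate_per_day : float
        Mean number of received Argos fixes per day (Poisson process).
    lc_probs : 7-tuple
        Probability of each location class 3,2,1,0,A,B,Z; sums to 1.
    lc_error_km : mapping
        Per-class isotropic observation error scale, km.
    """

    n_whales: int = 3
    duration_days: float = 60.0
    step_hours: float = 12.0
    gamma: tuple = (0.8, 0.2)
    theta: tuple = (0.0, 0.0)
    sigma_proc: float = 0.15
    switch_prob: tuple = (0.95, 0.95)
    argos_rate_per_day: float = 4.0
    lc_probs: tuple = DEFAULT_LC_PROBS
    lc_error_km: dict = field(default_factory=lambda: dict(DEFAULT_LC_ERROR_KM))
    lc_df: dict = field(default_factory=lambda: dict(DEFAULT_LC_DF))
    start_lon: float = 167.0
    start_lat: float = -22.5
    start_scatter_deg: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_whales < 1:
            raise ConfigError(f"n_whales must be >= 1, got {self.n_whales}")
        if self.duration_days * 24.0 < 2 * self.step_hours:
            raise ConfigError("duration_days must span at least 2 steps")
        for i, g in enumerate(self.gamma, 1):
            _check_prob(f"gamma[{i}]", g)
        for i, a in enumerate(self.switch_prob, 1):
            # 1.0 allowed: an absorbing chain is a useful degenerate case
            if not 0.0 < a <= 1.0:
                raise ConfigError(f"switch_prob[{i}] must lie in (0, 1], got {a}")
        if len(self.lc_probs) != len(LC_CLASSES):
            raise ConfigError("lc_probs must have 7 entries (classes 3,2,1,0,A,B,Z)")
        if any(p < 0 for p in self.lc_probs) or not math.isclose(sum(self.lc_probs), 1.0, abs_tol=1e-9):
            raise ConfigError(f"lc_probs must be non-negative and sum to 1, got {self.lc_probs}")
        if self.sigma_proc < 0:
            raise ConfigError(f"sigma_proc must be >= 0, got {self.sigma_proc}")
        if self.argos_rate_per_day <= 0:
            raise ConfigError(f"argos_rate_per_day must be > 0, got {self.argos_rate_per_day}")


@dataclass
class MCMCConfig:
    """MCMC run-length settings for the switching state-space model.

    The defaults — 40 000 iterations, the first 20 000 discarded as burn-in,
    then one of every 10 samples retained — leave exactly 2000 posterior
    draws per chain.
    """

    n_samples: int = 40000
    n_burn: int = 20000
    thin: int = 10
    n_chains: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_burn >= self.n_samples:
            raise ConfigError("n_burn must be smaller than n_samples")
        if self.thin < 1:
            raise ConfigError(f"thin must be >= 1, got {self.thin}")
        if self.n_chains < 1:
            raise ConfigError(f"n_chains must be >= 1, got {self.n_chains}")

    @property
    def retained_per_chain(self) -> int:
        """Number of posterior draws kept per chain after burn-in and thinning."""
        return (self.n_samples - self.n_burn + self.thin - 1) // self.thin
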