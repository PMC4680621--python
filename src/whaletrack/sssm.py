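"""Bayesian switching state-space model for Argos tracks.

The movement model is a two-state switching first-difference correlated
random walk (DCRW).  Latent positions ``x_t`` live on a regular 12-h grid
anchored at the first retained fix.  Displacements evolve as

    x_t - x_{t-1} = gamma_{b_t} T(theta_{b_t}) (x_{t-1} - x_{t-2}) + e_t,

where ``T`` is a 2x2 rotation, ``e_t`` is bivariate normal with
covariance built from (sigma_lon, sigma_lat, rho), and the behavioural
state ``b_t`` (1 = transit, 2 = area-restricted search) follows a
two-state Markov chain with stay probabilities (alpha1, alpha2).  Each
Argos fix observed at a time fraction ``w`` into a grid interval relates
to the states linearly,

    y = (1 - w) x_t + w x_{t+1} + eps,

with ``eps`` Student-t distributed per coordinate at a fixed
class-specific scale and degrees of freedom.

Inference is Metropolis-within-Gibbs:

* behavioural states by forward-filtering backward-sampling (FFBS);
* latent positions by vectorised single-site random-walk Metropolis over
  three interleaved colour groups (sites three apart are conditionally
  independent because the process dependence spans two steps);
* gamma/theta/Sigma by random-walk Metropolis with adaptation during
  burn-in; switch probabilities by their conjugate Beta update.

Priors follow the movement literature's identification of the two modes
(transit = faster, straighter): (gamma1, gamma2) uniform over the ordered
region 0 < gamma2 < gamma1 < 1; theta1 ~ U(-pi/4, pi/4) (transit is
near-straight) while theta2 ~ U(pi/2, 3pi/2) (course reversals dominate
area-restricted search); alpha ~ Beta(1,1); half-Cauchy(1 deg) on the
process SDs; rho ~ U(-1,1).  These support constraints make the labels
identified by construction, so the classification is invariant to chain
initialisation; a fully exchangeable prior would leave a
single-behaviour track with arbitrary coin-flip labels.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .config import DEFAULT_LC_DF, DEFAULT_LC_ERROR_KM, MCMCConfig
from .geo import KM_PER_DEG

__all__ = [
    "GRID_HOURS",
    "InsufficientDataError",
    "PosteriorDraws",
    "classify_mode",
    "fit_sssm",
    "regularize",
]

#: spacing of the regular prediction grid, hours
GRID_HOURS = 12.0

#: behavioural classification thresholds on the posterior-mean state
TRANSIT_MAX = 1.25
ARS_MIN = 1.75

_PARAM_NAMES = ("gamma1", "gamma2", "theta1", "theta2",
                "sigma_lon", "sigma_lat", "rho", "alpha1", "alpha2")


class InsufficientDataError(ValueError):
    """Track too short to fit the state-space model."""


@dataclass
class PosteriorDraws:
    """Retained MCMC draws for one whale.

    ``states`` are 1/2 labels for the DCRW steps (grid indices 2..N-1);
    ``positions`` are the latent positions at all N grid points.
    """

    whale_id: str
    grid_times: pd.DatetimeIndex
    params: pd.DataFrame            # columns: chain + _PARAM_NAMES
    states: np.ndarray              # (n_draws, N-2) int8, values 1/2
    positions: np.ndarray           # (n_draws, N, 2) lon/lat degrees
    rhat: dict = field(default_factory=dict)
    config: MCMCConfig = None

    @property
    def n_draws(self) -> int:
        return len(self.params)


def classify_mode(b_mean):
    """Classify the posterior-mean behaviour index.

    Strictly below 1.25 is transit, strictly above 1.75 is ARS, anything
    else (boundaries included) is uncertain.  Values outside [1, 2] are a
    caller error.
    """
    b = np.asarray(b_mean, dtype=float)
    if np.any((b < 1.0) | (b > 2.0)):
        raise ValueError(f"behaviour index outside [1, 2]: {b[(b < 1) | (b > 2)][:5]}")
    out = np.where(b < TRANSIT_MAX, "transit",
                   np.where(b > ARS_MIN, "ARS", "uncertain"))
    return out.item() if np.ndim(b_mean) == 0 else out


# ---------------------------------------------------------------------------
# sampler internals
# ---------------------------------------------------------------------------

def _bvn_logpdf(ux, uy, sl, sa, rho):
    """Elementwise bivariate normal log-density of residuals (ux, uy)."""
    om = 1.0 - rho * rho
    q = (ux * ux / (sl * sl) - 2.0 * rho * ux * uy / (sl * sa) + uy * uy / (sa * sa)) / om
    return -0.5 * q - np.log(2.0 * np.pi * sl * sa) - 0.5 * np.log(om)


class _Model:
    """Precomputed data and likelihood pieces for one track's sampler."""

    def __init__(self, y, t_idx, w, obs_scale, obs_df, n_grid, d1_sd=1.0,
                 cauchy_scale=1.0):
        self.y = y                  # (n_obs, 2)
        self.t_idx = t_idx          # (n_obs,) int, grid interval index
        self.w = w[:, None]         # (n_obs, 1) in [0, 1)
        self.s = obs_scale          # (n_obs, 2) degrees
        self.nu = obs_df[:, None]   # (n_obs, 1)
        self.N = n_grid
        self.d1_var = d1_sd ** 2
        self.cauchy = cauchy_scale
        self.obs_const = (gammaln((self.nu + 1) / 2) - gammaln(self.nu / 2)
                          - 0.5 * np.log(np.pi * self.nu) - np.log(self.s))

    def step_terms(self, X, S, gamma, theta, sl, sa, rho):
        """(per-step log-likelihoods for steps t=2..N-1, first-difference term)."""
        D = np.diff(X, axis=0)
        g = gamma[S]
        c = np.cos(theta)[S]
        sn = np.sin(theta)[S]
        px = g * (c * D[:-1, 0] - sn * D[:-1, 1])
        py = g * (sn * D[:-1, 0] + c * D[:-1, 1])
        ll = _bvn_logpdf(D[1:, 0] - px, D[1:, 1] - py, sl, sa, rho)
        ll_d1 = -0.5 * (D[0] ** 2).sum() / self.d1_var
        return ll, ll_d1

    def state_emissions(self, X, gamma, theta, sl, sa, rho):
        """Per-step log-likelihood under each state: (N-2, 2)."""
        D = np.diff(X, axis=0)
        E = np.empty((self.N - 2, 2))
        for k in range(2):
            c, sn = np.cos(theta[k]), np.sin(theta[k])
            px = gamma[k] * (c * D[:-1, 0] - sn * D[:-1, 1])
            py = gamma[k] * (sn * D[:-1, 0] + c * D[:-1, 1])
            E[:, k] = _bvn_logpdf(D[1:, 0] - px, D[1:, 1] - py, sl, sa, rho)
        return E

    def obs_terms(self, X):
        """Per-observation log-likelihood (n_obs,)."""
        if len(self.y) == 0:
            return np.zeros(0)
        pred = (1.0 - self.w) * X[self.t_idx] + self.w * X[self.t_idx + 1]
        r = (self.y - pred) / self.s
        ll = self.obs_const - 0.5 * (self.nu + 1.0) * np.log1p(r * r / self.nu)
        return ll.sum(axis=1)

    def sigma_logprior(self, sl, sa):
        # half-Cauchy(scale) on each SD; constant terms dropped
        return (-np.log1p((sl / self.cauchy) ** 2)
                - np.log1p((sa / self.cauchy) ** 2))


def _forward_loglik(E, alpha):
    """Log marginal likelihood of the steps with states summed out (HMM
    forward algorithm, scaled)."""
    n = E.shape[0]
    a1, a2 = alpha
    mx = E.max(axis=1)
    W = np.exp(E - mx[:, None])
    ll = mx.sum()
    f0 = 0.5 * W[0, 0]
    f1 = 0.5 * W[0, 1]
    tot = f0 + f1
    ll += np.log(tot)
    f0 /= tot
    f1 /= tot
    for j in range(1, n):
        p0 = (f0 * a1 + f1 * (1.0 - a2)) * W[j, 0]
        p1 = (f0 * (1.0 - a1) + f1 * a2) * W[j, 1]
        tot = p0 + p1
        ll += np.log(tot)
        f0 = p0 / tot
        f1 = p1 / tot
    return ll


def _ffbs(E, alpha, rng, S_out):
    """Forward-filter backward-sample the state sequence given emissions E."""
    n = E.shape[0]
    a1, a2 = alpha
    T11, T12, T21, T22 = a1, 1.0 - a1, 1.0 - a2, a2
    W = np.exp(E - E.max(axis=1, keepdims=True))
    f = np.empty((n, 2))
    f0 = 0.5 * W[0]
    f[0] = f0 / f0.sum()
    for j in range(1, n):
        p1 = (f[j - 1, 0] * T11 + f[j - 1, 1] * T21) * W[j, 0]
        p2 = (f[j - 1, 0] * T12 + f[j - 1, 1] * T22) * W[j, 1]
        tot = p1 + p2
        f[j, 0] = p1 / tot
        f[j, 1] = p2 / tot
    u = rng.random(n)
    S_out[n - 1] = 0 if u[n - 1] < f[n - 1, 0] else 1
    for j in range(n - 2, -1, -1):
        if S_out[j + 1] == 0:
            p0 = f[j, 0] * T11
            p1 = f[j, 1] * T21
        else:
            p0 = f[j, 0] * T12
            p1 = f[j, 1] * T22
        S_out[j] = 0 if u[j] * (p0 + p1) < p0 else 1
    return S_out


def _run_chain(model: _Model, n_iter, n_burn, thin, rng, init):
    """One MCMC chain; returns dict of retained arrays (unlabelled states 0/1)."""
    N = model.N
    X = init["X"].copy()
    gamma = np.asarray(init["gamma"], dtype=float).copy()
    theta = np.asarray(init["theta"], dtype=float).copy()
    sl, sa = float(init["sigma"][0]), float(init["sigma"][1])
    rho = 0.0
    alpha = np.asarray(init["alpha"], dtype=float).copy()
    S = rng.integers(0, 2, size=N - 2)

    n_keep = (n_iter - n_burn + thin - 1) // thin
    out_params = np.empty((n_keep, len(_PARAM_NAMES)))
    out_states = np.empty((n_keep, N - 2), dtype=np.int8)
    out_pos = np.empty((n_keep, N, 2))

    # adaptive proposal scales
    x_scale = np.full(3, max(0.02, float(np.median(model.s)) if model.s.size else 0.05))
    p_scale = {"gamma": 0.05, "theta": 0.15, "sigma": 0.12, "alpha": 0.8}
    x_acc = np.zeros(3)
    x_try = np.zeros(3)
    p_acc = {k: 0.0 for k in p_scale}
    p_try = {k: 0.0 for k in p_scale}

    m = np.arange(N - 2)
    t_idx = model.t_idx
    kept = 0

    for it in range(n_iter):
        # --- latent positions, three colour groups ------------------------
        ll0, d10 = model.step_terms(X, S, gamma, theta, sl, sa, rho)
        o0 = model.obs_terms(X)
        for color in range(3):
            G = np.arange(color, N, 3)
            Xp = X.copy()
            Xp[G] += rng.normal(0.0, x_scale[color], size=(len(G), 2))
            ll1, d11 = model.step_terms(Xp, S, gamma, theta, sl, sa, rho)
            o1 = model.obs_terms(Xp)
            dsite = np.zeros(N)
            # step term for grid step t=m+2 involves X[m], X[m+1], X[m+2]:
            # exactly one of those indices is in this colour group
            site = m + ((color - m) % 3)
            np.add.at(dsite, site, ll1 - ll0)
            if color <= 1:
                dsite[color] += d11 - d10
            if len(o0):
                off = (color - t_idx) % 3
                mask = off <= 1
                np.add.at(dsite, t_idx[mask] + off[mask], (o1 - o0)[mask])
            acc = np.log(rng.random(len(G))) < dsite[G]
            if acc.any():
                X[G[acc]] = Xp[G[acc]]
                ll0, d10 = model.step_terms(X, S, gamma, theta, sl, sa, rho)
                o0 = model.obs_terms(X)
            x_try[color] += len(G)
            x_acc[color] += acc.sum()

        # --- movement parameters, states integrated out -------------------
        # Collapsed Metropolis: the two-state labels are summed out by the
        # HMM forward algorithm, which lets gamma/theta/Sigma cross between
        # the mixture modes instead of being pinned by the current labels.
        E = model.state_emissions(X, gamma, theta, sl, sa, rho)
        cur_mll = _forward_loglik(E, alpha)

        for k in range(2):
            prop = gamma[k] + rng.normal(0.0, p_scale["gamma"])
            p_try["gamma"] += 1
            # flat prior on the ordered region 0 < gamma2 < gamma1 < 1
            lo, hi = (gamma[1], 1.0) if k == 0 else (0.0, gamma[0])
            if lo < prop < hi:
                g2 = gamma.copy()
                g2[k] = prop
                E_p = model.state_emissions(X, g2, theta, sl, sa, rho)
                new_mll = _forward_loglik(E_p, alpha)
                if np.log(rng.random()) < new_mll - cur_mll:
                    gamma, E, cur_mll = g2, E_p, new_mll
                    p_acc["gamma"] += 1

        for k in range(2):
            prop = theta[k] + rng.normal(0.0, p_scale["theta"])
            p_try["theta"] += 1
            if k == 0:
                # transit turns are near-straight by prior support
                if not -np.pi / 4 < prop < np.pi / 4:
                    continue
            else:
                # ARS turns centre on course reversal
                prop = (prop + np.pi) % (2 * np.pi) - np.pi
                if abs(prop) < np.pi / 2:
                    continue
            t2 = theta.copy()
            t2[k] = prop
            E_p = model.state_emissions(X, gamma, t2, sl, sa, rho)
            new_mll = _forward_loglik(E_p, alpha)
            if np.log(rng.random()) < new_mll - cur_mll:
                theta, E, cur_mll = t2, E_p, new_mll
                p_acc["theta"] += 1

        # Sigma block: random walk on (log sl, log sa, rho)
        prop_sl = sl * np.exp(rng.normal(0.0, p_scale["sigma"]))
        prop_sa = sa * np.exp(rng.normal(0.0, p_scale["sigma"]))
        prop_rho = rho + rng.normal(0.0, 0.06)
        p_try["sigma"] += 1
        if abs(prop_rho) < 0.995:
            E_p = model.state_emissions(X, gamma, theta, prop_sl, prop_sa, prop_rho)
            # prior + log-Jacobian of the log-parameterisation
            lp_new = (_forward_loglik(E_p, alpha)
                      + model.sigma_logprior(prop_sl, prop_sa)
                      + np.log(prop_sl) + np.log(prop_sa))
            lp_old = (cur_mll + model.sigma_logprior(sl, sa)
                      + np.log(sl) + np.log(sa))
            if np.log(rng.random()) < lp_new - lp_old:
                sl, sa, rho = prop_sl, prop_sa, prop_rho
                E, cur_mll = E_p, lp_new - (model.sigma_logprior(sl, sa)
                                            + np.log(sl) + np.log(sa))
                p_acc["sigma"] += 1

        # switch probabilities: collapsed logit random walk under the
        # flat Beta(1,1) prior (sampling them from the labels instead
        # feeds the label noise back and biases them towards 1/2)
        for k in range(2):
            logit = np.log(alpha[k] / (1.0 - alpha[k]))
            prop = 1.0 / (1.0 + np.exp(-(logit + rng.normal(0.0, p_scale["alpha"]))))
            prop = float(np.clip(prop, 1e-4, 1.0 - 1e-4))
            a2 = alpha.copy()
            a2[k] = prop
            p_try["alpha"] += 1
            new_mll = _forward_loglik(E, a2)
            jac = (np.log(prop * (1.0 - prop))
                   - np.log(alpha[k] * (1.0 - alpha[k])))
            if np.log(rng.random()) < new_mll - cur_mll + jac:
                alpha, cur_mll = a2, new_mll
                p_acc["alpha"] += 1

        # --- states by FFBS at the current parameters ---------------------
        _ffbs(E, alpha, rng, S)

        # --- adaptation (burn-in only) ------------------------------------
        if it < n_burn and (it + 1) % 100 == 0:
            for c in range(3):
                if x_try[c] > 0:
                    rate = x_acc[c] / x_try[c]
                    x_scale[c] *= np.exp(0.6 * (rate - 0.35))
            for k in p_scale:
                if p_try[k] > 0:
                    rate = p_acc[k] / p_try[k]
                    p_scale[k] = float(np.clip(p_scale[k] * np.exp(0.6 * (rate - 0.30)),
                                               1e-4, 2.0))
            x_acc[:] = 0
            x_try[:] = 0
            p_acc = {k: 0.0 for k in p_scale}
            p_try = {k: 0.0 for k in p_scale}

        # --- storage ------------------------------------------------------
        if it >= n_burn and (it - n_burn) % thin == 0:
            out_params[kept] = (gamma[0], gamma[1], theta[0], theta[1],
                                sl, sa, rho, alpha[0], alpha[1])
            out_states[kept] = S
            out_pos[kept] = X
            kept += 1

    if not np.isfinite(out_params).all():
        raise FloatingPointError(
            f"non-finite draw encountered; first offender at draw "
            f"{int(np.argwhere(~np.isfinite(out_params))[0, 0])}")
    return {"params": out_params[:kept], "states": out_states[:kept],
            "positions": out_pos[:kept]}


# ---------------------------------------------------------------------------
# public fitting interface
# ---------------------------------------------------------------------------

def _prepare(fixes: pd.DataFrame, error_km=None, error_df=None):
    fixes = fixes.sort_values("time", kind="stable").reset_index(drop=True)
    if len(fixes) < 8:
        raise InsufficientDataError(
            f"insufficient data: need >= 8 fixes, got {len(fixes)}")
    t0 = fixes["time"].iloc[0]
    hours = (fixes["time"] - t0).dt.total_seconds().to_numpy() / 3600.0
    span = hours[-1]
    if span < 2 * GRID_HOURS:
        raise InsufficientDataError(
            "insufficient data: track must span at least two 12-h grid intervals")
    n_grid = int(np.floor(span / GRID_HOURS)) + 1

    g = hours / GRID_HOURS
    t_idx = np.minimum(np.floor(g).astype(int), n_grid - 2)
    w = g - t_idx

    error_km = dict(DEFAULT_LC_ERROR_KM if error_km is None else error_km)
    error_df = dict(DEFAULT_LC_DF if error_df is None else error_df)
    lat0 = float(fixes["lat"].mean())
    scale_km = fixes["lc"].astype(str).map(error_km).to_numpy(dtype=float)
    nu = fixes["lc"].astype(str).map(error_df).to_numpy(dtype=float)
    s_lon = scale_km / (KM_PER_DEG * np.cos(np.radians(lat0)))
    s_lat = scale_km / KM_PER_DEG
    obs_scale = np.stack([s_lon, s_lat], axis=1)

    # work in a continuous longitude frame (tracks may straddle 180 E/W)
    lon = np.degrees(np.unwrap(np.radians(fixes["lon"].to_numpy(dtype=float))))
    y = np.stack([lon, fixes["lat"].to_numpy(dtype=float)], axis=1)
    grid_times = t0 + pd.to_timedelta(np.arange(n_grid) * GRID_HOURS, unit="h")
    return y, t_idx, w, obs_scale, nu, n_grid, pd.DatetimeIndex(grid_times)


def _initial_positions(y, t_idx, w, n_grid, rng, jitter):
    tobs = t_idx + w
    grid = np.arange(n_grid, dtype=float)
    X = np.stack([np.interp(grid, tobs, y[:, 0]),
                  np.interp(grid, tobs, y[:, 1])], axis=1)
    return X + rng.normal(0.0, jitter, size=X.shape)


def fit_sssm(fixes: pd.DataFrame, mcmc: MCMCConfig | None = None,
             error_km=None, error_df=None) -> PosteriorDraws:
    """Fit the switching DCRW to one whale's filtered fixes by MCMC.

    Parameters
    ----------
    fixes : DataFrame with columns ptt, time (UTC), lc, lon, lat for one whale.
    mcmc : MCMCConfig, run-length settings (40000/20000/10, 2 chains by default).
    error_km, error_df : optional per-class Argos error scale (km) and
        Student-t degrees of freedom; defaults are the package's class table.

    Returns the retained posterior draws, relabelled so gamma1 > gamma2
    (transit = faster, straighter mode), with split-R-hat convergence
    diagnostics per movement parameter.
    """
    mcmc = mcmc or MCMCConfig()
    if fixes["ptt"].nunique() > 1:
        raise ValueError("fit_sssm expects fixes of a single whale")
    whale_id = str(fixes["ptt"].iloc[0])
    y, t_idx, w, obs_scale, nu, n_grid, grid_times = _prepare(fixes, error_km, error_df)
    model = _Model(y, t_idx, w, obs_scale, nu, n_grid)

    ss = np.random.SeedSequence([int(mcmc.seed) % (2**31),
                                 zlib.crc32(whale_id.encode())])
    child_seeds = ss.spawn(mcmc.n_chains)

    # over-dispersed starts
    starts = [
        {"gamma": (0.7, 0.3), "theta": (0.0, np.pi), "alpha": (0.85, 0.85), "jitter": 0.0},
        {"gamma": (0.9, 0.1), "theta": (0.3, 2.2), "alpha": (0.7, 0.7), "jitter": 0.05},
        {"gamma": (0.6, 0.4), "theta": (-0.3, -2.2), "alpha": (0.9, 0.6), "jitter": 0.02},
    ]
    sig0 = max(0.02, float(np.median(np.abs(np.diff(y[:, 1])))) or 0.05)

    chains = []
    for c in range(mcmc.n_chains):
        rng = np.random.default_rng(child_seeds[c])
        st = starts[c % len(starts)]
        init = {
            "X": _initial_positions(y, t_idx, w, n_grid, rng, st["jitter"]),
            "gamma": st["gamma"], "theta": st["theta"],
            "sigma": (sig0, sig0), "alpha": st["alpha"],
        }
        chains.append(_run_chain(model, mcmc.n_samples, mcmc.n_burn,
                                 mcmc.thin, rng, init))

    # assemble (gamma1 > gamma2 holds by prior support; labels identified)
    params = np.concatenate([ch["params"] for ch in chains])
    states = np.concatenate([ch["states"] for ch in chains]).astype(np.int8)
    positions = np.concatenate([ch["positions"] for ch in chains])
    chain_ids = np.concatenate([np.full(len(ch["params"]), c)
                                for c, ch in enumerate(chains)])

    pdf = pd.DataFrame(params, columns=list(_PARAM_NAMES))
    pdf.insert(0, "chain", chain_ids)

    rhat = _split_rhat(pdf) if mcmc.n_chains > 1 else {}
    return PosteriorDraws(whale_id, grid_times, pdf, states + 1, positions,
                          rhat, mcmc)


def _split_rhat(pdf: pd.DataFrame) -> dict:
    """Split-chain potential scale reduction factor per parameter."""
    out = {}
    chains = sorted(pdf["chain"].unique())
    n = min((pdf["chain"] == c).sum() for c in chains)
    n -= n % 2
    for name in _PARAM_NAMES:
        halves = []
        for c in chains:
            x = pdf.loc[pdf["chain"] == c, name].to_numpy()[:n]
            halves.extend([x[: n // 2], x[n // 2:]])
        arr = np.stack(halves)                      # (2*m chains, n/2 draws)
        nd = arr.shape[1]
        w = arr.var(axis=1, ddof=1).mean()
        b = nd * arr.mean(axis=1).var(ddof=1)
        out[name] = float(np.sqrt(((nd - 1) / nd * w + b / nd) / w)) if w > 0 else 1.0
    return out


def regularize(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior-mean 12-h locations with behavioural classification.

    One row per grid time from the first to the last fix: posterior-mean
    position, posterior-mean behaviour index ``b_mean`` in [1, 2] (the mean
    over all retained draws of all chains) and the discrete mode from the
    1.25/1.75 rule.  The first two grid points carry the first step's
    state.  Warns (does not fail) if any movement parameter has
    split-R-hat above 1.1.
    """
    bad = {k: v for k, v in draws.rhat.items() if np.isfinite(v) and v > 1.1}
    if bad:
        warnings.warn(f"convergence warning, split-R-hat > 1.1: {bad}", stacklevel=2)

    N = len(draws.grid_times)
    mean_pos = draws.positions.mean(axis=0)
    b_steps = draws.states.mean(axis=0)           # (N-2,)
    b_mean = np.empty(N)
    b_mean[2:] = b_steps
    b_mean[:2] = b_steps[0] if len(b_steps) else 1.0
    from .geo import wrap_lon

    return pd.DataFrame(
        {"whale_id": draws.whale_id,
         "time": draws.grid_times,
         "lon": wrap_lon(mean_pos[:, 0]),
         "lat": mean_pos[:, 1],
         "b_mean": b_mean,
         "mode": classify_mode(np.clip(b_mean, 1.0, 2.0))}
    )
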