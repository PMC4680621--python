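"""Track metrics: distances, speeds by phase and reproductive category,
migration-onset detection, and the speed ANOVAs.

Speeds are computed over the 12-h regularized locations, so the minimum
total distance divided by the elapsed time equals the mean of per-segment
speeds exactly.  A whale's speed is reported as "not estimated" (None)
when fewer than 10 locations are available.  Reported speeds are rounded
half-up to one decimal.

Migration onset is operationalised purely bathymetrically: the first
location over water deeper than the 1000-m isobath such that the next
``sustain_steps`` locations (about two days at 12-h spacing) all remain
deeper — i.e. the whale has crossed the isobath and keeps travelling over
deep water.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .geo import great_circle_km

__all__ = [
    "WhaleMeta",
    "round_half_up",
    "track_distance_km",
    "segment_speeds_kmh",
    "mean_speed_kmh",
    "detect_migration_onset",
    "assign_phases",
    "speed_summary",
    "two_factor_anova",
    "newman_keuls",
    "whale_summary",
]

MIN_LOCATIONS_FOR_SPEED = 10


@dataclass
class WhaleMeta:
    """Sex and reproductive category of one tagged whale.

    Categories: M (male), F (female without calf), MC (female with calf at
    deployment); MC implies sex F.
    """

    whale_id: str
    sex: str
    category: str
    social_group: str = ""

    def __post_init__(self):
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be M or F, got {self.sex!r}")
        if self.category not in ("M", "F", "MC"):
            raise ValueError(f"category must be M, F or MC, got {self.category!r}")
        if self.category == "MC" and self.sex != "F":
            raise ValueError("category MC implies sex F")


def round_half_up(x, decimals: int = 1) -> float:
    """Decimal round-half-up (1.25 -> 1.3 at one decimal), matching the
    formatting of the published per-whale summary tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _leg_km(locs: pd.DataFrame) -> np.ndarray:
    lon = locs["lon"].to_numpy(dtype=float)
    lat = locs["lat"].to_numpy(dtype=float)
    return great_circle_km(lon[:-1], lat[:-1], lon[1:], lat[1:])


def track_distance_km(locs: pd.DataFrame) -> float:
    """Minimum total distance: sum of consecutive great-circle legs."""
    if len(locs) < 2:
        raise ValueError("track distance needs at least 2 locations")
    return float(_leg_km(locs).sum())


def segment_speeds_kmh(locs: pd.DataFrame) -> np.ndarray:
    """Per-segment speeds (km/h) between consecutive locations."""
    if len(locs) < 2:
        return np.empty(0)
    dt_h = np.diff(locs["time"].astype("int64").to_numpy()) / 3.6e12
    return _leg_km(locs) / dt_h


def mean_speed_kmh(locs: pd.DataFrame):
    """Mean of per-segment speeds; None ("not estimated") for < 10 locations.

    On the regular 12-h grid this equals total distance / elapsed time.
    """
    if len(locs) < MIN_LOCATIONS_FOR_SPEED:
        return None
    return float(segment_speeds_kmh(locs).mean())


def detect_migration_onset(locs: pd.DataFrame, bathymetry, isobath_m: float = 1000.0,
                           sustain_steps: int = 4):
    """Time of the first sustained crossing into deep water, or None.

    The onset is the first location deeper than ``isobath_m`` whose next
    ``sustain_steps`` locations all remain deeper.  Raises if any location
    falls outside the bathymetry raster.
    """
    depth = np.atleast_1d(bathymetry.sample(locs["lon"].to_numpy(),
                                            locs["lat"].to_numpy()))
    deep = depth < -abs(isobath_m)
    n = len(deep)
    for i in range(n - sustain_steps):
        if deep[i] and deep[i + 1: i + 1 + sustain_steps].all():
            return locs["time"].iloc[i]
    return None


def assign_phases(locs: pd.DataFrame, onset) -> pd.Series:
    """Phase label per location: breeding before onset, migration at/after."""
    if onset is None:
        return pd.Series("breeding", index=locs.index, name="phase")
    return pd.Series(np.where(locs["time"] >= onset, "migration", "breeding"),
                     index=locs.index, name="phase")


def _segment_table(locs: pd.DataFrame, phase: pd.Series) -> pd.DataFrame:
    """Per-segment speeds with the phase of the segment's later endpoint
    (segments spanning the onset belong to migration)."""
    sp = segment_speeds_kmh(locs)
    return pd.DataFrame({"speed": sp, "phase": phase.to_numpy()[1:]})


def speed_summary(locs_by_whale: dict, meta: pd.DataFrame, onsets: dict) -> pd.DataFrame:
    """Mean +/- SD of per-segment speeds per (category, phase) group.

    ``locs_by_whale`` maps whale_id -> regularized locations; ``onsets``
    maps whale_id -> onset time or None.  Groups with no segments are
    absent from the output rather than reported as zero.
    """
    meta_idx = meta.set_index("whale_id")
    rows = []
    for wid, locs in locs_by_whale.items():
        if len(locs) < 2:
            continue
        seg = _segment_table(locs, assign_phases(locs, onsets.get(wid)))
        seg["category"] = meta_idx.loc[wid, "category"]
        seg["whale_id"] = wid
        rows.append(seg)
    if not rows:
        return pd.DataFrame(columns=["category", "phase", "mean_kmh", "sd_kmh", "n_segments"])
    segs = pd.concat(rows, ignore_index=True)
    out = (segs.groupby(["category", "phase"])["speed"]
           .agg(mean_kmh="mean", sd_kmh="std", n_segments="size")
           .reset_index())
    return out


# ---------------------------------------------------------------------------
# ANOVA and post hoc
# ---------------------------------------------------------------------------

def two_factor_anova(speeds, category, phase) -> pd.DataFrame:
    """Fixed-effects two-way ANOVA of segment speeds on reproductive
    category and migration phase (Type-II sums of squares for unbalanced
    designs).

    Returns a table with rows for each factor (and the interaction when
    estimable) holding sum_sq, df, F and p.  If any factor has a single
    level the model collapses to a one-way ANOVA on the other factor; if
    the design has empty cells the interaction is dropped with a warning.
    Degenerate data with zero residual variance report F = 0 when the
    factor sum of squares is also zero.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"speed": np.asarray(speeds, dtype=float),
                       "category": pd.Categorical(category),
                       "phase": pd.Categorical(phase)})
    factors = [f for f in ("category", "phase") if df[f].nunique() > 1]
    if not factors:
        raise ValueError("need at least one factor with two levels")
    if len(factors) == 1:
        formula = f"speed ~ C({factors[0]})"
    else:
        cells = pd.crosstab(df["category"], df["phase"])
        if (cells.to_numpy() == 0).any():
            warnings.warn("empty cells in the two-way design; "
                          "interaction term dropped", stacklevel=2)
            formula = "speed ~ C(category) + C(phase)"
        else:
            formula = "speed ~ C(category) * C(phase)"
    model = smf.ols(formula, data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        tab = sm.stats.anova_lm(model, typ=2)
    tab = tab.rename(index=lambda s: s.replace("C(", "").replace(")", ""))
    # degenerate factors (no variation beyond floating-point noise) -> F = 0
    scale = float(np.var(df["speed"])) * len(df) + 1.0
    zero_ss = tab["sum_sq"] <= 1e-12 * scale
    tab.loc[zero_ss, "F"] = 0.0
    tab.loc[zero_ss, "PR(>F)"] = 1.0
    tab.loc[tab.index == "Residual", ["F", "PR(>F)"]] = np.nan
    return tab


def _nk_recurse(i, j, order_means, order_ns, mse, dfe, alpha, results, tested):
    """Stepwise studentized-range recursion: a pair is tested only while
    every enclosing range is significant."""
    from scipy.stats import studentized_range

    if (i, j) in tested:
        return results[(i, j)]["significant"]
    span = j - i + 1
    se = np.sqrt(mse / 2.0 * (1.0 / order_ns[i] + 1.0 / order_ns[j]))
    q = (order_means[j] - order_means[i]) / se if se > 0 else 0.0
    p = float(studentized_range.sf(q, span, dfe)) if se > 0 else 1.0
    sig = p < alpha
    results[(i, j)] = {"q": float(q), "p": p, "significant": bool(sig), "span": span}
    tested.add((i, j))
    if sig and span > 2:
        _nk_recurse(i, j - 1, order_means, order_ns, mse, dfe, alpha, results, tested)
        _nk_recurse(i + 1, j, order_means, order_ns, mse, dfe, alpha, results, tested)
    elif span > 2:
        # everything enclosed is declared non-significant without testing
        for a in range(i, j + 1):
            for b in range(a + 1, j + 1):
                if (a, b) not in tested:
                    results[(a, b)] = {"q": np.nan, "p": np.nan,
                                       "significant": False, "span": b - a + 1}
                    tested.add((a, b))
    return sig


def newman_keuls(groups: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Newman-Keuls stepwise post-hoc comparisons of group means.

    ``groups`` maps label -> 1-D array of observations.  Means are ordered
    and compared with the studentized range statistic at span-dependent
    critical values; ranges nested inside a non-significant range are
    declared non-significant without testing (the protection rule).

    Returns one row per pair: group_1, group_2 (smaller mean first),
    mean_diff, span, q, p, significant.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    data = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    ns = {k: len(v) for k, v in data.items()}
    if min(ns.values()) < 2:
        raise ValueError("each group needs at least two observations")
    means = {k: v.mean() for k, v in data.items()}
    dfe = sum(ns.values()) - len(labels)
    mse = sum(((v - means[k]) ** 2).sum() for k, v in data.items()) / dfe

    order = sorted(labels, key=lambda k: means[k])
    om = np.array([means[k] for k in order])
    on = np.array([ns[k] for k in order])
    results, tested = {}, set()
    k = len(order)
    _nk_recurse(0, k - 1, om, on, mse, dfe, alpha, results, tested)
    # fill any pair never reached (possible when the full range is ns)
    for a in range(k):
        for b in range(a + 1, k):
            if (a, b) not in results:
                results[(a, b)] = {"q": np.nan, "p": np.nan,
                                   "significant": False, "span": b - a + 1}
    rows = [{"group_1": order[a], "group_2": order[b],
             "mean_diff": om[b] - om[a], **results[(a, b)]}
            for a in range(k) for b in range(a + 1, k)]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-whale summary (published-table schema)
# ---------------------------------------------------------------------------

def whale_summary(locs_by_whale: dict, meta: pd.DataFrame, onsets: dict) -> pd.DataFrame:
    """Per-whale summary table: duration, distance, speeds by phase and
    behavioural-mode percentages, with the reporting-table rounding."""
    meta_idx = meta.set_index("whale_id")
    rows = []
    for wid, locs in locs_by_whale.items():
        phases = assign_phases(locs, onsets.get(wid))
        dur_days = ((locs["time"].iloc[-1] - locs["time"].iloc[0]).total_seconds()
                    / 86400.0 if len(locs) > 1 else 0.0)
        dist = track_distance_km(locs) if len(locs) > 1 else 0.0
        mean_sp = mean_speed_kmh(locs)
        seg = _segment_table(locs, phases) if len(locs) > 1 else pd.DataFrame()

        def _phase_speed(name):
            if seg.empty or (phases == name).sum() < MIN_LOCATIONS_FOR_SPEED:
                return None
            sp = seg.loc[seg["phase"] == name, "speed"]
            return round_half_up(sp.mean()) if len(sp) else None

        n = len(locs)
        pct = locs["mode"].value_counts(normalize=True) * 100.0 if n else {}
        rows.append({
            "whale_id": wid,
            "tag_duration_days": round_half_up(dur_days),
            "sex": meta_idx.loc[wid, "sex"],
            "category": meta_idx.loc[wid, "category"],
            "min_total_distance_km": round_half_up(dist, 0),
            "mean_speed_kmh": None if mean_sp is None else round_half_up(mean_sp),
            "breeding_speed_kmh": _phase_speed("breeding"),
            "migratory_speed_kmh": _phase_speed("migration"),
            "pct_ARS": round_half_up(pct.get("ARS", 0.0)),
            "pct_transit": round_half_up(pct.get("transit", 0.0)),
            "pct_uncertain": round_half_up(pct.get("uncertain", 0.0)),
        })
    return pd.DataFrame(rows)
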