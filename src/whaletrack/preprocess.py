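"""Argos fix cleaning: class-Z removal and the 12 km/h speed filter.

Raw Argos tracks routinely contain fixes implying impossible travel
speeds.  Following the standard practice for humpback whales, fixes of
location class Z are dropped outright and the remainder are filtered so
that no consecutive pair of retained fixes implies a travel speed above
``vmax_kmh`` (12 km/h by default, the upper bound of reported humpback
swimming speeds).

The speed filter's committed semantics: retain the largest possible
subset of fixes such that every consecutive retained pair satisfies the
speed bound (maximal retention, computed exactly by dynamic programming
over valid subsequences).  Among equally large optima the tie-break is
deterministic: latest feasible end fix, then latest feasible predecessor
at each step.  First and last fixes may be removed like any other.
Greedy one-at-a-time deletion rules (McConnell-style) approximate this
optimum but can strand retainable fixes; the exact rule is preferred
because it is directly checkable against an exhaustive-search oracle.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .config import LC_CLASSES
from .geo import great_circle_km

__all__ = ["FilterReport", "drop_lc_z", "speed_filter", "filter_fixes"]

#: rank of each class, lower = more accurate
_LC_RANK = {lc: i for i, lc in enumerate(LC_CLASSES)}


@dataclass
class FilterReport:
    """Bookkeeping of the cleaning stage; counts always add up."""

    n_input: int
    n_removed_lcz: int
    n_removed_speed: int
    n_retained: int

    def to_json(self, path=None):
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s


def _validate_lc(fixes: pd.DataFrame):
    bad = ~fixes["lc"].astype(str).isin(LC_CLASSES)
    if bad.any():
        rec = fixes[bad].iloc[0]
        raise ValueError(
            f"unknown Argos location class {rec['lc']!r} "
            f"(ptt={rec['ptt']}, time={rec['time']})")


def drop_lc_z(fixes: pd.DataFrame):
    """Remove class-Z (invalid) fixes; returns (kept, n_removed), order preserved."""
    _validate_lc(fixes)
    keep = fixes["lc"].astype(str) != "Z"
    return fixes[keep].reset_index(drop=True), int((~keep).sum())


def _resolve_duplicate_times(fixes: pd.DataFrame) -> pd.DataFrame:
    """Among exact-duplicate timestamps with differing positions keep the
    most accurate class; warn when this happens."""
    if fixes["time"].duplicated().any():
        dup_groups = fixes.groupby("time", sort=False)
        keep_idx = []
        warned = False
        for _, grp in dup_groups:
            if len(grp) == 1:
                keep_idx.append(grp.index[0])
                continue
            same_pos = (grp["lon"].nunique() == 1) and (grp["lat"].nunique() == 1)
            if same_pos:
                keep_idx.append(grp.index[0])
            else:
                if not warned:
                    warnings.warn(
                        "duplicate timestamps with differing positions; "
                        "keeping the most accurate location class", stacklevel=3)
                    warned = True
                best = grp.index[np.argmin([_LC_RANK[str(c)] for c in grp["lc"]])]
                keep_idx.append(best)
        fixes = fixes.loc[sorted(keep_idx)]
    return fixes.reset_index(drop=True)


def speed_filter(fixes: pd.DataFrame, vmax_kmh: float = 12.0):
    """Maximal-retention speed filter for a single-ptt, time-sorted track.

    Returns (retained, removed) DataFrames.  After filtering, no
    consecutive retained pair implies a speed above ``vmax_kmh``, and no
    larger subset with that property exists.
    """
    if fixes["ptt"].nunique() > 1:
        raise ValueError("speed_filter expects fixes of a single ptt; use filter_fixes")
    fixes = _resolve_duplicate_times(fixes)
    n = len(fixes)
    if n < 2:
        return fixes, fixes.iloc[0:0]

    lon = fixes["lon"].to_numpy(dtype=float)
    lat = fixes["lat"].to_numpy(dtype=float)
    hours = (fixes["time"] - fixes["time"].iloc[0]).dt.total_seconds().to_numpy() / 3600.0

    # pairwise feasibility: ok[j, i] iff the hop j -> i respects the bound
    d = great_circle_km(lon[None, :], lat[None, :], lon[:, None], lat[:, None])
    dt = hours[None, :] - hours[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(dt > 0, d / np.where(dt > 0, dt, 1.0), np.inf)
    v = np.where((dt == 0) & (d == 0), 0.0, v)
    ok = v <= vmax_kmh

    # longest valid subsequence ending at each fix; later index wins ties
    best = np.ones(n, dtype=int)
    prev = np.full(n, -1, dtype=int)
    for i in range(1, n):
        feas = np.flatnonzero(ok[:i, i])
        if feas.size:
            cand = best[feas]
            top = cand.max()
            j = int(feas[np.flatnonzero(cand == top)[-1]])
            best[i] = top + 1
            prev[i] = j
    end = int(np.flatnonzero(best == best.max())[-1])
    keep_idx = []
    while end != -1:
        keep_idx.append(end)
        end = prev[end]
    keep_idx = sorted(keep_idx)

    mask = np.zeros(n, dtype=bool)
    mask[keep_idx] = True
    kept = fixes.iloc[mask].reset_index(drop=True)
    dropped = fixes.iloc[~mask].reset_index(drop=True)
    return kept, dropped


def filter_fixes(fixes: pd.DataFrame, vmax_kmh: float = 12.0):
    """Full cleaning for a multi-ptt table: Z removal then per-ptt speed filter.

    Returns (retained fixes, FilterReport).
    """
    n_input = len(fixes)
    no_z, n_z = drop_lc_z(fixes)
    kept_parts = []
    n_speed = 0
    for _, grp in no_z.groupby("ptt", sort=False):
        grp = grp.sort_values("time", kind="stable").reset_index(drop=True)
        kept, dropped = speed_filter(grp, vmax_kmh)
        n_speed += len(grp) - len(kept)  # includes duplicate-time resolution
        kept_parts.append(kept)
    retained = (pd.concat(kept_parts, ignore_index=True)
                if kept_parts else no_z.iloc[0:0])
    report = FilterReport(n_input, n_z, n_speed, len(retained))
    return retained, report
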