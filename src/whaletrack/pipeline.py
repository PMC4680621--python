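"""One-command orchestration: simulate (or ingest), filter, fit, classify,
summarize.

``run`` executes the full chain — Argos cleaning, per-whale switching
state-space fits, 12-h regularization, migration-onset detection, the
per-whale summary table, occupancy gridding and habitat annotation — and
writes every artefact plus a manifest (config hash, seed, package
version) into a run directory.  A rerun with the same configuration and
seed is bit-identical except for the manifest timestamp.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bathymetry import BathymetryGrid
from .config import ConfigError, MCMCConfig, SimulationConfig
from .habitat import build_habitat_records, compare_modes
from .metrics import (assign_phases, detect_migration_onset, two_factor_anova,
                      whale_summary)
from .occupancy import build_occupancy
from .preprocess import filter_fixes
from .sssm import InsufficientDataError, fit_sssm, regularize
from .synthetic import bathymetry_for_tracks, simulate_fleet

log = logging.getLogger("whaletrack")

#: versioned output schemas, asserted by tests
REGULAR_COLUMNS = ["whale_id", "time", "lon", "lat", "b_mean", "mode"]
SUMMARY_COLUMNS = ["whale_id", "tag_duration_days", "sex", "category",
                   "min_total_distance_km", "mean_speed_kmh",
                   "breeding_speed_kmh", "migratory_speed_kmh",
                   "pct_ARS", "pct_transit", "pct_uncertain"]


@dataclass
class PipelineConfig:
    """Everything one run needs: either a simulation config or input paths."""

    simulation: SimulationConfig | None = None
    fixes_path: str | None = None
    metadata_path: str | None = None
    bathymetry_path: str | None = None
    vmax_kmh: float = 12.0
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    cell_size_km: float = 10.0
    isobath_levels_m: tuple = (200.0, 500.0)
    migration_isobath_m: float = 1000.0
    seed: int = 0

    def __post_init__(self):
        if self.simulation is None and self.fixes_path is None:
            raise ConfigError("either a simulation config or fixes_path is required")

    def digest(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)

        payload = json.dumps(dataclasses.asdict(self), default=enc, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run(config: PipelineConfig, outdir) -> Path:
    """Execute the full pipeline; returns the run directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    # --- inputs -----------------------------------------------------------
    stage = "input"
    try:
        if config.simulation is not None:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            tracks, fixes, meta = simulate_fleet(sim)
            bathy = bathymetry_for_tracks(tracks)
            pd.concat([t.to_frame() for t in tracks]).to_csv(
                out / "true_tracks.csv", index=False)
        else:
            fixes = pd.read_csv(config.fixes_path, parse_dates=["time"])
            if fixes["time"].dt.tz is None:
                fixes["time"] = fixes["time"].dt.tz_localize("UTC")
            meta = pd.read_csv(config.metadata_path)
            p = str(config.bathymetry_path)
            bathy = (BathymetryGrid.from_text(p) if p.endswith(".txt")
                     else BathymetryGrid.from_netcdf(p))
        fixes.to_csv(out / "fixes.csv", index=False)
        bathy.to_text(out / "bathymetry.txt")

        # --- preprocess ---------------------------------------------------
        stage = "preprocess"
        log.info("[preprocess] filtering %d fixes", len(fixes))
        filtered, report = filter_fixes(fixes, config.vmax_kmh)
        filtered.to_csv(out / "filtered.csv", index=False)
        report.to_json(out / "filter_report.json")

        # --- per-whale state-space fits ------------------------------------
        regular_parts = []
        onsets = {}
        mcmc = dataclasses.replace(config.mcmc, seed=config.seed)
        for wid, grp in filtered.groupby("ptt", sort=True):
            stage = f"sssm:{wid}"
            log.info("[sssm] fitting %s (%d fixes)", wid, len(grp))
            try:
                draws = fit_sssm(grp.reset_index(drop=True), mcmc)
            except InsufficientDataError as exc:
                log.warning("[sssm] skipping %s: %s", wid, exc)
                continue
            reg = regularize(draws)
            regular_parts.append(reg)
            stage = f"metrics:{wid}"
            onsets[wid] = detect_migration_onset(reg, bathy,
                                                 config.migration_isobath_m)
        if not regular_parts:
            raise RuntimeError("no whale could be fitted")
        regular = pd.concat(regular_parts, ignore_index=True)
        regular[REGULAR_COLUMNS].to_csv(out / "regular.csv", index=False)

        # --- summaries ------------------------------------------------------
        stage = "summary"
        locs_by_whale = {wid: g.reset_index(drop=True)
                         for wid, g in regular.groupby("whale_id", sort=True)}
        summary = whale_summary(locs_by_whale, meta, onsets)
        summary[SUMMARY_COLUMNS].to_csv(out / "whale_summary.csv", index=False)

        stage = "occupancy"
        grid = build_occupancy(regular, config.cell_size_km)
        grid.to_csv(out / "occupancy.csv")

        stage = "habitat"
        records = build_habitat_records(regular, bathy, config.isobath_levels_m)
        records.to_csv(out / "habitat.csv", index=False)
        anova = compare_modes(records)
        anova.to_csv(out / "habitat_anova.csv", index=False)

        # speed ANOVA over segments (phase x category) when both phases occur
        from .metrics import _segment_table
        segs = []
        meta_idx = meta.set_index("whale_id")
        for wid, locs in locs_by_whale.items():
            if len(locs) < 2:
                continue
            seg = _segment_table(locs, assign_phases(locs, onsets.get(wid)))
            seg["category"] = meta_idx.loc[wid, "category"]
            segs.append(seg)
        seg_all = pd.concat(segs, ignore_index=True)
        anova_report = {"n_segments": int(len(seg_all))}
        if seg_all["phase"].nunique() > 1 or seg_all["category"].nunique() > 1:
            tab = two_factor_anova(seg_all["speed"], seg_all["category"],
                                   seg_all["phase"])
            anova_report["speed_anova"] = {
                str(k): {"F": _j(v["F"]), "p": _j(v["PR(>F)"]), "df": _j(v["df"])}
                for k, v in tab.iterrows()}
        with open(out / "anova_report.json", "w") as fh:
            json.dump(anova_report, fh, indent=2)

        manifest = {
            "package": "whaletrack",
            "version": __version__,
            "seed": config.seed,
            "config_digest": config.digest(),
            "created": datetime.now(timezone.utc).isoformat(),
            "n_fixes": int(len(fixes)),
            "n_retained": int(report.n_retained),
            "n_whales_fit": int(regular["whale_id"].nunique()),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return out


def _j(v):
    return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)
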