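import numpy as np
import pandas as pd
import pytest

from whaletrack.bathymetry import BathymetryGrid
from whaletrack.geo import KM_PER_DEG
from whaletrack.metrics import (WhaleMeta, assign_phases,
                                detect_migration_onset, mean_speed_kmh,
                                newman_keuls, round_half_up, speed_summary,
                                track_distance_km, two_factor_anova,
                                whale_summary)
from whaletrack.reference import speed_identity_rows, tracking_summary
from whaletrack.synthetic import constant_speed_track


def regular_locs(lats, lons=None, whale_id="W"):
    n = len(lats)
    return pd.DataFrame({
        "whale_id": whale_id,
        "time": pd.date_range("2011-08-01", periods=n, freq="12h", tz="UTC"),
        "lon": np.full(n, 167.0) if lons is None else np.asarray(lons, float),
        "lat": np.asarray(lats, dtype=float),
    })


def shelf_bathymetry():
    """Flat -500 m shelf west of 168 E, -2500 m basin east of it."""
    lon = np.arange(160.0, 180.01, 0.1)
    lat = np.arange(-45.0, -15.0, 0.1)
    depth = np.where(lon[None, :] < 168.0, -500.0, -2500.0) * np.ones((lat.size, 1))
    return BathymetryGrid(lon, lat, depth)


class TestDistanceAndSpeed:
    def test_coincident_points_zero(self):
        assert track_distance_km(regular_locs([-22.0, -22.0])) == 0.0

    def test_three_collinear_points_sum_of_legs(self):
        locs = regular_locs([-22.0, -22.5, -23.25])
        assert track_distance_km(locs) == pytest.approx(1.25 * KM_PER_DEG, rel=1e-9)

    def test_single_location_errors(self):
        with pytest.raises(ValueError):
            track_distance_km(regular_locs([-22.0]))

    def test_straight_line_speed_times_time(self):
        """60-day track at a constant 4 km/h covers 5760 km."""
        locs = constant_speed_track("W", 60.0, 4.0 * 60 * 24, start_lat=-60)
        assert track_distance_km(locs) == pytest.approx(5760.0, rel=1e-6)
        assert mean_speed_kmh(locs) == pytest.approx(4.0, rel=1e-6)

    def test_fewer_than_ten_locations_not_estimated(self):
        assert mean_speed_kmh(regular_locs(np.linspace(-22, -23, 9))) is None

    def test_stationary_track_zero_speed(self):
        assert mean_speed_kmh(regular_locs([-22.0] * 12)) == 0.0

    def test_mean_speed_times_elapsed_equals_distance_on_regular_grid(self):
        rng = np.random.default_rng(3)
        locs = regular_locs(-22 + np.cumsum(rng.normal(0, 0.1, 40)),
                            167 + np.cumsum(rng.normal(0, 0.1, 40)))
        elapsed_h = (locs["time"].iloc[-1] - locs["time"].iloc[0]).total_seconds() / 3600
        assert mean_speed_kmh(locs) * elapsed_h == pytest.approx(
            track_distance_km(locs), rel=1e-12)

    def test_rounding_contract_half_up(self):
        assert round_half_up(1.25) == 1.3
        assert round_half_up(1.24999) == 1.2
        assert round_half_up(2.05) == 2.1


class TestPublishedWorkedExamples:
    def test_identity_rows_found(self):
        rows = speed_identity_rows()
        assert len(rows) >= 5
        assert "87761-12" in set(rows["ptt"])

    def test_longest_track_row_reproduced(self):
        """110 days covering 8540 km reads back as 3.2 km/h at 1 decimal."""
        locs = constant_speed_track("87761-12", 110.0, 8540.0)
        assert round_half_up(mean_speed_kmh(locs)) == 3.2

    def test_all_identity_rows_reproduced(self):
        for _, row in speed_identity_rows().iterrows():
            locs = constant_speed_track(row["ptt"], row["duration_days"],
                                        row["distance_km"])
            assert round_half_up(mean_speed_kmh(locs)) == row["mean_speed_kmh"], row["ptt"]

    def test_table_has_34_whales(self):
        assert len(tracking_summary()) == 34


class TestMigrationOnset:
    def test_never_leaves_shelf_no_onset(self):
        locs = regular_locs(np.linspace(-22, -25, 30), np.full(30, 165.0))
        assert detect_migration_onset(locs, shelf_bathymetry()) is None

    def test_onset_at_sustained_crossing(self):
        """Track crosses the shelf edge at step 30 and stays deep."""
        lons = np.concatenate([np.full(30, 165.0), np.full(20, 172.0)])
        locs = regular_locs(np.linspace(-22, -30, 50), lons)
        onset = detect_migration_onset(locs, shelf_bathymetry())
        assert onset == locs["time"].iloc[30]
        phases = assign_phases(locs, onset)
        assert (phases.iloc[:30] == "breeding").all()
        assert (phases.iloc[30:] == "migration").all()

    def test_brief_dip_does_not_trigger_onset(self):
        """One deep step followed by a shallow return is not migration."""
        lons = np.concatenate([np.full(10, 165.0), [172.0], np.full(10, 165.0),
                               np.full(8, 172.0)])
        locs = regular_locs(np.linspace(-22, -28, 29), lons)
        onset = detect_migration_onset(locs, shelf_bathymetry())
        assert onset == locs["time"].iloc[21]

    def test_out_of_raster_raises(self):
        locs = regular_locs([-22.0, -50.0], [165.0, 165.0])
        with pytest.raises(ValueError, match="outside"):
            detect_migration_onset(locs, shelf_bathymetry())


class TestSpeedSummary:
    def _meta(self):
        return pd.DataFrame([
            {"whale_id": "A", "sex": "M", "category": "M", "social_group": "S"},
            {"whale_id": "B", "sex": "F", "category": "MC", "social_group": "MC"},
        ])

    def test_all_breeding_has_no_migration_group(self):
        locs = {"A": regular_locs(np.linspace(-22, -23, 20))}
        out = speed_summary(locs, self._meta(), {"A": None})
        assert set(out["phase"]) == {"breeding"}

    def test_pooled_mean_with_equal_segment_counts(self):
        # two whales at constant 2 and 4 km/h -> pooled segment mean 3
        a = regular_locs(-22 + np.arange(11) * 2 * 12 / KM_PER_DEG, whale_id="A")
        b = regular_locs(-30 + np.arange(11) * 4 * 12 / KM_PER_DEG, whale_id="B")
        meta = self._meta()
        meta.loc[1, "category"] = "M"
        out = speed_summary({"A": a, "B": b}, meta, {})
        row = out[(out["category"] == "M") & (out["phase"] == "breeding")]
        assert row["mean_kmh"].iloc[0] == pytest.approx(3.0, rel=1e-6)

    def test_whale_meta_validation(self):
        with pytest.raises(ValueError):
            WhaleMeta("w", "M", "MC")


class TestTwoFactorAnova:
    @staticmethod
    def _balanced_toy():
        # 2x2 balanced design, 3 obs per cell
        data = {
            ("M", "breeding"): [1.0, 2.0, 3.0],
            ("M", "migration"): [4.0, 5.0, 6.0],
            ("F", "breeding"): [2.0, 3.0, 4.0],
            ("F", "migration"): [7.0, 8.0, 9.0],
        }
        speeds, cats, phases = [], [], []
        for (c, p), vals in data.items():
            speeds += vals
            cats += [c] * 3
            phases += [p] * 3
        return np.array(speeds), cats, phases

    @staticmethod
    def closed_form_balanced_2x2(y, a, b):
        """Hand-computed balanced two-way ANOVA with interaction."""
        y = np.asarray(y, dtype=float)
        a = np.asarray(a)
        b = np.asarray(b)
        n = len(y)
        gm = y.mean()
        lev_a, lev_b = np.unique(a), np.unique(b)
        ss_a = sum((y[a == la].mean() - gm) ** 2 * (a == la).sum() for la in lev_a)
        ss_b = sum((y[b == lb].mean() - gm) ** 2 * (b == lb).sum() for lb in lev_b)
        ss_cells = sum(
            (y[(a == la) & (b == lb)].mean() - gm) ** 2 * ((a == la) & (b == lb)).sum()
            for la in lev_a for lb in lev_b)
        ss_ab = ss_cells - ss_a - ss_b
        ss_e = sum(
            ((y[(a == la) & (b == lb)] - y[(a == la) & (b == lb)].mean()) ** 2).sum()
            for la in lev_a for lb in lev_b)
        df_a, df_b = len(lev_a) - 1, len(lev_b) - 1
        df_ab = df_a * df_b
        df_e = n - len(lev_a) * len(lev_b)
        ms = lambda ss, df: ss / df
        return {"category": ms(ss_a, df_a) / ms(ss_e, df_e),
                "phase": ms(ss_b, df_b) / ms(ss_e, df_e),
                "category:phase": ms(ss_ab, df_ab) / ms(ss_e, df_e)}

    def test_matches_hand_computation_on_balanced_design(self):
        y, cats, phases = self._balanced_toy()
        tab = two_factor_anova(y, cats, phases)
        expect = self.closed_form_balanced_2x2(y, cats, phases)
        for term, f in expect.items():
            assert tab.loc[term, "F"] == pytest.approx(f, abs=1e-6), term

    def test_all_equal_speeds_give_zero_f(self):
        tab = two_factor_anova([2.0] * 12,
                               ["M", "F"] * 6,
                               ["breeding"] * 6 + ["migration"] * 6)
        assert tab.loc["category", "F"] == 0.0
        assert tab.loc["phase", "F"] == 0.0

    def test_single_level_factor_reduces_to_one_way(self):
        rng = np.random.default_rng(1)
        y = np.concatenate([rng.normal(0, 1, 10), rng.normal(2, 1, 10)])
        cats = ["M"] * 10 + ["F"] * 10
        tab = two_factor_anova(y, cats, ["breeding"] * 20)
        from scipy.stats import f_oneway

        f, p = f_oneway(y[:10], y[10:])
        assert tab.loc["category", "F"] == pytest.approx(f, rel=1e-9)
        assert "phase" not in tab.index

    def test_empty_cell_drops_interaction_with_warning(self):
        y = [1.0, 2, 3, 4, 5, 6, 7, 8, 9]
        cats = ["M"] * 3 + ["F"] * 6
        phases = ["breeding"] * 3 + ["breeding"] * 3 + ["migration"] * 3
        with pytest.warns(UserWarning, match="empty cells"):
            tab = two_factor_anova(y, cats, phases)
        assert "category:phase" not in tab.index


class TestNewmanKeuls:
    def test_separated_groups_all_significant(self):
        rng = np.random.default_rng(2)
        groups = {"a": rng.normal(0, 1, 30), "b": rng.normal(5, 1, 30),
                  "c": rng.normal(10, 1, 30)}
        out = newman_keuls(groups)
        assert out["significant"].all()
        assert len(out) == 3

    def test_protection_rule_blocks_nested_ranges(self):
        rng = np.random.default_rng(3)
        groups = {k: rng.normal(0, 1, 8) for k in "abcd"}
        out = newman_keuls(groups)
        full = out[out["span"] == 4].iloc[0]
        if not full["significant"]:
            assert not out["significant"].any()

    def test_family_wise_error_near_nominal_under_null(self):
        """Complete null with three groups: the chance of any significant
        pair is gated by the full-range test, so FWER tracks alpha."""
        rng = np.random.default_rng(4)
        hits = 0
        n_sim = 400
        for _ in range(n_sim):
            groups = {k: rng.normal(0, 1, 10) for k in "abc"}
            hits += newman_keuls(groups, alpha=0.05)["significant"].any()
        fwer = hits / n_sim
        # binomial 3-sigma band around 0.05 at 400 simulations
        assert abs(fwer - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_sim)


class TestWhaleSummaryTable:
    def test_schema_and_rounding(self):
        locs = regular_locs(np.linspace(-22, -24, 30))
        locs["mode"] = ["transit"] * 15 + ["ARS"] * 10 + ["uncertain"] * 5
        meta = pd.DataFrame([{"whale_id": "W", "sex": "F", "category": "MC",
                              "social_group": "MC"}])
        out = whale_summary({"W": locs}, meta, {"W": None})
        assert list(out.columns) == [
            "whale_id", "tag_duration_days", "sex", "category",
            "min_total_distance_km", "mean_speed_kmh", "breeding_speed_kmh",
            "migratory_speed_kmh", "pct_ARS", "pct_transit", "pct_uncertain"]
        row = out.iloc[0]
        assert row["pct_transit"] == 50.0
        assert row["pct_ARS"] == pytest.approx(33.3)
        assert pd.isna(row["migratory_speed_kmh"])
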