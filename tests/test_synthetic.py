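import numpy as np
import pandas as pd
import pytest
from scipy import stats

from whaletrack import ConfigError, SimulationConfig
from whaletrack.bathymetry import BathymetryGrid
from whaletrack.geo import great_circle_km
from whaletrack.synthetic import (bathymetry_for_tracks,
                                  gaussian_isobath_radius_km, make_bathymetry,
                                  make_metadata, simulate_argos_fixes,
                                  simulate_fleet, simulate_true_track)


class TestTrueTrack:
    def test_absorbing_chain_stays_in_transit(self):
        cfg = SimulationConfig(duration_days=30, switch_prob=(1.0, 0.5), seed=0)
        tr = simulate_true_track(cfg, "W")
        assert (tr.states == 1).all()

    def test_noiseless_pure_inertia_gives_identical_displacements(self):
        cfg = SimulationConfig(duration_days=20, sigma_proc=0.0,
                               gamma=(1.0, 1.0), theta=(0.0, 0.0), seed=1)
        tr = simulate_true_track(cfg, "W")
        dlat = np.diff(tr.lat)
        # latitude displacement is exactly conserved under pure inertia
        np.testing.assert_allclose(dlat, dlat[0], atol=1e-12)

    def test_markov_stationary_fraction_matches_analytics(self):
        """With symmetric stay probabilities the stationary distribution of
        the two-state chain is (1/2, 1/2); the empirical fraction over
        10000 steps must fall within 3 standard errors, where the SE
        accounts for the chain's autocorrelation."""
        p_stay = 0.95
        cfg = SimulationConfig(duration_days=5000, step_hours=12,
                               switch_prob=(p_stay, p_stay), seed=4)
        tr = simulate_true_track(cfg, "W")
        n = 10_000
        frac = (tr.states[1:n + 1] == 1).mean()
        # var of the mean of a two-state chain: (pi1 pi2 / n) (1+rho)/(1-rho),
        # rho = a1 + a2 - 1
        rho = 2 * p_stay - 1
        se = np.sqrt(0.25 / n * (1 + rho) / (1 - rho))
        assert abs(frac - 0.5) < 3 * se

    def test_state_conditional_step_lengths_ordered(self):
        """Transit steps are longer than ARS steps whenever gamma1 > gamma2."""
        cfg = SimulationConfig(duration_days=3000, gamma=(0.8, 0.2), seed=8)
        tr = simulate_true_track(cfg, "W")
        step = great_circle_km(tr.lon[:-1], tr.lat[:-1], tr.lon[1:], tr.lat[1:])
        st_of_step = tr.states[1:]
        assert (st_of_step == 2).sum() > 1000  # enough of both states
        assert step[st_of_step == 1].mean() > step[st_of_step == 2].mean()

    def test_seed_determinism(self):
        cfg = SimulationConfig(duration_days=30, seed=9)
        a = simulate_true_track(cfg, "W")
        b = simulate_true_track(cfg, "W")
        np.testing.assert_array_equal(a.lon, b.lon)
        np.testing.assert_array_equal(a.states, b.states)
        c = simulate_true_track(SimulationConfig(duration_days=30, seed=10), "W")
        assert not np.array_equal(a.lon, c.lon)

    @pytest.mark.parametrize("field,value", [
        ("gamma", (1.2, 0.2)), ("gamma", (-0.1, 0.2)),
        ("switch_prob", (0.0, 0.9)), ("lc_probs", (1.0,) + (0.1,) * 6),
        ("sigma_proc", -1.0), ("n_whales", 0),
    ])
    def test_invalid_config_raises_naming_the_field(self, field, value):
        with pytest.raises(ConfigError):
            SimulationConfig(**{field: value})


class TestArgosFixes:
    def test_zero_error_fixes_lie_on_interpolated_path(self):
        cfg = SimulationConfig(duration_days=30, seed=2,
                               lc_probs=(1, 0, 0, 0, 0, 0, 0),
                               lc_error_km={k: 0.0 for k in "3210ABZ"},
                               argos_rate_per_day=8)
        tr = simulate_true_track(cfg, "W")
        fx = simulate_argos_fixes(tr, cfg)
        hours_t = (tr.times - tr.times[0]).total_seconds() / 3600.0
        hours_f = (fx["time"] - tr.times[0]).dt.total_seconds() / 3600.0
        lon_i = np.interp(hours_f, hours_t, np.degrees(np.unwrap(np.radians(tr.lon))))
        lat_i = np.interp(hours_f, hours_t, tr.lat)
        d = great_circle_km(fx["lon"], fx["lat"], lon_i % 360.0, lat_i)
        assert d.max() < 5e-3  # only fix-time rounding to 1 s (~1 m of travel)

    def test_class_probabilities_respected(self):
        cfg = SimulationConfig(duration_days=30, seed=2,
                               lc_probs=(1, 0, 0, 0, 0, 0, 0))
        tr = simulate_true_track(cfg, "W")
        fx = simulate_argos_fixes(tr, cfg)
        assert (fx["lc"] == "3").all()

    def test_fix_count_within_poisson_interval(self):
        """30-day track at 4 fixes/day: count inside the Poisson(120) 99%
        interval."""
        cfg = SimulationConfig(duration_days=30, argos_rate_per_day=4, seed=14)
        tr = simulate_true_track(cfg, "W")
        fx = simulate_argos_fixes(tr, cfg)
        lo, hi = stats.poisson.ppf([0.005, 0.995], 120)
        assert lo <= len(fx) <= hi

    def test_observation_errors_unbiased_per_class(self):
        cfg = SimulationConfig(duration_days=2000, argos_rate_per_day=6, seed=3)
        tr = simulate_true_track(cfg, "W")
        fx = simulate_argos_fixes(tr, cfg)
        hours_t = (tr.times - tr.times[0]).total_seconds() / 3600.0
        hours_f = (fx["time"] - tr.times[0]).dt.total_seconds() / 3600.0
        lat_i = np.interp(hours_f, hours_t, tr.lat)
        err_lat_km = (fx["lat"] - lat_i) * 111.195
        for lc in ("3", "2", "1"):
            sub = err_lat_km[fx["lc"] == lc]
            # t-errors with the class scale: mean within 4 SE of zero
            se = sub.std() / np.sqrt(len(sub))
            assert abs(sub.mean()) < 4 * se


class TestBathymetry:
    def test_no_seamounts_constant_floor(self):
        b = make_bathymetry((160, 165, -28, -24), 0.25, -3200.0)
        assert (b.depth == -3200.0).all()
        assert b.sample(162.2, -26.1) == pytest.approx(-3200.0)

    def test_summit_depth_at_center(self):
        b = make_bathymetry((160, 165, -28, -24), 0.05, -3000.0,
                            [(162.5, -26.0, -40.0, 15.0)])
        assert b.sample(162.5, -26.0) == pytest.approx(-40.0, abs=1.0)

    def test_summit_below_floor_rejected(self):
        with pytest.raises(ConfigError):
            make_bathymetry((160, 165, -28, -24), 0.25, -500.0,
                            [(162, -26, -800.0, 10.0)])

    def test_isobath_ring_radius_matches_closed_form(self):
        """The -200 m contour of a Gaussian seamount is a ring whose radius
        inverts the bump formula."""
        from whaletrack.habitat import isobath_contours

        b = make_bathymetry((163, 167, -27, -23), 0.02, -3000.0,
                            [(165.0, -25.0, -30.0, 20.0)])
        r_expect = gaussian_isobath_radius_km(-3000.0, -30.0, 20.0, 200.0)
        ring = max(isobath_contours(b, 200.0), key=len)
        r_measured = great_circle_km(ring[:, 0], ring[:, 1], 165.0, -25.0)
        cell_km = 0.02 * 111.195
        assert abs(r_measured.mean() - r_expect) < cell_km
        assert r_measured.std() < cell_km

    def test_text_round_trip(self, tmp_path):
        b = make_bathymetry((160, 162, -26, -24), 0.5, -3000.0,
                            [(161, -25, -100.0, 30.0)])
        p = tmp_path / "grid.txt"
        b.to_text(p)
        b2 = BathymetryGrid.from_text(p)
        np.testing.assert_allclose(b.depth, b2.depth, atol=1e-3)
        np.testing.assert_allclose(b.lon, b2.lon)

    def test_netcdf_round_trip(self, tmp_path):
        b = make_bathymetry((160, 162, -26, -24), 0.5, -3000.0)
        p = tmp_path / "grid.nc"
        b.to_netcdf(p)
        b2 = BathymetryGrid.from_netcdf(p)
        np.testing.assert_allclose(b.depth, b2.depth)


class TestFleet:
    def test_metadata_mc_implies_female(self):
        meta = make_metadata(SimulationConfig(n_whales=40, seed=6))
        assert (meta.loc[meta["category"] == "MC", "sex"] == "F").all()

    def test_fleet_determinism(self):
        cfg = SimulationConfig(n_whales=2, duration_days=20, seed=12)
        _, fx1, m1 = simulate_fleet(cfg)
        _, fx2, m2 = simulate_fleet(cfg)
        pd.testing.assert_frame_equal(fx1, fx2)
        pd.testing.assert_frame_equal(m1, m2)

    def test_seamounts_placed_under_ars_bouts(self):
        cfg = SimulationConfig(n_whales=3, duration_days=60,
                               gamma=(0.85, 0.15), seed=5)
        tracks, _, _ = simulate_fleet(cfg)
        bathy = bathymetry_for_tracks(tracks)
        # ARS positions sit over shallower water than transit on average
        depths = {1: [], 2: []}
        for tr in tracks:
            d = np.atleast_1d(bathy.sample(tr.lon, tr.lat))
            for s in (1, 2):
                depths[s].extend(d[tr.states == s])
        assert np.mean(np.abs(depths[2])) < np.mean(np.abs(depths[1]))
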