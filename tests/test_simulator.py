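"""Simulator tests: event bookkeeping, conservation ledgers, closed-form
limits, variant equivalence, solver refinement and performance indicators."""

from dataclasses import replace

import numpy as np
import pytest

from surfkin import (
    FeedSettings,
    KineticParameters,
    SimulationConfig,
    compute_performance,
    design_config,
    sample_trajectory,
    simulate_batch_free,
    simulate_fed_batch,
    space_time_yield,
)
from surfkin.errors import FeedStartError, ValidationError
from surfkin.synthetic import batch_experiment_config


class TestFedBatch:
    def test_event_sequence_and_feed_bookkeeping(self, hist_traj_025):
        ev = hist_traj_025.events
        assert ev["lag_end"] < ev["feed_start"] < ev["feed_depleted"]
        assert hist_traj_025.t_FS == pytest.approx(ev["feed_start"])
        assert hist_traj_025.X_FS > 0
        assert hist_traj_025.F0 > 0
        # glucose concentration at feed start sits at the trigger threshold
        states = hist_traj_025.interpolate([hist_traj_025.t_FS])[0]
        assert states[1] / states[4] == pytest.approx(
            hist_traj_025.config.params.c_S_crit, rel=1e-6
        )

    def test_no_acetate_without_source(self, params):
        cfg = batch_experiment_config(params.replace(b_max=0.0), 0.2)
        traj = simulate_fed_batch(cfg)
        assert np.all(traj.A == 0.0)

    def test_feed_glucose_ledger(self, hist_traj_025):
        cfg = hist_traj_025.config
        fed = cfg.params.c_S_feed * (cfg.v0 - hist_traj_025.v[-1])
        perf = compute_performance(hist_traj_025)
        assert perf.glucose_fed == pytest.approx(fed, rel=1e-12)
        assert fed == pytest.approx(cfg.params.c_S_feed * cfg.v0, rel=1e-6)

    def test_volume_ledger(self, hist_traj_025):
        cfg = hist_traj_025.config
        assert hist_traj_025.V[-1] - cfg.V0 == pytest.approx(
            cfg.params.c_vol * (cfg.v0 - hist_traj_025.v[-1]), rel=1e-9
        )

    def test_batch_phase_volume_constant(self, hist_traj_025):
        batch = hist_traj_025.t < hist_traj_025.t_FS
        assert np.allclose(hist_traj_025.V[batch], hist_traj_025.config.V0)

    def test_exponential_growth_limit(self, params):
        """With saturating glucose, no acetate and no inhibition, biomass grows
        as X0 * exp(mu_max_S (t - t_lag)) after the lag."""
        p = params.replace(b_max=0.0, t_lag=1.0)
        cfg = batch_experiment_config(p, 0.2, S0_conc=40.0)
        traj = simulate_fed_batch(cfg)
        # window where S/(S+K_S) >= 0.9985, so the Monod rate is within
        # ~1.5e-3 of mu_max and the accumulated deviation stays below 1%
        mask = (traj.t > 1.0) & (traj.t < 1.0 + 6.0) & (traj.S / traj.V > 30.0 * 1.1)
        mask &= traj.t < traj.t_FS
        expected = cfg.X0 * np.exp(p.mu_max_S * (traj.t[mask] - p.t_lag))
        np.testing.assert_allclose(traj.X[mask], expected, rtol=1e-2)

    def test_nonnegative_states(self, hist_traj_025, design_traj_28):
        for traj in (hist_traj_025, design_traj_28):
            for arr in (traj.X, traj.S, traj.P, traj.A, traj.v):
                assert np.all(arr >= 0.0)

    def test_regimes_never_conflict(self, hist_traj_025):
        """Acetate formation and consumption are mutually exclusive along the
        trajectory: wherever mu_A > 0 the formation rate b is zero."""
        consuming = hist_traj_025.mu_A > 0
        assert np.all(hist_traj_025.b[consuming] == 0.0)

    def test_trigger_never_crossed_raises(self, params):
        # biology switched off by a lag longer than the horizon
        p = params.replace(t_lag=5.25)
        cfg = batch_experiment_config(p, 0.2, t_max=4.0)
        with pytest.raises(FeedStartError):
            simulate_fed_batch(cfg)

    def test_initial_glucose_below_threshold_rejected(self, params):
        cfg = batch_experiment_config(params, 0.2, S0_conc=0.01)
        with pytest.raises(ValidationError):
            simulate_fed_batch(cfg)

    def test_mode_mismatch_rejected(self, params):
        cfg = design_config(params)
        with pytest.raises(ValidationError):
            simulate_fed_batch(cfg)


class TestVariants:
    def test_no_overflow_matches_full_when_acetate_absent(self, params):
        """With b_max = 0 and A0 = 0 the full model never produces acetate, so
        the reduced (no-overflow) variant must trace the same trajectory."""
        p = params.replace(b_max=0.0)
        cfg = batch_experiment_config(p, 0.2)
        full = simulate_fed_batch(cfg)
        reduced = simulate_fed_batch(replace(cfg, variant="no_overflow"))
        grid = np.linspace(0.0, min(full.t_end, reduced.t_end), 200)
        np.testing.assert_allclose(
            full.interpolate(grid), reduced.interpolate(grid), rtol=1e-6, atol=1e-8
        )

    def test_no_overflow_ignores_acetate_dynamics(self, params):
        cfg = replace(batch_experiment_config(params, 0.4), variant="no_overflow")
        traj = simulate_fed_batch(cfg)
        assert np.all(traj.A == 0.0)
        assert np.all(traj.mu_A == 0.0)


class TestRefinement:
    def test_tolerance_halving_stable(self, params):
        cfg = batch_experiment_config(params, 0.25)
        coarse = simulate_fed_batch(cfg)
        fine = simulate_fed_batch(replace(cfg, rtol=cfg.rtol / 2, atol=cfg.atol / 2))
        titre_c = coarse.P[-1] / coarse.V[-1]
        titre_f = fine.P[-1] / fine.V[-1]
        assert titre_c == pytest.approx(titre_f, rel=1e-3)
        # sampled concentrations stable well below assay resolution
        times = np.linspace(1.0, min(coarse.t_end, fine.t_end) - 0.1, 30)
        np.testing.assert_allclose(
            sample_trajectory(coarse, times).to_numpy(),
            sample_trajectory(fine, times).to_numpy(),
            atol=1e-4,
        )


class TestBatchFree:
    def test_feed_starts_at_fixed_time(self, design_traj_28):
        assert design_traj_28.events["feed_start"] == pytest.approx(1 / 60)
        assert design_traj_28.F0 == 28.0

    def test_requires_f0(self, params):
        cfg = design_config(params)
        cfg.feed.F0 = None
        with pytest.raises(ValidationError):
            simulate_batch_free(cfg)

    def test_volume_ledger_with_correction(self, design_traj_28):
        cfg = design_traj_28.config
        assert design_traj_28.V[-1] == pytest.approx(
            cfg.V0 + cfg.params.c_vol * cfg.v0, rel=1e-9
        )


class TestPerformance:
    def test_space_time_yield_identity(self, design_perf_28):
        assert design_perf_28.P_V == space_time_yield(
            design_perf_28.P_end, design_perf_28.V_end, design_perf_28.t_end
        )

    def test_yields_consistent(self, design_perf_28, design_traj_28):
        cfg = design_traj_28.config
        dX = design_traj_28.X[-1] - cfg.X0
        assert design_perf_28.Y_PX_overall == pytest.approx(
            design_perf_28.P_end / dX, rel=1e-9
        )
        assert design_perf_28.q_PX == pytest.approx(
            design_perf_28.Y_PX_overall / design_perf_28.t_end
        )

    def test_productivity_tracks_growth_coupling(self, design_traj_28):
        """(dP/dt)/X = mu_S * Y_PX along the whole trajectory."""
        productivity = design_traj_28.mu_S * design_traj_28.config.params.Y_PX
        dP = np.gradient(design_traj_28.P, design_traj_28.t)
        mask = design_traj_28.X > 1.0
        np.testing.assert_allclose(
            dP[mask] / design_traj_28.X[mask], productivity[mask], atol=5e-3
        )


class TestSampling:
    def test_identity_at_grid_nodes(self, hist_traj_025):
        nodes = hist_traj_025.t[::25]
        table = sample_trajectory(hist_traj_025, nodes)
        np.testing.assert_allclose(
            table["X_gL"].to_numpy(),
            (hist_traj_025.X / hist_traj_025.V)[::25],
            rtol=1e-9,
        )

    def test_initial_concentrations(self, hist_traj_025):
        cfg = hist_traj_025.config
        row = sample_trajectory(hist_traj_025, [0.0]).iloc[0]
        assert row["X_gL"] == pytest.approx(cfg.X0 / cfg.V0)
        assert row["S_gL"] == pytest.approx(cfg.S0 / cfg.V0)

    def test_outside_span_rejected(self, hist_traj_025):
        with pytest.raises(ValidationError):
            sample_trajectory(hist_traj_025, [hist_traj_025.t_end + 1.0])
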