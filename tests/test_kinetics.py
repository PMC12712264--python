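"""Rate-law unit and property tests: Monod limits, overflow switching,
Pirt yield, exponential feed, and the mass-balance structure of the RHS."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from surfkin import (
    BioprocessState,
    FeedSettings,
    KineticParameters,
    RegimeFlags,
    acetate_formation_rate,
    feed_rate,
    initial_feed_rate,
    monod_growth_rate_acetate,
    monod_growth_rate_glucose,
    pirt_biomass_yield,
    state_derivatives,
)
from surfkin.errors import ConfigurationError, ValidationError

P = KineticParameters.defaults()

conc = st.floats(0.0, 100.0, allow_nan=False)


class TestGrowthOnGlucose:
    @pytest.mark.parametrize(
        "s, a, expected",
        [
            (0.05, 0.0, 0.25),  # half-saturation: mu_max/2
            (0.0, 3.0, 0.0),  # no substrate, no growth
            (5.0, 5.0, 0.5 * (5 / 5.05) * 0.5),  # A = K_I halves the rate
        ],
    )
    def test_values(self, s, a, expected):
        assert monod_growth_rate_glucose(s, a, P) == pytest.approx(expected, rel=1e-12)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValidationError):
            monod_growth_rate_glucose(-0.1, 0.0, P)
        with pytest.raises(ValidationError):
            monod_growth_rate_glucose(0.1, -0.1, P)

    @given(s1=conc, s2=conc, a=conc)
    def test_monotone_in_glucose(self, s1, s2, a):
        lo, hi = sorted((s1, s2))
        assert monod_growth_rate_glucose(lo, a, P) <= monod_growth_rate_glucose(hi, a, P)

    @given(s=conc, a1=conc, a2=conc)
    def test_antitone_in_acetate_and_bounded(self, s, a1, a2):
        lo, hi = sorted((a1, a2))
        mu_lo_inh = monod_growth_rate_glucose(s, hi, P)
        mu_hi_inh = monod_growth_rate_glucose(s, lo, P)
        assert mu_lo_inh <= mu_hi_inh <= P.mu_max_S


class TestGrowthOnAcetate:
    def test_half_saturation(self):
        # A = K_A, glucose present but below critical level
        assert monod_growth_rate_acetate(0.01, 0.05, P) == pytest.approx(0.25)

    def test_gated_by_glucose_above_critical(self):
        assert monod_growth_rate_acetate(0.2, 1.0, P) == 0.0

    def test_gated_by_absent_glucose(self):
        assert monod_growth_rate_acetate(0.0, 1.0, P) == 0.0

    def test_gated_by_absent_acetate(self):
        assert monod_growth_rate_acetate(0.01, 0.0, P) == 0.0


class TestAcetateFormation:
    @pytest.mark.parametrize(
        "s, expected",
        [
            (0.075, 0.0),  # lower breakpoint
            (5.0, 0.072),  # upper breakpoint equals b_max
            ((0.075 + 5.0) / 2, 0.036),  # midpoint of linear segment: b_max/2
            (0.0, 0.0),
            (50.0, 0.072),  # clamped above
        ],
    )
    def test_piecewise_values(self, s, expected):
        assert acetate_formation_rate(s, P) == pytest.approx(expected, abs=1e-12)

    def test_threshold_ordering_enforced(self):
        bad = P.replace(c_S_crit_A1=5.0, c_S_crit_A2=0.075)
        with pytest.raises(ConfigurationError):
            acetate_formation_rate(1.0, bad)

    @given(
        s=conc,
        a1=st.floats(0.01, 0.2),
        width=st.floats(0.5, 10.0),
        b_max=st.floats(0.001, 0.5),
    )
    def test_continuous_piecewise_linear(self, s, a1, width, b_max):
        p = P.replace(c_S_crit_A1=a1, c_S_crit_A2=a1 + width, b_max=b_max)
        b = acetate_formation_rate(s, p)
        assert 0.0 <= b <= b_max
        if s <= a1:
            assert b == 0.0
        elif s >= a1 + width:
            assert b == b_max
        # continuity at the breakpoints
        eps = 1e-9
        assert acetate_formation_rate(a1 + eps, p) == pytest.approx(0.0, abs=1e-6 * b_max)
        assert acetate_formation_rate(a1 + width - eps, p) == pytest.approx(
            b_max, abs=1e-6 * b_max
        )


class TestPirtYield:
    def test_no_maintenance_recovers_true_yield(self):
        p = P.replace(m_S=0.0)
        assert pirt_biomass_yield(0.3, p) == pytest.approx(0.45)

    def test_zero_growth_limit(self):
        assert pirt_biomass_yield(0.0, P) == 0.0

    def test_worked_value(self):
        # 0.2 / (0.2/0.45 + 0.05)
        assert pirt_biomass_yield(0.2, P) == pytest.approx(0.40449, abs=1e-5)

    @given(mu=st.floats(1e-6, 10.0))
    def test_below_supremum_and_monotone(self, mu):
        y = pirt_biomass_yield(mu, P)
        assert 0.0 < y < P.Y_true_XS
        assert y <= pirt_biomass_yield(mu * 1.5, P)

    def test_approaches_supremum(self):
        assert pirt_biomass_yield(1e6, P) == pytest.approx(P.Y_true_XS, rel=1e-3)


class TestFeedRate:
    def test_at_zero(self):
        fs = FeedSettings(mu_F=0.2, F0=28.0)
        assert feed_rate(0.0, fs) == 28.0

    def test_doubling_time(self):
        fs = FeedSettings(mu_F=0.2, F0=28.0)
        assert feed_rate(math.log(2) / 0.2, fs) == pytest.approx(56.0)

    def test_constant_limit(self):
        fs = FeedSettings(mu_F=0.0, F0=28.0)
        assert feed_rate(17.3, fs) == 28.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            feed_rate(-1.0, FeedSettings(mu_F=0.2, F0=28.0))

    @given(t1=st.floats(0, 20), t2=st.floats(0, 20))
    def test_exponential_semigroup(self, t1, t2):
        fs = FeedSettings(mu_F=0.2, F0=28.0)
        lhs = feed_rate(t1 + t2, fs)
        rhs = feed_rate(t1, fs) * feed_rate(t2, fs) / fs.F0
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestInitialFeedRate:
    def test_table_values(self):
        # (0.2/0.28 + 0.05) * 84/500 * 1180
        f0 = initial_feed_rate(84.0, 0.2, P, Y_XS_batch=0.28)
        assert f0 == pytest.approx(151.5, abs=0.05)

    def test_unit_quotients(self):
        p = P.replace(m_S=0.0, c_S_feed=500.0, rho_feed=1180.0)
        assert initial_feed_rate(500.0, 0.5, p, Y_XS_batch=0.5) == pytest.approx(1180.0)

    def test_proportional_in_biomass(self):
        assert initial_feed_rate(20.0, 0.2, P) == pytest.approx(
            2 * initial_feed_rate(10.0, 0.2, P)
        )

    def test_zero_yield_rejected(self):
        with pytest.raises(ConfigurationError):
            initial_feed_rate(84.0, 0.2, P, Y_XS_batch=0.0)


class TestStateDerivatives:
    fs = FeedSettings(mu_F=0.2, F0=28.0, t_FS=0.0)

    def test_dormant_system(self):
        state = BioprocessState(t=10.0, X=5.0, S=0.0, P=1.0, A=0.0, V=10.0, v=5.0)
        d = state_derivatives(state, P, self.fs, RegimeFlags())
        assert np.allclose(d, 0.0)

    def test_lag_freezes_biology(self):
        state = BioprocessState(t=0.1, X=5.0, S=100.0, P=0.0, A=2.0, V=10.0, v=5.0)
        d = state_derivatives(state, P, self.fs, RegimeFlags(in_lag=True))
        assert np.allclose(d, 0.0)

    def test_lag_with_feed_only_moves_substrate_and_volume(self):
        state = BioprocessState(t=0.1, X=5.0, S=100.0, P=0.0, A=2.0, V=10.0, v=5.0)
        flags = RegimeFlags(in_lag=True, feeding_active=True)
        dX, dS, dP, dA, dV, dv = state_derivatives(state, P, self.fs, flags)
        f_vol = feed_rate(0.1, self.fs) / P.rho_feed
        assert dX == dP == dA == 0.0
        assert dS == pytest.approx(f_vol * P.c_S_feed)
        assert dV == pytest.approx(P.c_vol * f_vol)
        assert dv == pytest.approx(-f_vol)

    def test_product_rate_worked_value(self):
        # mu_S = 0.25 requires S/(S+K_S) = 0.5 with no inhibition: S = K_S
        state = BioprocessState(
            t=10.0, X=10.0, S=P.K_S * 10.0, P=0.0, A=0.0, V=10.0, v=5.0
        )
        d = state_derivatives(state, P, self.fs, RegimeFlags())
        assert d[2] == pytest.approx(0.25 * 0.71 * 10.0, rel=1e-12)  # 1.775 g/h

    @given(
        X=st.floats(0.1, 500.0),
        s_conc=st.floats(0.0, 60.0),
        a_conc=st.floats(0.0, 8.0),
        feeding=st.booleans(),
    )
    def test_glucose_ledger(self, X, s_conc, a_conc, feeding):
        """dS must equal feed inflow minus the biomass, product and
        acetate-formation drains, each recomputed independently."""
        V = 12.0
        state = BioprocessState(
            t=1.0, X=X, S=s_conc * V, P=0.0, A=a_conc * V, V=V, v=5.0
        )
        flags = RegimeFlags(feeding_active=feeding)
        dX, dS, dP, dA, dV, dv = state_derivatives(state, P, self.fs, flags)
        mu_s = monod_growth_rate_glucose(s_conc, a_conc, P)
        mu_a = monod_growth_rate_acetate(s_conc, a_conc, P)
        consuming = mu_a > 0.0
        inflow = (feed_rate(1.0, self.fs) / P.rho_feed) * P.c_S_feed if feeding else 0.0
        drain_x = (mu_s / P.Y_true_XS + P.m_S) * X if mu_s > 0 else 0.0
        drain_p = mu_s * P.Y_PX * X / P.Y_PS
        drain_a = 0.0 if consuming else acetate_formation_rate(s_conc, P) * X / P.Y_AS
        assert dS == pytest.approx(inflow - drain_x - drain_p - drain_a, rel=1e-9, abs=1e-12)
        # regime consistency: formation and consumption never both active
        if consuming:
            assert acetate_formation_rate(s_conc, P) == 0.0

    def test_feeding_with_empty_reservoir_rejected(self):
        state = BioprocessState(t=1.0, X=5.0, S=10.0, P=0.0, A=0.0, V=10.0, v=0.0)
        with pytest.raises(ValidationError):
            state_derivatives(state, P, self.fs, RegimeFlags(feeding_active=True))
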