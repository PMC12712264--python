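"""Rate laws and mass balances of the fed-batch surfactin process model.

The model tracks absolute amounts (g) of biomass X, glucose S, surfactin P
and acetate A, together with the reactor filling volume V and the remaining
feed volume v. All kinetic terms act on concentrations (amount / filling
volume).

Growth on glucose follows Monod kinetics with a general by-product
inhibition term in acetate; growth on acetate is Monod-limited and gated by
three conditions (acetate present, glucose present, glucose below the
critical concentration c_S_crit). Acetate formation by overflow metabolism
switches on linearly between two glucose thresholds and saturates at b_max.
Glucose consumption uses the Pirt relation (growth plus maintenance),
stoichiometric drains into surfactin and acetate, and an exponential feed
F(t) = F0 * exp(mu_F * t) measured from the feed start.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ValidationError
from .params import KineticParameters


@dataclass
class BioprocessState:
    """Absolute state of the reactor at time t (amounts in g, volumes in L)."""

    t: float
    X: float
    S: float
    P: float
    A: float
    V: float
    v: float

    def as_array(self) -> np.ndarray:
        return np.array([self.X, self.S, self.P, self.A, self.V, self.v], float)


@dataclass
class FeedSettings:
    """Exponential-feed configuration and the quantities recorded at feed start.

    mu_F is the feeding growth rate imposed by the exponential profile.
    In 'triggered' mode the feed starts when the glucose concentration drops
    below c_S_crit and F0 is computed from the biomass at that moment; in
    'fixed' mode the feed starts at t_feed_start with a user-supplied F0.
    """

    mu_F: float
    F0: float | None = None
    feed_start_mode: str = "triggered"  # 'triggered' | 'fixed'
    t_feed_start: float | None = None
    X_FS: float | None = None
    t_FS: float | None = None

    def validate(self) -> None:
        if self.mu_F < 0:
            raise ValidationError("feeding growth rate mu_F must be >= 0")
        if self.feed_start_mode not in ("triggered", "fixed"):
            raise ValidationError(
                f"feed_start_mode must be 'triggered' or 'fixed', got {self.feed_start_mode!r}"
            )
        if self.feed_start_mode == "fixed":
            if self.F0 is None or self.F0 <= 0:
                raise ValidationError("fixed-time feeding requires F0 > 0")


@dataclass
class RegimeFlags:
    """Discrete regime of the piecewise-defined right-hand side."""

    in_lag: bool = False
    feeding_active: bool = False
    acetate_consumption_allowed: bool = True


def monod_growth_rate_glucose(
    s_conc: float, a_conc: float, p: KineticParameters, inhibition: bool = True
) -> float:
    """Specific growth rate on glucose (1/h), Monod with acetate inhibition.

    mu_S = mu_max_S * S/(S+K_S) * K_I/(A+K_I); concentrations in g/L.
    """
    if s_conc < 0 or a_conc < 0:
        raise ValidationError("concentrations must be nonnegative")
    mu = p.mu_max_S * s_conc / (s_conc + p.K_S)
    if inhibition:
        mu *= p.K_I / (a_conc + p.K_I)
    return mu


def monod_growth_rate_acetate(s_conc: float, a_conc: float, p: KineticParameters) -> float:
    """Specific growth rate on acetate (1/h), gated by glucose availability.

    Nonzero only when acetate is present, glucose is present, and the glucose
    concentration is below c_S_crit (B. subtilis cannot grow on acetate alone).
    """
    if s_conc < 0 or a_conc < 0:
        raise ValidationError("concentrations must be nonnegative")
    if a_conc > 0 and 0.0 < s_conc < p.c_S_crit:
        return p.mu_max_A * a_conc / (a_conc + p.K_A)
    return 0.0


def acetate_formation_rate(s_conc: float, p: KineticParameters) -> float:
    """Specific acetate formation rate b (1/h): 0 below c_S_crit_A1, linear
    in glucose concentration up to c_S_crit_A2, clamped at b_max above it."""
    if s_conc < 0:
        raise ValidationError("glucose concentration must be nonnegative")
    a1, a2 = p.c_S_crit_A1, p.c_S_crit_A2
    if a1 >= a2:
        raise ConfigurationError("c_S_crit_A1 must be < c_S_crit_A2")
    b = p.b_max * (s_conc - a1) / (a2 - a1)
    return min(max(b, 0.0), p.b_max)


def pirt_biomass_yield(mu_s: float, p: KineticParameters) -> float:
    """Growth-rate dependent biomass yield Y_X/S = mu/(mu/Y_true + m_S) (g/g).

    Monotone increasing in mu with supremum Y_true_XS; defined as 0 at mu=0
    (limit convention, maintenance dominates at zero growth).
    """
    if mu_s < 0:
        raise ValidationError("specific growth rate must be nonnegative")
    if mu_s == 0.0:
        return 0.0 if p.m_S > 0 else p.Y_true_XS
    return mu_s / (mu_s / p.Y_true_XS + p.m_S)


def feed_rate(t_since_feed_start: float, fs: FeedSettings) -> float:
    """Exponential feed mass rate F(t) = F0 * exp(mu_F * t) in g/h."""
    if t_since_feed_start < 0:
        raise ValidationError("time since feed start must be nonnegative")
    if fs.F0 is None or fs.F0 <= 0:
        raise ValidationError("feed rate requires F0 > 0")
    return fs.F0 * math.exp(fs.mu_F * t_since_feed_start)


def initial_feed_rate(
    X_FS: float,
    mu_F: float,
    p: KineticParameters,
    Y_XS_batch: float | None = None,
) -> float:
    """Initial feed mass rate F0 = (mu_F/Y_XS_batch + m_S) * X_FS/c_S_feed * rho_feed.

    X_FS is the biomass amount (g) at feed start; Y_XS_batch defaults to the
    configured batch yield.
    """
    y_batch = p.Y_XS_batch if Y_XS_batch is None else Y_XS_batch
    if y_batch <= 0:
        raise ConfigurationError("batch biomass yield must be positive")
    if p.c_S_feed <= 0:
        raise ConfigurationError("feed glucose concentration must be positive")
    if X_FS <= 0:
        raise ValidationError("biomass at feed start must be positive")
    return (mu_F / y_batch + p.m_S) * X_FS / p.c_S_feed * p.rho_feed


def specific_rates(
    s_conc: float,
    a_conc: float,
    p: KineticParameters,
    in_lag: bool,
    acetate_consumption_allowed: bool,
    variant: str = "full",
) -> tuple[float, float, float, bool]:
    """Evaluate (mu_S, mu_A, b, consuming) for one concentration pair.

    During the lag phase all biological rates are zero. In the 'no_overflow'
    variant acetate formation, consumption and the growth inhibition term are
    removed.
    """
    if in_lag:
        return 0.0, 0.0, 0.0, False
    overflow = variant == "full"
    mu_s = monod_growth_rate_glucose(s_conc, a_conc if overflow else 0.0, p,
                                     inhibition=overflow)
    if not overflow:
        return mu_s, 0.0, 0.0, False
    consuming = (
        acetate_consumption_allowed
        and a_conc > 0.0
        and 0.0 < s_conc < p.c_S_crit
    )
    mu_a = p.mu_max_A * a_conc / (a_conc + p.K_A) if consuming else 0.0
    b = acetate_formation_rate(s_conc, p)
    return mu_s, mu_a, b, consuming


def _rhs(
    t: float,
    y: np.ndarray,
    p: KineticParameters,
    feed_fn,
    in_lag: bool,
    acetate_consumption_allowed: bool,
    variant: str,
) -> list[float]:
    """Time derivatives of (X, S, P, A, V, v); feed_fn(t)->g/h or None."""
    X, S, P, A, V, v = y
    s_conc = max(S, 0.0) / V
    a_conc = max(A, 0.0) / V
    f_vol = (feed_fn(t) / p.rho_feed) if feed_fn is not None else 0.0

    mu_s, mu_a, b, consuming = specific_rates(
        s_conc, a_conc, p, in_lag, acetate_consumption_allowed, variant
    )

    dX = (mu_s + mu_a) * X
    dP = mu_s * p.Y_PX * X
    a_formation = b * X
    a_consumption = (p.m_A + mu_a / p.Y_XA) * X if consuming else 0.0
    dA = a_formation - a_consumption
    # Pirt drain mu_S/Y_XS(mu_S) = mu_S/Y_true + m_S for mu_S > 0
    growth_drain = (mu_s / p.Y_true_XS + p.m_S) * X if mu_s > 0.0 else 0.0
    acetate_drain = 0.0 if consuming else a_formation / p.Y_AS
    dS = f_vol * p.c_S_feed - growth_drain - dP / p.Y_PS - acetate_drain
    dV = p.c_vol * f_vol
    dv = -f_vol
    return [dX, dS, dP, dA, dV, dv]


def state_derivatives(
    state: BioprocessState,
    p: KineticParameters,
    fs: FeedSettings,
    flags: RegimeFlags,
    variant: str = "full",
) -> np.ndarray:
    """Derivatives (dX, dS, dP, dA, dV, dv) at one state under given regime flags."""
    if flags.feeding_active:
        if state.v <= 0:
            raise ValidationError("feeding flagged active but feed volume is exhausted")
        t_ref = fs.t_FS if fs.t_FS is not None else 0.0
        def feed_fn(t):
            return feed_rate(t - t_ref, fs)
    else:
        feed_fn = None
    return np.array(
        _rhs(
            state.t,
            state.as_array(),
            p,
            feed_fn,
            flags.in_lag,
            flags.acetate_consumption_allowed,
            variant,
        )
    )
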