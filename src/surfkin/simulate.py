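"""Event-driven integration of the fed-batch ODE system.

The process is integrated phase by phase — lag, batch, exponential feeding —
with the integration restarted at every regime switch (feed trigger or fixed
feed start, lag end, acetate depletion/reappearance, the glucose gate for
acetate consumption, feed depletion) so that the piecewise-defined right-hand
side is never smoothed across a discontinuity. A stiff-capable multistep
solver (LSODA) is used, matching the implicit multistep integration the model
was built for.

Two entry points: :func:`simulate_fed_batch` starts the feed when the glucose
concentration drops below c_S_crit and computes F0 from the biomass at that
moment; :func:`simulate_batch_free` starts the feed at a fixed (early) time
with a user-chosen F0, the configuration used for the batch-free process
design. Both stop when the feed reservoir is empty (v = 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import FeedStartError, SimulationError, ValidationError
from .kinetics import FeedSettings, _rhs, initial_feed_rate, specific_rates
from .params import KineticParameters

_NUDGE = 1e-7  # micro Euler step after an event, h (moves off the switching surface)
_MAX_SEGMENTS = 1000


@dataclass
class SimulationConfig:
    """Initial state, parameters, feed settings and solver controls for one run.

    Amounts X0, S0, P0, A0 in g; volumes V0 (reactor) and v0 (feed reservoir)
    in L. `variant` is 'full' or 'no_overflow' (acetate dynamics, acetate
    growth and the inhibition term removed).
    """

    params: KineticParameters
    feed: FeedSettings
    X0: float = 0.696
    S0: float = 5.0
    P0: float = 0.0
    A0: float = 0.0
    V0: float = 10.0
    v0: float = 10.0
    variant: str = "full"
    rtol: float = 1e-8
    atol: float = 1e-10
    max_step: float = 0.05
    t_max: float = 120.0
    grid_dt: float = 0.02
    batch_yield_mode: str = "computed"  # 'computed' | 'fixed'

    def validate(self) -> None:
        self.params.validate()
        self.feed.validate()
        if self.V0 <= 0:
            raise ValidationError("initial reactor volume V0 must be positive")
        if self.v0 <= 0:
            raise ValidationError("feed volume v0 must be positive when feeding is enabled")
        if min(self.X0, self.S0, self.P0, self.A0) < 0:
            raise ValidationError("initial amounts must be nonnegative")
        if self.rtol <= 0 or self.atol <= 0 or self.max_step <= 0:
            raise ValidationError("solver tolerances and max step must be positive")
        if self.variant not in ("full", "no_overflow"):
            raise ValidationError(f"unknown model variant {self.variant!r}")
        if self.batch_yield_mode not in ("computed", "fixed"):
            raise ValidationError("batch_yield_mode must be 'computed' or 'fixed'")


@dataclass
class _Segment:
    t0: float
    t1: float
    sol: object  # scipy OdeSolution (dense output)
    in_lag: bool
    feeding: bool
    allow_consumption: bool
    phase: str


class Trajectory:
    """Dense simulated trajectory with event log and derived rate profiles.

    Attributes `t`, `X`, `S`, `P`, `A` (g), `V`, `v` (L) are aligned arrays on
    the output grid (amounts clipped at zero); `mu_S`, `mu_A`, `b` are the
    specific rates re-evaluated along the grid, and `phase` labels each point
    'lag', 'batch' or 'feeding'. `events` maps event names to times;
    `X_FS`, `t_FS`, `F0` and `Y_XS_batch` record the feed-start bookkeeping.
    """

    def __init__(
        self,
        config: SimulationConfig,
        segments: list[_Segment],
        events: dict,
        feed: FeedSettings,
        Y_XS_batch: float | None,
    ):
        self.config = config
        self._segments = segments
        self.events = events
        self.feed = feed
        self.F0 = feed.F0
        self.X_FS = feed.X_FS
        self.t_FS = feed.t_FS
        self.Y_XS_batch = Y_XS_batch

        pieces = [
            np.arange(seg.t0, seg.t1, config.grid_dt) for seg in segments
        ]
        pieces.append(np.array([segments[-1].t1]))
        t = np.concatenate([p for p in pieces if p.size])
        # strictly increasing grid (event restarts can produce ~1e-10 steps)
        keep = np.concatenate([[True], np.diff(t) > 1e-9])
        self.t = t[keep]
        states = self.interpolate(self.t)
        self.X = np.clip(states[:, 0], 0.0, None)
        self.S = np.clip(states[:, 1], 0.0, None)
        self.P = np.clip(states[:, 2], 0.0, None)
        self.A = np.clip(states[:, 3], 0.0, None)
        self.V = states[:, 4]
        self.v = np.clip(states[:, 5], 0.0, None)
        self._compute_rates()

    # -- evaluation ---------------------------------------------------------

    @property
    def t_end(self) -> float:
        return self._segments[-1].t1

    def _segment_index(self, times: np.ndarray) -> np.ndarray:
        ends = np.array([s.t1 for s in self._segments])
        idx = np.searchsorted(ends, times, side="left")
        return np.clip(idx, 0, len(self._segments) - 1)

    def interpolate(self, times) -> np.ndarray:
        """Dense-output states (n, 6) at arbitrary times within the span."""
        times = np.atleast_1d(np.asarray(times, float))
        if times.size and (times.min() < -1e-9 or times.max() > self.t_end + 1e-9):
            raise ValidationError(
                f"requested times outside trajectory span [0, {self.t_end:.4f}] h"
            )
        out = np.empty((times.size, 6))
        idx = self._segment_index(times)
        for i in np.unique(idx):
            mask = idx == i
            out[mask] = np.asarray(self._segments[i].sol(times[mask])).T
        return out

    def concentrations(self, times) -> pd.DataFrame:
        """Concentration table (g/L) for X, S, P, A at the requested times."""
        times = np.atleast_1d(np.asarray(times, float))
        states = self.interpolate(times)
        V = states[:, 4]
        return pd.DataFrame(
            {
                "t_h": times,
                "X_gL": np.clip(states[:, 0], 0.0, None) / V,
                "S_gL": np.clip(states[:, 1], 0.0, None) / V,
                "P_gL": np.clip(states[:, 2], 0.0, None) / V,
                "A_gL": np.clip(states[:, 3], 0.0, None) / V,
            }
        )

    def _compute_rates(self) -> None:
        p = self.config.params
        variant = self.config.variant
        idx = self._segment_index(self.t)
        mu_s = np.empty_like(self.t)
        mu_a = np.empty_like(self.t)
        b = np.empty_like(self.t)
        phase = np.empty(self.t.shape, dtype=object)
        s_conc = self.S / self.V
        a_conc = self.A / self.V
        for k in range(self.t.size):
            seg = self._segments[idx[k]]
            mu_s[k], mu_a[k], b[k], _ = specific_rates(
                s_conc[k], a_conc[k], p, seg.in_lag, seg.allow_consumption, variant
            )
            phase[k] = seg.phase
        self.mu_S = mu_s
        self.mu_A = mu_a
        self.b = b
        self.phase = phase

    def to_frame(self) -> pd.DataFrame:
        """Full trajectory table in the CSV schema used by the CLI."""
        return pd.DataFrame(
            {
                "t_h": self.t,
                "X_g": self.X,
                "S_g": self.S,
                "P_g": self.P,
                "A_g": self.A,
                "V_L": self.V,
                "v_L": self.v,
                "X_gL": self.X / self.V,
                "S_gL": self.S / self.V,
                "P_gL": self.P / self.V,
                "A_gL": self.A / self.V,
                "mu_S": self.mu_S,
                "mu_A": self.mu_A,
                "phase": self.phase,
            }
        )


@dataclass
class PerformanceIndicators:
    """Endpoint and derived performance measures of one completed run."""

    P_end: float
    V_end: float
    t_end: float
    max_titre: float
    P_V: float
    Y_PX_overall: float
    Y_PS_overall: float
    Y_XS_overall: float
    q_PX: float
    q_PS: float
    glucose_fed: float
    glucose_consumed: float


def space_time_yield(P_end: float, V_end: float, t_end: float) -> float:
    """Space-time yield P_V = P_end / (V_end * t_end), g/(L*h)."""
    if V_end <= 0 or t_end <= 0:
        raise ValidationError("space-time yield requires positive volume and time")
    return P_end / (V_end * t_end)


def _make_feed(F0: float, mu_F: float, t_ref: float):
    def feed_fn(t: float) -> float:
        return F0 * math.exp(mu_F * (t - t_ref))

    return feed_fn


def _simulate(cfg: SimulationConfig) -> Trajectory:
    cfg.validate()
    p = cfg.params
    fs = replace(cfg.feed)
    triggered = fs.feed_start_mode == "triggered"
    if triggered and cfg.S0 <= p.c_S_crit * cfg.V0:
        raise ValidationError(
            "triggered feeding requires initial glucose above the critical "
            f"concentration: S0/V0 = {cfg.S0 / cfg.V0:.4f} g/L <= c_S_crit = {p.c_S_crit} g/L"
        )
    if not triggered and fs.t_feed_start is None:
        fs.t_feed_start = 1.0 / 60.0

    t = 0.0
    y = np.array([cfg.X0, cfg.S0, cfg.P0, cfg.A0, cfg.V0, cfg.v0], float)
    feeding = False
    t_ref = math.nan
    F0 = fs.F0
    y_batch: float | None = None
    segments: list[_Segment] = []
    events: dict = {}
    switches: list[tuple[str, float]] = []
    full = cfg.variant == "full"
    completed = False
    pending_nudge = False

    for _ in range(_MAX_SEGMENTS):
        in_lag = t < p.t_lag - 1e-9
        # acetate consumption is possible only while the pool is nonempty;
        # reevaluated at every restart (the pool is clamped to 0 on depletion)
        allow_cons = y[3] > 1e-12
        t_stop = cfg.t_max
        if in_lag:
            t_stop = min(t_stop, p.t_lag)
        if not triggered and not feeding:
            t_stop = min(t_stop, fs.t_feed_start)
        feed_fn = _make_feed(F0, fs.mu_F, t_ref) if feeding else None

        def rhs(tt, yy, _feed=feed_fn, _lag=in_lag, _cons=allow_cons):
            return _rhs(tt, yy, p, _feed, _lag, _cons, cfg.variant)

        if pending_nudge:
            # step off the switching surface so restarted events see a
            # nonzero value (scipy's sign test treats 0 as a crossing)
            y = y + _NUDGE * np.asarray(rhs(t, y))
            t += _NUDGE
            pending_nudge = False

        evs: list = []
        labels: list[str] = []

        def add(label, fn, direction=0.0):
            fn.terminal = True
            fn.direction = direction
            evs.append(fn)
            labels.append(label)

        if feeding:
            add("feed_depleted", lambda tt, yy: yy[5], -1.0)
        if triggered and not feeding and not in_lag:
            add("feed_trigger", lambda tt, yy: yy[1] / yy[4] - p.c_S_crit, -1.0)
        if full and not in_lag:
            if feeding or not triggered:
                add(
                    "consumption_gate",
                    lambda tt, yy: max(yy[1], 0.0) / yy[4] - p.c_S_crit,
                    0.0,
                )
            if allow_cons:
                add("acetate_depleted", lambda tt, yy: yy[3], -1.0)

        sol = solve_ivp(
            rhs,
            (t, t_stop),
            y,
            method="LSODA",
            events=evs or None,
            dense_output=True,
            rtol=cfg.rtol,
            atol=cfg.atol,
            max_step=cfg.max_step,
        )
        if not sol.success:
            raise SimulationError(
                f"integration failed at t={sol.t[-1]:.4f} h "
                f"(phase={'feeding' if feeding else 'batch'}): {sol.message}"
            )
        t_new = float(sol.t[-1])
        y_new = sol.y[:, -1].copy()
        phase = "lag" if in_lag else ("feeding" if feeding else "batch")
        segments.append(
            _Segment(t, t_new, sol.sol, in_lag, feeding, allow_cons, phase)
        )

        fired = None
        if sol.status == 1:
            cand = [
                (te[0], lab)
                for te, lab in zip(sol.t_events, labels)
                if te.size
            ]
            fired = min(cand)[1] if cand else None

        if fired == "feed_depleted":
            y_new[5] = 0.0
            events["feed_depleted"] = t_new
            completed = True
            break
        elif fired == "feed_trigger":
            fs.X_FS = float(y_new[0])
            fs.t_FS = t_new
            s_fs = max(float(y_new[1]), 0.0)
            if cfg.batch_yield_mode == "computed":
                y_batch = (fs.X_FS - cfg.X0) / max(cfg.S0 - s_fs, 1e-9)
            else:
                y_batch = p.Y_XS_batch
            F0 = initial_feed_rate(fs.X_FS, fs.mu_F, p, Y_XS_batch=y_batch)
            fs.F0 = F0
            feeding = True
            t_ref = t_new
            events["feed_start"] = t_new
        elif fired == "acetate_depleted":
            y_new[3] = 0.0
            switches.append((fired, t_new))
        elif fired == "consumption_gate":
            switches.append((fired, t_new))
        else:  # reached t_stop without an event
            if in_lag and abs(t_new - p.t_lag) < 1e-9:
                events["lag_end"] = t_new
            elif (
                not triggered
                and not feeding
                and abs(t_new - fs.t_feed_start) < 1e-9
            ):
                F0 = fs.F0
                fs.X_FS = float(y_new[0])
                fs.t_FS = t_new
                feeding = True
                t_ref = t_new
                events["feed_start"] = t_new
            elif t_new >= cfg.t_max - 1e-9:
                if triggered and not feeding:
                    raise FeedStartError(
                        "glucose never dropped below the critical concentration "
                        f"within t_max = {cfg.t_max} h"
                    )
                raise SimulationError(
                    f"feed not depleted within t_max = {cfg.t_max} h "
                    f"(v = {y_new[5]:.4f} L remaining)"
                )

        pending_nudge = fired is not None
        t = t_new
        y = y_new
    else:
        raise SimulationError("too many integration restarts (regime chattering?)")

    if not completed:
        raise SimulationError("simulation ended without feed depletion")
    events.setdefault("lag_end", min(p.t_lag, t_new))
    events["regime_switches"] = switches
    return Trajectory(cfg, segments, events, fs, y_batch)


def simulate_fed_batch(cfg: SimulationConfig) -> Trajectory:
    """Batch phase then threshold-triggered exponential feeding until v = 0.

    The batch is integrated until the glucose concentration crosses c_S_crit;
    the biomass X_FS and time t_FS are recorded, the batch biomass yield
    Y_XS_batch = (X_FS - X0)/(S0 - S_FS) is computed (or taken from the
    configuration when batch_yield_mode='fixed') and F0 follows from it.
    """
    if cfg.feed.feed_start_mode != "triggered":
        raise ValidationError("simulate_fed_batch requires feed_start_mode='triggered'")
    return _simulate(cfg)


def simulate_batch_free(cfg: SimulationConfig) -> Trajectory:
    """Feeding from a fixed early start time with a supplied F0 (no batch phase)."""
    if cfg.feed.feed_start_mode != "fixed":
        raise ValidationError("simulate_batch_free requires feed_start_mode='fixed'")
    return _simulate(cfg)


def compute_performance(traj: Trajectory) -> PerformanceIndicators:
    """Endpoint performance: P_V by the space-time-yield relation, overall
    yields from the endpoint ledgers, specific rates as yield per process time."""
    cfg = traj.config
    P_end = float(traj.P[-1])
    V_end = float(traj.V[-1])
    t_end = float(traj.t[-1])
    max_titre = float(np.max(traj.P / traj.V))
    fed = cfg.params.c_S_feed * (cfg.v0 - float(traj.v[-1]))
    consumed = cfg.S0 + fed - float(traj.S[-1])
    dX = float(traj.X[-1]) - cfg.X0
    dP = P_end - cfg.P0
    y_px = dP / dX if dX > 0 else 0.0
    y_ps = dP / consumed if consumed > 0 else 0.0
    y_xs = dX / consumed if consumed > 0 else 0.0
    return PerformanceIndicators(
        P_end=P_end,
        V_end=V_end,
        t_end=t_end,
        max_titre=max_titre,
        P_V=space_time_yield(P_end, V_end, t_end),
        Y_PX_overall=y_px,
        Y_PS_overall=y_ps,
        Y_XS_overall=y_xs,
        q_PX=y_px / t_end,
        q_PS=y_ps / t_end,
        glucose_fed=fed,
        glucose_consumed=consumed,
    )


def sample_trajectory(traj: Trajectory, times) -> pd.DataFrame:
    """Interpolated concentration table (g/L) at the requested times."""
    return traj.concentrations(times)
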