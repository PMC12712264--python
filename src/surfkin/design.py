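"""Model-based process design: batch-free runs and the initial-feed-rate sweep.

The design configuration omits the batch phase: the reactor starts with the
preculture carry-over only (biomass from an OD600 of 0.3, ~0.5 g/L residual
glucose, no surfactin or acetate) and the exponential feed starts 1 min
after inoculation at a chosen F0 with feeding growth rate mu_F = 0.2 1/h.
Sweeping F0 yields the maximum-titre and space-time-yield curves from which
an operating point is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import SimulationError, ValidationError
from .kinetics import FeedSettings
from .params import KineticParameters
from .simulate import (
    SimulationConfig,
    Trajectory,
    compute_performance,
    simulate_batch_free,
)

#: g CDW per L per OD600 unit for B. subtilis BMV9
OD_TO_CDW = 0.232


def design_config(
    params: KineticParameters | None = None,
    F0: float = 28.0,
    mu_F: float = 0.2,
    V0: float = 10.0,
    v0: float = 10.0,
    od600_0: float = 0.3,
    S0_conc: float = 0.5,
    t_feed_start: float = 1.0 / 60.0,
    **solver_kwargs,
) -> SimulationConfig:
    """SimulationConfig for the batch-free design.

    Defaults: Table-style design parameters (Y_PX=0.71, t_lag=0.25 h), 10 L
    initial volume, 10 L of 500 g/L feed, X0 = od600_0 * 0.232 g/L * V0 and
    S0 = S0_conc * V0 as preculture carry-over.
    """
    p = (params or KineticParameters.defaults()).for_process_design()
    feed = FeedSettings(
        mu_F=mu_F, F0=F0, feed_start_mode="fixed", t_feed_start=t_feed_start
    )
    return SimulationConfig(
        params=p,
        feed=feed,
        X0=od600_0 * OD_TO_CDW * V0,
        S0=S0_conc * V0,
        P0=0.0,
        A0=0.0,
        V0=V0,
        v0=v0,
        **solver_kwargs,
    )


@dataclass
class DesignResult:
    """Per-F0 sweep records plus failures; records sorted by F0."""

    table: pd.DataFrame
    failures: dict[float, str]

    def argmax(self, column: str) -> pd.Series:
        return self.table.loc[self.table[column].idxmax()]


def default_f0_grid(step: float = 0.5) -> np.ndarray:
    """1-100 g/h grid at the given step, plus the named operating points."""
    grid = np.arange(1.0, 100.0 + step / 2, step)
    named = np.array([14.7, 28.0, 38.0, 38.5, 40.0, 100.0])
    return np.unique(np.round(np.concatenate([grid, named]), 6))


def sweep_initial_feed_rate(
    cfg: SimulationConfig, F0_grid
) -> DesignResult:
    """Run one batch-free simulation per grid point and tabulate performance.

    Individual failures are recorded in `failures` and skipped in the table.
    """
    F0_grid = np.asarray(F0_grid, float)
    if F0_grid.size == 0 or np.any(F0_grid <= 0):
        raise ValidationError("F0 grid must be nonempty and positive")
    if cfg.feed.feed_start_mode != "fixed":
        raise ValidationError("feed-rate sweep requires the batch-free (fixed) mode")
    records = []
    failures: dict[float, str] = {}
    for f0 in np.sort(F0_grid):
        run_cfg = replace(cfg, feed=replace(cfg.feed, F0=float(f0)))
        try:
            traj = simulate_batch_free(run_cfg)
        except SimulationError as exc:
            failures[float(f0)] = str(exc)
            continue
        perf = compute_performance(traj)
        records.append(
            {
                "F0_gh": float(f0),
                "max_titre_gL": perf.max_titre,
                "P_end_g": perf.P_end,
                "V_end_L": perf.V_end,
                "t_end_h": perf.t_end,
                "sty_gLh": perf.P_V,
                "X_end_gL": float(traj.X[-1] / traj.V[-1]),
                "S_end_gL": float(traj.S[-1] / traj.V[-1]),
                "A_end_gL": float(traj.A[-1] / traj.V[-1]),
            }
        )
    table = pd.DataFrame.from_records(records).sort_values("F0_gh").reset_index(drop=True)
    return DesignResult(table=table, failures=failures)


def select_operating_point(
    res: DesignResult, policy: str, backoff: float = 0.25
) -> pd.Series:
    """Deterministic operating-point selection.

    policy='max_titre' or 'max_sty' return the argmax record; 'sty_backoff'
    returns the record whose F0 is closest to (1 - backoff) times the
    space-time-yield argmax F0, from below.
    """
    if res.table.empty:
        raise ValidationError("empty design result")
    if policy == "max_titre":
        return res.argmax("max_titre_gL")
    if policy == "max_sty":
        return res.argmax("sty_gLh")
    if policy == "sty_backoff":
        f_star = float(res.argmax("sty_gLh")["F0_gh"])
        target = (1.0 - backoff) * f_star
        below = res.table[res.table["F0_gh"] <= target + 1e-9]
        if below.empty:
            below = res.table[res.table["F0_gh"] < f_star]
        if below.empty:
            return res.argmax("sty_gLh")
        return below.loc[(target - below["F0_gh"]).abs().idxmin()]
    raise ValidationError(f"unknown selection policy {policy!r}")
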