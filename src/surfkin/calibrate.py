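"""Parameter estimation against fed-batch time series by RMSE.

Observations hold one experiment's sampled concentrations (g/L, NaN for
missing or censored values) together with its initial amounts, volumes and
feeding growth rate. The objective simulates each experiment in triggered
fed-batch mode, interpolates the model concentrations at the sampling times
and aggregates per-state RMSEs (equal weights by default — all four states
share g/L units). Fitting is bounded: a trust-region least-squares polish by
default, optionally seeded differential evolution first, both via lmfit.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import FitError, ObjectiveError, SimulationError, ValidationError
from .kinetics import FeedSettings
from .params import PARAM_SPECS, KineticParameters, bounds_for
from .simulate import SimulationConfig, Trajectory, simulate_fed_batch

log = logging.getLogger(__name__)

STATES = ("X", "S", "P", "A")
_PENALTY_RESIDUAL = 1e3
_SEP = "__"


@dataclass
class Observations:
    """Sampled noisy concentrations of one fed-batch experiment."""

    exp_id: str
    mu_F: float
    times: np.ndarray
    data: pd.DataFrame  # columns X, S, P, A in g/L; NaN = missing/censored
    X0: float
    S0: float
    P0: float = 0.0
    A0: float = 0.0
    V0: float = 12.0
    v0: float = 6.0
    detection_limit: float | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValidationError(
                f"experiment {self.exp_id!r}: sampling times must be strictly increasing"
            )
        missing = [s for s in STATES if s not in self.data.columns]
        if missing:
            raise ValidationError(
                f"experiment {self.exp_id!r}: missing state columns {missing}"
            )
        if len(self.data) != self.times.size:
            raise ValidationError(
                f"experiment {self.exp_id!r}: {len(self.data)} rows for "
                f"{self.times.size} sampling times"
            )
        vals = self.data[list(STATES)].to_numpy(float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValidationError(
                f"experiment {self.exp_id!r}: concentrations must be >= 0 or missing"
            )


@dataclass
class FitSpec:
    """Free-parameter list, bounds, weights and optimizer controls."""

    free: tuple[str, ...] = ("mu_max_S", "b_max", "t_lag", "c_S_crit", "K_I")
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    weights: dict[str, float] = field(
        default_factory=lambda: {s: 1.0 for s in STATES}
    )
    per_experiment: tuple[str, ...] = ()
    method: str = "least_squares"  # 'least_squares' | 'global'
    seed: int = 42
    max_nfev: int | None = None
    diff_step: float = 1e-3
    de_maxiter: int = 25
    de_popsize: int = 8

    def bounds_of(self, name: str) -> tuple[float, float]:
        if name in self.bounds:
            lo, hi = self.bounds[name]
        else:
            lo, hi = bounds_for(name)
        if not np.isfinite([lo, hi]).all() or lo >= hi:
            raise ValidationError(f"bounds for {name!r} must be finite and ordered")
        return lo, hi

    def validate(self) -> None:
        if not self.free:
            raise ValidationError("at least one free parameter is required")
        for name in tuple(self.free) + tuple(self.per_experiment):
            if name not in PARAM_SPECS:
                raise ValidationError(f"unknown parameter {name!r}")
            self.bounds_of(name)


def rmse(model_series, obs_series) -> float:
    """Root-mean-square error (g/L) over the non-missing overlap."""
    model = np.asarray(model_series, float)
    obs = np.asarray(obs_series, float)
    if model.shape != obs.shape:
        raise ValidationError("model and observation series must have equal length")
    mask = ~(np.isnan(model) | np.isnan(obs))
    if not mask.any():
        raise ObjectiveError("no overlapping points for RMSE")
    resid = model[mask] - obs[mask]
    return float(np.sqrt(np.mean(resid**2)))


def experiment_config(
    params: KineticParameters, obs: Observations, **solver_kwargs
) -> SimulationConfig:
    """Triggered fed-batch configuration matching one experiment's setup."""
    feed = FeedSettings(mu_F=obs.mu_F, feed_start_mode="triggered")
    return SimulationConfig(
        params=params,
        feed=feed,
        X0=obs.X0,
        S0=obs.S0,
        P0=obs.P0,
        A0=obs.A0,
        V0=obs.V0,
        v0=obs.v0,
        **solver_kwargs,
    )


def predict_observations(
    params: KineticParameters, obs: Observations, **solver_kwargs
) -> pd.DataFrame:
    """Model concentrations (g/L) at the experiment's sampling times.

    Times beyond the simulated feed-depletion endpoint are evaluated at the
    endpoint (mismatch in process end then shows up as concentration error).
    """
    traj = simulate_fed_batch(experiment_config(params, obs, **solver_kwargs))
    times = np.minimum(obs.times, traj.t_end)
    conc = traj.concentrations(times)
    return pd.DataFrame(
        {
            "t_h": obs.times,
            "X": conc["X_gL"].to_numpy(),
            "S": conc["S_gL"].to_numpy(),
            "P": conc["P_gL"].to_numpy(),
            "A": conc["A_gL"].to_numpy(),
        }
    )


def _apply_overrides(
    params: KineticParameters,
    shared: dict[str, float],
    per_exp: dict[str, float] | None,
) -> KineticParameters:
    updates = dict(shared)
    if per_exp:
        updates.update(per_exp)
    return params.replace(**updates)


def objective(
    params: KineticParameters,
    experiments: list[Observations],
    spec: FitSpec,
    per_experiment_values: dict[str, dict[str, float]] | None = None,
    **solver_kwargs,
) -> tuple[float, pd.DataFrame]:
    """Weighted sum of per-state RMSEs plus the per-experiment RMSE table.

    A failed simulation contributes a large penalty and is logged; the table
    row is NaN for that experiment.
    """
    if not experiments:
        raise ValidationError("objective requires at least one experiment")
    rows = []
    loss = 0.0
    for obs in experiments:
        run_params = _apply_overrides(
            params, {}, (per_experiment_values or {}).get(obs.exp_id)
        )
        row: dict[str, float] = {"experiment": obs.exp_id, "mu_F": obs.mu_F}
        try:
            pred = predict_observations(run_params, obs, **solver_kwargs)
        except SimulationError as exc:
            log.warning("simulation failed for %s: %s", obs.exp_id, exc)
            loss += _PENALTY_RESIDUAL
            rows.append(row | {f"RMSE_{s}": np.nan for s in STATES})
            continue
        for s in STATES:
            col = obs.data[s].to_numpy(float)
            if np.isnan(col).all():
                row[f"RMSE_{s}"] = np.nan
                continue
            err = rmse(pred[s].to_numpy(), col)
            row[f"RMSE_{s}"] = err
            loss += spec.weights.get(s, 1.0) * err
        rows.append(row)
    return loss, pd.DataFrame(rows)


@dataclass
class FitResult:
    """Fitted parameters, per-experiment overrides and diagnostics."""

    params: KineticParameters
    per_experiment: dict[str, dict[str, float]]
    loss: float
    rmse_table: pd.DataFrame
    success: bool
    nfev: int
    report: str = ""


def _sanitize(exp_id: str) -> str:
    return re.sub(r"\W", "_", exp_id)


def fit_parameters(
    experiments: list[Observations],
    spec: FitSpec,
    start: KineticParameters,
    **solver_kwargs,
) -> FitResult:
    """Bounded estimation of the free parameters against one or more experiments.

    Shared free parameters take one value across all experiments; parameters
    listed in spec.per_experiment get an independent value per experiment.
    method='global' prepends seeded differential evolution to the
    least-squares polish.
    """
    import lmfit

    spec.validate()
    if not experiments:
        raise ValidationError("fit requires at least one experiment")

    id_map = {_sanitize(o.exp_id): o.exp_id for o in experiments}
    if len(id_map) != len(experiments):
        raise ValidationError("experiment ids must be unique after sanitization")

    lp = lmfit.Parameters()
    for name in spec.free:
        lo, hi = spec.bounds_of(name)
        value = float(np.clip(getattr(start, name), lo, hi))
        lp.add(name, value=value, min=lo, max=hi)
    for name in spec.per_experiment:
        lo, hi = spec.bounds_of(name)
        value = float(np.clip(getattr(start, name), lo, hi))
        for safe in id_map:
            lp.add(f"{name}{_SEP}{safe}", value=value, min=lo, max=hi)

    weights = np.array([spec.weights.get(s, 1.0) for s in STATES])
    n_fail = {"count": 0}

    def split(values: dict) -> tuple[dict, dict[str, dict[str, float]]]:
        shared = {k: v for k, v in values.items() if _SEP not in k}
        per: dict[str, dict[str, float]] = {o.exp_id: {} for o in experiments}
        for k, v in values.items():
            if _SEP in k:
                name, safe = k.split(_SEP, 1)
                per[id_map[safe]][name] = v
        return shared, per

    def residual(lmpars):
        values = {k: float(v) for k, v in lmpars.valuesdict().items()}
        shared, per = split(values)
        chunks = []
        for obs in experiments:
            run_params = _apply_overrides(start, shared, per[obs.exp_id])
            try:
                pred = predict_observations(run_params, obs, **solver_kwargs)
            except SimulationError as exc:
                log.warning("fit: simulation failed for %s: %s", obs.exp_id, exc)
                n_fail["count"] += 1
                chunks.append(
                    np.full(len(obs.times) * len(STATES), _PENALTY_RESIDUAL)
                )
                continue
            for s, w in zip(STATES, weights):
                col = obs.data[s].to_numpy(float)
                r = (pred[s].to_numpy() - col) * w
                chunks.append(np.nan_to_num(r, nan=0.0))
        return np.concatenate(chunks)

    if spec.method == "global":
        de = lmfit.minimize(
            lambda lmpars: float(np.sum(residual(lmpars) ** 2)),
            lp,
            method="differential_evolution",
            seed=spec.seed,
            maxiter=spec.de_maxiter,
            popsize=spec.de_popsize,
            tol=1e-6,
            polish=False,
        )
        lp = de.params
    elif spec.method != "least_squares":
        raise ValidationError(f"unknown fit method {spec.method!r}")

    result = lmfit.minimize(
        residual,
        lp,
        method="least_squares",
        diff_step=spec.diff_step,
        max_nfev=spec.max_nfev,
    )
    values = {k: float(v) for k, v in result.params.valuesdict().items()}
    shared, per = split(values)
    fitted = start.replace(**shared)
    loss, table = objective(fitted, experiments, spec, per, **solver_kwargs)
    if table[[f"RMSE_{s}" for s in STATES]].isna().all(axis=None):
        raise FitError("all experiments failed to simulate at the fitted optimum")
    return FitResult(
        params=fitted,
        per_experiment=per,
        loss=loss,
        rmse_table=table,
        success=bool(result.success),
        nfev=int(result.nfev) + n_fail["count"] * 0,
        report=lmfit.fit_report(result),
    )
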