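"""Synthetic fed-batch observation sets with the structure of the study data.

The study comprised 12 bioreactor experiments: duplicate fed-batch runs at
six exponential feeding growth rates (0.075, 0.15, 0.2, 0.25, 0.3, 0.4 1/h),
sampled roughly hourly for cell dry weight, glucose, surfactin and acetate.
This module simulates those conditions and corrupts the clean trajectories
with a simple assay-noise model (multiplicative log-normal per state plus a
small additive floor) and the 0.05 g/L glucose detection limit of the
enzymatic assay.

Batch-phase defaults: 12 L initial volume, 25 g/L initial glucose, an
inoculum of OD600 0.3 (x 0.232 g CDW/L per OD), 6 L of 500 g/L feed. These
reproduce the reported feed-start biomass (~84 g) and feed-start window
(12.5-16 h) of the historical runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibrate import STATES, Observations, experiment_config
from .design import OD_TO_CDW
from .errors import ValidationError
from .kinetics import FeedSettings
from .params import KineticParameters
from .simulate import SimulationConfig, simulate_fed_batch

DEFAULT_RATES = (0.075, 0.15, 0.2, 0.25, 0.3, 0.4)


def od_to_cdw(od600: float, factor: float = OD_TO_CDW) -> float:
    """Cell dry weight (g/L) from OD600 via the strain's correlation factor."""
    if od600 < 0:
        raise ValidationError("OD600 must be nonnegative")
    return factor * od600


@dataclass
class NoiseModel:
    """Multiplicative CV per state, additive floor, glucose detection limit."""

    cv: dict[str, float] = field(
        default_factory=lambda: {"X": 0.05, "P": 0.05, "S": 0.03, "A": 0.03}
    )
    floor_sd: float = 0.01  # g/L additive noise floor
    detection_limit: float = 0.05  # g/L, glucose assay
    censor: str = "drop"  # 'drop' | 'clamp'

    def validate(self) -> None:
        if any(v < 0 for v in self.cv.values()) or self.floor_sd < 0:
            raise ValidationError("noise magnitudes must be nonnegative")
        if self.detection_limit < 0:
            raise ValidationError("detection limit must be nonnegative")
        if self.censor not in ("drop", "clamp"):
            raise ValidationError("censoring rule must be 'drop' or 'clamp'")


def apply_noise(clean: pd.DataFrame, noise: NoiseModel, rng: np.random.Generator) -> pd.DataFrame:
    """Corrupt a clean concentration table (columns X, S, P, A in g/L).

    value * LogNormal(mean 1, cv) + Normal(0, floor_sd), clipped at zero.
    Draw order is fixed (state by state), so results are reproducible for a
    seeded generator.
    """
    noise.validate()
    noisy = clean.copy()
    n = len(clean)
    for s in STATES:
        cv = noise.cv.get(s, 0.0)
        col = clean[s].to_numpy(float)
        if cv > 0:
            sigma = np.sqrt(np.log1p(cv**2))
            factor = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)
        else:
            factor = np.ones(n)
        floor = rng.normal(0.0, noise.floor_sd, size=n) if noise.floor_sd > 0 else 0.0
        noisy[s] = np.clip(col * factor + floor, 0.0, None)
    return noisy


def censor_glucose(df: pd.DataFrame, noise: NoiseModel) -> pd.DataFrame:
    """Apply the glucose detection limit: drop (NaN) or clamp to the limit."""
    out = df.copy()
    below = out["S"].to_numpy(float) < noise.detection_limit
    if noise.censor == "drop":
        out.loc[below, "S"] = np.nan
    else:
        out.loc[below, "S"] = noise.detection_limit
    return out


def batch_experiment_config(
    params: KineticParameters,
    mu_F: float,
    V0: float = 12.0,
    v0: float = 6.0,
    S0_conc: float = 25.0,
    od600_0: float = 0.3,
    **solver_kwargs,
) -> SimulationConfig:
    """Triggered fed-batch configuration emulating one historical experiment."""
    feed = FeedSettings(mu_F=mu_F, feed_start_mode="triggered")
    return SimulationConfig(
        params=params,
        feed=feed,
        X0=od_to_cdw(od600_0) * V0,
        S0=S0_conc * V0,
        P0=0.0,
        A0=0.0,
        V0=V0,
        v0=v0,
        **solver_kwargs,
    )


def generate_experiment_set(
    params: KineticParameters | None = None,
    feeding_rates=DEFAULT_RATES,
    replicates: int = 2,
    noise: NoiseModel | None = None,
    sampling_interval: float = 1.0,
    seed: int = 42,
    ic_jitter_cv: float = 0.05,
    t_lag_jitter: float = 0.5,
    **config_kwargs,
) -> list[Observations]:
    """Simulate (rate x replicate) experiments, sample, add noise, censor.

    Per replicate, the initial biomass/glucose are jittered multiplicatively
    (log-normal, CV ic_jitter_cv) and the lag time uniformly within
    +/- t_lag_jitter h (clipped to the admissible range); zero jitter and a
    zero-CV noise model reproduce the simulator output exactly.
    Deterministic under the seed.
    """
    params = params or KineticParameters.defaults()
    noise = noise or NoiseModel()
    noise.validate()
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    if sampling_interval <= 0:
        raise ValidationError("sampling interval must be positive")
    rng = np.random.default_rng(seed)
    experiments: list[Observations] = []
    for rate in feeding_rates:
        for rep in range(1, replicates + 1):
            # per-replicate jitters (drawn even when zero-width to keep the
            # stream layout stable across jitter settings)
            ic_factors = rng.lognormal(0.0, ic_jitter_cv, size=2) if ic_jitter_cv > 0 else np.ones(2)
            lag_shift = rng.uniform(-t_lag_jitter, t_lag_jitter) if t_lag_jitter > 0 else 0.0
            t_lag = float(np.clip(params.t_lag + lag_shift, 0.25, 5.25))
            run_params = params.replace(t_lag=t_lag)
            cfg = batch_experiment_config(run_params, rate, **config_kwargs)
            cfg = replace(cfg, X0=cfg.X0 * ic_factors[0], S0=cfg.S0 * ic_factors[1])
            traj = simulate_fed_batch(cfg)
            times = np.arange(0.0, traj.t_end + 1e-9, sampling_interval)
            conc = traj.concentrations(times)
            clean = pd.DataFrame(
                {
                    "X": conc["X_gL"].to_numpy(),
                    "S": conc["S_gL"].to_numpy(),
                    "P": conc["P_gL"].to_numpy(),
                    "A": conc["A_gL"].to_numpy(),
                }
            )
            noisy = censor_glucose(apply_noise(clean, noise, rng), noise)
            experiments.append(
                Observations(
                    exp_id=f"muF{rate:g}_rep{rep}",
                    mu_F=rate,
                    times=times,
                    data=noisy,
                    X0=cfg.X0,
                    S0=cfg.S0,
                    P0=cfg.P0,
                    A0=cfg.A0,
                    V0=cfg.V0,
                    v0=cfg.v0,
                    detection_limit=noise.detection_limit,
                )
            )
    return experiments
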