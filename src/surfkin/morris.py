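"""Morris elementary-effects screening of the model parameters.

One-at-a-time trajectories are sampled on a regular grid in the normalized
[0, 1]^k hypercube (p discretization levels, step delta) and mapped affinely
onto each parameter's +/- range around its nominal value. For each objective
(per-state RMSE against a reference experiment by default) the mean absolute
elementary effect mu* ranks parameter influence. Effects are computed in the
normalized space, so mu* is range-relative — appropriate here because the
parameters span several orders of magnitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibrate import STATES, Observations, predict_observations, rmse
from .errors import SimulationError, ValidationError
from .params import KineticParameters

log = logging.getLogger(__name__)

#: biological parameter set screened by default (17 parameters; the feed
#: configuration, volume correction and experiment settings are excluded)
DEFAULT_SCREEN = (
    "mu_max_S",
    "mu_max_A",
    "K_S",
    "K_A",
    "K_I",
    "Y_true_XS",
    "Y_PX",
    "Y_PS",
    "Y_AS",
    "Y_XA",
    "m_S",
    "m_A",
    "t_lag",
    "b_max",
    "c_S_crit",
    "c_S_crit_A1",
    "c_S_crit_A2",
)


@dataclass
class MorrisDesign:
    """Screening configuration: parameter list, ranges and sampling controls."""

    names: tuple[str, ...] = DEFAULT_SCREEN
    nominal: dict[str, float] = field(default_factory=dict)
    rel_range: float = 0.10
    r: int = 50
    levels: int = 6
    delta: float = 0.2
    seed: int = 42
    objectives: tuple[str, ...] = tuple(f"RMSE_{s}" for s in STATES)

    @property
    def k(self) -> int:
        return len(self.names)

    def validate(self) -> None:
        if self.k == 0:
            raise ValidationError("Morris design requires at least one parameter")
        if self.r < 2:
            raise ValidationError("Morris design requires r >= 2 trajectories")
        if self.levels < 2 or self.levels % 2:
            raise ValidationError("number of levels must be even and >= 2")
        if not 0.0 < self.delta < 1.0:
            raise ValidationError("delta must lie in (0, 1)")
        if self.rel_range <= 0:
            raise ValidationError("relative range must be positive")

    def nominal_vector(self, base: KineticParameters | None = None) -> np.ndarray:
        base_dict = (base or KineticParameters.defaults()).to_dict()
        return np.array(
            [self.nominal.get(n, base_dict[n]) for n in self.names], float
        )


@dataclass
class MorrisTrace:
    """Bookkeeping of the one-at-a-time moves: which parameter moved when."""

    order: np.ndarray  # (r, k) parameter index moved at each step
    signs: np.ndarray  # (r, k) direction of each move (+1/-1)


@dataclass
class MorrisResult:
    """mu* table (parameters x objectives), raw effects and evaluation count."""

    mu_star: pd.DataFrame
    effects: np.ndarray  # (r, k, n_objectives), NaN where excluded
    n_evaluations: int


def morris_sample(design: MorrisDesign) -> tuple[np.ndarray, MorrisTrace]:
    """Sample r one-at-a-time trajectories in [0, 1]^k.

    Returns the (r*(k+1), k) matrix of normalized parameter vectors and the
    move bookkeeping. Deterministic under the design seed; trajectories are
    drawn sequentially, so a smaller r is a prefix of a larger one.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    k, r, p, delta = design.k, design.r, design.levels, design.delta
    grid = np.arange(p) / (p - 1)
    rows = np.empty((r * (k + 1), k))
    order = np.empty((r, k), dtype=int)
    signs = np.empty((r, k), dtype=int)
    for i in range(r):
        x = rng.choice(grid, size=k)
        perm = rng.permutation(k)
        x_cur = x.copy()
        rows[i * (k + 1)] = x_cur
        for step, j in enumerate(perm):
            feasible = [s for s in (+1, -1) if 0.0 <= x_cur[j] + s * delta <= 1.0]
            s = int(rng.choice(feasible))
            x_cur = x_cur.copy()
            x_cur[j] += s * delta
            rows[i * (k + 1) + step + 1] = x_cur
            order[i, step] = j
            signs[i, step] = s
    return rows, MorrisTrace(order=order, signs=signs)


def to_physical(unit_samples: np.ndarray, design: MorrisDesign,
                base: KineticParameters | None = None) -> np.ndarray:
    """Map normalized samples onto nominal * (1 - range + 2*range*u)."""
    nominal = design.nominal_vector(base)
    lo = nominal * (1.0 - design.rel_range)
    hi = nominal * (1.0 + design.rel_range)
    return lo + (hi - lo) * unit_samples


def elementary_effects(
    samples: np.ndarray, outputs: np.ndarray, design: MorrisDesign, trace: MorrisTrace
) -> MorrisResult:
    """Per-parameter elementary effects and mu* from evaluated sample rows.

    outputs has shape (r*(k+1),) or (r*(k+1), n_objectives); NaN outputs
    (failed evaluations) void the affected effects, which are excluded from
    mu* with a warning.
    """
    design.validate()
    outputs = np.asarray(outputs, float)
    if outputs.ndim == 1:
        outputs = outputs[:, None]
    k, r, delta = design.k, design.r, design.delta
    n_expected = r * (k + 1)
    if samples.shape[0] != n_expected or outputs.shape[0] != n_expected:
        raise ValidationError(
            f"expected {n_expected} sample rows (r*(k+1)), got {samples.shape[0]}"
        )
    m = outputs.shape[1]
    ee = np.full((r, k, m), np.nan)
    for i in range(r):
        base_row = i * (k + 1)
        for step in range(k):
            j = trace.order[i, step]
            f0 = outputs[base_row + step]
            f1 = outputs[base_row + step + 1]
            ee[i, j] = trace.signs[i, step] * (f1 - f0) / delta
    n_bad = int(np.isnan(ee[:, :, 0]).sum())
    if n_bad:
        log.warning("%d elementary effects excluded (failed evaluations)", n_bad)
    with np.errstate(invalid="ignore"):
        mu_star = np.nanmean(np.abs(ee), axis=0)
    table = pd.DataFrame(
        mu_star, index=list(design.names), columns=list(design.objectives)[:m]
        if m == len(design.objectives)
        else [f"objective_{i}" for i in range(m)],
    )
    return MorrisResult(mu_star=table, effects=ee, n_evaluations=n_expected)


def run_morris(
    base_params: KineticParameters,
    reference: Observations,
    design: MorrisDesign | None = None,
    **solver_kwargs,
) -> MorrisResult:
    """Full screen: sample, simulate against the reference, rank mu*.

    Each sampled parameter vector is simulated in triggered fed-batch mode
    with the reference experiment's setup; the four per-state RMSEs are the
    objectives. Failed simulations yield NaN rows and are excluded.
    """
    design = design or MorrisDesign()
    samples, trace = morris_sample(design)
    physical = to_physical(samples, design, base_params)
    outputs = np.full((samples.shape[0], len(STATES)), np.nan)
    obs_cols = {s: reference.data[s].to_numpy(float) for s in STATES}
    for row in range(physical.shape[0]):
        params = base_params.replace(
            **dict(zip(design.names, physical[row]))
        )
        try:
            pred = predict_observations(params, reference, **solver_kwargs)
        except (SimulationError, ValidationError) as exc:
            log.warning("Morris evaluation %d failed: %s", row, exc)
            continue
        for col, s in enumerate(STATES):
            if np.isnan(obs_cols[s]).all():
                continue
            outputs[row, col] = rmse(pred[s].to_numpy(), obs_cols[s])
    return elementary_effects(samples, outputs, design, trace)
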