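"""Carbon mass balance for model validation.

Endpoint masses of glucose, biomass, surfactin and acetate are converted to
carbon equivalents (mol C) with factors derived from each species' carbon
atom count and molar mass; carbon recovery is the percentage of the fed
glucose carbon found in biomass, product and by-product. The model has no
explicit CO2 sink, so recovery below 100% is expected (respiration and minor
by-products are unmodelled).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError


def carbon_factor(atoms: float, molar_mass: float) -> float:
    """Carbon conversion factor (mol C per g) = atoms / molar_mass."""
    if atoms < 1:
        raise ValidationError("carbon atom count must be >= 1")
    if molar_mass <= 0:
        raise ValidationError("molar mass must be positive")
    return atoms / molar_mass


@dataclass(frozen=True)
class CarbonFactors:
    """Per-species carbon conversion factors (mol C / g).

    Defaults: glucose 6 C / 180.16 g/mol, B. subtilis biomass on a
    1 C / 24.83 g/mol-C basis, surfactin 53 C / 1036.34 g/mol, acetate
    2 C / 60.05 g/mol.
    """

    glucose: float = carbon_factor(6, 180.16)
    biomass: float = carbon_factor(1, 24.83)
    surfactin: float = carbon_factor(53, 1036.34)
    acetate: float = carbon_factor(2, 60.05)


DEFAULT_FACTORS = CarbonFactors()


def carbon_recovery(
    glucose_in: float,
    biomass: float,
    product: float,
    acetate: float,
    factors: CarbonFactors = DEFAULT_FACTORS,
) -> float:
    """Carbon recovery in percent: 100 * (C_X + C_P + C_A) / C_S_in.

    All inputs are masses in g; glucose_in is the total glucose supplied
    (initial charge plus feed).
    """
    if glucose_in <= 0:
        raise ValidationError("carbon recovery undefined for zero glucose input")
    if min(biomass, product, acetate) < 0:
        raise ValidationError("output masses must be nonnegative")
    c_in = glucose_in * factors.glucose
    c_out = (
        biomass * factors.biomass
        + product * factors.surfactin
        + acetate * factors.acetate
    )
    return 100.0 * c_out / c_in


def recovery_from_mol_c(c_biomass: float, c_product: float, c_acetate: float,
                        c_glucose_in: float) -> float:
    """Carbon recovery in percent directly from mol-C pools."""
    if c_glucose_in <= 0:
        raise ValidationError("carbon recovery undefined for zero carbon input")
    return 100.0 * (c_biomass + c_product + c_acetate) / c_glucose_in


def trajectory_carbon_balance(traj, factors: CarbonFactors = DEFAULT_FACTORS) -> dict:
    """Mol-C pools and recovery for a completed trajectory.

    Glucose input = initial glucose + c_S_feed * (v0 - v_end).
    """
    cfg = traj.config
    glucose_in = cfg.S0 + cfg.params.c_S_feed * (cfg.v0 - float(traj.v[-1]))
    pools = {
        "mol_C_glucose_in": glucose_in * factors.glucose,
        "mol_C_biomass": float(traj.X[-1]) * factors.biomass,
        "mol_C_surfactin": float(traj.P[-1]) * factors.surfactin,
        "mol_C_acetate": float(traj.A[-1]) * factors.acetate,
    }
    pools["recovery_percent"] = carbon_recovery(
        glucose_in, float(traj.X[-1]), float(traj.P[-1]), float(traj.A[-1]), factors
    )
    return pools
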