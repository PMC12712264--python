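"""Kinetic parameters of the *B. subtilis* BMV9 fed-batch surfactin model.

The defaults describe the published operating point of the process
(strain BMV9, 37 °C, pH 7, pO2 50%): Monod constants for growth on
glucose and on the overflow metabolite acetate, stoichiometric and Pirt
yields, maintenance coefficients, the glucose thresholds that switch
acetate formation/consumption on and off, and the feed configuration
(500 g/L glucose solution, density 1180 g/L, volume correction 0.8).

Each parameter carries a fixed/free flag and, for the free (fitting)
parameters, the admissible range used for bounded estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace, asdict

from .errors import ConfigurationError


@dataclass(frozen=True)
class ParamSpec:
    """Metadata for one model parameter: default, unit, fixed flag, fit bounds."""

    default: float
    unit: str
    fixed: bool
    lower: float | None = None
    upper: float | None = None
    description: str = ""


#: Registry of every model parameter. Free parameters carry fitting bounds.
PARAM_SPECS: dict[str, ParamSpec] = {
    # growth kinetics
    "mu_max_S": ParamSpec(0.5, "1/h", False, 0.36, 1.0,
                          "maximum specific growth rate on glucose"),
    "mu_max_A": ParamSpec(0.5, "1/h", False, 0.36, 1.0,
                          "maximum specific growth rate on acetate"),
    "K_S": ParamSpec(0.05, "g/L", True, description="glucose half-saturation constant"),
    "K_A": ParamSpec(0.05, "g/L", True, description="acetate half-saturation constant"),
    "K_I": ParamSpec(5.0, "g/L", False, 1.0, 10.0,
                     "acetate inhibition constant on glucose growth"),
    # yields
    "Y_true_XS": ParamSpec(0.45, "g/g", False, 0.4, 0.46,
                           "theoretical maximum biomass-per-glucose yield (Pirt)"),
    "Y_PX": ParamSpec(0.71, "g/g", False, 0.54, 0.75,
                      "surfactin-per-biomass yield (growth-associated product)"),
    "Y_PS": ParamSpec(0.46, "g/g", True, description="surfactin-per-glucose stoichiometric yield"),
    "Y_AS": ParamSpec(0.67, "g/g", True, description="acetate-per-glucose stoichiometric yield"),
    "Y_XA": ParamSpec(0.45, "g/g", False, 0.2, 0.6,
                      "biomass-per-acetate yield"),
    "Y_XS_batch": ParamSpec(0.28, "g/g", True, 0.22, 0.37,
                            "batch-phase biomass yield (normally recomputed from the trajectory)"),
    # maintenance
    "m_S": ParamSpec(0.05, "g/(g*h)", True, description="glucose maintenance coefficient"),
    "m_A": ParamSpec(0.05, "g/(g*h)", True, description="acetate maintenance coefficient"),
    # lag phase
    "t_lag": ParamSpec(2.75, "h", False, 0.25, 5.25, "lag-phase duration"),
    # switching thresholds
    "c_S_crit": ParamSpec(0.05, "g/L", False, 0.005, 0.5,
                          "critical glucose concentration: feed trigger and acetate-use gate"),
    "c_S_crit_A1": ParamSpec(0.075, "g/L", False, 0.05, 0.1,
                             "glucose threshold below which acetate formation stops"),
    "c_S_crit_A2": ParamSpec(5.0, "g/L", False, 1.0, 10.0,
                             "glucose threshold above which acetate formation is maximal"),
    "b_max": ParamSpec(0.072, "1/h", False, 0.01, 0.2,
                       "maximum specific acetate formation rate"),
    # feed configuration
    "c_S_feed": ParamSpec(500.0, "g/L", True, description="glucose concentration of the feed"),
    "rho_feed": ParamSpec(1180.0, "g/L", True, description="density of the feed solution"),
    "c_vol": ParamSpec(0.8, "-", True,
                       description="volume correction factor for the feed inflow"),
}


@dataclass
class KineticParameters:
    """One concrete parameter set (all values as plain floats, units per PARAM_SPECS)."""

    mu_max_S: float = 0.5
    mu_max_A: float = 0.5
    K_S: float = 0.05
    K_A: float = 0.05
    K_I: float = 5.0
    Y_true_XS: float = 0.45
    Y_PX: float = 0.71
    Y_PS: float = 0.46
    Y_AS: float = 0.67
    Y_XA: float = 0.45
    Y_XS_batch: float = 0.28
    m_S: float = 0.05
    m_A: float = 0.05
    t_lag: float = 2.75
    c_S_crit: float = 0.05
    c_S_crit_A1: float = 0.075
    c_S_crit_A2: float = 5.0
    b_max: float = 0.072
    c_S_feed: float = 500.0
    rho_feed: float = 1180.0
    c_vol: float = 0.8

    @classmethod
    def defaults(cls) -> "KineticParameters":
        return cls()

    def for_process_design(self) -> "KineticParameters":
        """Parameter overrides used for the batch-free design: Y_PX=0.71, t_lag=0.25 h."""
        return replace(self, Y_PX=0.71, t_lag=0.25)

    def replace(self, **updates: float) -> "KineticParameters":
        return replace(self, **updates)

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def names(cls) -> list[str]:
        return [f.name for f in fields(cls)]

    @classmethod
    def free_names(cls) -> list[str]:
        return [n for n, s in PARAM_SPECS.items() if not s.fixed]

    def validate(self) -> None:
        """Check nonnegativity and threshold ordering; raise ConfigurationError."""
        for name, value in self.to_dict().items():
            if not (value >= 0.0):
                raise ConfigurationError(f"parameter {name!r} must be >= 0, got {value}")
        if not self.c_S_crit_A1 < self.c_S_crit_A2:
            raise ConfigurationError(
                "acetate formation thresholds must satisfy c_S_crit_A1 < c_S_crit_A2 "
                f"(got {self.c_S_crit_A1} >= {self.c_S_crit_A2})"
            )
        for name in ("Y_true_XS", "Y_PS", "Y_AS", "Y_XS_batch"):
            if getattr(self, name) > 1.0:
                raise ConfigurationError(f"yield {name!r} must be <= 1 g/g")
        if self.rho_feed <= 0 or self.c_S_feed <= 0:
            raise ConfigurationError("feed concentration and density must be positive")


def bounds_for(name: str) -> tuple[float, float]:
    """Fitting bounds for a free parameter (ConfigurationError if none declared)."""
    spec = PARAM_SPECS[name]
    if spec.lower is None or spec.upper is None:
        raise ConfigurationError(f"parameter {name!r} has no declared fitting range")
    return (spec.lower, spec.upper)
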