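# Methods

## Model structure and assumptions

The process model is an unstructured, four-state ODE system for fed-batch
surfactin production by *Bacillus subtilis* (strain BMV9 conditions: 37 °C,
pH 7, pO2 50%). It is formulated in absolute amounts — biomass X, glucose S,
surfactin P, acetate A, all in g — because the reactor volume changes during
feeding; every kinetic term divides by the filling volume V to act on
concentrations.

Assumptions, in the order they enter the equations:

- **Lag phase.** For t < t_lag all biological rates (mu_S, mu_A, b, and
  acetate maintenance) are zero and substrate is untouched; feeding, if
  active, still adds glucose and volume. This is the simplest mechanism
  consistent with a fitted lag duration; the alternative of letting product
  formation continue during lag is moot because production is tied to mu_S.
- **Growth on glucose** is Monod in S/V with a general (Yano–Koga style)
  inhibition term K_I/(A/V + K_I) in acetate. The inhibition applies to
  mu_S only; growth on acetate is uninhibited.
- **Growth on acetate** is Monod in A/V and requires three gates
  simultaneously: acetate present, glucose present, and glucose below the
  critical concentration c_S_crit (the organism co-utilizes acetate only
  under glucose limitation).
- **Glucose consumption** combines the feed inflow (F/rho_feed · c_S_feed),
  a Pirt drain mu_S/Y_X/S(mu_S) · X with Y_X/S(mu) = mu/(mu/Y_true + m_S)
  — equivalently (mu_S/Y_true + m_S)·X for mu_S > 0, defined as 0 at
  mu_S = 0 — and stoichiometric drains (1/Y_P/S)·dP/dt and
  (1/Y_A/S)·(formation part of dA/dt). The acetate drain counts only the
  formation term b·X and is set to zero whenever the consumption regime is
  active; acetate consumption never credits glucose back.
- **Product formation** is purely growth-associated: dP/dt = mu_S·Y_P/X·X
  (a Luedeking–Piret law with the non-growth term set to zero, matching the
  observed coupling of surfactin to growth).
- **Acetate formation** switches on linearly in glucose concentration
  between two thresholds c_S_crit_A1 and c_S_crit_A2 and saturates at
  b_max; the linear law is clamped to [0, b_max] outside the thresholds, so
  b is continuous and piecewise linear. Acetate consumption
  (m_A + mu_A/Y_X/A)·X is active exactly when the growth-on-acetate gate is
  open; with the default thresholds (c_S_crit = 0.05 < c_S_crit_A1 = 0.075
  g/L) formation and consumption are mutually exclusive.
- **Volumes.** The filling volume grows as c·F/rho_feed during feeding
  (c = 0.8 lumps sampling, pH agents, antifoam and the feed's water
  content); it is constant during the batch phase. The feed reservoir
  shrinks as F/rho_feed; integration stops when it empties. In the
  batch-free mode the correction factor applies from the first feed
  instant.

### Feeding modes

- **Triggered (classic fed-batch).** The batch is integrated until S/V
  crosses c_S_crit from above. At that event the biomass X_FS and time t_FS
  are recorded, the batch biomass yield is computed from the trajectory
  ledger, Y_X/S,batch = (X_FS − X0)/(S0 − S_FS), and the initial feed rate
  follows as F0 = (mu_F/Y_X/S,batch + m_S)·X_FS/c_S_feed·rho_feed. A
  configured fixed batch yield can be used instead
  (`batch_yield_mode="fixed"`).
- **Batch-free (design mode).** Feeding starts at a fixed time (default
  1 min after inoculation) with a user-chosen F0. The feed clock in
  F(t) = F0·exp(mu_F·(t − t_FS)) runs from the feed start, not from
  inoculation.

### Model variants

`variant="no_overflow"` removes every acetate-related effect — formation,
consumption, growth on acetate and the inhibition term — leaving plain
Monod/Pirt dynamics. Wherever the full model keeps acetate identically zero
(no initial acetate and b_max = 0) the two variants coincide; the test
suite asserts this equivalence.

## Parameters

Defaults (units, fixed/free status and fitting ranges) live in
`surfkin.params.PARAM_SPECS`. Highlights:

| parameter | default | unit | status |
|---|---|---|---|
| mu_max_S, mu_max_A | 0.5 | 1/h | free, 0.36–1 |
| K_S = K_A | 0.05 | g/L | fixed |
| K_I | 5 | g/L | free, 1–10 |
| Y_X/S^true | 0.45 | g/g | free, 0.4–0.46 |
| Y_P/X | 0.71 | g/g | free, 0.54–0.75 |
| Y_P/S / Y_A/S | 0.46 / 0.67 | g/g | fixed (stoichiometry) |
| Y_X/A | 0.45 | g/g | free, 0.2–0.6 |
| m_S = m_A | 0.05 | g/(g·h) | fixed |
| t_lag | 2.75 | h | free, 0.25–5.25 |
| c_S_crit | 0.05 | g/L | free, 0.005–0.5 |
| c_S_crit_A1 / A2 | 0.075 / 5 | g/L | free |
| b_max | 0.072 | 1/h | free, 0.01–0.2 |
| c_S_feed / rho_feed / c | 500 / 1180 / 0.8 | g/L, g/L, – | fixed |

Three defaults required a choice where only ranges are reported: Y_P/X is
set to 0.71 (the value used for the process-design configuration, inside
the observed 0.54–0.75 range), t_lag to 2.75 h (mid-range of 0.25–5.25; lag
is a per-run quantity in reality), and Y_X/A carries invented fitting
bounds 0.2–0.6 (±~30% around its 0.45 value) because none are reported.
`KineticParameters.for_process_design()` applies the design overrides
(Y_P/X = 0.71, t_lag = 0.25 h).

## Numerical integration

The right-hand side is piecewise-defined, so the simulator is event-driven:
LSODA (stiff-capable multistep) integrates each regime segment and restarts
at every switching event — feed trigger, fixed feed start, lag end, the
glucose gate for acetate consumption, acetate-pool depletion, feed
depletion. Restarting prevents the multistep history from smearing the
derivative discontinuities. After each event a 1e-7 h explicit-Euler
micro-step moves the state off the switching surface so the restarted event
functions have a definite sign (root finders misbehave when a segment
starts exactly on a root). Defaults: rtol 1e-8, atol 1e-10 g, max step
0.05 h (keeps the exponential feed resolved), dense output sampled on a
0.02 h grid. State amounts are clipped at zero in post-processing only;
the acetate pool is clamped to zero at its depletion event and its
consumption terms are disabled until it becomes positive again. Halving
the tolerances moves the endpoint titre by far less than 0.1% (asserted in
the suite).

Degenerate inputs: triggered mode refuses S0 at or below the trigger
threshold; a trigger never crossed within t_max (default 120 h) raises a
feed-start error; feeding not finished by t_max raises an integration
error; more than 1000 event restarts is treated as regime chattering and
aborts.

## Performance indicators and carbon balance

`compute_performance` evaluates the endpoint ledgers at feed depletion:
P_V = P_end/(V_end·t_end); overall yields ΔP/ΔX, ΔP/ΔS_consumed,
ΔX/ΔS_consumed with S_consumed = S0 + c_S_feed·(v0 − v_end) − S_end; the
specific rates q_P/X and q_P/S are the corresponding yields divided by the
process time; the instantaneous productivity series is (dP/dt)/X =
mu_S·Y_P/X.

The carbon balance converts endpoint masses to mol C with factors
atoms/molar-mass: glucose 6/180.16, surfactin 53/1036.34, acetate 2/60.05,
and biomass on a 1 C per 24.83 g/mol-C basis. Recovery is the percentage of
fed glucose carbon (initial charge plus c_S_feed·(v0 − v_end)) found in
biomass, product and acetate. The model has no CO2 sink, so recovery is
reported, not bounded — values near 55–60% are expected, the gap being
respiration and minor by-products.

## Calibration

The objective simulates each experiment in triggered mode from its own
initial amounts and feeding growth rate, interpolates model concentrations
at the sampling times (times beyond the simulated endpoint are held at the
endpoint, so process-length mismatch surfaces as concentration error) and
sums per-state RMSEs. All four states share g/L units, so the default
aggregation is an unweighted sum; weights are configurable. Missing values
and censored glucose points (below the 0.05 g/L assay detection limit)
enter as NaN and are excluded from the RMSE; a clamp-at-limit censoring
mode is available in the generator for sensitivity checks.

Fitting is bounded (ranges above) via lmfit: a trust-region least-squares
polish on the stacked residual vector by default (finite-difference step
1e-3 relative, chosen well above the integration noise floor), optionally
preceded by seeded differential evolution (`method="global"`, default seed
42). Parameters listed as per-experiment (typically t_lag, optionally
Y_P/X) get independent values per experiment; all others are shared in a
joint fit. Simulation failures during fitting contribute a large constant
penalty residual and are logged. On noiseless synthetic data the five free
parameters mu_max_S, b_max, t_lag, c_S_crit and K_I are recovered to
machine-level accuracy (the suite asserts ≤1%) provided the experiment set
spans both glucose-limited and overflow regimes — a 0.4 1/h run is included
for exactly that reason, since K_I and b_max are barely excited at moderate
feeding rates.

## Sensitivity screening

The Morris elementary-effects screen perturbs 17 biological parameters
±10% around their nominal values (feed configuration, volume correction and
the experiment setting mu_F are excluded; the set is configurable).
Trajectories are sampled one-at-a-time on a 6-level grid in the normalized
unit cube with step delta = 0.2 (delta is interpreted in normalized space,
the standard convention); r trajectories cost r·(k+1) simulations. Effects
are computed in normalized space, so mu* is range-relative — appropriate
because the parameters span four orders of magnitude. Defaults r = 50,
seed 42; trajectories are drawn sequentially from one generator, so a
reduced-r screen is a prefix of a larger one under the same seed. Failed
simulations void only the affected elementary effects, which are excluded
from mu* with a warning.

A caveat on interpreting mu* against synthetic references: when the
reference data are generated by the nominal parameters themselves, the
nominal RMSE is ~0 and mu* measures pure trajectory sensitivity. That
ranks t_lag high (its default of 2.75 h makes a ±10% step shift the whole
batch phase) and m_S low (~5% of the glucose drain). Screens against real
data behave differently: parameters fitted per run sit at local RMSE
minima and show small effects, while literature-fixed parameters need not.
Rank orderings from this screen therefore transfer to real-data screens
only for parameters whose influence is structural (mu_max_S dominant;
mu_max_A, K_A, m_A negligible at moderate feeding rates).

## Synthetic data generator

`generate_experiment_set` emulates the study design the model is meant for:
duplicate fed-batch runs at feeding growth rates 0.075, 0.15, 0.2, 0.25,
0.3 and 0.4 1/h (12 experiments), sampled hourly. Batch-phase defaults —
12 L initial volume, 25 g/L initial glucose, inoculation at OD600 0.3 with
0.232 g CDW/L per OD unit, 6 L of 500 g/L feed — were chosen once from the
reported process constraints and reproduce the reported feed-start biomass
(~84 g) and feed-start window (12.5–16 h) without tuning.

Measurement noise is multiplicative log-normal per state (unit mean; CV 5%
for CDW and surfactin, 3% for the enzymatic glucose and acetate assays)
plus a 0.01 g/L additive floor, clipped at zero; glucose readings below the
0.05 g/L detection limit are censored (dropped by default, clamp-to-limit
available). Replicate variability enters as log-normal jitter (CV 5%) on
the initial biomass and glucose and a uniform ±0.5 h jitter on t_lag. The
noise magnitudes and jitters are this package's own stand-ins for
unreported assay error; they are configurable, and zero-noise/zero-jitter
settings reproduce the simulator output exactly (asserted). Everything is
deterministic under the seed, including file output byte-for-byte.

What passing tests on these data do and do not show: the generator shares
the simulator's structural assumptions, so calibration tests demonstrate
estimator correctness (recovery, bounds, determinism), not model adequacy
for real bioreactors; real data add model misfit, autocorrelated assay
error and foam-related losses that the generator does not emulate.

## Known limitations

- **No product degradation.** Extending the feed beyond the nominal
  reservoir keeps predicting titre growth; real processes can degrade
  surfactin late in the run. Do not extrapolate past feed depletion.
- **Single overflow metabolite.** Acetate stands in for the whole overflow
  spectrum (acetoin, butanediol, lactate, ...); under strong glucose excess
  (feeding growth rates ≥ 0.3 1/h, or large F0 in the batch-free design)
  the lumped description degrades.
- **Inoculum hypersensitivity near the collapse threshold.** The batch-free
  design exhibits a sharp feed-rate threshold above which acetate
  accumulation, growth inhibition and glucose accumulation run away and the
  titre collapses. The threshold's position, and the height/timing of the
  early glucose peak, depend strongly on the initial biomass: with the
  default inoculum (OD600 0.3, X0 = 0.696 g in 10 L) the collapse sits near
  F0 ≈ 37 g/h and the glucose peak reaches ~11.5 g/L, while a ~40% larger
  inoculum moves the collapse beyond 40 g/h and lowers the peak to ~8 g/L.
  Endpoint predictions at moderate feed rates (titre, biomass, process
  time) are insensitive to this. For quantitative work near the threshold,
  set measured initial conditions in `design_config` rather than nominal
  inoculation targets.
- **No pH, oxygen or temperature dynamics; no foam partitioning.** The
  volume correction factor lumps all secondary volume flows.
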