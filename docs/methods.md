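# Methods

## Model

The package models the minimal sucrose-cleavage system of a plant cell:

    --r_in-->  Suc  --r_inv-->  Glc + Frc  --r_out,Glc / r_out,Frc-->

`r_in` is a constant sucrose supply (biosynthesis/import, treated as a
boundary condition rather than mechanistically); `r_inv` is invertase-
catalysed hydrolysis; the two efflux terms stand for hexose-consuming
processes such as phosphorylation by hexokinases. The *metabolic
function* f(X) of a species is the sum of rates affecting it, i.e. the
right-hand side of its ODE. Grid analyses of f(Suc) = r_in − r_inv use
the efflux-free mode (the hexose functions then both equal r_inv); time
integration uses the full system.

### Invertase rate law

Plant invertases are product-inhibited, glucose acting non-competitively
and fructose competitively. These two mechanisms are encoded in their
textbook algebraic form,

    r_inv = V_max S / [ (K_M (1 + F/K_iF) + S) (1 + G/K_iG) ],

the competitive term scaling the apparent K_M and the non-competitive
term scaling the whole rate. This is the conventional reading of the
stated mechanisms, not a transcription of any particular laboratory's
fitted form; users holding an independently derived equation for a
specific isoform should verify it against this one (the rate law lives
in a single function, `kinetics.invertase_rate`, and every derivative
in the package is hand-derived from it).

Assumptions: irreversible cleavage (no sucrose re-synthesis via SPS;
cycling enters only through the influx term), no pH or continuous
temperature dependence (temperature is a discrete scenario label), and
spatially well-mixed compartments.

### Units

Internal unit is mM (= µmol ml⁻¹) and hours. Whole-tissue amounts in
µmol gFW⁻¹ are numerically equal to mM under the convention that 1 g
fresh weight of leaf tissue holds ≈ 1 ml of water; the conversion
factor is explicit (`TissueAmounts.fw_to_volume`) and defaults to 1.

## Parameters

| parameter | meaning | unit | default source |
|---|---|---|---|
| V_max | maximal cleavage rate | mM h⁻¹ | config / generator U[1,10] warm |
| K_M | sucrose half-saturation | mM | generator U[1,10] (low-millimolar) |
| K_iG | glucose (non-competitive) inhibition | mM | generator U[0.5,20] |
| K_iF | fructose (competitive) inhibition | mM | generator U[0.5,20] |
| r_in | sucrose influx | mM h⁻¹ | generator U[0.1,1] warm |
| efflux V_max, K_M | hexose consumption | mM h⁻¹, mM | 2–5 × r_in, U[1,10] |

No biological constant is hard-coded outside the synthetic-data
defaults and the bundled example configs, which are labelled synthetic
placeholders; measured Arabidopsis parameters (Kitashova et al. 2021)
can be dropped into the same config schema.

### Compartments

The cytosol is taken to occupy 5 % and the vacuole 80 % of cell volume,
so equal amounts are 16-fold more dilute in the vacuole. Effective
concentrations follow `c = fraction × amount / (volume_fraction ×
fw_to_volume)` with the default sugar-distribution fractions (fraction
of the total cellular amount): cytosolic/vacuolar sucrose 50 %/25 %
(22 °C) and 40 %/33 % (4 °C); cytosolic/vacuolar hexoses 30 %/55 %
(22 °C) and 30 %/50 % (4 °C).

The preset subcellular sucrose grid ranges (cytosol 8–24 mM and vacuole
0.25–0.75 mM at 22 °C; 25.6–51.2 mM and 1.32–2.64 mM at 4 °C) are kept
as authoritative inputs rather than re-derived, because no single
formula convention reproduces all four from the distribution fractions
(e.g. the 22 °C cytosolic range corresponds to a 40 % — not 50 % —
fraction, and the vacuolar ranges equal fraction × amount with no
volume division). Both routes — the explicit formula and the preset
ranges — are exposed and clearly separated.

Subcellular hexose grid ranges *are* derived from the whole-cell hexose
ranges (0.05–3 µmol gFW⁻¹ warm, 0.25–15 cold) via the fractions and
volumes above.

## Derivatives

Jacobian and Hessian surfaces are closed forms derived by hand from the
rate laws (spot-checked symbolically with sympy in the test suite), not
runtime numeric differentiation: the analysis hinges on exact
derivative surfaces, and closed forms make the sign structure provable
— for every admissible state, j₁₁ ≤ 0, j₁₂ ≥ 0, j₁₃ ≥ 0 in the
(Suc, Glc, Frc) ordering.

A central finite-difference oracle (relative steps 10⁻⁶ for gradients,
10⁻⁴ for Hessians, with boundary-aware one-sided stencils at zero
concentrations) verifies the closed forms; `derivative_report` returns
both routes with their maximal discrepancy so disagreement is recorded,
never discarded. Discrepancies are measured relative to the matrix
block's largest entry: entry-wise relative error is not meaningful for
entries orders of magnitude below the dominant one, where the
finite-difference value is round-off limited in double precision.

## Grid scans

Default resolution is 50 × 50 hexose points per sucrose plane and three
planes (range endpoints plus midpoint); the evaluation is vectorised so
a full scan with all derivative surfaces costs milliseconds. Row order
is deterministic (plane-major, then glucose, then fructose) and floats
are serialised with 17 significant digits, so re-running a scan is
byte-identical.

The "overlap" of the glucose and fructose sensitivities j₁₂ and j₁₃
across a grid is operationalised as the Jaccard overlap of their value
intervals — an interpretation chosen here, since the notion is
otherwise only visual.

### Warm/cold and cytosol/vacuole contrasts

Two qualitative contrasts are treated as pipeline-level checks:

1. **Cold reduces dynamics.** Generated 4 °C scenarios must show a
   smaller dynamic range of f(Suc) and of |j₁₁|, |j₁₂|, |j₁₃| than
   their 22 °C partners on their respective grids.
2. **Vacuolar dilution preserves elasticity.** With identical kinetic
   constants, the dilute vacuole keeps invertase far from saturation
   (S ≪ K_M) and weakly inhibited, so f(Suc) stays responsive; the
   concentrated cytosol saturates the enzyme. This is quantified as
   (a) the grid-median |j₁₁| being larger in the vacuole and (b) the
   median relative response of the cleavage rate across the sucrose
   planes being larger in the vacuole, at both temperatures. A naive
   alternative — comparing order-of-magnitude spans of the Jacobian
   entries — measures the opposite mechanism (the cytosol's far wider
   absolute hexose range inflates its spans) and is deliberately not
   used; the elasticity-based measures are the mechanistically faithful
   ones and hold across the generator's whole parameter space.

## Simulation

`scipy.integrate.solve_ivp` with LSODA (stiff-capable) and the analytic
Jacobian, rtol 10⁻⁸ and atol 10⁻¹⁰ mM: inhibition constants can be
small against cold-accumulated sugar levels, which makes the system
locally stiff. Solver trial steps that undershoot zero are evaluated on
the boundary; reported states clip negatives only within −10⁻¹² (round-
off). The two-compartment mode couples cytosolic and vacuolar copies by
first-order transport in the donor concentration with volume-weighted,
amount-conserving exchange; the scans treat compartments independently,
which remains the default.

Steady states are located with a root finder in square-root coordinates
(x = u², confining the search to the non-negative orthant), and
convergence is judged by the actual residual max|f| < 10⁻¹⁰ — the
parametrisation is singular at zero concentrations, where the solver's
own status flag is unreliable. Non-convergence is reported explicitly.

## Synthetic data generator

The generator emulates the *structure* of a measured warm/cold kinetic
parameter table: one 22 °C scenario with parameters drawn from the
ranges above, one 4 °C partner with V_max and r_in attenuated by a
factor drawn from U[0.15, 0.4], shared K_M and K_i (constants of the
same enzyme), and concentration grids shifted upward in the cold
(sucrose planes 1/2/3 → 4/6/8 µmol gFW⁻¹; hexose range scaled 5-fold to
0.25–15 µmol gFW⁻¹, cold-acclimated hexose pools staying elevated
across the whole range). The attenuation range corresponds to a
temperature coefficient Q10 of ≈ 2–3 over the 18 °C difference; a
markedly weaker attenuation would be overwhelmed by the saturation gain
from cold sucrose accumulation and would not produce the reduced cold
dynamics that characterise the modelled physiology.

Observation noise is multiplicative log-normal (each value times
exp(ε), ε ~ N(0, σ)): metabolite measurements are positive with roughly
concentration-proportional error. Every generated artefact embeds its
seed and template.

What the generator does **not** emulate: diurnal dynamics, correlations
between parameters (all draws independent), isoform-specific
differences between compartments, measurement-batch effects, or the
actual measured parameter values. Passing contrasts therefore
demonstrate that the pipeline detects the modelled physiology across a
broad synthetic parameter space — not that any particular experimental
dataset shows it.

## Calibration

Least squares on log-concentrations over log-parameters
(`scipy.optimize.least_squares`, trf, bound-constrained), matching the
multiplicative error model; multi-start (default 10, log-normally
perturbed) with best-of selection. The objective sorts observations by
time, so it is invariant to row order.

Identifiability: from a low-sucrose relaxation experiment only the
ratio V_max/K_M is constrained; recovery experiments therefore start
from saturating sucrose (≈ 20 mM ≳ 5 K_M) so the trajectory probes
V_max early and K_M on the way down. The inhibition constants are
weakly identifiable unless initial hexose levels are perturbed across
experiments; the default free set is (V_max, K_M, r_in).

## Problem sizes and numerical checks

Derivative verification uses 100 log-uniform states in [10⁻², 10²] mM
per scenario across the four bundled subcellular scenarios. The
warm/cold contrast uses 50 generated pairs scanned at 25 × 25 × 3.
Recovery studies use 50 time points over 24 h, 5 % noise, 20
replicates, 2 starts each. Closed-system conservation of hexose units
(2·Suc + Glc + Frc, volume-weighted across compartments in the coupled
mode) holds to ~10⁻¹² relative over 100 h, against a tolerance of 10⁻⁸.

## Known limitations

- The rate law is the conventional mixed-inhibition form; a measured
  isoform may deviate (e.g. substrate inhibition at high sucrose).
- No sucrose re-synthesis, so "cycling" is only implicit in r_in;
  f(Suc) = 0 loci are balances of supply and cleavage, not futile-cycle
  equilibria.
- Transport between compartments is first-order only; carrier
  saturation would need the Michaelis–Menten variant to be wired into
  the coupled mode per transporter.
- Elasticities are undefined where a metabolic function vanishes; the
  scaled-elasticity helper raises rather than returning ±inf.
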