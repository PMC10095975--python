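# Subcellular (cytosol/vacuole) sucrose cleavage example.
#
# Four scenarios: temperature (22C/4C) x compartment (cytosol/vacuole).
# Sucrose plane ranges are the compartment-effective concentration
# ranges the subcellular analysis is defined on (cytosol 22C: 8-24 mM;
# vacuole 22C: 0.25-0.75 mM; cytosol 4C: 25.6-51.2 mM; vacuole 4C:
# 1.32-2.64 mM); hexose ranges are derived from whole-cell hexose
# amounts (0.05-3 umol/gFW warm, 0.25-15 cold) via the distribution
# fractions and compartment volumes below (cytosol 5 %, vacuole 80 % of
# cell volume).
#
# NOTE: kinetic constants are SYNTHETIC placeholders; the same set is
# used in both compartments so that differences between scenarios are
# purely concentration-driven.  Measured isoform-specific activities
# (neutral/cytosolic vs. acidic/vacuolar invertase) were published in
# Kitashova et al. 2021.

seed = 0
include_efflux = false

[[compartments]]
name = "cytosol"
volume_fraction = 0.05

[compartments.sugar_fractions]
"sucrose/22C" = 0.50
"hexose/22C" = 0.30
"sucrose/4C" = 0.40
"hexose/4C" = 0.30

[[compartments]]
name = "vacuole"
volume_fraction = 0.80

[compartments.sugar_fractions]
"sucrose/22C" = 0.25
"hexose/22C" = 0.55
"sucrose/4C" = 0.33
"hexose/4C" = 0.50

[[scenarios]]
name = "22C_cytosol"
temperature_label = "22C"
compartment_label = "cytosol"

[scenarios.invertase]
v_max = 5.0
k_m = 2.0
k_i_glc = 5.0
k_i_frc = 5.0

[scenarios.fluxes]
r_in = 0.5

[scenarios.grid]
glc_range = [0.3, 18.0]
frc_range = [0.3, 18.0]
suc_planes = [8.0, 16.0, 24.0]
n_glc = 50
n_frc = 50

[[scenarios]]
name = "22C_vacuole"
temperature_label = "22C"
compartment_label = "vacuole"

[scenarios.invertase]
v_max = 5.0
k_m = 2.0
k_i_glc = 5.0
k_i_frc = 5.0

[scenarios.fluxes]
r_in = 0.5

[scenarios.grid]
glc_range = [0.034375, 2.0625]
frc_range = [0.034375, 2.0625]
suc_planes = [0.25, 0.5, 0.75]
n_glc = 50
n_frc = 50

[[scenarios]]
name = "4C_cytosol"
temperature_label = "4C"
compartment_label = "cytosol"

[scenarios.invertase]
v_max = 1.5
k_m = 2.0
k_i_glc = 5.0
k_i_frc = 5.0

[scenarios.fluxes]
r_in = 0.15

[scenarios.grid]
glc_range = [1.5, 90.0]
frc_range = [1.5, 90.0]
suc_planes = [25.6, 38.4, 51.2]
n_glc = 50
n_frc = 50

[[scenarios]]
name = "4C_vacuole"
temperature_label = "4C"
compartment_label = "vacuole"

[scenarios.invertase]
v_max = 1.5
k_m = 2.0
k_i_glc = 5.0
k_i_frc = 5.0

[scenarios.fluxes]
r_in = 0.15

[scenarios.grid]
glc_range = [0.15625, 9.375]
frc_range = [0.15625, 9.375]
suc_planes = [1.32, 1.98, 2.64]
n_glc = 50
n_frc = 50
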