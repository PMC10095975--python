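# Whole-cell sucrose cleavage example: ambient (22C) and cold (4C) scenarios.
#
# NOTE: the kinetic constants below are SYNTHETIC placeholders with the
# right structure (cold v_max and r_in attenuated, cold grids shifted to
# the accumulated-sugar range).  Experimentally determined values for
# Arabidopsis invertases were published separately (Kitashova et al.
# 2021, Physiol. Plant.); substitute them here to reproduce measured
# conditions.  Units: mM and mM/h (1 gFW ~ 1 ml water, so umol/gFW
# amounts are numerically mM).

seed = 0
include_efflux = false

[[scenarios]]
name = "22C_whole_cell"
temperature_label = "22C"
compartment_label = "whole_cell"

[scenarios.invertase]
v_max = 5.0
k_m = 2.0
k_i_glc = 5.0
k_i_frc = 5.0

[scenarios.fluxes]
r_in = 0.5

[scenarios.fluxes.efflux_glc]
kind = "michaelis_menten"
v_max = 1.5
k_m = 2.0

[scenarios.fluxes.efflux_frc]
kind = "michaelis_menten"
v_max = 1.5
k_m = 2.0

[scenarios.grid]
glc_range = [0.05, 3.0]
frc_range = [0.05, 3.0]
suc_planes = [1.0, 2.0, 3.0]
n_glc = 50
n_frc = 50
units = "mM"

[[scenarios]]
name = "4C_whole_cell"
temperature_label = "4C"
compartment_label = "whole_cell"

[scenarios.invertase]
v_max = 1.5
k_m = 2.0
k_i_glc = 5.0
k_i_frc = 5.0

[scenarios.fluxes]
r_in = 0.15

[scenarios.fluxes.efflux_glc]
kind = "michaelis_menten"
v_max = 0.45
k_m = 2.0

[scenarios.fluxes.efflux_frc]
kind = "michaelis_menten"
v_max = 0.45
k_m = 2.0

[scenarios.grid]
glc_range = [0.25, 15.0]
frc_range = [0.25, 15.0]
suc_planes = [4.0, 6.0, 8.0]
n_glc = 50
n_frc = 50
units = "mM"
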