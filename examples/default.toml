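# Default H20 shape-memory polyurethane foam run configuration.
# Every key is optional; omitted keys take these same documented defaults.

[geometry]
theta_deg = 65.92       # rise half-angle of the elongated Kelvin cell
L_m = 0.00058           # hexagon edge length (m)
r_m = 5.044e-05         # ligament section radius parameter (m)
torsion_factor = 1.0    # Jt = torsion_factor * (Iy + Iz)
nx = 1
ny = 1
nz = 1
jitter_frac = 0.0       # node jitter amplitude as a fraction of L (0 = regular)
seed = 0

[material]
Tg_K = 328.0
dThl_K = 30.0
Eh_Pa = 527000.0        # solid modulus at the cold end of the transition
El_Pa = 2030000.0       # solid modulus at the hot end
mu_h = 116.0            # viscosity, cold end (mu_units)
mu_l = 11.0             # viscosity, hot end
mu_units = "GPa_s"      # literal table units; "MPa_s" etc. selectable
lam_h_s = 124.0         # retardation time, cold end (s)
lam_l_s = 80.0          # retardation time, hot end (s)
alpha_h = 0.002         # thermal expansion (1/K)
alpha_l = 0.002
nu_s = 0.3              # solid Poisson ratio (3-D law only)
maxwell_floor = 0.001   # E_Maxwell floored at maxwell_floor * Es

[cycle]
Th_K = 353.15           # hot (loading/recovery) temperature = 80 C
Tl_K = 293.15           # cold (fixing) temperature = 20 C
eps_max = 0.8           # compressive fixing strain
strain_rate = 0.01      # 1/s
thermal_rate_K_s = 1.0  # K/s
unload_time_s = 20.0
dwell_after_unload_s = 0.0

[solver]
direction = "x"
dt_s = 0.5
applied_strain = 0.001
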