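# foamsim

Micromechanics simulator for open-cell **shape-memory polyurethane foams**
(SMPUFs) — the expandable foams used to fill cerebral aneurysms.  Such a foam
is compressed ("programmed") above its glass transition temperature Tg,
cooled to lock the compact shape, delivered by catheter, and recovers its
expanded shape when reheated above Tg.  `foamsim` models this end to end at
desk scale, for engineers designing foam implants and for anyone needing a
transparent reference implementation of the underlying models:

- **Kelvin-cell geometry** — elongated tetrakaidecahedron cells
  (8 hexagons, 4 diamonds, 2 squares; `b = sqrt(2) L cos(theta)`,
  `H = 4 L sin(theta)`), plateau-border ligament sections
  (`A = (sqrt(3) - pi/2) r^2`, `I = (20 sqrt(3) - 11 pi)/24 r^4`), space-filling
  body-centred tilings, and the closed-form relative density `gamma`.
- **Homogenization** — closed-form effective moduli and Poisson ratios of
  the foam (`Ex`, `Ey = Ez`, `nu_zx`, `nu_yx`) from beam theory.
- **Constitutive law** — a Tobushi-type thermo-visco-elastic solid with
  phase mixing `Es(T) = (1-z) Eh + z El` through the binding fraction
  `z(T) = 1 - (1 + e^{-a(Tg - dThl/2 - T)})^{-1}`, `a = 1/|ln(mu_h/mu_l)|`,
  Maxwell modulus `E_M = Es - 3 mu/lambda`, storage strain for shape
  fixing/recovery, and an exact consistent Jacobian (the user-material
  contract of commercial FE codes).
- **Beam-lattice FE** — sparse 3-D Euler–Bernoulli space-frame solver over
  foam lattices (the in-repo stand-in for a commercial solver with cubic
  beam elements), with tied planar faces, periodic homogenization, and a
  viscoelastic time stepper.
- **Shape-memory cycle driver** — the four-step thermodynamic cycle
  (load hot → cool fixed → reheat fixed → unload) at material-point or RVE
  level, with fixity/recovery summaries, CSV time series and VTK snapshots.

See `docs/methods.md` for the model equations, parameter provenance
(including how the ambiguous published parameter table is read) and
limitations.

## Worked example

The default configuration (`examples/default.toml`) is the published H20
foam: cell angle 65.92°, L = 0.58 mm, r = 50.44 µm, Tg = 328 K, cycled
between 80 °C and 20 °C at 80 % compressive fixing strain.

```bash
$ foamsim cycle --config examples/default.toml --output-dir out
fixing stress (end of step 2): 2.151 kPa
residual strain (end of step 4): -0.03144 %
shape-fixity ratio: 1.0051
strain-recovery ratio: 0.9996
```

Reading the numbers: during cooling at fixed 80 % strain the phase change
freezes the deformation into storage strain and the stress collapses from
~1.6 MPa to a **2.15 kPa** thermal residual (the shape is held by the glassy
phase, not by the grips — releasing the grips at 20 °C would spring back
only 0.5 %, the fixity ratio).  After reheating and unloading the residual
strain is **-0.031 %**: the foam recovers its original shape essentially
completely (recovery ratio 0.9996).  The full history lands in
`out/cycle.csv` (columns `t_s,T_K,z,eps_total,eps_S,eps_viscous,sigma_Pa,step_id`).

Effective elastic properties of the same foam, closed form vs beam-lattice
finite elements:

```bash
$ foamsim homogenize --config examples/default.toml
effective properties at Es = 527000 Pa
  gamma    0.00258481
  Ex_Pa    10.2639
  Ey_Pa    0.740705
  Ez_Pa    0.740705
  nu_zx    0.102628
  nu_yx    0.178562

$ foamsim rve --config examples/default.toml --periodic
E_x (beam FE):    10.2639 Pa
E_x (closed form): 10.2639 Pa
relative deviation: 0.000%
```

The foam is ultra-light (relative density 0.26 %), so its moduli sit five
orders below the solid's; the boundary-free periodic FE reproduces the
closed form to machine precision, while a finite block (`foamsim rve`
without `--periodic`) is a few percent stiffer-to-softer depending on size
from surface effects.

Other entry points: `foamsim geometry` (VTK/CSV lattice export) and the
library API (`foamsim.build_kelvin_cell`, `foamsim.effective_moduli`,
`foamsim.update_state`, `foamsim.run_material_point_cycle`, ...).  Every run
writes a `manifest.json` (config hash, seed, version) sufficient to
reproduce its outputs exactly.

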