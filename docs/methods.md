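# Methods

`foamsim` simulates the thermo-mechanics of open-cell shape-memory
polyurethane foams (SMPUFs) of the kind used to fill cerebral aneurysms: the
foam is compressed at high temperature, cooled to fix the compact shape,
delivered, and recovers its expanded shape on reheating above the glass
transition.  The package covers the micromechanics chain end to end —
idealized cell geometry, closed-form homogenization, a thermo-visco-elastic
solid law with glassy/rubbery phase mixing, a 3-D beam-lattice finite-element
solver, and a driver for the four-step shape-memory cycle.  This note records
the model equations, the parameter choices and their provenance, the
numerical decisions, and the known limits of validity.

## Cell geometry

The representative cell is an elongated tetrakaidecahedron (Kelvin cell):
14 faces (8 hexagons, 4 rhombic "diamonds", 2 squares), 24 vertices, 36
edges.  It is generated from the truncated octahedron with integer vertices
at the signed permutations of (0, 1, 2), scaled anisotropically so that the
rise (elongation) axis is global x.  With rise half-angle `theta` and
hexagon edge length `L`:

```
b = sqrt(2) L cos(theta)      (square/diamond edge)
H = 4 L sin(theta)            (cell height, x)
D = 4 L cos(theta)            (transverse tiling period)
```

Edges take only the lengths `L` (24 inclined edges) and `b` (12 edges in
transverse planes).  Cells tile space on a body-centred arrangement with
periods (H, D, D); every edge of the tiling is shared by three cells.

Ligaments carry a plateau-border cross-section parametrized by a radius `r`:

```
A = (sqrt(3) - pi/2) r^2,     Iy = Iz = (20 sqrt(3) - 11 pi) / 24 r^4
```

No torsion constant exists in closed form for this section; we use
`Jt = c (Iy + Iz)` with `c = 1` by default.  The effective-property formulas
contain no torsion term and the periodic homogenization confirms torsion does
not enter the normal-strain response, so results of interest are insensitive
to `c`; any positive value regularizes the 3-D frame.

The closed-form relative density

```
gamma = 2 A (2L + b) / (L sin(theta) (2L cos(theta) + sqrt(2) b)^2)
```

is equivalent to "per-cell solid volume A (24L + 12b)/3 over per-cell volume
H D^2 / 2" and is verified in the tests against a numeric oracle that sums
deduplicated ligament lengths on a periodic tiling.  It ignores the material
overlap where ligaments meet, which is negligible for slender ligaments
(r/L <~ 0.15).

"Random equilateral" microstructure: the default lattice is the regular
tiling, which is what every closed form assumes.  A seeded uniform node
jitter (amplitude as a fraction of `L`) is available but off by default.

## Closed-form effective properties

Beam-theory homogenization of the elongated Kelvin lattice gives (with
`I = Iy = Iz`, `t = theta`):

```
Ex       = 48 Es I sin t / { L^2 [cos^2 t + 12 I sin^2 t/(A L^2)] D^2 }
Ey = Ez  = 12 Es I / { L sin t [2 L^3 sin^2 t + b^3 + (12I/A)(2L cos^2 t + b)] }
nu_zx    = b (A b^2 - 12 I) / { 12 I (2L cos^2 t + b) + A (2L^3 sin^2 t + b^3) }
nu_yx    = (A L^2 - 12 I)(2L cos t + sqrt(2) b) cos t / { 2 [same bracket] }
```

Two transcription points needed resolution, both settled by using the
beam-FE lattice as an independent oracle (itself validated against the
classical regular-Kelvin closed form at theta = 45 deg to 1 %):

- **Axial normalization.**  Formulations of `Ex` that divide the per-cell
  axial force by the full transverse period area `D^2` understate the
  modulus by exactly a factor of two: in the space-filling body-centred
  tiling a transverse plane of area `D^2` is crossed by *two* cell columns,
  so the tributary area per cell is `D^2/2`.  The factor 48 above uses the
  tributary area; the periodic FE agrees with it to machine precision at
  every slenderness and angle tested.
- **Poisson subscripts.**  Measured on the lattice, `nu_yx` is the axial (x)
  contraction per unit transverse (y) compression, and `nu_zx` the
  transverse-transverse ratio (z per y) under the same load; both match the
  FE to ~1e-4.  The rise-direction ratio (-eps_y/eps_x under x load) is a
  different, much larger number for elongated cells (~2.5 at theta = 65.92
  deg, a real feature of high-rise foams) and is available from the periodic
  homogenization (`nu_xy`).

Both formula groups are *exact* within Euler-Bernoulli beam kinematics —
the homogenization includes the axial-stretch term, so there is no residual
slender-limit error for the FE comparison to converge through; the tests
therefore assert near-machine agreement on the periodic lattice and a 10 %
band on the finite block (see boundary conditions below).

## Constitutive model

The solid polymer follows a Tobushi-type small-strain rheology: an elastic
spring in parallel with a Maxwell branch, in series with thermal and storage
elements:

```
eps_total = eps_me + eps_th + eps_S,   eps_me = eps_elastic + eps_viscous
sigma     = sigma_elastic + sigma_maxwell
```

Glassy/rubbery switching uses the binding (phase) fraction

```
z(T) = 1 - (1 + exp(-a (Tg - dThl/2 - T)))^-1,   a = 1 / |ln(mu_h/mu_l)|
```

(z = 0 cold/glassy, z = 1 hot/rubbery, z = 1/2 at Tg - dThl/2), and every
material function mixes linearly: `Es = (1-z) Eh + z El`, likewise mu,
lambda, alpha.  The Maxwell spring modulus is `E_M = Es - 3 mu / lambda`,
floored at `1e-3 Es` where negative; the parallel spring carries
`E_e = Es - E_M`, so the instantaneous modulus is exactly `Es`.  The branch
dashpot `mu' = E_M lambda` makes the branch relaxation time equal lambda.
The 3-D law is isotropic with solid Poisson ratio `nu_s = 0.3` (not in the
source table; configurable; it only shapes the 3-D stiffness structure).

The published 1-D rate equation for this rheology is dimensionally
inhomogeneous as printed (a `sigma_dot/mu` term); the standard repaired form
`eps_dot = sigma_dot/Es + sigma/mu - (eps - eps_S)/lambda + eps_th_dot` is
provided as a reference function, while the integrator uses the equivalent
branch decomposition above.

### Storage strain: progressive freezing

No evolution law for the storage strain is published.  Two candidate rules
were analysed:

1. *Viscous transfer* (`d eps_S = -eps_viscous dz` on cooling): under every
   reading of the source parameter table the hot retardation time (80-480 s)
   far exceeds the loading step, so almost no viscous strain exists when
   cooling starts; the rule then fixes almost nothing, the cold spring holds
   the full mechanical strain, and the end-of-fixing stress stays at the
   *MPa* scale — two orders above the documented few-kPa outcome — while
   unloading at the cold end rebounds the shape.  Rejected.
2. *Progressive freezing* (implemented): on cooling, the mechanical strain —
   both branch strains and the Maxwell stress — scales by `z_new/z_old`,
   the complement moving into `eps_S`; on heating, `eps_S` scales by
   `(1-z_new)/(1-z_old)`, releasing storage back into the mechanical
   branches (empty at z = 1).

The freezing factors telescope over substeps, so the transfer depends on the
temperature path only through its endpoints; fixity is perfect at z -> 0; and
the rule has a sharp analytic consequence that matches the documented cycle:
during cooling at fixed total strain, the competition between thermal
contraction (rate `alpha` per kelvin, resisted by the grips) and freezing
(absorption rate `a` per kelvin in the exponential tail of z) leaves a small
steady tensile residual

```
|sigma_fix| ~= Eh * alpha / a    (~2.5 kPa with the default parameters)
```

independent of the cooling rate.  This is the quantity reported as the
end-of-fixing stress.

### Parameter set and its ambiguities

The source parameter table for the H20 polyurethane foam solid prints
several rows run together; the defaults are the literal reading:

| quantity | default | note |
|---|---|---|
| Tg | 328 K | |
| dThl | 30 K | |
| Eh / El | 0.527 / 2.03 MPa | literal column order |
| mu_h / mu_l | 116 / 11 GPa s | ratio ~10.5 gives a = 0.4245 /K |
| lam_h / lam_l | 124 / 80 s | glassy retardation longer |
| alpha_h = alpha_l | 20e-4 /K | |

Consequences and sensitivity (documented because the end-of-fixing stress
depends on them):

- With mu in GPa s, `Es - 3 mu/lambda` is negative everywhere, the Maxwell
  floor is always active, and the solid is quasi-elastic with a weak
  relaxing branch.  That is the regime in which both documented cycle
  outcomes (full recovery, kPa fixing stress) are reproduced.  A `mu_units`
  switch (`Pa_s` ... `GPa_s`) selects other readings; with `MPa_s` the
  Maxwell branch dominates at the hot end with an 80 s retardation time, and
  recovery within any plausible protocol duration is lost.
- The literal column order makes the *rubbery* modulus the larger one.  A
  `swap_moduli` switch in `MaterialParams.table_default` restores the
  physically conventional order (glassy stiffer); the cycle still fixes and
  recovers (the mechanism is storage, not modulus contrast), but the
  end-of-fixing stress scales with `Eh` and becomes ~9.6 kPa.
- The fixing stress also scales as `1/a`, i.e. with `1/|ln(mu_h/mu_l)|`:
  candidate alternative splits of the viscosity row span a in
  [0.21, 22.7] /K and fixing stresses of ~0.2-19 kPa.  The default reading
  gives 2.15 kPa at dt = 0.5 s (2.4 kPa extrapolated to dt -> 0).

## Time integration

Backward Euler on the Maxwell branch with properties evaluated at the
end-of-step temperature; thermal strain by midpoint quadrature on <= 1 K
subintervals (exact for equal alphas); the storage update precedes the
mechanical update.  Because the storage and thermal increments do not depend
on the strain increment, the discrete update is *affine* in `d_eps`: the
consistent Jacobian `rho (E_e + beta E_M) Cbar(nu_s)` (with
`beta = 1/(1 + dt/lambda)` and `rho` the freezing factor) is exact, which the
tests confirm against central finite differences, and uniaxial-stress /
mixed control reduces to one linear solve per step.  Halving dt moves the
cycle stress history by < 0.5 % of its span; the small end-of-fixing residual
converges first-order in dt (0.5 s: 2.15 kPa; 0.25 s: 2.28 kPa; limit
~2.4 kPa).

## Beam-lattice finite elements

Each ligament is a 12-DOF two-node Euler-Bernoulli space-frame element
(axial, two bending planes, torsion with `G = Es/(2(1+nu_s))`) — the
standard equivalent of a cubic 3-D beam element.  Assembly is sparse;
constraints are eliminated through a reduction matrix supporting prescribed
DOFs and *tied planar faces* (all normal displacements of a face share one
master unknown that can be prescribed or loaded).  Direct sparse
factorization; solves verify a relative residual < 1e-10.

The viscoelastic stepper applies the material law to each element's
generalized local displacement vector (legitimate because all beam stiffness
terms scale linearly with Es): parallel elastic/Maxwell branch update,
axial thermal strain, and the freezing/release transfer all carry over with
strains replaced by generalized displacements.  The update is again affine,
so the "Newton loop" converges in one iteration and is retained as a
residual check; element histories commit only after convergence.

**RVE boundary conditions.**  The block compression uses planar faces: the
loading faces prescribe the normal displacement, and each lateral face is
tied planar with zero net force, so the block contracts freely but uniformly
— the uniaxial-stress state the closed forms describe.  (Roller lateral
faces were considered and rejected: they suppress lateral contraction and
bias the measured modulus by the Poisson coupling.)  A finite block still
carries a boundary-layer softness from surface cells with missing
neighbours: +21 % (1 cell), +7.6 % (2^3), +4.6 % (3^3) on the axial modulus,
independent of slenderness.  For boundary-free comparisons the package
provides true periodic homogenization on a wrapped lattice (image
translations carry the affine strain; the 3x3 normal-stress stiffness is
recovered by virtual work and inverted), which represents the infinite
lattice already at a single wrapped cell pair.

**Kinematics.**  The solver is small-displacement.  The four-step cycle at
80 % compression is therefore run at material-point level (where the
small-strain constitutive model is the model, applied uniaxially); RVE
cycles are intended for moderate strains and warn above 10 %.  Geometric
nonlinearity (ligament buckling, densification contact) is out of scope, so
lattice-level stress-strain curves at deep compression are not quantitative.

## The four-step cycle driver

Protocol defaults (the published protocol states temperatures and fixing
strain but no rates or durations): Th = 353.15 K (80 C), Tl = 293.15 K
(20 C), eps_max = 0.80 compressive, strain rate 0.01 /s, thermal rate 1 K/s,
20 s stress-controlled unload, no dwell.  The storage transfer is
rate-independent by construction and the summaries shift < 10 % when the
rates are halved (tested).  Scalar summaries: fixing stress (end of step 2),
residual strain (end of step 4), recovery ratio, and a shape-fixity ratio
computed by virtually unloading a clone of the end-of-fixing state at Tl.
With the defaults: fixing stress 2.15 kPa, residual strain -0.031 %,
fixity 1.005 (the >1 part is thermal contraction), recovery 0.9996.
Disabling cooling (Tl = Th) collapses the fixity ratio to ~0.0004,
demonstrating that fixity comes from the z-driven storage mechanism.

## Problem sizes

All shipped verification runs are desk-scale by design: the material-point
cycle integrates 440 steps (dt = 0.5 s, < 1 s wall time); FE comparisons use
1- to 27-cell lattices (24-432 nodes, direct solves well under a second);
the slenderness study spans r/L in {0.12, 0.08, 0.04}.

## Known limitations

- Small-strain kinematics at lattice level (see above); no contact or
  densification; no co-rotational update is currently shipped.
- Spatially uniform temperature (the underlying model's own assumption);
  no heat conduction or laser-heating physics.
- The storage rule is a reconstruction constrained by the documented cycle
  outcomes, not a published law; alternatives change the fixing-stress
  scale (see sensitivity above).
- The parameter table's ambiguous rows mean absolute stress levels carry
  order-of-magnitude uncertainty; trends and mechanisms are robust.
- The regular lattice is deterministic; the jitter option perturbs geometry
  but no statistics over random microstructures are implemented.
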