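"""Thermo-visco-elastic shape-memory constitutive law (Tobushi-type rheology).

Model structure
---------------
The solid polymer is a three-branch small-strain rheology: an elastic spring
in parallel with a Maxwell (spring + dashpot) branch, in series with a thermal
element and a storage element.  The total strain decomposes as

    eps_total = eps_me + eps_th + eps_S,        eps_me = eps_elastic + eps_viscous

and the stress is additive over the two mechanical branches,

    sigma = sigma_elastic + sigma_maxwell.

Glassy/rubbery switching is governed by the phase (binding) fraction

    z(T) = 1 - 1 / (1 + exp(-a (Tg - dThl/2 - T))),   a = 1 / |ln(mu_h / mu_l)|

which runs from 0 (cold) to 1 (hot); every material function interpolates
linearly in z between its two end values, e.g. Es = (1-z) Eh + z El.

The Maxwell-branch spring modulus follows E_Maxwell = Es - 3 mu / lambda,
floored at a small positive fraction of Es where that expression turns
negative (with viscosities read literally from the parameter table in GPa*s
the floor is always active, leaving a quasi-elastic solid with a weak
relaxing branch).  The parallel spring carries the remainder
E_elastic = Es - E_Maxwell so the instantaneous modulus is exactly Es.  The
branch dashpot is chosen as mu' = E_Maxwell * lambda, which makes the
retardation time of the branch equal to lambda by construction.

Storage strain (shape fixing / recovery)
----------------------------------------
No evolution law for eps_S is published for this model; the rule implemented
here is progressive freezing, chosen because it reproduces both documented
cycle outcomes (near-total stress decay while cooling at fixed strain, and
full strain recovery after reheating) and reduces to perfect fixity at z = 0:

- cooling (z decreasing): the mechanical strain — both branch strains and the
  Maxwell stress — scales by z_new/z_old; the complement (1 - z_new/z_old) of
  the mechanical strain transfers into eps_S.
- heating (z increasing): eps_S scales by (1 - z_new)/(1 - z_old), releasing
  the stored strain back into the mechanical branches; storage is empty at
  z = 1.

Both factors telescope over substeps, so the transfer depends on the
temperature path only through its endpoints (rate-independent), and the
frozen state at z -> 0 holds the shape with zero mechanical strain.

Time integration is backward Euler on the Maxwell branch; because the storage
and thermal updates do not depend on the strain increment, the discrete
update is affine in ``d_eps`` and the consistent Jacobian is exact.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MaterialParams",
    "MaterialState",
    "phase_fraction",
    "interpolate_properties",
    "maxwell_modulus",
    "thermal_strain_increment",
    "storage_strain_update",
    "update_state",
    "isotropic_stiffness",
    "tobushi_strain_rate",
    "uniaxial_step",
]

_MU_UNIT_FACTORS = {"Pa_s": 1.0, "kPa_s": 1e3, "MPa_s": 1e6, "GPa_s": 1e9}

#: Voigt identity for isotropic (volumetric) strains
_VOIGT_I = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])


@dataclass(frozen=True)
class MaterialParams:
    """Tobushi-type shape-memory polymer parameter set (SI units).

    Defaults are the literal reading of the published parameter table for the
    H20 polyurethane foam solid: subscripts h/l follow the phase-mixing law
    Es = (1-z) Eh + z El with z = 0 cold and z = 1 hot, so ``Eh`` is the
    modulus the solid exhibits at low temperature.  Read literally the table
    gives Eh = 0.527 MPa < El = 2.03 MPa; pass ``swap_moduli=True`` to
    :meth:`table_default` for the reversed (glassy-stiffer) reading.
    Viscosities are stored in ``mu_units`` (default the table's GPa*s).
    """

    Tg: float = 328.0           # glass transition (K)
    dThl: float = 30.0          # transition width Delta T_hl (K)
    Eh: float = 0.527e6         # solid modulus at z=0, cold end (Pa)
    El: float = 2.03e6          # solid modulus at z=1, hot end (Pa)
    mu_h: float = 116.0         # viscosity, cold end (mu_units)
    mu_l: float = 11.0          # viscosity, hot end (mu_units)
    mu_units: str = "GPa_s"
    lam_h: float = 124.0        # retardation time, cold end (s)
    lam_l: float = 80.0         # retardation time, hot end (s)
    alpha_h: float = 20e-4      # thermal expansion, cold end (1/K)
    alpha_l: float = 20e-4      # thermal expansion, hot end (1/K)
    nu_s: float = 0.3           # solid Poisson ratio (not in the table)
    maxwell_floor: float = 1e-3  # E_Maxwell >= maxwell_floor * Es

    def __post_init__(self):
        if self.mu_units not in _MU_UNIT_FACTORS:
            raise ValueError(f"unknown mu_units {self.mu_units!r}; "
                             f"choose from {sorted(_MU_UNIT_FACTORS)}")
        for name in ("Eh", "El", "mu_h", "mu_l", "lam_h", "lam_l", "dThl", "Tg"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"material parameter {name} must be positive")
        if not (0.0 < self.nu_s < 0.5):
            raise ValueError(f"nu_s must lie in (0, 0.5), got {self.nu_s!r}")
        if not (0.0 < self.maxwell_floor < 1.0):
            raise ValueError("maxwell_floor must lie in (0, 1)")
        if self.mu_h == self.mu_l:
            raise ValueError("mu_h must differ from mu_l (transition sharpness "
                             "a = 1/|ln(mu_h/mu_l)| is undefined otherwise)")
        # NOTE: Eh < El (rubbery stiffer than glassy) is allowed: the default
        # literal-table reading has that order, and shape memory in this model
        # arises from the storage mechanism, not the modulus contrast.

    @property
    def a(self) -> float:
        """Transition sharpness a = 1/|ln(mu_h/mu_l)| (1/K)."""
        return 1.0 / abs(math.log(self.mu_h / self.mu_l))

    @property
    def mu_h_pa_s(self) -> float:
        return self.mu_h * _MU_UNIT_FACTORS[self.mu_units]

    @property
    def mu_l_pa_s(self) -> float:
        return self.mu_l * _MU_UNIT_FACTORS[self.mu_units]

    @classmethod
    def table_default(cls, swap_moduli: bool = False, **overrides) -> "MaterialParams":
        """The default (literal-table) parameter set, optionally with Eh/El swapped."""
        if swap_moduli:
            overrides.setdefault("Eh", 2.03e6)
            overrides.setdefault("El", 0.527e6)
        return cls(**overrides)


@dataclass
class MaterialState:
    """Evolving small-strain state at one material point (Voigt 6-vectors).

    Shear components use engineering shear strain.  The bookkeeping
    invariants ``eps_total = eps_me + eps_th + eps_S`` and
    ``eps_me = eps_elastic + eps_viscous`` hold after every update.
    """

    T: float
    eps_total: np.ndarray = field(default_factory=lambda: np.zeros(6))
    eps_th: np.ndarray = field(default_factory=lambda: np.zeros(6))
    eps_S: np.ndarray = field(default_factory=lambda: np.zeros(6))
    eps_viscous: np.ndarray = field(default_factory=lambda: np.zeros(6))
    sigma: np.ndarray = field(default_factory=lambda: np.zeros(6))
    z: float = 0.0
    t: float = 0.0

    @property
    def eps_me(self) -> np.ndarray:
        return self.eps_total - self.eps_th - self.eps_S

    @property
    def eps_elastic(self) -> np.ndarray:
        return self.eps_me - self.eps_viscous

    def copy(self) -> "MaterialState":
        return MaterialState(T=self.T, eps_total=self.eps_total.copy(),
                             eps_th=self.eps_th.copy(), eps_S=self.eps_S.copy(),
                             eps_viscous=self.eps_viscous.copy(),
                             sigma=self.sigma.copy(), z=self.z, t=self.t)

    @classmethod
    def initial(cls, T: float, p: MaterialParams) -> "MaterialState":
        return cls(T=T, z=phase_fraction(T, p))


def phase_fraction(T: float, p: MaterialParams) -> float:
    """Binding/phase fraction z(T) in [0, 1]; 0 cold (glassy), 1 hot (rubbery).

    z = 1 - (1 + exp(-a (Tg - dThl/2 - T)))^-1, continuous and strictly
    increasing in T, with z = 1/2 exactly at T = Tg - dThl/2.
    """
    x = p.a * (p.Tg - 0.5 * p.dThl - T)
    # evaluate the logistic stably on both tails (no 1 - (1 - tiny) cancellation)
    if x >= 0.0:
        e = math.exp(-x)
        return e / (1.0 + e)
    return 1.0 / (1.0 + math.exp(x))


def interpolate_properties(z: float, p: MaterialParams) -> tuple[float, float, float, float]:
    """Linear glassy/rubbery mixing: (Es, mu [Pa*s], lambda [s], alpha [1/K]) at z."""
    if not (0.0 <= z <= 1.0):
        raise ValueError(f"phase fraction must lie in [0, 1], got {z!r}")
    w = 1.0 - z
    Es = w * p.Eh + z * p.El
    mu = w * p.mu_h_pa_s + z * p.mu_l_pa_s
    lam = w * p.lam_h + z * p.lam_l
    alpha = w * p.alpha_h + z * p.alpha_l
    return Es, mu, lam, alpha


def maxwell_modulus(Es: float, mu: float, lam: float, floor: float = 1e-3) -> float:
    """Maxwell-branch spring modulus E_M = Es - 3 mu/lam, floored at floor*Es.

    The unfloored expression turns negative whenever 3 mu/lam > Es (which it
    is for the literal GPa*s viscosity reading); the floor keeps the branch
    positive-definite while leaving the instantaneous modulus Es intact.
    """
    if lam <= 0.0:
        raise ValueError("retardation time must be positive")
    return max(Es - 3.0 * mu / lam, floor * Es)


def thermal_strain_increment(T0: float, T1: float, p: MaterialParams,
                             max_dT: float = 1.0) -> float:
    """Scalar (per-axis) thermal strain increment int_{T0}^{T1} alpha(z(T)) dT.

    Midpoint quadrature on subintervals no wider than ``max_dT`` kelvin;
    exact when alpha_h = alpha_l.
    """
    if T1 == T0:
        return 0.0
    n = max(1, int(math.ceil(abs(T1 - T0) / max_dT)))
    Ts = np.linspace(T0, T1, n + 1)
    mids = 0.5 * (Ts[:-1] + Ts[1:])
    alphas = np.array([interpolate_properties(phase_fraction(T, p), p)[3] for T in mids])
    return float(np.sum(alphas * np.diff(Ts)))


def storage_strain_update(eps_me: np.ndarray, eps_viscous: np.ndarray,
                          eps_S: np.ndarray, z_old: float, z_new: float):
    """Progressive-freezing storage transfer for one z increment.

    Returns ``(eps_me, eps_viscous, eps_S)`` after the phase change, keeping
    ``eps_me + eps_S`` constant (so the total-strain bookkeeping is untouched).

    Cooling (z_new < z_old): mechanical and viscous strains scale by
    ``z_new/z_old``; the complement of eps_me moves into storage.  Heating
    (z_new > z_old): storage scales by ``(1-z_new)/(1-z_old)`` and the
    released strain rejoins eps_me.  At z_old = 1 on cooling the factor is
    z_new (full freezing from a storage-free state); at z_old = 1 on heating
    release is a no-op.
    """
    eps_me = np.asarray(eps_me, dtype=float)
    eps_viscous = np.asarray(eps_viscous, dtype=float)
    eps_S = np.asarray(eps_S, dtype=float)
    if z_new < z_old:
        rho = z_new / z_old if z_old > 0.0 else 1.0
        eps_S = eps_S + (1.0 - rho) * eps_me
        eps_me = rho * eps_me
        eps_viscous = rho * eps_viscous
    elif z_new > z_old and z_old < 1.0:
        rel = (1.0 - z_new) / (1.0 - z_old)
        eps_me = eps_me + (1.0 - rel) * eps_S
        eps_S = rel * eps_S
    return eps_me, eps_viscous, eps_S


def isotropic_stiffness(E: float, nu: float) -> np.ndarray:
    """6x6 isotropic stiffness in Voigt order (11, 22, 33, 12, 13, 23)."""
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    G = E / (2.0 * (1.0 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.arange(3), np.arange(3)] = lam + 2.0 * G
    C[np.arange(3, 6), np.arange(3, 6)] = G
    return C


def update_state(state: MaterialState, d_eps_total: np.ndarray, dT: float,
                 dt: float, p: MaterialParams) -> tuple[MaterialState, np.ndarray]:
    """One backward-Euler increment of the three-branch rheology.

    Order of operations: temperature/phase update, thermal strain increment,
    progressive-freezing storage transfer, then the mechanical (elastic +
    Maxwell) stress update with branch properties evaluated at the end-of-step
    temperature.  Returns the new state and the consistent material Jacobian
    d(d_sigma)/d(d_eps) of the discrete update (exact: the update is affine
    in ``d_eps_total``).
    """
    d_eps_total = np.asarray(d_eps_total, dtype=float)
    if d_eps_total.shape != (6,):
        raise ValueError("d_eps_total must be a Voigt 6-vector")
    if not (np.all(np.isfinite(d_eps_total)) and np.isfinite(dT) and np.isfinite(dt)):
        raise ValueError("non-finite input to update_state")
    if dt <= 0.0:
        raise ValueError("dt must be positive")

    T1 = state.T + dT
    z0 = state.z
    z1 = phase_fraction(T1, p)
    Es, mu, lam, _ = interpolate_properties(z1, p)
    if dt > 10.0 * lam:
        warnings.warn(f"dt = {dt} exceeds 10x the retardation time {lam}; "
                      "accuracy of the viscous update is degraded", stacklevel=2)

    d_eth = thermal_strain_increment(state.T, T1, p)
    eps_th1 = state.eps_th + d_eth * _VOIGT_I
    eps_total1 = state.eps_total + d_eps_total

    eps_me_trial = eps_total1 - eps_th1 - state.eps_S
    eps_me1, eps_v1, eps_S1 = storage_strain_update(
        eps_me_trial, state.eps_viscous, state.eps_S, z0, z1)
    # factor by which the trial mechanical strain entered the frozen update
    rho = (z1 / z0 if z0 > 0.0 else 1.0) if z1 < z0 else 1.0

    E_M = maxwell_modulus(Es, mu, lam, p.maxwell_floor)
    E_e = Es - E_M
    beta = 1.0 / (1.0 + dt / lam)
    eps_v_new = beta * eps_v1 + (1.0 - beta) * eps_me1

    Cbar = isotropic_stiffness(1.0, p.nu_s)
    sigma = (E_e * (Cbar @ eps_me1)
             + E_M * beta * (Cbar @ (eps_me1 - eps_v1)))
    jac = rho * (E_e + beta * E_M) * Cbar

    new = MaterialState(T=T1, eps_total=eps_total1, eps_th=eps_th1,
                        eps_S=eps_S1, eps_viscous=eps_v_new, sigma=sigma,
                        z=z1, t=state.t + dt)
    return new, jac


def uniaxial_step(state: MaterialState, dT: float, dt: float, p: MaterialParams,
                  eps_x: float | None = None,
                  sigma_x: float | None = None) -> tuple[MaterialState, np.ndarray]:
    """Advance one step under uniaxial-stress conditions.

    Exactly one of ``eps_x`` / ``sigma_x`` prescribes the axial condition at
    the end of the step; lateral normal stresses are zero and shears vanish.
    Because the discrete update is affine in the strain increment, the
    lateral (and, under stress control, axial) strain increments follow from
    one linear solve; the returned state satisfies the conditions exactly.
    """
    if (eps_x is None) == (sigma_x is None):
        raise ValueError("prescribe exactly one of eps_x or sigma_x")
    # affine decomposition: sigma_new = sigma0 + J @ d_eps
    base, jac = update_state(state, np.zeros(6), dT, dt, p)
    sigma0 = base.sigma
    d_eps = np.zeros(6)
    if eps_x is not None:
        d_eps[0] = eps_x - state.eps_total[0]
        rhs = -(sigma0[1:3] + jac[1:3, 0] * d_eps[0])
        d_eps[1:3] = np.linalg.solve(jac[1:3, 1:3], rhs)
    else:
        rhs = np.array([sigma_x, 0.0, 0.0]) - sigma0[:3]
        d_eps[:3] = np.linalg.solve(jac[:3, :3], rhs)
    return update_state(state, d_eps, dT, dt, p)


def tobushi_strain_rate(sigma: float, sigma_dot: float, eps: float, eps_S: float,
                        Es: float, mu: float, lam: float,
                        eps_th_rate: float = 0.0) -> float:
    """Classic 1-D shape-memory polymer rate form (reference/diagnostic only).

    eps_dot = sigma_dot/Es + sigma/mu - (eps - eps_S)/lam + eps_th_rate

    The published rate equation for this rheology is dimensionally
    inconsistent as printed (a sigma_dot/mu term); this is the standard
    repaired form.  The 3-D branch update integrates the equivalent parallel
    elastic/Maxwell decomposition instead.
    """
    return sigma_dot / Es + sigma / mu - (eps - eps_S) / lam + eps_th_rate
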