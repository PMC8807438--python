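import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from foamsim.constitutive import (
    MaterialParams,
    MaterialState,
    interpolate_properties,
    isotropic_stiffness,
    maxwell_modulus,
    phase_fraction,
    storage_strain_update,
    thermal_strain_increment,
    tobushi_strain_rate,
    uniaxial_step,
    update_state,
)


class TestPhaseFraction:
    def test_half_at_transition_midpoint(self, table_params):
        T_half = table_params.Tg - 0.5 * table_params.dThl
        assert phase_fraction(T_half, table_params) == pytest.approx(0.5, abs=1e-14)

    def test_logistic_saturation(self, table_params):
        p = table_params
        assert phase_fraction(p.Tg - 10 * p.dThl, p) < 1e-3
        assert phase_fraction(p.Tg + 10 * p.dThl, p) > 1.0 - 1e-3

    def test_reference_value_at_tg(self):
        # mu ratio of 10 gives transition sharpness a = 1/ln(10);
        # frozen high-precision evaluation of z at T = Tg
        p = MaterialParams(mu_h=100.0, mu_l=10.0)
        assert p.a == pytest.approx(1.0 / math.log(10.0), rel=1e-14)
        assert phase_fraction(328.0, p) == pytest.approx(0.998520273567, abs=1e-9)

    @given(T=st.floats(200.0, 450.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_increasing_and_bounded(self, T, table_params):
        z0 = phase_fraction(T, table_params)
        z1 = phase_fraction(T + 0.5, table_params)
        assert 0.0 <= z0 <= 1.0
        if 1e-12 < z0 < 1.0 - 1e-12:
            assert z1 > z0           # strictly increasing through the transition
        else:
            assert z1 >= z0          # saturated tails at float resolution


class TestPropertyMixing:
    @pytest.mark.parametrize("z,expect", [
        (0.0, "cold"), (1.0, "hot"), (0.5, "mean")])
    def test_mixing_endpoints_and_midpoint(self, z, expect, table_params):
        p = table_params
        Es, mu, lam, alpha = interpolate_properties(z, p)
        ref = {
            "cold": (p.Eh, p.mu_h_pa_s, p.lam_h, p.alpha_h),
            "hot": (p.El, p.mu_l_pa_s, p.lam_l, p.alpha_l),
            "mean": (0.5 * (p.Eh + p.El), 0.5 * (p.mu_h_pa_s + p.mu_l_pa_s),
                     0.5 * (p.lam_h + p.lam_l), 0.5 * (p.alpha_h + p.alpha_l)),
        }[expect]
        assert (Es, mu, lam, alpha) == pytest.approx(ref, rel=1e-14)

    def test_solid_modulus_monotone_decreasing_for_glassy_stiff_reading(self):
        p = MaterialParams.table_default(swap_moduli=True)
        # strictly decreasing through the transition region (outside it the
        # mixing saturates below float resolution)
        Ts = np.linspace(270.0, 360.0, 60)
        Es = [interpolate_properties(phase_fraction(T, p), p)[0] for T in Ts]
        assert np.all(np.diff(Es) < 0)

    def test_properties_continuous_in_temperature(self, table_params):
        Ts = np.linspace(250.0, 420.0, 3000)
        vals = np.array([interpolate_properties(phase_fraction(T, table_params),
                                                table_params)[:3] for T in Ts])
        rel_jump = np.abs(np.diff(vals, axis=0)) / np.abs(vals[:-1])
        assert rel_jump.max() < 0.05


class TestMaxwellModulus:
    def test_limits_and_reference_value(self):
        assert maxwell_modulus(2.03e6, 0.0, 1.0) == pytest.approx(2.03e6)
        assert maxwell_modulus(2.03e6, 1.0, 1e30) == pytest.approx(2.03e6)
        # 3 mu / lam = 1.0 MPa
        assert maxwell_modulus(2.03e6, 1.0e6 / 3.0, 1.0) == pytest.approx(1.03e6)

    def test_floor_engages_for_table_viscosities(self, table_params):
        p = table_params
        Es, mu, lam, _ = interpolate_properties(0.0, p)
        assert Es - 3.0 * mu / lam < 0.0          # literal GPa*s reading
        assert maxwell_modulus(Es, mu, lam, p.maxwell_floor) == \
            pytest.approx(p.maxwell_floor * Es)


class TestThermalStrain:
    def test_zero_and_constant_alpha(self, table_params):
        p = table_params
        assert thermal_strain_increment(300.0, 300.0, p) == 0.0
        # alpha_h = alpha_l = 20e-4 -> exact closed form 0.09 over 45 K
        assert thermal_strain_increment(300.0, 345.0, p) == pytest.approx(0.09, rel=1e-12)
        assert thermal_strain_increment(345.0, 300.0, p) == pytest.approx(-0.09, rel=1e-12)

    def test_mixed_alpha_path_additivity(self):
        p = MaterialParams(alpha_h=1e-4, alpha_l=9e-4)
        full = thermal_strain_increment(280.0, 380.0, p)
        split = (thermal_strain_increment(280.0, 331.7, p)
                 + thermal_strain_increment(331.7, 380.0, p))
        assert full == pytest.approx(split, rel=1e-6)


class TestStorageStrain:
    def test_full_cooling_transfers_creep_strain(self):
        # fully crept state: mechanical strain all viscous
        eps_v = np.array([0.4, 0, 0, 0, 0, 0.0])
        me, v, S = storage_strain_update(eps_v, eps_v, np.zeros(6), 1.0, 0.0)
        assert S[0] == pytest.approx(0.4)
        assert me[0] == pytest.approx(0.0)

    def test_reheat_to_unity_releases_all(self):
        S0 = np.array([0.4, 0, 0, 0, 0, 0.0])
        me, v, S = storage_strain_update(np.zeros(6), np.zeros(6), S0, 0.0, 1.0)
        assert S[0] == pytest.approx(0.0)
        assert me[0] == pytest.approx(0.4)

    def test_half_release_is_proportional(self):
        S0 = np.array([0.4, 0, 0, 0, 0, 0.0])
        me, v, S = storage_strain_update(np.zeros(6), np.zeros(6), S0, 0.0, 0.5)
        assert S[0] == pytest.approx(0.2)

    def test_release_noop_when_storage_empty_at_hot_end(self):
        me, v, S = storage_strain_update(np.ones(6), np.zeros(6), np.zeros(6),
                                         1.0, 1.0)
        assert np.allclose(S, 0.0)

    @given(z0=st.floats(0.05, 1.0), z1=st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_transfer_conserves_total_strain(self, z0, z1):
        me0 = np.array([-0.5, 0.1, 0.1, 0, 0, 0])
        v0 = 0.5 * me0
        S0 = np.array([-0.1, 0, 0, 0, 0, 0.0])
        me, v, S = storage_strain_update(me0, v0, S0, z0, z1)
        assert np.allclose(me + S, me0 + S0, atol=1e-12)


class TestUpdateState:
    def test_parallel_springs_in_elastic_limit(self, viscous_params):
        # dashpot locked (lam huge): one increment gives (E_e + E_M) d_eps
        p = MaterialParams(Eh=4.0e6, El=2.03e6, mu_h=2.0e5, mu_l=1.0e5,
                           mu_units="Pa_s", lam_h=1e9, lam_l=1e9)
        st0 = MaterialState.initial(400.0, p)      # hot: z ~ 1
        d_eps = np.array([1e-3, 0, 0, 0, 0, 0.0])
        new, _ = update_state(st0, d_eps, 0.0, 1.0, p)
        Es, mu, lam, _ = interpolate_properties(new.z, p)
        C = isotropic_stiffness(Es, p.nu_s)
        assert np.allclose(new.sigma, C @ d_eps, rtol=1e-6)

    def test_relaxation_matches_closed_form(self, viscous_params):
        # fixed full strain tensor: sigma(t) = (E_e + E_M exp(-t/lam)) Cbar eps
        p = viscous_params
        T = 420.0                                  # deep rubbery: z = 1
        st0 = MaterialState.initial(T, p)
        Es, mu, lam, _ = interpolate_properties(st0.z, p)
        E_M = Es - 3.0 * mu / lam
        E_e = Es - E_M
        eps = 1e-2
        dt = lam / 100.0
        st1, _ = update_state(st0, np.array([eps, 0, 0, 0, 0, 0.0]), 0.0, dt, p)
        worst = 0.0
        state = st1
        for k in range(2, 301):
            state, _ = update_state(state, np.zeros(6), 0.0, dt, p)
            t = (k - 1) * dt   # time since the strain step completed
            Cxx = isotropic_stiffness(1.0, p.nu_s)[0, 0]
            exact = (E_e + E_M * math.exp(-t / lam)) * Cxx * eps
            worst = max(worst, abs(state.sigma[0] - exact) / exact)
        assert worst < 0.01

    def test_jacobian_matches_finite_differences(self, viscous_params, rng):
        p = viscous_params
        for _ in range(3):
            st0 = MaterialState.initial(float(rng.uniform(290, 420)), p)
            st0.eps_total = rng.normal(0, 0.05, 6)
            st0.eps_viscous = rng.normal(0, 0.02, 6)
            st0.eps_S = rng.normal(0, 0.02, 6)
            st0.eps_th = np.zeros(6)
            d_eps = rng.normal(0, 1e-3, 6)
            dT, dt = float(rng.uniform(-2, 2)), 0.1
            _, J = update_state(st0, d_eps, dT, dt, p)
            Jfd = np.zeros((6, 6))
            h = 1e-7
            for j in range(6):
                dp, dm = d_eps.copy(), d_eps.copy()
                dp[j] += h
                dm[j] -= h
                sp_, _ = update_state(st0, dp, dT, dt, p)
                sm_, _ = update_state(st0, dm, dT, dt, p)
                Jfd[:, j] = (sp_.sigma - sm_.sigma) / (2 * h)
            assert np.allclose(J, Jfd, rtol=1e-6, atol=1e-6 * np.abs(J).max())

    def test_strain_bookkeeping_invariants(self, table_params, rng):
        # eps_total = eps_me + eps_th + eps_S and eps_me = eps_el + eps_v
        # hold after every update of a random thermomechanical path
        p = table_params
        state = MaterialState.initial(360.0, p)
        for _ in range(50):
            d_eps = rng.normal(0, 2e-3, 6)
            dT = float(rng.uniform(-3, 3))
            state, _ = update_state(state, d_eps, dT, 1.0, p)
            assert np.allclose(state.eps_me + state.eps_th + state.eps_S,
                               state.eps_total, atol=1e-10)
            assert np.allclose(state.eps_elastic + state.eps_viscous,
                               state.eps_me, atol=1e-10)
            assert 0.0 <= state.z <= 1.0

    def test_input_validation(self, table_params):
        st0 = MaterialState.initial(350.0, table_params)
        with pytest.raises(ValueError):
            update_state(st0, np.full(6, np.nan), 0.0, 1.0, table_params)
        with pytest.raises(ValueError):
            update_state(st0, np.zeros(6), 0.0, -1.0, table_params)
        with pytest.warns(UserWarning, match="retardation"):
            update_state(st0, np.zeros(6), 0.0, 1e5, table_params)


class TestUniaxialDriver:
    def test_lateral_stresses_vanish(self, table_params):
        state = MaterialState.initial(353.15, table_params)
        state, _ = uniaxial_step(state, 0.0, 0.5, table_params, eps_x=-0.01)
        assert state.eps_total[0] == pytest.approx(-0.01)
        assert abs(state.sigma[1]) < 1e-9 * abs(state.sigma[0])
        assert abs(state.sigma[2]) < 1e-9 * abs(state.sigma[0])

    def test_stress_control_hits_target(self, table_params):
        state = MaterialState.initial(353.15, table_params)
        state, _ = uniaxial_step(state, 0.0, 0.5, table_params, sigma_x=-1e4)
        assert state.sigma[0] == pytest.approx(-1e4, rel=1e-9)

    def test_exactly_one_control_required(self, table_params):
        state = MaterialState.initial(353.15, table_params)
        with pytest.raises(ValueError):
            uniaxial_step(state, 0.0, 0.5, table_params)


def test_tobushi_rate_form_limits():
    # at zero stress the classic rate form relaxes strain toward the stored
    # strain with the retardation time
    rate = tobushi_strain_rate(0.0, 0.0, 0.3, 0.1, Es=1e6, mu=1e5, lam=10.0)
    assert rate == pytest.approx(-(0.3 - 0.1) / 10.0)
    # equilibrium: eps = eps_S + lam * sigma / mu
    sigma = 5e4
    eps_eq = 0.1 + 10.0 * sigma / 1e5
    assert tobushi_strain_rate(sigma, 0.0, eps_eq, 0.1, 1e6, 1e5, 10.0) == \
        pytest.approx(0.0, abs=1e-15)
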