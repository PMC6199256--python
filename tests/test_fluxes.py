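"""Membrane transport models against independent closed-form oracles.

Expected values were computed independently (closed-form stationary
solutions and direct high-precision evaluation of the rate laws) and are
frozen here.
"""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from spinecalc import (
    ModelConfig,
    calibrate_leakage,
    ip3r_flux_density,
    ip3r_open_probability,
    ncx_flux_density,
    pmca_flux_density,
    release_flux,
    ryr_flux_density,
    ryr_steady_state,
    ryr_step,
    serca_flux_density,
)
from spinecalc.fluxes import (
    RyRState,
    er_leak_flux_density,
    nmdar_single_channel_current,
    pm_leak_flux_density,
)
from spinecalc.units import mol_per_um3_to_uM, uM_to_mol_per_um3


@pytest.fixture(scope="module")
def cfg():
    return ModelConfig()


class TestIP3R:
    def test_open_probability_at_equilibrium(self, cfg):
        assert ip3r_open_probability(0.05, 0.04, cfg) == pytest.approx(
            3.396e-4, rel=1e-3)

    @pytest.mark.parametrize("c,p", [(0.0, 0.5), (0.3, 0.0), (0.0, 0.0)])
    def test_vanishes_without_calcium_or_ip3(self, cfg, c, p):
        assert ip3r_open_probability(c, p, cfg) == 0.0

    def test_flux_at_equilibrium(self, cfg):
        assert ip3r_flux_density(0.05, 250.0, 0.04, cfg) == pytest.approx(
            6.46e-22, rel=2e-3)

    def test_zero_gradient_zero_flux(self, cfg):
        assert ip3r_flux_density(1.0, 1.0, 0.5, cfg) == 0.0

    def test_flux_linear_in_density(self, cfg):
        j1 = ip3r_flux_density(0.05, 250.0, 0.04, cfg)
        j2 = ip3r_flux_density(0.05, 250.0, 0.04, cfg.with_(rho_I=2 * cfg.rho_I))
        assert j2 == pytest.approx(2 * j1, rel=1e-12)

    def test_bell_shape_in_calcium(self, cfg):
        c = np.linspace(0.01, 20.0, 2000)
        po = ip3r_open_probability(c, 0.5, cfg)
        k = int(po.argmax())
        assert 0 < k < len(c) - 1
        assert np.all(np.diff(po[:k + 1]) > 0)
        assert np.all(np.diff(po[k:]) < 0)
        # maximum location agrees with a brute-force scan on a finer grid
        cf = np.linspace(0.01, 20.0, 40000)
        kf = ip3r_open_probability(cf, 0.5, cfg).argmax()
        assert abs(cf[kf] - c[k]) < 0.02


class TestRyR:
    def test_stationary_open_probability_at_rest(self, cfg):
        ss = ryr_steady_state(0.05, cfg)
        assert float(ss.open_probability) == pytest.approx(3.24e-4, rel=1e-3)

    def test_stationary_open_probability_saturates(self, cfg):
        ss = ryr_steady_state(10.0, cfg)
        assert float(ss.open_probability) == pytest.approx(0.995, rel=1e-3)

    @pytest.mark.parametrize("c", [0.0, 0.01, 0.05, 0.5, 2.0, 10.0])
    def test_states_on_simplex(self, cfg, c):
        ss = ryr_steady_state(c, cfg)
        states = [float(ss.c1), float(ss.o1), float(ss.o2), float(ss.c2)]
        assert all(-1e-12 <= s <= 1 + 1e-12 for s in states)
        assert sum(states) == pytest.approx(1.0, abs=1e-12)

    def test_absorbing_closed_state_without_calcium(self, cfg):
        ss = ryr_steady_state(0.0, cfg)
        assert float(ss.c1) == 1.0 and float(ss.open_probability) == 0.0

    def test_open_probability_monotone_in_calcium(self, cfg):
        c = np.linspace(0.01, 10.0, 500)
        po = ryr_steady_state(c, cfg).open_probability
        assert np.all(np.diff(po) >= 0)

    def test_flux_at_equilibrium(self, cfg):
        ss = ryr_steady_state(0.05, cfg)
        assert float(ryr_flux_density(ss, 0.05, 250.0, cfg)) == pytest.approx(
            3.40e-21, rel=2e-3)

    def test_fully_open_flux(self, cfg):
        s = RyRState(c1=np.array(0.0), o2=np.array(1.0), c2=np.array(0.0))
        j = float(ryr_flux_density(s, 0.0, 250.0, cfg))
        assert j == pytest.approx(1.05e-17, rel=1e-3)

    def test_step_keeps_steady_state_fixed(self, cfg):
        ss = ryr_steady_state(0.3, cfg)
        out = ryr_step(ss, 0.3, 0.01, cfg)
        assert float(out.open_probability) == pytest.approx(
            float(ss.open_probability), rel=1e-9)

    def test_step_converges_to_new_stationary_point(self, cfg):
        s = ryr_steady_state(0.05, cfg)
        for _ in range(40000):
            s = ryr_step(s, 5.0, 1e-3, cfg)
        assert float(s.open_probability) == pytest.approx(
            float(ryr_steady_state(5.0, cfg).open_probability), rel=1e-3)

    def _oracle(self, cfg, s0, c, T):
        """Independent stiff integration of the gating master equation."""
        ka_p, ka_m = cfg.k_a_plus, cfg.k_a_minus
        kb_p, kb_m = cfg.k_b_plus, cfg.k_b_minus
        kc_p, kc_m = cfg.k_c_plus, cfg.k_c_minus

        def rhs(t, x):
            c1, o2, c2 = x
            o1 = 1.0 - c1 - o2 - c2
            return [ka_m * o1 - ka_p * c**4 * c1,
                    kb_p * c**3 * o1 - kb_m * o2,
                    kc_p * o1 - kc_m * c2]

        sol = solve_ivp(rhs, (0, T), [float(s0.c1), float(s0.o2), float(s0.c2)],
                        method="LSODA", rtol=1e-10, atol=1e-12)
        return sol.y[:, -1]

    def test_step_matches_stiff_ode_oracle(self, cfg):
        s0 = ryr_steady_state(0.05, cfg)
        T, c = 0.05, 5.0
        ref = self._oracle(cfg, s0, c, T)
        s = s0
        n = 5000
        for _ in range(n):
            s = ryr_step(s, c, T / n, cfg)
        got = np.array([float(s.c1), float(s.o2), float(s.c2)])
        assert np.allclose(got, ref, atol=2e-4)
        # after the fast activation transient the open probability
        # approaches the stationary value monotonically (slow adaptation)
        po_inf = float(ryr_steady_state(c, cfg).open_probability)
        s, dist = s0, []
        for _ in range(100):
            s = ryr_step(s, c, T / 100, cfg)
            dist.append(abs(float(s.open_probability) - po_inf))
        assert np.all(np.diff(dist[2:]) <= 1e-12)
        assert dist[-1] < dist[2]

    def test_step_is_first_order_in_dt(self, cfg):
        s0 = ryr_steady_state(0.05, cfg)
        T, c = 0.02, 2.0
        ref = self._oracle(cfg, s0, c, T)

        def err(n):
            s = s0
            for _ in range(n):
                s = ryr_step(s, c, T / n, cfg)
            return abs(float(s.o2) - ref[1]) + abs(float(s.c1) - ref[0])

        ratio = err(50) / err(100)
        assert 1.6 < ratio < 2.6


class TestPumps:
    def test_serca_at_equilibrium(self, cfg):
        assert float(serca_flux_density(0.05, 250.0, cfg)) == pytest.approx(
            1.351e-20, rel=1e-3)

    def test_serca_zero_without_cytosolic_calcium(self, cfg):
        assert float(serca_flux_density(0.0, 250.0, cfg)) == 0.0

    def test_serca_inverse_in_store_level(self, cfg):
        assert float(serca_flux_density(0.1, 500.0, cfg)) == pytest.approx(
            0.5 * float(serca_flux_density(0.1, 250.0, cfg)), rel=1e-12)

    def test_serca_rejects_empty_store(self, cfg):
        with pytest.raises(ValueError):
            serca_flux_density(0.1, 0.0, cfg)

    def test_pmca_half_saturation(self, cfg):
        assert float(pmca_flux_density(0.06, cfg)) == pytest.approx(
            4.25e-21, rel=1e-3)

    def test_pmca_at_rest_and_saturation(self, cfg):
        assert float(pmca_flux_density(0.05, cfg)) == pytest.approx(
            3.48e-21, rel=2e-3)
        assert float(pmca_flux_density(1e6, cfg)) == pytest.approx(
            8.5e-21, rel=1e-3)

    def test_ncx_half_saturation_and_rest(self, cfg):
        assert float(ncx_flux_density(1.8, cfg)) == pytest.approx(
            1.875e-20, rel=1e-3)
        assert float(ncx_flux_density(0.05, cfg)) == pytest.approx(
            1.01e-21, rel=2e-3)
        assert float(ncx_flux_density(0.0, cfg)) == 0.0


class TestLeakCalibration:
    def test_er_leak_reproduces_printed_value(self, cfg):
        v_le, _ = calibrate_leakage(cfg)
        assert v_le * 1e3 == pytest.approx(38.0, rel=0.02)  # nm/s

    def test_pm_leak_from_balance(self, cfg):
        # the zero-net-flux balance, not the printed table entry
        _, v_lp = calibrate_leakage(cfg)
        assert v_lp * 1e3 == pytest.approx(2.25, rel=0.01)

    def test_nothing_to_balance_gives_zero_leak(self, cfg):
        v_le, _ = calibrate_leakage(cfg, er_mechanisms=())
        assert v_le == 0.0

    def test_equilibrium_net_fluxes_are_machine_zero(self, cfg):
        c, e, p = cfg.c_c_eq, cfg.c_e_eq, cfg.p_eq
        v_le, v_lp = calibrate_leakage(cfg)
        ss = ryr_steady_state(c, cfg)
        j_erm = (float(ip3r_flux_density(c, e, p, cfg))
                 + float(ryr_flux_density(ss, c, e, cfg))
                 - float(serca_flux_density(c, e, cfg))
                 + float(er_leak_flux_density(c, e, v_le, cfg)))
        j_pm = (-float(pmca_flux_density(c, cfg))
                - float(ncx_flux_density(c, cfg))
                + float(pm_leak_flux_density(c, v_lp, cfg)))
        assert abs(j_erm) < 1e-30
        assert abs(j_pm) < 1e-30


class TestRelease:
    def test_pulse_ramp(self, cfg):
        j0, _ = release_flux("pulse1ms", 0.0, 0.05, cfg)
        jh, _ = release_flux("pulse1ms", 0.5e-3, 0.05, cfg)
        j1, _ = release_flux("pulse1ms", 1.5e-3, 0.05, cfg)
        assert j0 == pytest.approx(1.0e-16, rel=1e-12)
        assert jh == pytest.approx(5.0e-17, rel=1e-12)
        assert j1 == 0.0

    def test_exponential_profile(self, cfg):
        j0, _ = release_flux("exp10ms", 0.0, 0.05, cfg)
        j10, _ = release_flux("exp10ms", 0.010, 0.05, cfg)
        assert j0 == pytest.approx(5.0e-17, rel=1e-12)
        assert j10 == pytest.approx(5.0e-17 / math.e, rel=1e-9)

    def test_nmdar_single_channel_current(self, cfg):
        I = nmdar_single_channel_current(0.0, cfg)
        assert abs(I) == pytest.approx(8.56e-20, rel=2e-3)
        assert I < 0  # inward at -70 mV

    def test_nmdar_one_open_channel_calibration(self, cfg):
        area = 0.0708
        j, _ = release_flux("nmdar150ms", 0.0, 0.0, cfg, synapse_area=area)
        assert j * area == pytest.approx(8.56e-20, rel=2e-3)

    def test_ip3_production_ramp(self, cfg):
        _, j0 = release_flux("pulse1ms", 0.0, 0.05, cfg, with_ip3=True)
        _, j100 = release_flux("pulse1ms", 0.1, 0.05, cfg, with_ip3=True)
        _, j300 = release_flux("pulse1ms", 0.3, 0.05, cfg, with_ip3=True)
        assert j0 == pytest.approx(5.0e-18, rel=1e-12)
        assert j100 == pytest.approx(2.5e-18, rel=1e-12)
        assert j300 == 0.0

    def test_unknown_profile_rejected(self, cfg):
        with pytest.raises(ValueError, match="unknown release profile"):
            release_flux("bogus", 0.0, 0.05, cfg)


def test_unit_conversions_roundtrip_exactly():
    for c in (0.04, 0.05, 40.0, 250.0, 2000.0):
        assert mol_per_um3_to_uM(uM_to_mol_per_um3(c)) == c
    assert uM_to_mol_per_um3(1.0) == 1e-21
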