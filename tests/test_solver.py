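"""Finite-volume solver: stationarity, conservation, convergence, oracles."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from spinecalc import (
    MembraneComposition,
    ModelConfig,
    SolverConfig,
    SpineParams,
    build_compartment_grid,
    equilibrium_state,
    run_simulation,
    total_calcium,
)
from spinecalc.fluxes import RyRState, ryr_steady_state
from spinecalc.grid import CompartmentGrid, ERM_SPINE
from spinecalc.solver import Discretization, assemble_residual, step


def passive_cfg(**kw):
    comp = MembraneComposition(erm_spine=(), erm_dendrite=(), pm=())
    return ModelConfig(composition=comp, **kw)


def make_cylinder_grid(n=200, length=10.0, radius=0.45):
    """Plain sealed cylinder: cytosol only, no membranes (test harness)."""
    h = length / n
    pos = (np.arange(n) + 0.5) * h
    A = math.pi * radius**2
    edges = np.array([[k, k + 1] for k in range(n - 1)], int)
    return CompartmentGrid(
        params=SpineParams(),
        cyt_pos=pos, cyt_branch=np.zeros(n, int),
        cyt_vol=np.full(n, A * h), pm_area=np.zeros(n),
        syn_area=np.zeros(n), roi=np.zeros(n, int),
        cyt_edges=edges, cyt_coeff=np.full(n - 1, A / h),
        er_pos=np.zeros(0), er_branch=np.zeros(0, int), er_vol=np.zeros(0),
        er_edges=np.zeros((0, 2), int), er_coeff=np.zeros(0),
        erm_cyt=np.zeros(0, int), erm_er=np.zeros(0, int),
        erm_area=np.zeros(0), erm_subset=np.zeros(0, int),
    )


def make_two_compartment_grid(V_cyt=0.1, V_er=0.01, A_erm=0.5, A_pm=1.0,
                              A_syn=0.05):
    """One well-mixed cytosol node + one ER node + one membrane patch."""
    return CompartmentGrid(
        params=SpineParams(),
        cyt_pos=np.array([0.0]), cyt_branch=np.array([1]),
        cyt_vol=np.array([V_cyt]), pm_area=np.array([A_pm]),
        syn_area=np.array([A_syn]), roi=np.array([1]),
        cyt_edges=np.zeros((0, 2), int), cyt_coeff=np.zeros(0),
        er_pos=np.array([0.0]), er_branch=np.array([1]),
        er_vol=np.array([V_er]),
        er_edges=np.zeros((0, 2), int), er_coeff=np.zeros(0),
        erm_cyt=np.array([0]), erm_er=np.array([0]),
        erm_area=np.array([A_erm]), erm_subset=np.array([ERM_SPINE]),
    )


class TestResidual:
    def test_equilibrium_is_machine_zero(self, default_grid, cfg):
        disc = Discretization(default_grid, cfg)
        s = equilibrium_state(default_grid, cfg)
        F, J, _ = assemble_residual(disc, s, s, 2e-5, s.ryr.open_probability)
        assert np.max(np.abs(F)) < 1e-10

    def test_all_mechanisms_off_uniform_fields(self, default_grid):
        cfg = passive_cfg()
        disc = Discretization(default_grid, cfg)
        s = equilibrium_state(default_grid, cfg)
        F, _ = assemble_residual(disc, s, s, 1e-4, s.ryr.open_probability,
                                 want_jacobian=False)
        assert np.max(np.abs(F)) < 1e-9

    def test_diffusion_stencil_conserves_mass(self, default_grid, cfg):
        disc = Discretization(default_grid, cfg)
        ones = np.ones(default_grid.n_cyt)
        assert np.max(np.abs(disc.L_c @ ones)) < 1e-12
        colsum = np.asarray(disc.L_c.sum(axis=0)).ravel()
        assert np.max(np.abs(colsum)) < 1e-12

    def test_mismatched_state_rejected(self, default_grid, cfg):
        disc = Discretization(default_grid, cfg)
        s = equilibrium_state(default_grid, cfg)
        bad = s.copy()
        bad.c_c = bad.c_c[:-1]
        with pytest.raises(ValueError, match="does not match"):
            assemble_residual(disc, bad, s, 1e-4, s.ryr.open_probability)


class TestStationarity:
    def test_equilibrium_fixed_point_over_100ms(self, default_grid, cfg):
        res = run_simulation(default_grid, cfg, SolverConfig(),
                             release_profile=None, duration=0.1)
        for name in ("head", "neck", "dendrite_roi"):
            drift = np.abs(res.traces[name] - cfg.c_c_eq).max()
            assert drift < 0.01 * cfg.c_c_eq
        assert np.abs(res.traces["er_spine"] - cfg.c_e_eq).max() < 0.01 * cfg.c_e_eq

    def test_ryr_only_composition_is_also_stationary(self, default_grid):
        comp = MembraneComposition(erm_spine=("RyR", "SERCA", "leak"),
                                   erm_dendrite=("RyR", "SERCA", "leak"))
        cfg = ModelConfig(composition=comp)
        res = run_simulation(default_grid, cfg, SolverConfig(),
                             release_profile=None, duration=0.02)
        drift = np.abs(res.traces["head"] - cfg.c_c_eq).max()
        assert drift < 0.01 * cfg.c_c_eq


class TestDiffusionOracle:
    def _heat_kernel_images(self, x, t, x0, sigma0, D, L, n_images=6):
        """Sealed-interval solution as an image sum of Gaussians."""
        out = np.zeros_like(x)
        s2 = sigma0**2 + 2 * D * t
        for k in range(-n_images, n_images + 1):
            for xs in (2 * k * L + x0, 2 * k * L - x0):
                out += np.exp(-((x - xs) ** 2) / (2 * s2))
        return out * sigma0 / math.sqrt(s2)

    def test_gaussian_matches_analytic_solution(self):
        D, L, sigma0, x0 = 220.0, 10.0, 0.3, 5.0
        n, dt, T = 200, 1e-5, 5e-4
        grid = make_cylinder_grid(n=n, length=L)
        cfg = passive_cfg(kappa_b_plus=0.0, kappa_b_minus=0.0, kappa_p=0.0)
        disc = Discretization(grid, cfg)
        s = equilibrium_state(grid, cfg)
        amp = 1.0
        s.c_c = cfg.c_c_eq + amp * np.exp(
            -((grid.cyt_pos - x0) ** 2) / (2 * sigma0**2))
        scfg = SolverConfig(dt_fine=dt, fine_until=1.0)
        t = 0.0
        while t < T - 1e-12:
            s, _ = step(disc, s, dt, scfg)
            t = s.t
        ref = cfg.c_c_eq + amp * self._heat_kernel_images(
            grid.cyt_pos, T, x0, sigma0, D, L)
        err = np.linalg.norm(s.c_c - ref) / np.linalg.norm(ref - cfg.c_c_eq)
        assert err < 0.01

    def test_second_order_in_h(self):
        D, L, sigma0, x0 = 220.0, 10.0, 0.3, 5.0
        dt, T = 5e-7, 1e-4
        cfg = passive_cfg(kappa_b_plus=0.0, kappa_b_minus=0.0, kappa_p=0.0)

        def l2_error(n):
            grid = make_cylinder_grid(n=n, length=L)
            disc = Discretization(grid, cfg)
            s = equilibrium_state(grid, cfg)
            s.c_c = cfg.c_c_eq + np.exp(
                -((grid.cyt_pos - x0) ** 2) / (2 * sigma0**2))
            t = 0.0
            while t < T - 1e-12:
                s, _ = step(disc, s, dt, SolverConfig())
                t = s.t
            ref = cfg.c_c_eq + self._heat_kernel_images(
                grid.cyt_pos, T, x0, sigma0, D, L)
            h = L / n
            return math.sqrt(float(np.sum(h * (s.c_c - ref) ** 2)))

        ratio = l2_error(50) / l2_error(100)
        assert 3.0 < ratio < 5.0


class TestTwoCompartmentOracle:
    """PDE solver collapsed to two well-mixed compartments vs an
    independently coded stiff-ODE integration of the same flux models."""

    def _oracle(self, cfg, grid, v_le, v_lp, y0, T):
        V1 = float(grid.cyt_vol[0])
        V2 = float(grid.er_vol[0])
        A = float(grid.erm_area[0])
        A_pm = float(grid.pm_area[0])
        UM = 1e-21

        def rhs(t, y):
            c, b, p, e, c1, o2, c2 = y
            # calbindin and IP3 reactions
            R = cfg.kappa_b_minus * (cfg.b_sites - b) - cfg.kappa_b_plus * b * c
            dp = -cfg.kappa_p * (p - cfg.p_r)
            # ER membrane: IP3R + RyR - SERCA + leak
            q = (cfg.d2 * c * p
                 / ((c * p + cfg.d2 * p + cfg.d3 * c + cfg.d1 * cfg.d2)
                    * (c + cfg.d5)))
            j = cfg.rho_I * q**3 * cfg.I_I_ref * (e - c) / cfg.c_e_ref
            o1 = 1 - c1 - o2 - c2
            j += cfg.rho_R * (o1 + o2) * cfg.I_R_ref * (e - c) / cfg.c_e_ref
            j -= cfg.rho_S * cfg.I_S * c / ((cfg.K_S + c) * e)
            j += v_le * (e - c) * UM
            # plasma membrane: -PMCA - NCX + leak
            jp = -cfg.rho_P * cfg.I_P * c**2 / (cfg.K_P**2 + c**2)
            jp -= cfg.rho_N * cfg.I_N * c / (cfg.K_N + c)
            jp += v_lp * (cfg.c_o - c) * UM
            dc = (A * j + A_pm * jp) / (V1 * UM) + R
            db = R
            de = -A * j / (V2 * UM)
            dc1 = cfg.k_a_minus * o1 - cfg.k_a_plus * c**4 * c1
            do2 = cfg.k_b_plus * c**3 * o1 - cfg.k_b_minus * o2
            dc2 = cfg.k_c_plus * o1 - cfg.k_c_minus * c2
            return [dc, db, dp, de, dc1, do2, dc2]

        sol = solve_ivp(rhs, (0, T), y0, method="LSODA",
                        rtol=1e-10, atol=1e-12, max_step=1e-4)
        return sol.y[:, -1]

    def test_trajectory_matches_ode_integration(self):
        grid = make_two_compartment_grid()
        cfg = ModelConfig()
        disc = Discretization(grid, cfg)
        s = equilibrium_state(grid, cfg)
        # perturb cytosolic calcium well off equilibrium to engage the
        # nonlinear channel kinetics
        s.c_c[:] = 0.8
        T = 0.02
        y0 = [0.8, float(s.b[0]), float(s.p[0]), float(s.c_e[0]),
              float(s.ryr.c1[0]), float(s.ryr.o2[0]), float(s.ryr.c2[0])]
        ref = self._oracle(cfg, grid, disc.v_le[ERM_SPINE], disc.v_lp, y0, T)

        scfg = SolverConfig(dt_fine=2e-6, fine_until=1.0)
        t = 0.0
        while t < T - 1e-12:
            s, _ = step(disc, s, 2e-6, scfg)
            t = s.t
        assert float(s.c_c[0]) == pytest.approx(ref[0], rel=5e-3)
        assert float(s.b[0]) == pytest.approx(ref[1], rel=5e-3)
        assert float(s.c_e[0]) == pytest.approx(ref[3], rel=5e-3)
        assert float(s.ryr.o2[0]) == pytest.approx(ref[5], rel=2e-2, abs=1e-9)


class TestConservationAndDeterminism:
    def test_mass_ledger_balances(self, no_spine_er_run):
        res = no_spine_er_run.result
        dmass = res.total_ca - res.total_ca[0]
        net = sum(res.ledger[k] for k in res.ledger)
        err = np.max(np.abs(dmass - net)) / res.released
        assert err < 1e-3
        assert res.released > 0

    def test_transient_returns_toward_baseline(self, no_spine_er_run):
        tr = no_spine_er_run.result.traces["head"]
        assert tr.max() > 20 * tr[0]          # clear transient
        assert tr[-1] < 0.2 * tr.max()        # decays back toward baseline

    def test_concentrations_stay_positive(self, no_spine_er_run, ryr_15_run):
        for run in (no_spine_er_run, ryr_15_run):
            s = run.result.final_state
            assert s.c_c.min() >= 0 and s.b.min() >= 0 and s.p.min() >= 0
            if len(s.c_e):
                assert s.c_e.min() >= 0
            for name in ("head", "neck", "dendrite_roi"):
                assert run.result.traces[name].min() >= 0

    def test_repeat_run_is_bit_identical(self, cfg):
        grid = build_compartment_grid(SpineParams(spine_er_length=0.8))
        kw = dict(release_profile="pulse1ms", duration=0.01)
        a = run_simulation(grid, cfg, SolverConfig(), **kw)
        b = run_simulation(grid, cfg, SolverConfig(), **kw)
        for name in a.traces:
            assert np.array_equal(a.traces[name], b.traces[name])
        assert a.released == b.released

    def test_staggered_and_coupled_ryr_agree_at_small_dt(self, cfg):
        grid = build_compartment_grid(SpineParams(spine_er_length=1.5))
        kw = dict(release_profile="pulse1ms", duration=0.004)
        a = run_simulation(grid, cfg, SolverConfig(dt_fine=1e-5), **kw)
        b = run_simulation(
            grid, cfg, SolverConfig(dt_fine=1e-5, ryr_coupling="within-newton"),
            **kw)
        ha, hb = a.traces["head"][-1], b.traces["head"][-1]
        assert hb == pytest.approx(ha, rel=0.02)


class TestTimeConvergence:
    def test_first_order_in_dt(self, cfg):
        grid = build_compartment_grid(SpineParams(spine_er_length=1.5))
        T = 0.004

        def head_at_T(dt):
            res = run_simulation(
                grid, cfg, SolverConfig(dt_fine=dt, fine_until=1.0),
                release_profile="pulse1ms", duration=T)
            return res.traces["head"][-1]

        ref = head_at_T(2.5e-6)
        e40 = abs(head_at_T(4e-5) - ref)
        e20 = abs(head_at_T(2e-5) - ref)
        e10 = abs(head_at_T(1e-5) - ref)
        assert 1.5 < e40 / e20 < 3.0
        assert 1.5 < e20 / e10 < 3.5
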