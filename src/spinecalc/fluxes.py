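"""Single-channel / pump flux-density models, RyR gating, leakage calibration
and the synaptic release profiles.

Sign conventions: every function returns the flux density positive in the
direction its mechanism physically moves Ca²⁺ —

* IP₃R, RyR, ER leak: ER → cytosol (positive when c_e > c_c),
* SERCA: cytosol → ER,
* PMCA, NCX: cytosol → extracellular,
* PM leak, synaptic release: into the cytosol.

The solver applies the ER-membrane (j_I + j_R − j_S + j_le) and
plasma-membrane (−j_P − j_N + j_lp) sign patterns at assembly time.

Concentrations are in µM, flux densities in mol s⁻¹ µm⁻².
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import ModelConfig
from .units import MOL_PER_UM3_PER_UM


# ---------------------------------------------------------------------------
# IP₃ receptor
# ---------------------------------------------------------------------------

def ip3r_open_probability(c_c, p, cfg: ModelConfig):
    """Open-state probability of a single IP₃R channel.

    Joint Ca²⁺/IP₃ gating with four dissociation constants; bell-shaped in
    c_c at fixed p (activation at low, inhibition at high Ca²⁺). Cubed
    because three subunits must be in the permissive state.
    """
    c_c = np.asarray(c_c, dtype=float)
    p = np.asarray(p, dtype=float)
    num = cfg.d2 * c_c * p
    den = (c_c * p + cfg.d2 * p + cfg.d3 * c_c + cfg.d1 * cfg.d2) * (c_c + cfg.d5)
    q = num / den
    return q**3


def _ip3r_q_derivs(c_c, p, cfg: ModelConfig):
    """(q, dq/dc_c, dq/dp) for the IP₃R gating ratio q (p° = q³)."""
    c_c = np.asarray(c_c, dtype=float)
    p = np.asarray(p, dtype=float)
    G = c_c * p + cfg.d2 * p + cfg.d3 * c_c + cfg.d1 * cfg.d2
    H = c_c + cfg.d5
    N = cfg.d2 * c_c * p
    q = N / (G * H)
    dN_dc = cfg.d2 * p
    dN_dp = cfg.d2 * c_c
    dG_dc = p + cfg.d3
    dG_dp = c_c + cfg.d2
    dq_dc = (dN_dc * G * H - N * (dG_dc * H + G)) / (G * H) ** 2
    dq_dp = (dN_dp * G * H - N * dG_dp * H) / (G * H) ** 2
    return q, dq_dc, dq_dp


def ip3r_flux_density(c_c, c_e, p, cfg: ModelConfig):
    """IP₃R Ca²⁺ flux density, positive ER → cytosol (mol s⁻¹ µm⁻²)."""
    po = ip3r_open_probability(c_c, p, cfg)
    return cfg.rho_I * po * cfg.I_I_ref * (np.asarray(c_e) - np.asarray(c_c)) / cfg.c_e_ref


# ---------------------------------------------------------------------------
# RyR: 4-state gating chain (c1 <-> o1 <-> o2, o1 <-> c2)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RyRState:
    """Occupancies of the RyR gating chain; o1 is defined by closure."""

    c1: np.ndarray
    o2: np.ndarray
    c2: np.ndarray

    @property
    def o1(self) -> np.ndarray:
        return 1.0 - self.c1 - self.o2 - self.c2

    @property
    def open_probability(self) -> np.ndarray:
        return self.o1 + self.o2

    def validate(self):
        for name in ("c1", "o2", "c2"):
            v = np.asarray(getattr(self, name))
            if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
                raise ValueError(f"RyR state {name} outside [0, 1]")
        if np.any(np.asarray(self.o1) < -1e-12):
            raise ValueError("RyR state o1 outside [0, 1]")
        return self


def ryr_steady_state(c_c, cfg: ModelConfig) -> RyRState:
    """Stationary distribution of the gating chain at fixed cytosolic Ca²⁺.

    Detailed balance around o1: c1 = (k_a⁻/(k_a⁺ c⁴)) o1,
    o2 = (k_b⁺ c³/k_b⁻) o1, c2 = (k_c⁺/k_c⁻) o1, normalized. As c → 0 the
    closed state c1 is absorbing (open probability → 0).
    """
    c = np.asarray(c_c, dtype=float)
    scalar = c.ndim == 0
    c = np.atleast_1d(c)
    pos = c > 0
    c_safe = np.where(pos, c, 1.0)
    r1 = cfg.k_a_minus / (cfg.k_a_plus * c_safe**4)
    r2 = cfg.k_b_plus * c_safe**3 / cfg.k_b_minus
    r3 = cfg.k_c_plus / cfg.k_c_minus
    s = 1.0 + r1 + r2 + r3
    o1 = np.where(pos, 1.0 / s, 0.0)
    c1 = np.where(pos, r1 / s, 1.0)  # c = 0: the closed state is absorbing
    o2 = np.where(pos, r2 / s, 0.0)
    c2 = np.where(pos, r3 / s, 0.0)
    if scalar:
        return RyRState(c1=c1[0], o2=o2[0], c2=c2[0])
    return RyRState(c1=c1, o2=o2, c2=c2)


def ryr_step(s: RyRState, c_c, dt: float, cfg: ModelConfig) -> RyRState:
    """Advance the gating ODEs one implicit-Euler step at frozen c_c.

    The chain is a linear master equation, so backward Euler amounts to one
    3×3 solve per patch (o1 eliminated by closure). The scheme is
    unconditionally stable, keeps the four occupancies on the simplex
    exactly (closure is algebraic, the implicit matrix is an M-matrix), and
    converges to :func:`ryr_steady_state` for t → ∞ at fixed c_c.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    c = np.atleast_1d(np.asarray(c_c, dtype=float))
    c1 = np.atleast_1d(np.asarray(s.c1, dtype=float))
    o2 = np.atleast_1d(np.asarray(s.o2, dtype=float))
    c2 = np.atleast_1d(np.asarray(s.c2, dtype=float))
    n = c1.shape[0]

    ka = cfg.k_a_plus * c**4
    kb = cfg.k_b_plus * c**3
    # x' = M x + r with x = (c1, o2, c2), o1 = 1 − Σx:
    M = np.zeros((n, 3, 3))
    M[:, 0, 0] = -cfg.k_a_minus - ka
    M[:, 0, 1] = -cfg.k_a_minus
    M[:, 0, 2] = -cfg.k_a_minus
    M[:, 1, 0] = -kb
    M[:, 1, 1] = -kb - cfg.k_b_minus
    M[:, 1, 2] = -kb
    M[:, 2, 0] = -cfg.k_c_plus
    M[:, 2, 1] = -cfg.k_c_plus
    M[:, 2, 2] = -cfg.k_c_plus - cfg.k_c_minus
    r = np.empty((n, 3))
    r[:, 0] = cfg.k_a_minus
    r[:, 1] = kb
    r[:, 2] = cfg.k_c_plus

    A = np.eye(3)[None, :, :] - dt * M
    rhs = np.stack([c1, o2, c2], axis=1) + dt * r
    x = np.linalg.solve(A, rhs[..., None])[..., 0]
    out = RyRState(c1=x[:, 0], o2=x[:, 1], c2=x[:, 2])
    if np.isscalar(c_c) or np.asarray(s.c1).ndim == 0:
        return RyRState(c1=x[0, 0], o2=x[0, 1], c2=x[0, 2])
    return out


def ryr_flux_density(s: RyRState, c_c, c_e, cfg: ModelConfig):
    """RyR Ca²⁺ flux density, positive ER → cytosol (mol s⁻¹ µm⁻²)."""
    po = s.open_probability
    return cfg.rho_R * po * cfg.I_R_ref * (np.asarray(c_e) - np.asarray(c_c)) / cfg.c_e_ref


# ---------------------------------------------------------------------------
# Pumps
# ---------------------------------------------------------------------------

def serca_flux_density(c_c, c_e, cfg: ModelConfig):
    """SERCA flux density, positive cytosol → ER (mol s⁻¹ µm⁻²).

    Michaelis–Menten in c_c with an extra 1/c_e factor expressing reduced
    pumping into a saturated store. Undefined for an empty store.
    """
    c_e = np.asarray(c_e, dtype=float)
    if np.any(c_e <= 0):
        raise ValueError("SERCA flux undefined for empty store (c_e <= 0)")
    c_c = np.asarray(c_c, dtype=float)
    return cfg.rho_S * cfg.I_S * c_c / ((cfg.K_S + c_c) * c_e)


def pmca_flux_density(c_c, cfg: ModelConfig):
    """PMCA flux density, positive efflux; second-order Hill in c_c."""
    c = np.asarray(c_c, dtype=float)
    return cfg.rho_P * cfg.I_P * c**2 / (cfg.K_P**2 + c**2)


def ncx_flux_density(c_c, cfg: ModelConfig):
    """NCX flux density, positive efflux; first-order Hill in c_c."""
    c = np.asarray(c_c, dtype=float)
    return cfg.rho_N * cfg.I_N * c / (cfg.K_N + c)


# ---------------------------------------------------------------------------
# Leakage calibration
# ---------------------------------------------------------------------------

def er_leak_flux_density(c_c, c_e, v_le, cfg: ModelConfig):
    """Passive ER leak, positive ER → cytosol: v_le (c_e − c_c)."""
    return v_le * (np.asarray(c_e) - np.asarray(c_c)) * MOL_PER_UM3_PER_UM


def pm_leak_flux_density(c_c, v_lp, cfg: ModelConfig):
    """Passive PM leak, positive inward: v_lp (c_o − c_c)."""
    return v_lp * (cfg.c_o - np.asarray(c_c)) * MOL_PER_UM3_PER_UM


def calibrate_leakage(cfg: ModelConfig, er_mechanisms=("IP3R", "RyR", "SERCA")):
    """Solve the zero-net-flux balance at the equilibrium state.

    v_le balances SERCA uptake against IP₃R + RyR release (all channel
    states at their stationary values for the equilibrium concentrations):
        j_S − j_I − j_R − v_le (c_e − c_c) = 0.
    v_lp balances PMCA + NCX extrusion:
        j_P + j_N − v_lp (c_o − c_c) = 0.
    With these values the total ER-membrane and plasma-membrane fluxes
    vanish identically at equilibrium, making the resting state a fixed
    point of the full model.

    Only the mechanisms named in ``er_mechanisms`` enter the ER balance, so
    a receptor composition (e.g. RyR-only) gets the leak that keeps *its*
    resting state stationary.

    Returns (v_le, v_lp) in µm/s.
    """
    c_c, c_e, p = cfg.c_c_eq, cfg.c_e_eq, cfg.p_eq
    j = 0.0
    if "SERCA" in er_mechanisms:
        j += float(serca_flux_density(c_c, c_e, cfg))
    if "IP3R" in er_mechanisms:
        j -= float(ip3r_flux_density(c_c, c_e, p, cfg))
    if "RyR" in er_mechanisms:
        ss = ryr_steady_state(c_c, cfg)
        j -= float(ryr_flux_density(ss, c_c, c_e, cfg))
    v_le = j / ((c_e - c_c) * MOL_PER_UM3_PER_UM)

    j_pm = float(pmca_flux_density(c_c, cfg)) + float(ncx_flux_density(c_c, cfg))
    v_lp = j_pm / ((cfg.c_o - c_c) * MOL_PER_UM3_PER_UM)

    if er_mechanisms and v_le <= 0:
        raise ValueError(
            f"non-positive ER leak {v_le:.3g} µm/s: the ER channel models "
            "release more at rest than SERCA pumps back (inconsistent parameters)"
        )
    if v_lp <= 0:
        raise ValueError(f"non-positive PM leak {v_lp:.3g} µm/s")
    return v_le, v_lp


# ---------------------------------------------------------------------------
# Synaptic release profiles
# ---------------------------------------------------------------------------

RELEASE_PROFILES = ("pulse1ms", "exp10ms", "nmdar150ms")


def nmdar_single_channel_current(c_c, cfg: ModelConfig):
    """GHK single-channel Ca²⁺ current of an open NMDAR (mol/s, signed).

    Negative = inward at hyperpolarized V_m. Concentrations enter in
    mol/µm³ so that p_NMDAR (µm³/s) × concentration gives mol/s.
    """
    x = cfg.V_m / cfg.V_tilde
    e = math.exp(x)
    c_o = cfg.c_o * MOL_PER_UM3_PER_UM
    c_c_int = np.asarray(c_c, dtype=float) * MOL_PER_UM3_PER_UM
    return cfg.p_NMDAR * x * (c_o - c_c_int * e) / (1.0 - e)


def release_flux(profile: str, t: float, c_c, cfg: ModelConfig,
                 synapse_area: float | None = None, with_ip3: bool = False):
    """Synaptic (j_ca, j_ip3) flux densities at time t, inward positive.

    * ``pulse1ms``: linear ramp from j_c_rls_1ms to zero over 1 ms.
    * ``exp10ms``: exponential decay, peak j_c_rls_10ms, τ = 10 ms.
    * ``nmdar150ms``: GHK single-channel current × exp(−t/150 ms), with
      ρ_NMDAR·p°_max calibrated so the expected maximum number of open
      channels on the synaptic patch is one (requires ``synapse_area``
      unless cfg.rho_p_max_product is set).

    j_ip3 is the linearly decaying IP₃ production (duration 200 ms) when
    ``with_ip3`` is true, else zero.
    """
    if profile == "pulse1ms":
        j_ca = cfg.j_c_rls_1ms * max(0.0, 1.0 - t / 1e-3)
    elif profile == "exp10ms":
        j_ca = cfg.j_c_rls_10ms * math.exp(-t / cfg.tau_rls)
    elif profile == "nmdar150ms":
        rp = cfg.rho_p_max_product
        if rp is None:
            if synapse_area is None:
                raise ValueError("nmdar150ms needs synapse_area to calibrate density")
            rp = 1.0 / synapse_area
        I = nmdar_single_channel_current(c_c, cfg)
        j_ca = rp * math.exp(-t / cfg.tau_NMDAR) * np.abs(I)
    else:
        raise ValueError(f"unknown release profile {profile!r}")

    j_ip3 = 0.0
    if with_ip3:
        j_ip3 = cfg.j_p_rls * max(0.0, 1.0 - t / cfg.ip3_release_duration)
    return j_ca, j_ip3
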