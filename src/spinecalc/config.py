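"""Biophysical model constants and per-membrane-subset mechanism composition.

All values live in a single :class:`ModelConfig` dataclass; nothing else in
the package hard-codes a scientific constant, so perturbing a default here
propagates to every simulation.

Units (the field docstrings state each):
  concentrations µM, lengths µm, time s, amount mol. Flux densities are
  mol s⁻¹ µm⁻²; single-channel currents mol s⁻¹; surface densities µm⁻².
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

ER_MECHANISMS = ("IP3R", "RyR", "SERCA", "leak")
PM_MECHANISMS = ("PMCA", "NCX", "leak")


@dataclass(frozen=True)
class MembraneComposition:
    """Which transport mechanisms are active on each membrane subset.

    A "passive" ER subset is an empty tuple: the membrane is a pure
    geometric obstacle with no Ca²⁺ exchange at all.
    """

    erm_spine: tuple = ("IP3R", "RyR", "SERCA", "leak")
    erm_dendrite: tuple = ("IP3R", "RyR", "SERCA", "leak")
    pm: tuple = ("PMCA", "NCX", "leak")

    def __post_init__(self):
        for name, allowed in (
            ("erm_spine", ER_MECHANISMS),
            ("erm_dendrite", ER_MECHANISMS),
            ("pm", PM_MECHANISMS),
        ):
            bad = set(getattr(self, name)) - set(allowed)
            if bad:
                raise ValueError(f"unknown mechanism(s) {sorted(bad)} on {name}")


@dataclass(frozen=True)
class ModelConfig:
    # ---- initial / equilibrium values (µM) --------------------------------
    c_c_eq: float = 0.05      # cytosolic Ca²⁺, 50 nM
    c_e_eq: float = 250.0     # ER Ca²⁺
    c_o: float = 2000.0       # extracellular Ca²⁺, 2 mM (constant)
    p_eq: float = 0.04        # IP₃, 40 nM
    b_tot: float = 40.0       # total calbindin-D28k concentration
    # Calbindin carries four high-affinity sites treated as one effective,
    # non-cooperative site; the model therefore quadruples the concentration.
    calbindin_sites: float = 4.0

    # ---- diffusion (µm²/s) and reaction ------------------------------------
    D_c: float = 220.0        # Ca²⁺ (cytosolic and ER lumen)
    D_p: float = 280.0        # IP₃
    D_b: float = 20.0         # calbindin
    kappa_b_minus: float = 19.0    # 1/s, calbindin unbinding
    kappa_b_plus: float = 27.0     # 1/(µM·s), calbindin binding
    kappa_p: float = 0.11          # 1/s, IP₃ decay rate
    p_r: float = 0.04              # µM, basal IP₃

    # ---- IP₃R channel -------------------------------------------------------
    d1: float = 0.13          # µM
    d2: float = 1.05          # µM
    d3: float = 0.94          # µM
    d5: float = 0.0823        # µM (82.3 nM)
    rho_I: float = 17.3       # µm⁻²
    I_I_ref: float = 1.1e-19  # mol/s reference single-channel current
    c_e_ref: float = 250.0    # µM reference ER concentration for the quasi-
    #                           linear current laws (equals c_e_eq)

    # ---- RyR channel --------------------------------------------------------
    k_a_minus: float = 28.8       # 1/s
    k_a_plus: float = 1500.0      # µM⁻⁴ s⁻¹
    k_b_minus: float = 385.9      # 1/s
    k_b_plus: float = 1500.0      # µM⁻³ s⁻¹
    k_c_minus: float = 0.1        # 1/s
    k_c_plus: float = 1.75        # 1/s
    rho_R: float = 3.0            # µm⁻²
    I_R_ref: float = 3.5e-18      # mol/s

    # ---- SERCA pumps --------------------------------------------------------
    I_S: float = 6.5e-21      # mol·µM/s
    K_S: float = 0.18         # µM (180 nM)
    rho_S: float = 2390.0     # µm⁻²

    # ---- PMCA pumps ---------------------------------------------------------
    I_P: float = 1.7e-23      # mol/s
    K_P: float = 0.06         # µM (60 nM)
    rho_P: float = 500.0      # µm⁻²

    # ---- NCX pumps ----------------------------------------------------------
    I_N: float = 2.5e-21      # mol/s
    K_N: float = 1.8          # µM
    rho_N: float = 15.0       # µm⁻²

    # ---- calcium / IP₃ release ---------------------------------------------
    j_c_rls_1ms: float = 1.0e-16    # mol s⁻¹ µm⁻², 1 ms linear pulse peak
    j_c_rls_10ms: float = 5.0e-17   # mol s⁻¹ µm⁻², 10 ms exponential peak
    tau_rls: float = 0.010          # s, exponential release time constant
    tau_NMDAR: float = 0.150        # s, NMDAR release decay
    p_NMDAR: float = 8.15e-3        # µm³/s, GHK permeability
    V_tilde: float = 13.4           # mV
    V_m: float = -70.0              # mV, constant membrane potential
    # ρ_NMDAR · p°_max; by default calibrated at run time to 1/synapse_area
    # ("at most one open channel in the spine"); None = auto-calibrate.
    rho_p_max_product: float | None = None
    j_p_rls: float = 5.0e-18        # mol s⁻¹ µm⁻², IP₃ production peak
    ip3_release_duration: float = 0.200  # s, linear IP₃ ramp duration

    # ---- leakage (computed by calibrate_leakage; µm/s) ----------------------
    v_le: float | None = None
    v_lp: float | None = None

    # ---- mechanism composition ---------------------------------------------
    composition: MembraneComposition = field(default_factory=MembraneComposition)

    @property
    def b_sites(self) -> float:
        """Effective calbindin binding-site concentration (µM)."""
        return self.b_tot * self.calbindin_sites

    def with_(self, **kwargs) -> "ModelConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["composition"] = {
            "erm_spine": list(self.composition.erm_spine),
            "erm_dendrite": list(self.composition.erm_dendrite),
            "pm": list(self.composition.pm),
        }
        return d
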