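# spinecalc

Spatial calcium signaling in dendritic spines with endoplasmic reticulum
(ER): a parametric spine/dendrite/ER geometry generator coupled to a
conservative finite-volume reaction–diffusion solver, built to ask how the
*position and shape of the spine ER* control whether a synaptic Ca²⁺
signal stays confined to the spine head or is amplified into the dendrite
(calcium-induced calcium release, CICR).

It is aimed at computational neuroscientists studying synaptic plasticity
and ER/spine-apparatus function who want a desk-scale, fully scripted
alternative to 3D tetrahedral simulations: every experiment here runs in
seconds to minutes on one core, deterministically.

## Model

Four fields on a branched axisymmetric control-volume grid — cytosolic
Ca²⁺ (c_c), ER Ca²⁺ (c_e), free calbindin-D28k (b), IP₃ (p):

    ∂c_c/∂t = D_c Δc_c + κ⁻(bᵗᵒᵗ − b) − κ⁺ b c_c
    ∂b/∂t   = D_b Δb   + κ⁻(bᵗᵒᵗ − b) − κ⁺ b c_c
    ∂p/∂t   = D_p Δp   − κ_p (p − pʳ)
    ∂c_e/∂t = D_c Δc_e

with membrane fluxes as boundary conditions:

    ER membrane:     j_ERM = j_IP3R + j_RyR − j_SERCA + v_le (c_e − c_c)
    plasma membrane: j_PM  = −j_PMCA − j_NCX + v_lp (c_o − c_c)
    synapse:         1 ms ramp, 10 ms exponential, or GHK-based NMDAR
                     release (τ = 150 ms, one open channel max)

IP₃R gating follows the De Young–Keizer-type joint Ca²⁺/IP₃ open
probability (cubed, bell-shaped in Ca²⁺); RyR follows a Keizer–Levine
four-state chain with c⁴/c³ activation and slow adaptation, advanced per
membrane patch; SERCA is Michaelis–Menten with store-saturation; PMCA and
NCX are second- and first-order Hill pumps. Both leak coefficients are
*calibrated* so all fluxes cancel exactly at the resting state (50 nM
cytosolic, 250 µM ER, 2 mM extracellular, 40 nM IP₃) — the resting state
is a machine-precision fixed point of the discrete system. Time stepping
is backward Euler with Newton linearization and sparse LU solves.

## Worked example

Calibrate the leaks and run the signature experiment — a 1 ms synaptic
release into a spine whose RyR-carrying ER reaches 1.5 µm up the spine
axis, versus the identical geometry with a passive (mechanism-free) ER:

```python
from spinecalc import (ModelConfig, ScenarioConfig, run_scenario,
                       amplification_metrics, calibrate_leakage)

cfg = ModelConfig()
v_le, v_lp = calibrate_leakage(cfg)
print(f"v_le = {v_le*1e3:.2f} nm/s, v_lp = {v_lp*1e3:.2f} nm/s")

active = run_scenario(ScenarioConfig(er_composition="RyR",
                                     spine_er_lengths=(1.5,)), cfg).runs[0]
passive = run_scenario(ScenarioConfig(er_composition="passive",
                                      spine_er_lengths=(1.5,)), cfg).runs[0]
m = amplification_metrics(active.result, passive.result)
print(f"neck peak: {active.peaks['neck']:.2f} µM (passive "
      f"{passive.peaks['neck']:.2f} µM, fold {m['neck_fold_change']:.1f})")
print(f"dendritic signal: {active.detected}, passive: {passive.detected}")
```

prints

    v_le = 37.86 nm/s, v_lp = 2.25 nm/s
    neck peak: 10.58 µM (passive 1.50 µM, fold 7.1)
    dendritic signal: True, passive: False

The calibrated ER leak (37.86 nm/s) balances SERCA uptake against the
resting IP₃R/RyR release. The RyR-carrying ER turns the sub-µM passive
neck transient into a sustained ~10 µM store-driven signal and pushes a
detectable Ca²⁺ signal into the dendrite; the passive ER — a pure
geometric obstacle — does not. Scanning the ER length shows the
all-or-nothing character of this switch:

    spinecalc scan --lengths 0.5:1.5:0.05

reports the critical transition length (0.65 µm under the default 1 ms
release): below it the dendrite stays silent, above it CICR ignites.
Other entry points: `spinecalc mesh` exports the labeled surface mesh
(VTK/OBJ), `spinecalc run` writes ROI traces + metrics + a checksummed
manifest, `spinecalc compensate` runs the head-growth compensation series, and
`spinecalc calibrate` / `spinecalc selftest` print the leak calibration
and run fast invariant checks. All commands accept a TOML/JSON `--config`
whose sections mirror the dataclasses (unknown keys are errors).

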