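# Methods

## The model

`spinecalc` simulates spatio-temporal Ca²⁺ signaling in a single dendritic
spine and the adjoining dendrite segment, with an endoplasmic-reticulum (ER)
tubule nested inside both. Four fields are evolved:

* `c_c` — cytosolic free Ca²⁺,
* `c_e` — ER-lumen Ca²⁺ (the store),
* `b` — free calbindin-D28k (mobile buffer),
* `p` — IP₃,

each by a diffusion equation (D_c = 220, D_b = 20, D_p = 280 µm²/s), with
mass-action calbindin buffering coupling `c_c` and `b`, first-order IP₃
decay toward its basal level (κ_p = 0.11 s⁻¹), and pure diffusion in the ER
lumen. All membrane transport enters through flux boundary conditions:

* **ER membrane**: j_ERM = j_IP3R + j_RyR − j_SERCA + j_leak,e
  - IP₃R: open probability is the cube of a joint Ca²⁺/IP₃ gating ratio
    with dissociation constants d₁, d₂, d₃, d₅ (bell-shaped in Ca²⁺);
    single-channel current is quasi-linear in the store gradient,
    I_ref·(c_e − c_c)/c_e_ref.
  - RyR: four-state gating chain (two closed, two open states) driven by
    c_c⁴ (activation) and c_c³ (second open state), plus a slow adaptation
    state; the same quasi-linear current law. Gated states are solved per
    membrane patch.
  - SERCA: Michaelis–Menten uptake in c_c with a 1/c_e store-saturation
    factor.
  - leak: v_le·(c_e − c_c).
* **Plasma membrane**: j_PM = −j_PMCA − j_NCX + j_leak,p, with a
  second-order Hill PMCA, first-order Hill NCX and leak v_lp·(c_o − c_c)
  at fixed extracellular c_o = 2 mM and membrane potential −70 mV.
* **Synapse**: a time-dependent influx on a spherical cap at the distal
  pole of the head — a 1 ms linear ramp (peak 1.0×10⁻¹⁶ mol s⁻¹µm⁻²), a
  10 ms exponential (peak 5.0×10⁻¹⁷), or an NMDAR-type 150 ms decay whose
  single-channel current follows the Goldman–Hodgkin–Katz law and whose
  density is calibrated so the expected maximum number of open channels on
  the patch is one. IP₃ production (for IP₃R scenarios) is a 200 ms linear
  ramp on the same patch.

**Leakage calibration.** Both leaks are solved from the zero-net-flux
condition at the resting state (c_c = 50 nM, c_e = 250 µM, p = 40 nM, all
gating at stationarity), making the resting state an exact fixed point.
The calibration is evaluated *per membrane composition*: an ER carrying
only RyR + SERCA gets the leak that balances those two, so every scenario
starts from a true equilibrium. With the full composition the ER leak
evaluates to 37.86 nm/s. The same balance on the plasma membrane gives
v_lp = 2.25 nm/s; we use the balance value (the calibration rule is what
guarantees stationarity), and note that it differs from the tabulated
4.5 nm/s by exactly a factor of two.

**Calbindin.** Calbindin-D28k carries four high-affinity sites; the model
treats them as one effective, non-cooperative site while quadrupling the
concentration, so the default 40 µM calbindin enters the kinetics as
160 µM of binding sites (κ⁺ = 27 µM⁻¹s⁻¹, κ⁻ = 19 s⁻¹, K_d ≈ 0.7 µM).
This choice is load-bearing: at 160 µM of sites the buffer capacity is
~130× at rest, the synaptic transit signal arriving at mid-neck is damped
to sub-µM levels, and RyR ignition becomes a genuine threshold phenomenon.
With only 40 µM of sites the transit reaches several µM everywhere in the
neck and RyR fires within a millisecond at any ER position — no
all-or-nothing behavior exists in that regime.

## Geometry

The morphology is parametric: a dendrite cylinder (radius 0.45 µm, length
10 µm) with a concentric ER tubule (0.11 µm / 8 µm), and a spine at the
dendrite midpoint — cylindrical neck (radius 0.08 µm, length 0.7 µm)
topped by a spherical head (radius 0.29 µm) whose center is placed so the
sphere meets the neck rim. A thin spine-ER tubule (radius 0.036–0.054 µm)
extends from the dendritic ER along the spine axis; **its length is
measured from the dendrite centerline**, so lengths below 0.45 µm describe
a stub that has not yet reached the neck entrance and the maximum
realizable extent with the default head is ≈ 1.72 µm. The tubule may end
in a spherical bulb inside the head (the "spine-within-spine"
morphology). Head growth is expressed as a volume factor; the radius
scales with its cube root. The synaptic patch is a 30° half-angle
spherical cap of the *unscaled* head (0.0708 µm²), kept constant under
head growth so that Ca²⁺ entry is unchanged by it.

Two discrete representations are produced:

* a labeled triangle/quad **surface mesh** (8 rim vertices by default,
  configurable), built by circle approximation, barrel extrusion, branch
  holes stitched by angular zipping, sphere projection for the head, and
  fan-closed caps — watertight per compartment and exported as OBJ or
  legacy-ASCII VTK with per-face subset labels. It serves visualization
  and geometric regression only.
* the **branched axisymmetric control-volume grid** the solver runs on: a
  1D skeleton (dendrite axis + spine axis) whose cells carry exact annular
  cross-section volumes, membrane patch areas and interface-area /
  center-distance coupling coefficients, all from closed forms. Grid sums
  reproduce the analytic measures to machine precision. The reduction is
  justified by the radii involved: with D_c = 220 µm²/s the radial
  equilibration time of the neck (0.08 µm) is well under 0.1 ms.

Default resolutions are h = 0.02 µm on the spine branch and 0.05 µm on the
dendrite, so ER-length scans in 0.05 µm steps land on cell boundaries.
The dendritic measurement window is 1 µm of dendrite centered on the spine
(configurable). The dendrite ends are sealed (no-flux).

## Numerics

Conservative finite volumes in space; backward Euler in time; Newton
linearization with an analytic Jacobian of all flux laws; sparse LU for
the linear sub-solves. Concentrations are carried in µM (1 µM ≡ 10⁻²¹
mol/µm³ exactly); membrane flux densities are mol s⁻¹ µm⁻². The membrane
coupling applies equal and opposite sources to the two sides of the ER
membrane, so total calcium (free + calbindin-bound + store) changes only
by the recorded plasma-membrane and synaptic exchange; the mass ledger
reproduces the change in total calcium to well below 0.1% of throughput.

RyR gating advances by one unconditionally stable implicit-Euler step per
time step (a linear 3×3 solve per patch, simplex-exact). By default the
gating is staggered — advanced once with beginning-of-step Ca²⁺ and frozen
during the Newton iteration — an O(Δt) splitting consistent with the
overall first-order scheme; a "within-newton" mode re-advances gating from
the current iterate in each Newton iteration and agrees with the staggered
mode to <2% at Δt = 10 µs.

Time steps: 20 µs from release onset to +10 ms, 100 µs thereafter, with
halve-and-retry (max 3 halvings) on Newton failure. Newton tolerances:
relative residual 10⁻⁶ with a small absolute floor; max 12 iterations. The
equilibrium state is an exact discrete fixed point (zero Newton iterations
when unperturbed). No positivity clipping is applied anywhere; positivity
is asserted by the test suite instead. Verified convergence: first order
in Δt on the full nonlinear scenario (Richardson ratios ≈ 2), second order
in h for pure diffusion against the sealed-interval heat-kernel solution,
and <0.5% agreement with an independent stiff-ODE integration when the
geometry is collapsed to two well-mixed compartments.

## Scenarios and metrics

Receptor compositions are scenario labels applied uniformly to the spine
and dendritic ER (per-subset overrides are available): *passive* disables
every ER mechanism ("a geometric obstacle"); *RyR*, *IP3R* and *RyR+IP3R*
always include SERCA and the composition-calibrated leak. The *none*
scenario removes the spine ER and keeps the default fully active dendritic
ER. IP₃ production accompanies Ca²⁺ release only in IP₃R-containing
scenarios.

A dendritic signal is *detected* when the peak window-averaged [Ca²⁺]
reaches 5× the 50 nM baseline; the onset is the first crossing of 2×
baseline. The 5× threshold is this package's own operationalization — it
sits far from both the near-baseline passive regime (≈0.052 µM) and the
store-driven regime (≥0.5 µM), and moving it between 3× and 10× does not
change any reported transition length by more than one 0.05 µm scan step.
Transition scans assert the all-or-nothing property (monotone indicator).
Amplification metrics: the neck fold-change is the ratio of peak neck
[Ca²⁺] between an active-ER run and the passive-ER run of identical
geometry; the dendrite transfer ratio divides the peak free cytosolic
Ca²⁺ amount above baseline in the dendritic window by the total released
amount from the ledger (a variant including calbindin-bound Ca²⁺ is also
reported, since the choice is a genuine ambiguity).

Run lengths: 250 ms for the 1 ms and 10 ms release profiles (dendritic
responses peak at 70–115 ms) and 500 ms for the NMDAR profile (≈3 release
time constants; near-threshold store ignition occurs at ≈220 ms).

## What the reduced geometry does and does not reproduce

All *model-level* quantities match their closed-form values to high
precision (channel open probabilities, flux densities, leak calibration),
and the *qualitative* scenario structure reproduces: passive ER transfers
<0.1% of the released Ca²⁺ to the dendrite regardless of position; RyR-ER
produces an all-or-nothing, strictly monotone transition in ER length;
IP₃R-only ER is much weaker than RyR-ER; combined RyR+IP₃R rescues
sub-critical ER positions with a delayed (>5 ms) dendritic signal; head
doubling halves the head peak, and among the compensation morphologies the
spine-within-spine ER ranks best in head-peak recovery.

Quantitatively, the axisymmetric reduction averages concentrations over
cross-sections, which makes the transit spike reaching the spine-ER
membrane hotter than the corresponding 3D near-membrane values and makes
dendritic store recruitment gradual rather than wave-like. The measured
consequences, under the default conditions: the 1 ms-pulse transition sits
at 0.65 µm rather than 0.8 µm; the NMDAR transition at 0.55–0.6 µm rather
than 0.45 µm; the store-release onset at the critical configuration is
1–2.4 ms rather than ≈8 ms; the neck fold-change is ≈7 rather than ≈20;
and the free-Ca²⁺ dendrite transfer ratio is far below the ≈2 obtained in
full 3D (the buffered variant overshoots it). These shifts are properties
of the reduced geometry, not tuning targets; the defaults were frozen
before the scenario outcomes were compared.

Passing tests therefore demonstrate correctness of the transport models,
the discretization and the conservation structure, and reproduction of the
study's qualitative phenomenology — not quantitative equivalence with
3D-resolved simulations, and not realism with respect to EM-reconstructed
morphologies, stochastic channel gating, store-operated entry or voltage
dynamics, all of which are out of scope.

## Degenerate inputs and edge cases

Zero spine-ER length is a valid configuration (no spine ER; identical grid
to the *none* scenario). A spine-ER length at or below the dendritic-ER
radius is rejected as not reaching past the dendritic ER surface (use 0
instead). An empty store (c_e = 0) is rejected by the SERCA law. RyR
gating at c_c = 0 returns the absorbing closed state. Resolutions coarser
than a compartment, ER wider than its host compartment, and ER extending
past the spine tip are validation errors listing every violated invariant.
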