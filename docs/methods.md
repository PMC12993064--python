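# Methods

## Model

`calspine` simulates the concentration of free Ca²⁺ in an unbranched
dendritic shaft and in the heads of spines attached to it, and the synaptic
weight changes that calcium drives.

**Dendrite.** The shaft is a cylinder of radius r_d = 1 μm discretized into
segments of length dx. Per segment, the calcium concentration C_d (μM)
obeys

    ∂C_d/∂t = D ∂²C_d/∂x² − J_ds + J_sd − C_d/τ_decay

with diffusion constant D = 220 μm²/s (free calcium) and a lumped leak
τ_decay = 80 ms that stands in for buffering and extrusion. Exchange terms
are active only at segments hosting a spine.

**Spine–dendrite exchange.** A spine is a sphere of radius r_s = 0.34 μm
coupled through a neck (length l_n = 0.5 μm, radius a_s = 0.1 μm). The
fluxes are first order, J_ds = k_d C_d and J_sd = k_s C_s, with rates given
by inverse mean first passage times through the neck:

    k_d = 4 D a_s / V_d,      k_s = 1 / ( V_s/(4 D a_s) + l_n²/(2D) )

where V_d = π r_d² dx and V_s = (4/3) π r_s³. At dx = 1 μm and default
parameters, k_d = 88/π ≈ 28.0 s⁻¹ and k_s ≈ 410 s⁻¹.

**Synaptic influx.** A presynaptic spike at time t_i injects a current
I(t) = I₀ e^{−(t−t_i)/τ_d} Θ(t−t_i) with I₀ = 0.1 pA, τ_d = 1 ms, of which
a fraction γ = 0.11 is carried by calcium:

    J_syn = γ I / (z F V_s),

z = 2, F = 96485 C/mol. In internal units (s, μm, μM) this is
346.2 μM/s per 0.1 pA; the single unit conversion lives in
`current_to_concentration_rate` and is tested against SI arithmetic.

**Plasticity.** Each spine's weight w ∈ [0,1] follows the two-threshold
calcium rule

    dw/dt = (1−w) γ_p Θ[C_s − θ_p] − w γ_d Θ[C_s − θ_d],    θ_d < θ_p,

so supra-θ_p calcium drives w toward γ_p/(γ_p+γ_d), the band (θ_d, θ_p]
gives pure exponential depression, and sub-θ_d calcium is silent.
Heavisides are strict (Θ(0)=0).

**Soma and voltage.** For sequence selectivity a passive compartmental
cable carries voltage (leak τ_m = 22 ms, electrotonic space constant λ,
sealed ends) driven at spine segments by the synaptic current waveform
scaled by the spine's weight; the soma is a leaky integrator coupled
one-way to the terminal compartment with R_soma/R_s,axial = 5,
u_rest = −70 mV, τ = 22 ms. There is no feedback from soma to dendrite and
no regenerative currents. The cable equation, gain and λ are not
constrained by the calcium model; their defaults (λ = 30 μm,
syn_amp = 1600 mV per unit weight per spike) were chosen so that
pre-learning responses stay below the nominal firing threshold (−54 mV).

## Numerics

* Backward (implicit) Euler for the coupled (C_d, C_s) vector: diffusion,
  leak and both exchange fluxes are implicit; the synaptic influx is
  evaluated at the step start, so the system matrix is constant and is
  LU-factorized once per run. The matrix is an M-matrix; concentrations
  remain non-negative at every step (roundoff-level negatives are clipped
  at zero).
* Defaults dx = 0.5 μm, dt = 0.05 ms; experiment drivers use dt = 0.1 ms
  (τ_d/10). dt must not exceed τ_d/5. Halving dt changes calcium peaks by
  well under 2% ; final weights are more sensitive (observed up to ~7e-3)
  because threshold-crossing times converge only at first order — a
  convergence test asserts both bounds.
* Boundary conditions are reflecting (no-flux) at both ends; the discrete
  operator conserves total calcium exactly when the leak is switched off.
* Weight updates use the exact one-step exponential solution of the linear
  weight ODE at the (piecewise-constant) end-of-step calcium, rather than a
  forward-Euler step. This is exact for piecewise-constant calcium, keeps
  w in [0,1] by construction, and matches the concatenated closed-form
  solution to machine precision; a guard still rejects
  dt (γ_p + γ_d) ≥ 1.
* Exchange fluxes enter both compartments with equal magnitude in
  concentration units, exactly as the model equations are written
  ("plain" flux mode, default). Because the compartment volumes differ,
  this bookkeeping does not conserve moles across the neck; an optional
  "volume-corrected" mode rescales transferred amounts by the volume ratio
  so that it does. The spine-side dynamics are essentially identical in
  both modes (the dendritic field rescales), so the default follows the
  printed equations.
* Mirror symmetry holds to LU roundoff (~1e-12), not bitwise, because
  pivoting order differs for the reflected matrix.

## Plasticity presets (calibrated)

Only the two-spine thresholds θ_d = 2·10⁻³ μM, θ_p = 4·10⁻³ μM are
literature-given. The rate constants, the multi-spine thresholds and the
stimulation frequencies are not published anywhere; they were calibrated
once against the qualitative sign patterns the model is meant to
reproduce, and are exposed as named presets:

| preset | θ_d (μM) | θ_p (μM) | γ_p (s⁻¹) | γ_d (s⁻¹) |
|---|---|---|---|---|
| fig2 | 2e-3 | 4e-3 | 16 | 8.25 |
| fig3 | 1.8e-2 | 3.0e-2 | 7.2 | 3.0 |
| fig4-grid | 2e-3 | 1.2e-2 | 16 | 8.25 |

Frequency presets (also calibrated): low = 0.5 Hz × 5 pulses,
medium = 45 Hz × 5 pulses, high = 50 Hz × 15 pulses. The driving
distinction is temporal summation against the ~30 ms decay of the cluster
calcium field: below ~25 Hz successive pulses do not overlap, so "medium"
must sit in the summation range and "high" is separated by train length
(sustained supra-θ_p exposure).

Two-spine demonstrations start from unequal initial weights (0.48, 0.30),
mirroring the randomly drawn initial weights of the multi-spine protocols;
the multi-spine generator draws weights uniformly from [0.3, 0.7].

## What the experiments show — and their honest limits

* **Competition / cooperation / timing reversal (two spines, 1 μm).**
  A single spike at spine 1 potentiates it (Δw ≈ +0.01 at the calibrated
  operating point) while its neighbour's calcium lands between the two
  thresholds and depresses (Δw ≈ −0.2). A 5-spike burst at 25 ms spacing
  lifts the neighbour's calcium above θ_p: both potentiate. Pairing the two
  spines 15 ms apart reverses the single-spike pattern to (−, +). At
  D = 220 μm²/s the two spines share one dendritic calcium field within
  ~2 ms, so their threshold exposures are nearly identical and the
  15 ms reversal is intrinsically weak: the margins on the small legs of
  these sign patterns are ≈ 0.008 in Δw, and the reversal grows an order
  of magnitude at inter-input lags of 60–100 ms. This is a property of the
  model equations at physiological D, not of the integrator.
* **Multi-spine frequency regimes.** With the fig3 preset at D = 220
  (5 random arrangements): medium-frequency trains potentiate the
  stimulated cluster while depressing its unstimulated neighbours
  (+, −, 0), and long high-frequency trains potentiate the whole cluster
  at the expense of outside spines (+, +, −). At D = 1 μm²/s all
  unstimulated groups are silent. One cell of the low-frequency pattern is
  not reproduced: stimulated spines potentiate (≈ +0.04) instead of
  depressing, because a stimulated spine's own influx transient always
  gives it a supra-θ_p exposure comparable to its depression-band exposure
  regardless of thresholds — any parameter choice that lets depression win
  at low frequency also silences the required potentiation elsewhere or
  depresses Un_in at low frequency. The matching-error ordering still
  holds (0.20 at D = 220 vs 0.29 at 440 and 0.44 at 1), i.e. the
  physiological diffusion constant remains the best fit.
* **Input-timing windows.** With the fig4-grid preset the heterosynaptic
  magnitude, measured as max |Δw − Δw_isolated| over the ±100 ms grid, is
  non-increasing across distances 1 → 2 → 3 μm (0.20, 0.19, 0.18). With
  the lower fig2 θ_p this monotonicity breaks (the 1 μm partner field
  crosses θ_p and potentiation offsets the deviation) — the window shape is
  threshold-dependent.
* **Sequence selectivity.** A passive cable always responds more strongly
  to the inward order (the distal EPSP is attenuated and broadened, so it
  sums better when it arrives first). After 5 presentations of either
  order with 100 ms inter-input interval, the later-activated spine ends
  relatively stronger, and the learned order then evokes the larger
  somatic response in the test phase (response ratio ≈ 1.01). Both
  weights decline during learning at this operating point, so the
  post-learning peaks sit below the passive ones and no somatic threshold
  crossing occurs; selectivity is expressed in the ratio, not in spiking.

## Problem sizes used by the test suite

The shipped experiments are scaled for interactive runs: 5 random
arrangements per condition (seeded, prefix-stable in the configuration
counter, so larger studies extend rather than replace them), diffusion grid
{1, 220, 440} μm²/s, 9-point timing grids, and dt = 0.1 ms in the drivers.
The full 20-configuration, 10-value diffusion grid is a parameter change
(`n_configs=20`, `D_list=...`), not a code change.

## Known limitations

* Single unbranched cable; no branching, no 3-D or radial diffusion.
* No calcium stores (ER/RyR/SOCE), no buffering kinetics beyond the lumped
  leak, no stochastic channel gating; influx uses one representative
  channel waveform.
* No back-propagating action potentials or dendritic spikes; the soma has
  no feedback to the dendrite.
* The synthetic arrangements place at most one spine per segment at
  segment centers; spines do not act as diffusion barriers.
* Plasticity is the memoryless two-threshold rule: no early/late phases,
  no tagging, no weight-dependence of calcium influx.
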