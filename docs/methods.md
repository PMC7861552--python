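# Methods

`mitoca` simulates a ventricular myocyte as a 3-D lattice of stochastic
Ca²⁺ release units (CRUs) coupled to a coarser lattice of mitochondria, with
whole-cell membrane voltage and slow ROS/CaMKII/ATP signaling. This note
documents the model, its assumptions, the numerical scheme, the calibration
of the default parameter set, and known limitations.

## Model structure

**Geometry.** CRUs form a regular `(nx, ny, nz)` grid with x-fastest linear
indexing; mitochondria form a coarser grid whose dimensions must divide the
CRU dimensions axis-wise. Each mitochondrion is coupled to the contiguous
block of CRUs it tiles (1×2×2 at full scale: 21504 CRUs, 5376 mitochondria).
Boundaries are no-flux. The default working lattice is a reduced 16×8×4 CRU
/ 16×4×2 mitochondrion grid: whole-cell statistics (transient shape, open
fractions, slow-variable trajectories) are insensitive to lattice size well
below full scale, while a 30-s paced run stays around one to two minutes on
one CPU core. Presets `full`, `medium`, `reduced`, `small` are provided.

**Membrane.** The voltage follows

    Cm dV/dt = ΣI − I_sti

with the stimulus amplitude −80 µA/cm² for 0.5 ms per pacing cycle. Note
the sign convention this equation fixes: the depolarizing stimulus is
negative, and depolarizing ionic currents are positive — the negative of
the common `Cm dV/dt = −ΣI` form. Internally currents are evaluated in the
standard outward-positive convention and negated at the interface. The current set contains I_Na,
I_Na,L, I_Ca,L, I_NCX, I_K1, I_Kr, I_Ks, I_to,f, I_to,s, I_NaK, I_K,ATP and
I_Ca,b. Gate formulations are reduced rabbit-type Hodgkin–Huxley forms
(Luo–Rudy fast Na⁺ and inward-rectifier kinetics; single-gate delayed
rectifiers and transient outward currents); quantitative AP morphology is a
calibration choice, not a constraint, and every conductance is a parameter.
Intracellular Na⁺ and K⁺ are fixed. I_K,ATP activates as cytosolic ATP
falls (half-activation 0.25 mM, Hill 2). The whole-cell L-type current and
exchanger current are obtained from the summed per-CRU Ca²⁺ fluxes through
a flux↔current conversion of 0.01 µM·ms⁻¹ per µA·cm⁻² (z = 2), i.e. the
surface-to-volume ratio of a T-tubulated myocyte.

**CRU calcium cycling.** Each CRU carries five compartments: dyadic cleft,
submembrane space, local cytosol, network SR and junctional SR, with
volumes relative to the local cytosol (v_sub 0.1, v_NSR 0.02, v_JSR 0.01).
The dyad is treated as quasi-static: the cleft concentration solves the
instantaneous balance between release/trigger influx and efflux to the
submembrane space, `c_p = (c_s + A·(g_rel·p_o·c_JSR + J_LCC)) / (1 +
A·g_rel·p_o)` with gain A = 400 µM/(µM/ms). RyR clusters (100 channels per
CRU) open with the rate

    k12 = k_base·k_u·(1 + Δk_CaMKII + Δk_ROS)·[Ca²⁺]_p²

where the CaMKII and ROS increments are saturating Hill functions. Open
channels close at 0.1 ms⁻¹ into a refractory state that recovers at
1.5×10⁻³ ms⁻¹ (~670 ms), giving release restitution; see Design decisions.
Release flux is proportional to the open fraction and the JSR–dyad
gradient. SERCA uptake follows

    J_up = v_up·f_ATP·f_ROS·c² / (c² + (K_i − PLB(a))²)

with the ADP/ATP factor of the Cortassa-type pump law, the redox factor
falling from 1 to 0.75 with ROS, and a phospholamban term that lowers the
half-maximal Ca²⁺ as CaMKII activation rises (Hill form, max reduction
0.25 µM at half-point 0.15). NSR→JSR refill, an NSR leak, submembrane↔
cytosol transfer, nearest-neighbor cytosolic and NSR diffusion, forward-mode
Na⁺/Ca²⁺ exchange, background Ca²⁺ influx, and instantaneous (rapid-buffer)
approximations for cytosolic, submembrane, and calsequestrin buffering
complete the Ca²⁺ bookkeeping. All updates are written as shared fluxes so
a closed cell conserves total (free + buffered) Ca²⁺ to Euler accuracy.

**Mitochondria.** Each mitochondrion exchanges Ca²⁺ with its block of CRUs:
uniporter influx (scaled by α_MCU and a Δψ driving factor), Na⁺/Ca²⁺
exchanger efflux, and — while the permeability transition pore is open — a
conductive efflux toward the local cytosolic level. The mPTP is a 3-state
Markov chain C₀ ↔ C₁ ↔ O. The Ca²⁺-dependent activation step is

    k_c0c1 = α₀·(1 + 199·ca^h/(ca^h + ca₀^h)),

other rates are constant, and the C₁→O rate is α_mPTP·k_c1o0. The exact
stationary open probability of this chain,

    P_O = k01·k1o / (k01·k1o + k01·ko1 + k10·ko1),

is implemented as the exact stationary distribution of the declared chain;
it satisfies P→0 as α_mPTP→0 and P→1 as α_mPTP→∞, and the unit tests verify
it against the numerically solved stationary vector of the generator over a
broad rate grid. Δψ, ROS emission, and ATP production are two-level
relaxation processes: an open pore drives Δψ toward a depolarized level
(τ 50 ms) and a closed pore lets it recover (τ 120 ms); ROS emission
interpolates linearly in Δψ between a polarized baseline and an elevated
depolarized rate; a mitochondrion produces ATP when its pore is shut and Δψ
has recovered at least a quarter of the way to the polarized level. This
deliberately treats mitochondria as switched ROS/ATP sources rather than as
full metabolic-flux models, and pore opening is mitochondrial-Ca²⁺-dependent
only (no ROS-induced ROS release).

**Slow signaling.** Cytosolic ROS is a per-CRU field with local
mitochondrial emission, first-order scavenging (baseline 0.1 µM with all
mitochondria polarized), and nearest-neighbor diffusion. CaMKII activation
is a whole-cell fraction obeying autocatalytic (logistic) growth toward a
drive-dependent ceiling,

    dA/dt = g·A·(1 − A/A_∞(ROS, Ca)),

a reduced account of oxidized-CaMKII kinetics in which active kinase
promotes further activation: growth away from the 0.4% resting floor is
slow on the half-minute scale while the quasi-steady level under sustained
oxidative drive is large. ATP relaxes (τ = 300 s) toward a level set by
the fraction of ATP-producing mitochondria, `ATP_∞ = ATP_rest·frac^2.45`,
with ADP mirroring ATP against a fixed adenine pool. A fast-forward mode
(`mitoca.signaling.fast_forward_slow`) integrates only these two slow
variables against frozen time-averaged drives of the fast subsystem,
making 1000-s horizons immediate.

**Clamps.** Any of ROS, CaMKII activation, ATP, mitochondrial Ca²⁺,
cytosolic Ca²⁺ can be clamped to a fixed value from a start time onward
(the variable is overwritten after every step wherever it is read), and all
pores can be commanded closed. These implement the mechanism-dissection
protocols: clamped-ROS, clamped-CaMKII, clamped-ATP, clamped-Ca, and
pore-block experiments, plus the redox-arm switches Δk_ROS,max = 0 (RyR arm
off) and f_up,ROS ≡ 1 (SERCA arm off).

## Numerics

Explicit Euler for all continuous variables with a globally adaptive step:
0.001 ms while |dV/dt| > 5 mV/ms (the AP upstroke), 0.01 ms otherwise.
Stochastic channels (LCC, RyR, mPTP) take per-step binomial transition
counts with exact exponential probabilities `1 − exp(−rate·dt)`, sampled by
single-uniform CDF inversion. Every uniform comes from a counter-based
splitmix64 stream hashed from (master seed, step index, lattice site,
transition type), so trajectories are bit-reproducible for a seed,
independent of iteration order, and resumable from snapshots; snapshots
round-trip bit-exactly through `.npz` files. The dyadic gain and RyR rate
cap (k12 ≤ 30 ms⁻¹) keep per-channel per-step probabilities well below 1;
API-level stepping functions additionally reject probabilities above 0.5.
Degenerate inputs: zero dyadic or cytosolic Ca²⁺ give zero rates/fluxes;
Hill functions are written in the `x^h/(x^h+K^h)` form so the x→0 limits
are exact; concentrations are floored at zero after each step (sub-10⁻⁹
excursions only); non-finite V or Ca²⁺ aborts the run with a diagnostic.

## Calibration

The defaults target a reduced-lattice operating point and were frozen after
calibration; the `mitoca calibrate` command re-measures the anchors.

- **AP and Ca²⁺ transient (control, PCL 500 ms):** resting potential
  ≈ −87 mV, APD90 ≈ 250 ms, diastolic Ca²⁺ ≈ 0.2 µM, transient peak
  ≈ 0.6 µM, SR load stable, 1:1 capture from PCL 300–600 ms.
- **mPTP:** α₀, ca₀ and the constant rates are set so the paced control
  (α_mPTP = 1) open fraction is < 1% while α_mPTP = 60 yields ≈ 30% — the
  study's depolarized condition. The closed-form stationary law evaluated
  at the time-averaged mitochondrial Ca²⁺ reproduces the measured open
  fraction within Monte-Carlo/coupling error.
- **ROS:** emission rates and scavenging give a 0.1 µM polarized baseline
  and ≈ 0.75 µM whole-cell ROS at 30% open fraction.
- **CaMKII:** the logistic growth rate (3.9×10⁻⁵ ms⁻¹) and the ROS-drive
  Hill curve (half-max 0.44 µM, exponent 3.4) place activation at ≈ 1.2%
  after 30 s of depolarized pacing and ≈ 74% at the 1000-s quasi-steady
  state, stable across seeds.
- **ATP:** τ = 300 s and the production exponent give a small (<5%) decline
  over 30 s at 30% depolarization and ≈ 2 mM at 1000 s.

## Design decisions

- **RyR cluster topology.** The closed→open rate is the k12 law above; the
  cluster is a 3-state chain (closed → open → closed-refractory → closed)
  rather than the minimal 2-state cluster. The refractory state implements
  release restitution with a recovery time constant (~670 ms) — without it
  the beat-to-beat SR release map is dead-beat stable (release always drains
  to a k12-determined floor, erasing beat-to-beat memory), and no pacing
  rate produces Ca²⁺ alternans. Setting the recovery rate to infinity (or
  `k_recover=None` in the API) recovers the 2-state limit, which the
  stationary-occupancy unit tests use. Luminal (calsequestrin-mediated)
  RyR regulation is deliberately not modeled; the JSR→dyad gradient is the
  only luminal influence on gating.
- **Quasi-static dyad.** The dyadic volume is far smaller than its exchange
  fluxes, so the cleft concentration is solved algebraically instead of
  integrated; this removes the stiffest time scale from the system.
- **Whole-cell scalars.** CaMKII and ATP are whole-cell scalars; ROS is
  per-CRU. Clamps act on the variable wherever it is read, so clamping ROS
  also clamps the oxidized CaMKII drive.
- **Voltage-gate memory.** The L-type voltage-inactivation gate recovers
  slowly at rest (τ 350 ms) and inactivates on a 70-ms scale during the
  plateau, giving beat-to-beat trigger restitution.
- **Seeding.** One logical stream per lattice site via counter-based
  hashing (no stored RNG state), which makes scan points and restarts
  order-independent.
- **Adaptation scope.** The upstroke criterion switches the global step for
  the whole lattice, not per site.

## Known limitations

- **Whole-cell Ca²⁺ alternans.** Under the frozen calibration the model
  does *not* develop macroscopic Ca²⁺ alternans at any tested pacing rate
  (300–600 ms) in either the control or the depolarized condition, so the
  alternans-amplitude and alternans-onset anchors and the directional
  mechanism studies that presuppose alternans are not reproduced.
  Individual CRUs do alternate: the lag-1 autocorrelation of per-CRU
  beat-wise release is ≈ −0.33 under depolarized pacing, i.e. subcellular
  period-2 release is present, but the phases remain spatially incoherent
  and cancel in the whole-cell average. In the source lineage of such
  models the synchronizing steepness comes from calsequestrin-mediated
  luminal RyR gating, which is intentionally outside this model's scope;
  the JSR-gradient ignition steepness plus time-based restitution
  implemented here leaves the whole-cell loop gain just below the
  period-doubling threshold (~0.9 by perturbation-ring measurement).
  The analysis machinery (beat-wise peak detection, bifurcation curves,
  onset extraction, scans) is fully implemented and exercised against
  synthetic traces.
- Mitochondrial depolarization waves, ROS-induced ROS release, mBK/mKATP
  channels, fission/fusion, and T-tubule heterogeneity are not modeled.
- The AP current set is a reduced rabbit-type formulation; it reproduces
  gross AP morphology, not any specific experimental recording.
- The synthetic stimulus/lattice data the tests run on emulate paced
  steady-state behavior of a homogeneous cell; passing tests say nothing
  about heterogeneous or diseased myocytes beyond the modeled mechanisms.
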