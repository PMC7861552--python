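# mitoca

A stochastic, spatially resolved ventricular myocyte model for studying how
mitochondrial depolarization reshapes intracellular Ca²⁺ cycling.

Cardiac Ca²⁺ alternans — beat-to-beat large–small alternation of the Ca²⁺
transient — is a precursor of lethal arrhythmias and is promoted by
metabolic stress. `mitoca` is built for computational cardiologists who
want to dissect that coupling mechanistically: it represents a myocyte as a
3-D lattice of Ca²⁺ release units (stochastic RyR clusters with local SR
compartments and L-type channel clusters) coupled to a lattice of
mitochondria that exchange Ca²⁺ (MCU, mNCX), carry a Ca²⁺-dependent 3-state
permeability transition pore (mPTP), and act as switched ROS and ATP
sources, plus slow oxidized-CaMKII and ATP signaling that feeds back on the
RyRs and the SERCA pump.

The core relations:

- RyR opening: `k12 = k_base·k_u·(1 + Δk_CaMKII + Δk_ROS)·[Ca²⁺]_p²`
- SERCA uptake: `J_up = v_up·f_ATP·f_ROS·c²/(c² + (K_i − PLB(a))²)`
- mPTP activation: `k_C0→C1 = α₀·(1 + 199·ca^h/(ca^h + ca₀^h))`, with the
  C₁→O rate scaled by the pre-factor `α_mPTP`; the stationary open
  probability `P_O = k01·k1o/(k01·k1o + k01·ko1 + k10·ko1)` is ~0 for
  `α_mPTP = 1` and ≈ 30% under pacing for `α_mPTP = 60`.

Membrane voltage follows `Cm dV/dt = ΣI − I_sti` over a configurable
rabbit-type current set, paced by a −80 µA/cm², 0.5-ms stimulus. The
numerical engine (explicit Euler with an adaptive upstroke step, per-step
binomial channel sampling, counter-based seeding) is compiled with numba
and fully reproducible by seed. See `docs/methods.md` for the complete
model description and calibration.

## A worked example

Pace the reduced lattice (16×8×4 CRUs, 16×4×2 mitochondria) for 30 s under
mitochondrial depolarization (`α_mPTP = 60`) and read out the study's
headline quantities:

```python
from mitoca import Protocol, SimConfig, run_simulation
from mitoca.protocols import measure_mptp_open_fraction
from mitoca.calibration import fast_forward_from_run

traj, snap = run_simulation(
    SimConfig(duration=30_000.0, seed=1),          # 30 s, fixed seed
    Protocol(pcl=500.0, alpha_mptp=60.0),          # PCL 500 ms, depolarized
    preset="reduced",
)
print(f"mPTP open fraction : {measure_mptp_open_fraction(traj, 2000.0):.3f}")
print(f"CaMKII at 30 s     : {traj['camkii'].iloc[-1] * 100:.2f} %")
print(f"cytosolic ROS      : {traj['ros'].iloc[-1]:.2f} uM")

ff = fast_forward_from_run(traj, t_end_ms=1e6)     # slow variables to 1000 s
print(f"CaMKII at 1000 s   : {ff['camkii'] * 100:.1f} %")
print(f"ATP at 1000 s      : {ff['atp']:.2f} mM")
```

Output (seed 1):

```
mPTP open fraction : 0.310
CaMKII at 30 s     : 1.26 %
cytosolic ROS      : 0.80 uM
CaMKII at 1000 s   : 74.4 %
ATP at 1000 s      : 2.02 mM
```

Meaning: with the pore's closed→open rate raised 60-fold, about 30% of the
pores are open at any instant, which elevates cytosolic ROS roughly
eight-fold over its 0.1 µM baseline. The slow variables barely move within
the 30-s acute window (CaMKII 0.4% → 1.3%) but differ drastically at their
1000-s quasi-steady state (CaMKII ≈ 74%, ATP fallen from 5 to ≈ 2 mM) —
the time-scale separation that justifies treating them as quasi-steady in
half-minute studies.

The trace table also carries V, whole-cell Ca²⁺ (cytosolic, JSR, NSR,
mitochondrial), uptake/release fluxes, Δψ, and the pore open fraction;
`mitoca.protocols` supplies beat-wise transient-peak analysis
(`alternans_amplitude`), bifurcation curves, onset extraction, and
parameter scans. `examples/` contains one short narrative script per
capability. A thin CLI (`mitoca run|scan|calibrate|report`) wraps the same
functions for shell use with YAML configuration files.

## Caveat

Under the frozen reduced-lattice calibration the model exhibits subcellular
(per-CRU) period-2 release but does not synchronize it into whole-cell Ca²⁺
alternans; see "Known limitations" in `docs/methods.md` before using it to
study macroscopic alternans amplitudes.
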