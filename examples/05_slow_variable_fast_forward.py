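"""Fast-forward the slow variables (CaMKII, ATP) to the 1000-s horizon.

CaMKII activation and ATP evolve orders of magnitude slower than Ca2+
cycling. The fast-forward mode freezes the fast subsystem at its paced
periodic steady state (summarized by time-averaged ROS, Ca2+, and the
ATP-producing mitochondrial fraction) and integrates only the slow ODEs.
"""

from mitoca import Protocol, SimConfig, run_simulation
from mitoca.calibration import fast_forward_from_run, slow_drives_of

traj, _ = run_simulation(
    SimConfig(duration=8000.0, seed=1),
    Protocol(pcl=500.0, alpha_mptp=60.0),
    preset="small",
)
drives = slow_drives_of(traj, window=3000.0)
print(f"drives from the paced run: ROS {drives['ros']:.2f} uM, "
      f"Ca2+ {drives['ca']:.2f} uM, producing fraction {drives['frac_producing']:.2f}")

for t_s in (30, 100, 300, 1000):
    ff = fast_forward_from_run(traj, t_end_ms=t_s * 1000.0)
    print(f"  t = {t_s:5d} s: CaMKII {ff['camkii'] * 100:5.1f} %   ATP {ff['atp']:.2f} mM")

print("\nOn the half-minute scale both variables are quasi-steady.  This "
      "demo samples the drives after only 8 s on a small lattice, before "
      "mitochondrial Ca2+ and ROS finish loading, so the forecast "
      "underestimates the chronic levels; the full 30-s reduced-lattice "
      "protocol (scripts/acceptance.py) reaches ~74% CaMKII and ~2 mM ATP.")
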