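"""Pace a small myocyte lattice under control and depolarized conditions.

Runs 5 s at PCL 500 ms on the 8x4x2 preset and compares the whole-cell
state: with alpha_mPTP = 60 the permeability transition pore opens often,
collapsing Delta-psi in part of the population and raising cytosolic ROS.
"""

from mitoca import Protocol, SimConfig, run_simulation

for label, alpha in (("control (alpha_mPTP=1)", 1.0), ("depolarized (alpha_mPTP=60)", 60.0)):
    traj, _ = run_simulation(
        SimConfig(duration=5000.0, seed=1),
        Protocol(pcl=500.0, alpha_mptp=alpha),
        preset="small",
    )
    last = traj[traj.t > 4000.0]
    print(f"{label}:")
    print(f"  Ca2+ transient peak   {last.ca_i.max():6.3f} uM   "
          f"diastolic {last.ca_i.min():.3f} uM")
    print(f"  mPTP open fraction    {last.mptp_open.mean():6.3f}")
    print(f"  mean Delta-psi        {last.dpsi.mean():6.1f} mV (polarized = 180)")
    print(f"  cytosolic ROS         {last.ros.iloc[-1]:6.3f} uM (baseline 0.1)")

print("\nThe pore pre-factor turns mitochondria from quiet Ca2+ sinks into "
      "ROS sources without touching any other parameter.")
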