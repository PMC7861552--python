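"""Clamp protocols: fix a signaling variable, or command every pore shut.

Mid-run interventions are first-class: here the depolarized cell has all
its mPTPs commanded closed at t = 3 s, which lets Delta-psi recover and
returns ROS to baseline.
"""

from mitoca import ClampSpec, Protocol, SimConfig, run_simulation

proto = Protocol(
    pcl=500.0,
    alpha_mptp=60.0,
    clamps=[ClampSpec("mptp_closed", start_time=3000.0)],
)
traj, _ = run_simulation(SimConfig(duration=6000.0, seed=2), proto, preset="small")

for t0, t1, label in [(2000, 3000, "before block"), (5000, 6000, "after block")]:
    w = traj[(traj.t >= t0) & (traj.t < t1)]
    print(f"{label}: open fraction {w.mptp_open.mean():.3f}  "
          f"Delta-psi {w.dpsi.mean():6.1f} mV  ROS {w.ros.iloc[-1]:.3f} uM")

# a ROS clamp pins the field exactly, everywhere it is read
proto2 = Protocol(pcl=500.0, alpha_mptp=60.0, clamps=[ClampSpec("ros_cyt", 0.1)])
traj2, _ = run_simulation(SimConfig(duration=2000.0, seed=2), proto2, preset="small")
print(f"\nwith ROS clamped to 0.1 uM: measured ROS = {traj2.ros.iloc[-1]:.3f} uM "
      "(redox drive on RyR, SERCA, and CaMKII all see the clamped value)")
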