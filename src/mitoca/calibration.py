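"""Calibration anchors: paced-run measurements against the model's frozen
operating points.

The reduced-lattice defaults in :mod:`mitoca.params` were calibrated against
a small set of anchors -- whole-cell mPTP open fraction ~30% under the
depolarized condition (alpha_mPTP = 60, PCL 500 ms), CaMKII activation
~1.2% after 30 s of depolarized pacing, and quasi-steady CaMKII ~74% and
cytosolic ATP ~2 mM at 1000 s -- and then frozen.  ``evaluate_anchors``
recomputes them from scratch so a user can verify the calibration on their
own hardware; it is what the ``mitoca calibrate`` CLI command runs.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .engine import Protocol, SimConfig, run_simulation
from .params import CellParams
from .protocols import alternans_amplitude, measure_mptp_open_fraction
from .signaling import fast_forward_slow

__all__ = [
    "paced_run",
    "slow_drives_of",
    "fast_forward_from_run",
    "evaluate_anchors",
]


def paced_run(
    alpha_mptp: float = 1.0,
    pcl: float = 500.0,
    duration: float = 30000.0,
    seed: int = 1,
    preset: str = "reduced",
    params: CellParams | None = None,
    protocol: Protocol | None = None,
) -> pd.DataFrame:
    """Free-running paced simulation from the resting state; returns the
    whole-cell trace table."""
    proto = protocol or Protocol(pcl=pcl, alpha_mptp=alpha_mptp)
    cfg = SimConfig(duration=duration, seed=seed)
    traj, _ = run_simulation(cfg, proto, params=params, preset=preset)
    return traj


def slow_drives_of(traj: pd.DataFrame, window: float = 10000.0) -> dict:
    """Time-averaged drives of the slow subsystem over the terminal window:
    cytosolic ROS and Ca2+ and the ATP-producing mitochondrial fraction."""
    tt = traj["t"].to_numpy()
    m = tt >= tt[-1] - window
    return {
        "ros": float(traj["ros"].to_numpy()[m].mean()),
        "ca": float(traj["ca_i"].to_numpy()[m].mean()),
        "frac_producing": float(traj["frac_producing"].to_numpy()[m].mean()),
    }


def fast_forward_from_run(
    traj: pd.DataFrame,
    params: CellParams | None = None,
    t_end_ms: float = 1.0e6,
) -> dict:
    """Slow-variable fast-forward: freeze the fast subsystem at its paced
    periodic steady state (summarized by the terminal drives of ``traj``)
    and integrate CaMKII and ATP from their resting values to ``t_end_ms``.

    Returns the final CaMKII activation fraction and ATP (mM).
    """
    p = (params or CellParams()).signaling
    drives = slow_drives_of(traj)
    _, camk, atp = fast_forward_slow(
        p, drives["ros"], drives["ca"], drives["frac_producing"], t_end_ms
    )
    return {"camkii": float(camk[-1]), "atp": float(atp[-1]), **drives}


def evaluate_anchors(seed: int = 1, quick: bool = True,
                     params: CellParams | None = None) -> dict:
    """Recompute the calibration anchors on the reduced lattice.

    Always computed: terminal mPTP open fraction and 30-s CaMKII under
    alpha_mPTP = 60 at PCL 500 ms; the 1000-s fast-forward CaMKII and ATP;
    the last-two-peak Ca2+ alternans amplitude for the same run; the control
    open fraction.  With ``quick=False`` a control 30-s run is added.
    """
    out: dict = {}
    traj = paced_run(alpha_mptp=60.0, seed=seed, params=params)
    out["mptp_open_fraction_alpha60"] = measure_mptp_open_fraction(traj, 2000.0)
    out["camkii_30s_percent"] = float(traj["camkii"].iloc[-1]) * 100.0
    ff = fast_forward_from_run(traj, params=params, t_end_ms=1.0e6)
    out["camkii_1000s_percent"] = ff["camkii"] * 100.0
    out["atp_1000s_mM"] = ff["atp"]
    out["ros_alpha60_uM"] = ff["ros"]
    res = alternans_amplitude(traj, 500.0)
    out["alternans_amplitude_alpha60_uM"] = res.amplitude
    if not quick:
        ctrl = paced_run(alpha_mptp=1.0, seed=seed, params=params)
        out["mptp_open_fraction_control"] = measure_mptp_open_fraction(ctrl, 2000.0)
        out["alternans_amplitude_control_uM"] = alternans_amplitude(ctrl, 500.0).amplitude
        out["camkii_30s_control_percent"] = float(ctrl["camkii"].iloc[-1]) * 100.0
    return out
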