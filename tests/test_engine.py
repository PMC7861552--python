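import numpy as np
import pandas as pd
import pytest

from mitoca import CellParams, ClampSpec, Protocol, SimConfig, run_simulation
from mitoca.calcium import total_calcium
from mitoca.engine import Snapshot, _state_from_snapshot, init_state
from mitoca.params import ConfigError

# a closed cell: no sarcolemmal Ca fluxes, no pacing, no mito exchange
CLOSED_CELL = {
    "membrane.g_cab": 0.0,
    "membrane.v_ncx": 0.0,
    "lcc.r_open": 0.0,
    "mito.v_mcu": 0.0,
    "mito.v_mncx": 0.0,
    "mito.g_ptp_rel": 0.0,
}


def test_equal_seeds_bit_identical():
    cfg = SimConfig(duration=600.0, seed=123)
    proto = Protocol(pcl=300.0)
    t1, s1 = run_simulation(cfg, proto, preset="small")
    t2, s2 = run_simulation(cfg, proto, preset="small")
    pd.testing.assert_frame_equal(t1, t2)
    assert np.array_equal(s1.ci, s2.ci)
    assert np.array_equal(s1.nryr, s2.nryr)
    t3, _ = run_simulation(SimConfig(duration=600.0, seed=124), proto, preset="small")
    assert not np.allclose(t1["ca_i"], t3["ca_i"])


def test_snapshot_roundtrip_resumes_identically(tmp_path):
    cfg_a = SimConfig(duration=400.0, seed=5)
    proto = Protocol(pcl=200.0)
    params = CellParams()
    # uninterrupted 800 ms
    full, _ = run_simulation(SimConfig(duration=800.0, seed=5), proto,
                             params=params, preset="small")
    # interrupted at 400 ms with a disk round trip
    _, snap = run_simulation(cfg_a, proto, params=params, preset="small")
    path = tmp_path / "state.npz"
    snap.save(path)
    snap2 = Snapshot.load(path)
    assert np.array_equal(snap.scalars, snap2.scalars)
    rest, _ = run_simulation(cfg_a, proto, initial=snap2, params=params,
                             preset="small")
    # align on the first sample after the resume point (the uninterrupted run
    # also records the boundary-crossing sample itself)
    tail = full[full.t >= rest["t"].iloc[0] - 1e-3].reset_index(drop=True)
    n = min(len(rest), len(tail))
    np.testing.assert_allclose(rest["ca_i"].to_numpy()[:n],
                               tail["ca_i"].to_numpy()[:n], rtol=0, atol=0)
    np.testing.assert_allclose(rest["v"].to_numpy()[:n],
                               tail["v"].to_numpy()[:n], rtol=0, atol=0)


def test_zero_duration_returns_empty_trajectory():
    traj, snap = run_simulation(SimConfig(duration=0.0, seed=1),
                                Protocol(), preset="small")
    assert len(traj) == 0
    st = init_state(CellParams(), preset="small")
    assert np.allclose(snap.ci, st.cru.ca_cyt)


def test_one_transient_per_stimulus():
    pcl = 400.0
    traj, _ = run_simulation(SimConfig(duration=10 * pcl, seed=2),
                             Protocol(pcl=pcl), preset="small")
    n_up = 0
    for k in range(10):
        b = traj[(traj.t >= k * pcl) & (traj.t < (k + 1) * pcl)]
        if b.v.max() > 0:
            n_up += 1
    assert n_up == 10  # 1:1 capture


def test_closed_cell_calcium_conservation():
    """With sarcolemmal and mitochondrial pathways off, total buffered Ca2+
    drifts by less than 0.1% over 1e5 steps."""
    params = CellParams().with_overrides(CLOSED_CELL)
    proto = Protocol(pacing=False)
    comp = params.compartments

    def cell_total(snap):
        return float(np.sum(
            total_calcium(snap.ci, comp.buf_cyt_b, comp.buf_cyt_k)
            + comp.v_sub * total_calcium(snap.cs, comp.buf_sub_b, comp.buf_sub_k)
            + comp.v_nsr * snap.cnsr
            + comp.v_jsr * total_calcium(snap.cjsr, comp.buf_jsr_b, comp.buf_jsr_k)
        ))

    _, snap0 = run_simulation(SimConfig(duration=0.0, seed=6), proto,
                              params=params, preset="small")
    _, snap = run_simulation(SimConfig(duration=1000.0, seed=6), proto,
                             params=params, preset="small")  # 1e5 steps at dt 0.01
    drift = abs(cell_total(snap) - cell_total(snap0)) / cell_total(snap0)
    assert drift < 1e-3


def test_halving_dt_changes_peak_by_less_than_one_percent():
    peaks = []
    for dtn in (0.01, 0.005):
        traj, _ = run_simulation(
            SimConfig(duration=1000.0, seed=4, dt_normal=dtn),
            Protocol(pcl=500.0), preset="small",
        )
        peaks.append(float(traj["ca_i"].max()))
    assert abs(peaks[0] - peaks[1]) / peaks[1] < 0.01


def test_empty_clamp_list_identical_to_unclamped():
    cfg = SimConfig(duration=500.0, seed=9)
    a, _ = run_simulation(cfg, Protocol(pcl=250.0, clamps=[]), preset="small")
    b, _ = run_simulation(cfg, Protocol(pcl=250.0), preset="small")
    pd.testing.assert_frame_equal(a, b)


def test_ros_clamp_is_exact_after_start():
    clamp = ClampSpec("ros_cyt", 0.1, start_time=100.0)
    traj, _ = run_simulation(SimConfig(duration=600.0, seed=3),
                             Protocol(pcl=300.0, clamps=[clamp]), preset="small")
    after = traj[traj.t > 101.0]
    assert np.allclose(after["ros"], 0.1, atol=1e-12)


def test_conflicting_clamps_rejected():
    with pytest.raises(ConfigError, match="conflicting"):
        run_simulation(
            SimConfig(duration=10.0, seed=1),
            Protocol(clamps=[ClampSpec("atp_cyt", 5.0), ClampSpec("atp_cyt", 2.0)]),
            preset="small",
        )


def test_upstroke_engages_fine_time_step():
    """The adaptive scheme takes many more steps when the upstroke criterion
    can trigger than when it is disabled by an unreachable threshold."""
    cfg_fine = SimConfig(duration=400.0, seed=8, upstroke_threshold=5.0)
    cfg_never = SimConfig(duration=400.0, seed=8, upstroke_threshold=1e9)
    _, s_fine = run_simulation(cfg_fine, Protocol(pcl=400.0), preset="small")
    _, s_never = run_simulation(cfg_never, Protocol(pcl=400.0), preset="small")
    assert s_fine.step > s_never.step + 1000
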