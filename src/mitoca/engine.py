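"""Run orchestration: full model state, hybrid time stepping, snapshots.

``run_simulation`` paces the coupled lattice for a configured duration and
returns whole-cell averaged traces (the over-bar quantities: cytosolic and
SR Ca2+, uptake/release fluxes, mitochondrial Ca2+, mPTP open fraction,
Delta-psi, ROS, CaMKII, ATP) sampled at the output interval, plus a final
:class:`Snapshot` for warm restarts.  Trajectories are fully determined by
(seed, config, protocol): the kernel draws all randomness from a
counter-based stream keyed by the master seed and the absolute step index.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernel
from .calcium import CRUState
from .geometry import SpatialGrid, build_lattice
from .mitochondria import MitoState
from .params import CellParams, ConfigError, LATTICE_PRESETS
from .sarcolemma import InstabilityError, MembraneState, resting_gates
from .signaling import CLAMP_TARGETS, ClampSpec, SignalingState

__all__ = [
    "SimConfig",
    "Protocol",
    "ModelState",
    "Snapshot",
    "TRACE_COLUMNS",
    "init_state",
    "advance_step",
    "run_simulation",
]

TRACE_COLUMNS = (
    "t", "v", "ca_i", "ca_jsr", "ca_nsr", "j_up", "j_rel",
    "ca_m", "mptp_open", "dpsi", "ros", "camkii", "atp", "frac_producing",
)

SNAPSHOT_VERSION = 1


@dataclass
class SimConfig:
    """Numerical configuration of a run.

    ``dt_upstroke`` is engaged globally while |dV/dt| exceeds
    ``upstroke_threshold`` (the action-potential upstroke); ``dt_normal``
    is used otherwise.
    """

    dt_normal: float = 0.01          # ms
    dt_upstroke: float = 0.001       # ms
    upstroke_threshold: float = 5.0  # mV/ms
    duration: float = 30000.0        # ms
    seed: int = 0
    output_interval: float = 1.0     # ms

    def __post_init__(self) -> None:
        if self.dt_upstroke > self.dt_normal:
            raise ConfigError("dt_upstroke must be <= dt_normal")
        if self.duration < 0:
            raise ConfigError("duration must be >= 0")
        if self.output_interval <= 0:
            raise ConfigError("output_interval must be > 0")


@dataclass
class Protocol:
    """Experimental protocol: pacing, interventions, clamps.

    ``alpha_mptp`` scales the mPTP C1->O rate (1 = control, 60 = the
    depolarized condition); ``alpha_mcu`` scales maximal MCU conductance.
    ``ryr_redox`` / ``serca_redox`` disable the corresponding redox arm when
    False (dk_ROS,max = 0 / f_up,ROS = 1).  ``param_overrides`` accepts
    dotted parameter names.
    """

    pcl: float = 500.0
    pacing: bool = True
    alpha_mptp: float = 1.0
    alpha_mcu: float = 1.0
    ryr_redox: bool = True
    serca_redox: bool = True
    clamps: list[ClampSpec] = field(default_factory=list)
    param_overrides: dict = field(default_factory=dict)

    def apply_to(self, params: CellParams) -> CellParams:
        p = params.with_overrides(self.param_overrides)
        p.stimulus.period = float(self.pcl)
        p.mptp.alpha_mptp = float(self.alpha_mptp)
        p.mito.alpha_mcu = float(self.alpha_mcu)
        if not self.ryr_redox:
            p.ryr.dk_ros_max = 0.0
        return p


@dataclass
class ModelState:
    """Complete state of the coupled cell model."""

    grid: SpatialGrid
    params: CellParams
    cru: CRUState
    mito: MitoState
    signaling: SignalingState
    membrane: MembraneState
    t: float = 0.0
    step: int = 0
    dvdt: float = 0.0  # last dV/dt; persisted so the adaptive step resumes exactly


@dataclass
class Snapshot:
    """Serialized model state + stepping counters; round-trips bit-exactly."""

    cru_dims: tuple
    mito_dims: tuple
    scalars: np.ndarray
    cp: np.ndarray
    cs: np.ndarray
    ci: np.ndarray
    cnsr: np.ndarray
    cjsr: np.ndarray
    ros: np.ndarray
    nryr: np.ndarray
    nrefr: np.ndarray
    nlcc: np.ndarray
    cam: np.ndarray
    dpsi: np.ndarray
    pstate: np.ndarray
    step: int
    version: int = SNAPSHOT_VERSION

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path,
            version=self.version,
            cru_dims=np.asarray(self.cru_dims),
            mito_dims=np.asarray(self.mito_dims),
            scalars=self.scalars, cp=self.cp, cs=self.cs, ci=self.ci,
            cnsr=self.cnsr, cjsr=self.cjsr, ros=self.ros,
            nryr=self.nryr, nrefr=self.nrefr, nlcc=self.nlcc,
            cam=self.cam, dpsi=self.dpsi,
            pstate=self.pstate, step=np.int64(self.step),
        )

    @classmethod
    def load(cls, path: str | Path) -> "Snapshot":
        with np.load(path) as z:
            version = int(z["version"])
            if version != SNAPSHOT_VERSION:
                raise ConfigError(f"unsupported snapshot version {version}")
            return cls(
                cru_dims=tuple(int(x) for x in z["cru_dims"]),
                mito_dims=tuple(int(x) for x in z["mito_dims"]),
                scalars=z["scalars"], cp=z["cp"], cs=z["cs"], ci=z["ci"],
                cnsr=z["cnsr"], cjsr=z["cjsr"], ros=z["ros"],
                nryr=z["nryr"], nrefr=z["nrefr"], nlcc=z["nlcc"], cam=z["cam"],
                dpsi=z["dpsi"], pstate=z["pstate"], step=int(z["step"]),
            )


def init_state(
    params: CellParams | None = None,
    preset: str = "reduced",
    grid: SpatialGrid | None = None,
) -> ModelState:
    """Resting initial condition on a preset lattice (default the reduced
    16x8x4 CRU / 16x4x2 mitochondrion grid)."""
    params = params or CellParams()
    if grid is None:
        if preset not in LATTICE_PRESETS:
            raise ConfigError(f"unknown preset {preset!r}; valid: {sorted(LATTICE_PRESETS)}")
        grid = build_lattice(*LATTICE_PRESETS[preset])
    nc, nm = grid.cru_count, grid.mito_count
    return ModelState(
        grid=grid,
        params=params,
        cru=CRUState.resting(nc, params.ryr.n_per_cluster, params.lcc.n_per_cru),
        mito=MitoState.resting(nm, params.mito),
        signaling=SignalingState.resting(nc, params.signaling),
        membrane=MembraneState(v=-85.0, gates=resting_gates(-85.0), cm=params.membrane.cm),
    )


def _pack_scalars(state: ModelState) -> np.ndarray:
    sc = np.zeros(_kernel.NSC, dtype=np.float64)
    sc[_kernel.SC_V] = state.membrane.v
    sc[_kernel.SC_GATE0:_kernel.SC_GATE0 + 11] = state.membrane.gates
    sc[_kernel.SC_CAMK] = state.signaling.camkii_act
    sc[_kernel.SC_ATP] = state.signaling.atp_cyt
    sc[_kernel.SC_T] = state.t
    sc[_kernel.SC_DVDT] = state.dvdt
    return sc


def _unpack_scalars(state: ModelState, sc: np.ndarray) -> None:
    state.membrane.v = float(sc[_kernel.SC_V])
    state.membrane.gates = sc[_kernel.SC_GATE0:_kernel.SC_GATE0 + 11].copy()
    state.signaling.camkii_act = float(sc[_kernel.SC_CAMK])
    state.signaling.atp_cyt = float(sc[_kernel.SC_ATP])
    state.signaling.adp_cyt = max(
        state.params.signaling.adenine_pool - state.signaling.atp_cyt, 0.0
    )
    state.t = float(sc[_kernel.SC_T])
    state.dvdt = float(sc[_kernel.SC_DVDT])


def _clamp_arrays(clamps: list[ClampSpec]):
    on = np.zeros(6, dtype=np.float64)
    val = np.zeros(6, dtype=np.float64)
    t0 = np.zeros(6, dtype=np.float64)
    seen = set()
    for c in clamps:
        if c.target in seen:
            raise ConfigError(f"conflicting clamps on target {c.target!r}")
        seen.add(c.target)
        k = CLAMP_TARGETS.index(c.target)
        on[k] = 1.0
        val[k] = c.value
        t0[k] = c.start_time
    return on, val, t0


def _run_kernel(state, config, protocol, params, t_end, out_rows):
    grid = state.grid
    P = params.flatten()
    flags = np.zeros(_kernel.NFLAGS, dtype=np.int64)
    flags[_kernel.FL_STIM] = 1 if protocol.pacing else 0
    flags[_kernel.FL_SERCA_REDOX] = 1 if protocol.serca_redox else 0
    on, val, t0 = _clamp_arrays(protocol.clamps)

    nc, nm = grid.cru_count, grid.mito_count
    out = np.zeros((out_rows, _kernel.NCOL), dtype=np.float64)
    out_n = np.zeros(1, dtype=np.int64)
    scratch = [np.zeros(nc), np.zeros(nc), np.zeros(nc), np.zeros(nm)]
    sc = _pack_scalars(state)
    # absolute recording grid: resumed runs sample at the same instants as
    # uninterrupted ones
    next_out = (np.floor(state.t / config.output_interval + 1e-9) + 1.0) * config.output_interval

    try:
        step, _ = _kernel.run_chunk(
            sc, state.cru.ca_dyad, state.cru.ca_sub, state.cru.ca_cyt,
            state.cru.ca_nsr, state.cru.ca_jsr, state.signaling.ros_cyt,
            state.cru.ryr_open, state.cru.ryr_refractory, state.cru.lcc_open,
            state.mito.ca_m, state.mito.dpsi, state.mito.mptp_state,
            grid.cru_to_mito, grid.neighbors, P, flags, on, val, t0,
            config.seed, state.step,
            config.dt_normal, config.dt_upstroke, config.upstroke_threshold,
            t_end, config.output_interval, next_out,
            out, out_n, *scratch,
        )
    except RuntimeError as exc:  # re-raise with timestamp context
        raise InstabilityError(f"{exc} (around t = {sc[_kernel.SC_T]:.3f} ms)") from exc
    state.step = int(step)
    _unpack_scalars(state, sc)
    return out[: out_n[0]]


def advance_step(state: ModelState, config: SimConfig, protocol: Protocol | None = None) -> ModelState:
    """Advance the full model by exactly one hybrid step (kernel-backed)."""
    protocol = protocol or Protocol(pcl=state.params.stimulus.period, pacing=False)
    params = protocol.apply_to(state.params)
    dt = config.dt_normal  # single normal-length step
    _run_kernel(state, config, protocol, params, state.t + dt, out_rows=2)
    return state


def run_simulation(
    config: SimConfig,
    protocol: Protocol,
    initial: ModelState | Snapshot | None = None,
    params: CellParams | None = None,
    preset: str = "reduced",
) -> tuple[pd.DataFrame, Snapshot]:
    """Pace the model for ``config.duration`` ms under ``protocol``.

    Returns the whole-cell trace table (columns ``TRACE_COLUMNS``) and the
    final snapshot.  ``initial`` may be a prior snapshot for warm starts;
    trajectories resumed mid-run are identical to uninterrupted ones at
    equal seed.
    """
    base = params or CellParams()
    if isinstance(initial, Snapshot):
        state = _state_from_snapshot(initial, base)
    elif initial is not None:
        state = initial
        base = state.params
    else:
        state = init_state(base, preset=preset)
    run_params = protocol.apply_to(base)
    state.params = run_params

    if config.duration <= 0:
        return (
            pd.DataFrame(np.empty((0, _kernel.NCOL)), columns=list(TRACE_COLUMNS)),
            snapshot_of(state),
        )
    t_end = state.t + config.duration
    rows = int(np.ceil(config.duration / config.output_interval)) + 2
    out = _run_kernel(state, config, protocol, run_params, t_end, rows)
    traj = pd.DataFrame(out, columns=list(TRACE_COLUMNS))
    return traj, snapshot_of(state)


def snapshot_of(state: ModelState) -> Snapshot:
    return Snapshot(
        cru_dims=state.grid.cru_dims,
        mito_dims=state.grid.mito_dims,
        scalars=_pack_scalars(state).copy(),
        cp=state.cru.ca_dyad.copy(), cs=state.cru.ca_sub.copy(),
        ci=state.cru.ca_cyt.copy(), cnsr=state.cru.ca_nsr.copy(),
        cjsr=state.cru.ca_jsr.copy(), ros=state.signaling.ros_cyt.copy(),
        nryr=state.cru.ryr_open.copy(), nrefr=state.cru.ryr_refractory.copy(),
        nlcc=state.cru.lcc_open.copy(),
        cam=state.mito.ca_m.copy(), dpsi=state.mito.dpsi.copy(),
        pstate=state.mito.mptp_state.copy(), step=state.step,
    )


def _state_from_snapshot(snap: Snapshot, params: CellParams) -> ModelState:
    grid = build_lattice(snap.cru_dims, snap.mito_dims)
    state = init_state(params, grid=grid)
    state.cru.ca_dyad = snap.cp.copy()
    state.cru.ca_sub = snap.cs.copy()
    state.cru.ca_cyt = snap.ci.copy()
    state.cru.ca_nsr = snap.cnsr.copy()
    state.cru.ca_jsr = snap.cjsr.copy()
    state.signaling.ros_cyt = snap.ros.copy()
    state.cru.ryr_open = snap.nryr.copy()
    state.cru.ryr_refractory = snap.nrefr.copy()
    state.cru.lcc_open = snap.nlcc.copy()
    state.mito.ca_m = snap.cam.copy()
    state.mito.dpsi = snap.dpsi.copy()
    state.mito.mptp_state = snap.pstate.copy()
    state.step = snap.step
    _unpack_scalars(state, snap.scalars.copy())
    return state
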