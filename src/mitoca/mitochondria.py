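"""Mitochondrial Ca2+ handling, the 3-state mPTP channel, and ROS/ATP source
behavior.

The permeability transition pore (mPTP) is a Markov chain C0 <-> C1 <-> O.
Its C0 -> C1 rate is mitochondrial-Ca2+ dependent,

    k_c0c1 = alpha0 * (1 + 199 * ca^h / (ca^h + ca0^h)),

and the C1 -> O rate is scaled by the dimensionless pre-factor alpha_mPTP
(k_c1o = alpha_mPTP * kc1o0).  Pore opening collapses the inner-membrane
potential Delta-psi, which halts ATP production and elevates ROS emission;
closing lets Delta-psi recover.  Delta-psi, ROS emission, and ATP production
are modeled as two-level relaxation processes (polarized/depolarized
targets), not as a full metabolic flux network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import MPTPParams, MitoParams

__all__ = [
    "MitoState",
    "MPTP_C0",
    "MPTP_C1",
    "MPTP_O",
    "mptp_activation_rate",
    "mptp_rate_matrix",
    "mptp_steady_state",
    "mptp_transition_step",
    "mito_fluxes",
    "mito_energetics",
    "mcu_flux",
    "mncx_flux",
]

MPTP_C0, MPTP_C1, MPTP_O = 0, 1, 2


@dataclass
class MitoState:
    """Per-mitochondrion state arrays.

    ``dpsi`` is the inner-membrane potential magnitude (mV, polarized
    ~180); ``mptp_state`` holds 0/1/2 for C0/C1/O.  A mitochondrion produces
    ATP only while polarized (dpsi above the midpoint between the polarized
    and depolarized levels).
    """

    ca_m: np.ndarray
    dpsi: np.ndarray
    mptp_state: np.ndarray

    @classmethod
    def resting(cls, n_mito: int, params: MitoParams | None = None) -> "MitoState":
        params = params or MitoParams()
        return cls(
            ca_m=np.full(n_mito, 0.2, dtype=np.float64),
            dpsi=np.full(n_mito, params.psi_polarized, dtype=np.float64),
            mptp_state=np.zeros(n_mito, dtype=np.int64),
        )

    def producing_atp(self, params: MitoParams) -> np.ndarray:
        """ATP synthesis requires a closed pore and Delta-psi recovered at
        least a quarter of the way back to the polarized level."""
        thr = params.psi_depolarized + 0.25 * (
            params.psi_polarized - params.psi_depolarized
        )
        return (self.mptp_state != MPTP_O) & (self.dpsi >= thr)

    def ros_emission(self, emit_polarized: float, emit_depolarized: float,
                     params: MitoParams) -> np.ndarray:
        """Emission rate (uM/ms) interpolated linearly on Delta-psi between the
        polarized baseline and the elevated depolarized rate."""
        frac = np.clip(
            (params.psi_polarized - self.dpsi)
            / (params.psi_polarized - params.psi_depolarized),
            0.0, 1.0,
        )
        return emit_polarized + (emit_depolarized - emit_polarized) * frac


def mptp_activation_rate(params: MPTPParams, ca_m):
    """Ca2+-dependent C0 -> C1 rate (ms^-1): alpha0 at zero mitochondrial
    Ca2+, 100.5*alpha0 at the half-max ca0, saturating at 200*alpha0."""
    ca = np.asarray(ca_m, dtype=np.float64)
    if np.any(ca < 0):
        raise ValueError("ca_m must be >= 0")
    cah = ca**params.h_mptp
    return (params.alpha0 * (1.0 + 199.0 * cah / (cah + params.ca0**params.h_mptp)))[()]


def mptp_rate_matrix(params: MPTPParams, ca_m: float) -> np.ndarray:
    """Generator matrix Q (ms^-1) of the C0 <-> C1 <-> O chain at fixed ca_m;
    rows sum to zero, Q[i, j] is the i -> j rate."""
    k01 = float(mptp_activation_rate(params, ca_m))
    k10 = params.kc1c0
    k1o = params.alpha_mptp * params.kc1o0
    ko1 = params.koc1
    return np.array(
        [
            [-k01, k01, 0.0],
            [k10, -(k10 + k1o), k1o],
            [0.0, ko1, -ko1],
        ]
    )


def mptp_steady_state(params: MPTPParams, ca_m) -> np.ndarray:
    """Exact stationary open probability of the 3-state chain.

    P_O = k01*k1o / (k01*k1o + k01*ko1 + k10*ko1), with k1o = alpha_mPTP *
    kc1o0.  Limits: 0 as alpha_mPTP -> 0, and 1 as alpha_mPTP -> infinity.
    """
    k01 = np.asarray(mptp_activation_rate(params, ca_m), dtype=np.float64)
    k10 = params.kc1c0
    k1o = params.alpha_mptp * params.kc1o0
    ko1 = params.koc1
    return (k01 * k1o / (k01 * k1o + k01 * ko1 + k10 * ko1))[()]


def mptp_transition_step(
    state: MitoState,
    params: MPTPParams,
    dt: float,
    rng: np.random.Generator,
    ca_m=None,
    forced_closed: bool = False,
) -> MitoState:
    """One stochastic step of every pore's C0 <-> C1 <-> O chain.

    Transition probabilities are ``1 - exp(-rate*dt)``; with ``forced_closed``
    all pores are commanded to C0 and transitions are disabled (the
    pore-block protocol).  Raises if any rate*dt exceeds 0.5.
    """
    if forced_closed:
        state.mptp_state[:] = MPTP_C0
        return state
    ca = state.ca_m if ca_m is None else np.broadcast_to(ca_m, state.ca_m.shape)
    k01 = np.asarray(mptp_activation_rate(params, ca), dtype=np.float64)
    k01 = np.broadcast_to(k01, state.mptp_state.shape)
    k10 = params.kc1c0
    k1o = params.alpha_mptp * params.kc1o0
    ko1 = params.koc1
    if max(k01.max() * dt, (k10 + k1o) * dt, ko1 * dt) > 0.5:
        raise RuntimeError("mPTP transition probability exceeds 0.5; reduce dt")

    u = rng.random(state.mptp_state.shape)
    s = state.mptp_state
    new = s.copy()
    at0 = s == MPTP_C0
    new[at0 & (u < -np.expm1(-k01 * dt))] = MPTP_C1
    at1 = s == MPTP_C1
    p_leave = -np.expm1(-(k10 + k1o) * dt)
    leave = at1 & (u < p_leave)
    to_open = leave & (u < p_leave * (k1o / (k10 + k1o)))
    new[leave] = MPTP_C0
    new[to_open] = MPTP_O
    at2 = s == MPTP_O
    new[at2 & (u < -np.expm1(-ko1 * dt))] = MPTP_C1
    state.mptp_state = new
    return state


def mcu_flux(params: MitoParams, ca_cyt, dpsi, alpha_mcu: float = 1.0):
    """Mitochondrial Ca2+ uniporter influx (uM/ms, cytosol-volume units),
    scaled by alpha_MCU and by the Delta-psi driving factor."""
    ca = np.asarray(ca_cyt, dtype=np.float64)
    f_psi = params.psi_mcu_floor + (1.0 - params.psi_mcu_floor) * np.clip(
        np.asarray(dpsi) / params.psi_polarized, 0.0, 1.0
    )
    return (alpha_mcu * params.v_mcu * f_psi * ca**2 / (ca**2 + params.k_mcu**2))[()]


def mncx_flux(params: MitoParams, ca_m):
    """Mitochondrial Na+/Ca2+ exchange efflux (uM/ms)."""
    ca = np.asarray(ca_m, dtype=np.float64)
    return (params.mncx_scale * params.v_mncx * ca / (ca + params.k_mncx))[()]


def mito_fluxes(
    state: MitoState,
    params: MitoParams,
    ca_cyt_local,
    dt: float,
    alpha_mcu: float = 1.0,
) -> MitoState:
    """Update mitochondrial free Ca2+ from MCU influx, mNCX efflux, and --
    when the pore is open -- conductive release toward the local cytosolic
    level.  ``alpha_mcu = 0`` or ``mncx_scale = 0`` implement the transporter
    inhibition protocols."""
    if alpha_mcu < 0:
        raise ValueError("alpha_mcu must be >= 0")
    ca_cyt = np.broadcast_to(np.asarray(ca_cyt_local, dtype=np.float64), state.ca_m.shape)
    j_in = mcu_flux(params, ca_cyt, state.dpsi, alpha_mcu)
    j_out = mncx_flux(params, state.ca_m)
    j_ptp = np.where(
        state.mptp_state == MPTP_O, params.g_ptp_rel * (state.ca_m - ca_cyt), 0.0
    )
    state.ca_m = np.maximum(state.ca_m + dt * (j_in - j_out - j_ptp) / params.v_mito, 0.0)
    return state


def mito_energetics(state: MitoState, params: MitoParams, dt: float) -> MitoState:
    """Relax Delta-psi toward its state-dependent target: the depolarized
    level while the pore is open, the polarized resting level otherwise.
    ATP production and ROS emission follow Delta-psi (see MitoState)."""
    open_ = state.mptp_state == MPTP_O
    target = np.where(open_, params.psi_depolarized, params.psi_polarized)
    tau = np.where(open_, params.tau_psi_depol, params.tau_psi_repol)
    state.dpsi = state.dpsi + dt * (target - state.dpsi) / tau
    return state
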