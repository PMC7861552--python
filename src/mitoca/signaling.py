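"""Slow signaling variables: cytosolic ROS field, oxidized-CaMKII activation,
ATP/ADP pools, and the clamp machinery.

ROS is a per-CRU field fed by local mitochondrial emission, removed by
first-order scavenging, and diffusing between neighbors; with every
mitochondrion polarized it settles at the configured baseline (~0.1 uM).

CaMKII activation is a whole-cell fraction following autocatalytic
(logistic) growth toward a drive-dependent quasi-steady level

    dA/dt = g * A * (1 - A / A_inf(ROS, Ca)),

a reduced form of oxidized-CaMKII kinetics: activation of the kinase
promotes further activation, so growth away from the resting floor is slow
at first (sub-minute changes stay ~1%) while the long-run level under
sustained depolarization is large.  ATP relaxes slowly toward a level set by
the fraction of polarized (ATP-producing) mitochondria; ADP mirrors ATP
against a fixed adenine pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ConfigError, SignalingParams

__all__ = [
    "SignalingState",
    "ClampSpec",
    "CLAMP_TARGETS",
    "ros_field_update",
    "camkii_target",
    "camkii_update",
    "atp_target",
    "atp_update",
    "apply_clamps",
    "fast_forward_slow",
]

CLAMP_TARGETS = ("ros_cyt", "camkii_act", "atp_cyt", "ca_mito", "ca_cyt", "mptp_closed")


@dataclass
class SignalingState:
    """Cytosolic ROS field (per CRU, uM), whole-cell CaMKII activation
    fraction, and cytosolic ATP/ADP (mM)."""

    ros_cyt: np.ndarray
    camkii_act: float
    atp_cyt: float
    adp_cyt: float

    @classmethod
    def resting(cls, n_cru: int, params: SignalingParams | None = None) -> "SignalingState":
        p = params or SignalingParams()
        baseline = p.ros_emit_polarized / p.k_ros_scav
        return cls(
            ros_cyt=np.full(n_cru, baseline, dtype=np.float64),
            camkii_act=p.camk_floor,
            atp_cyt=p.atp_rest,
            adp_cyt=p.adenine_pool - p.atp_rest,
        )

    def validate(self) -> None:
        if np.any(self.ros_cyt < 0):
            raise ValueError("negative ROS")
        if not 0.0 <= self.camkii_act <= 1.0:
            raise ValueError("CaMKII activation outside [0, 1]")
        if self.atp_cyt < 0 or self.adp_cyt < 0:
            raise ValueError("negative adenine pool member")


@dataclass
class ClampSpec:
    """Clamp one variable to a fixed value from ``start_time`` on.

    ``target`` is one of ``ros_cyt`` (uM), ``camkii_act`` (fraction),
    ``atp_cyt`` (mM), ``ca_mito`` (uM), ``ca_cyt`` (uM), or ``mptp_closed``
    (value ignored; all pores commanded to C0).  The clamp overwrites the
    target after every step; everything else keeps its dynamics.
    """

    target: str
    value: float = 0.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.target not in CLAMP_TARGETS:
            raise ConfigError(
                f"unknown clamp target {self.target!r}; valid: {CLAMP_TARGETS}"
            )
        if self.target == "camkii_act" and not 0.0 <= self.value <= 1.0:
            raise ConfigError("camkii_act clamp must lie in [0, 1]")
        if self.target in ("ros_cyt", "atp_cyt", "ca_mito", "ca_cyt") and self.value < 0:
            raise ConfigError(f"{self.target} clamp must be >= 0")


def ros_field_update(
    state: SignalingState,
    emission,
    dt: float,
    params: SignalingParams | None = None,
    neighbors: np.ndarray | None = None,
) -> SignalingState:
    """Advance the per-CRU ROS field one Euler step.

    ``emission`` is the local mitochondrial emission rate (uM/ms, per CRU).
    Steady state under spatially uniform emission E is E / k_scavenge.
    """
    p = params or SignalingParams()
    emission = np.broadcast_to(np.asarray(emission, dtype=np.float64), state.ros_cyt.shape)
    lap = 0.0
    if neighbors is not None:
        valid = neighbors >= 0
        idx = np.where(valid, neighbors, 0)
        lap = np.where(valid, np.take(state.ros_cyt, idx), 0.0).sum(axis=1)
        lap = lap - valid.sum(axis=1) * state.ros_cyt
    state.ros_cyt = np.maximum(
        state.ros_cyt + dt * (emission - p.k_ros_scav * state.ros_cyt + p.d_ros * lap),
        0.0,
    )
    return state


def camkii_target(params: SignalingParams, ros_cyt: float, ca_cyt: float) -> float:
    """Drive-dependent quasi-steady CaMKII activation level A_inf in
    [floor, camk_max]; rises with ROS (oxidized arm) and, weakly, with
    cytosolic Ca2+."""
    rh = ros_cyt**params.h_ros_camk
    drive_ros = rh / (rh + params.k_ros_camk**params.h_ros_camk)
    ca2 = ca_cyt * ca_cyt
    drive_ca = params.w_ca_camk * ca2 / (ca2 + params.k_ca_camk**2)
    drive = min(drive_ros + drive_ca, 1.0)
    return params.camk_floor + (params.camk_max - params.camk_floor) * drive


def camkii_update(
    state: SignalingState,
    ca_cyt: float,
    ros_cyt: float,
    dt: float,
    params: SignalingParams | None = None,
) -> SignalingState:
    """One Euler step of the logistic CaMKII activation law.  With clamped
    drives the long-run fixed point is exactly ``camkii_target``."""
    p = params or SignalingParams()
    a_inf = camkii_target(p, ros_cyt, ca_cyt)
    a = state.camkii_act
    state.camkii_act = float(np.clip(a + dt * p.camk_growth * a * (1.0 - a / a_inf), 0.0, 1.0))
    return state


def atp_target(params: SignalingParams, fraction_producing: float) -> float:
    """Quasi-steady cytosolic ATP (mM) as a function of the fraction of
    polarized, ATP-producing mitochondria."""
    return params.atp_rest * fraction_producing**params.atp_frac_exp


def atp_update(
    state: SignalingState,
    fraction_producing: float,
    consumption_load: float = 0.0,
    dt: float = 0.01,
    params: SignalingParams | None = None,
) -> SignalingState:
    """Relax ATP toward its production-set target (time constant tau_atp,
    minutes-scale) with an optional extra consumption load (mM/ms); ADP
    mirrors ATP against the fixed adenine pool."""
    if not 0.0 <= fraction_producing <= 1.0:
        raise ValueError("fraction_producing must lie in [0, 1]")
    p = params or SignalingParams()
    target = atp_target(p, fraction_producing)
    atp = state.atp_cyt + dt * ((target - state.atp_cyt) / p.tau_atp - consumption_load)
    state.atp_cyt = float(np.clip(atp, 0.0, p.adenine_pool))
    state.adp_cyt = p.adenine_pool - state.atp_cyt
    return state


def apply_clamps(model_state, clamps: list[ClampSpec], t: float):
    """Overwrite clamped targets of a full model state at time ``t``.

    Duplicate clamps on one target raise a configuration error.  Called by
    the engine after every step; also usable directly on a
    :class:`~mitoca.engine.ModelState`.
    """
    seen: set[str] = set()
    for c in clamps:
        if c.target in seen:
            raise ConfigError(f"conflicting clamps on target {c.target!r}")
        seen.add(c.target)
    for c in clamps:
        if t < c.start_time:
            continue
        if c.target == "ros_cyt":
            model_state.signaling.ros_cyt[:] = c.value
        elif c.target == "camkii_act":
            model_state.signaling.camkii_act = c.value
        elif c.target == "atp_cyt":
            model_state.signaling.atp_cyt = c.value
            model_state.signaling.adp_cyt = max(
                model_state.params.signaling.adenine_pool - c.value, 0.0
            )
        elif c.target == "ca_mito":
            model_state.mito.ca_m[:] = c.value
        elif c.target == "ca_cyt":
            model_state.cru.ca_cyt[:] = c.value
        elif c.target == "mptp_closed":
            model_state.mito.mptp_state[:] = 0
    return model_state


def fast_forward_slow(
    params: SignalingParams,
    ros_level: float,
    ca_level: float,
    fraction_producing: float,
    t_end_ms: float,
    camkii0: float | None = None,
    atp0: float | None = None,
    n_out: int = 200,
):
    """Fast-forward mode: integrate only the slow variables (CaMKII, ATP)
    against a frozen periodic steady state of the fast subsystem.

    The fast subsystem is summarized by its time-averaged ROS and cytosolic
    Ca2+ and by the fraction of polarized mitochondria; CaMKII and ATP are
    then integrated to ``t_end_ms`` with scipy's stiff ODE solver.  Returns
    ``(t_ms, camkii, atp)`` arrays.
    """
    from scipy.integrate import solve_ivp

    a0 = params.camk_floor if camkii0 is None else camkii0
    atp0 = params.atp_rest if atp0 is None else atp0
    a_inf = camkii_target(params, ros_level, ca_level)
    atp_inf = atp_target(params, fraction_producing)

    def rhs(_t, y):
        a, atp = y
        return [
            params.camk_growth * a * (1.0 - a / a_inf),
            (atp_inf - atp) / params.tau_atp,
        ]

    t_eval = np.linspace(0.0, t_end_ms, n_out)
    sol = solve_ivp(rhs, (0.0, t_end_ms), [a0, atp0], t_eval=t_eval,
                    method="LSODA", rtol=1e-8, atol=1e-12)
    return sol.t, sol.y[0], sol.y[1]
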