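"""Intracellular Ca2+ cycling per Ca2+ release unit (CRU).

Each CRU carries five Ca2+ compartments (dyadic cleft, submembrane space,
local cytosol, network SR, junctional SR), a stochastic RyR cluster, and a
small stochastic L-type channel cluster.  The RyR closed-to-open rate is

    k12 = k_base * k_u * (1 + dk_CaMKII + dk_ROS) * [Ca2+]_p^2

with saturating CaMKII- and ROS-dependent increments, and SERCA uptake is

    J_up = v_up * f_ATP * f_ROS * c^2 / (c^2 + (k_i - PLB(a))^2)

where f_ATP is the ADP/ATP-dependent factor, f_ROS the redox factor
(1 -> 0.75 as ROS rises), and PLB(a) the CaMKII/phospholamban reduction of
the half-maximal Ca2+.  The formula functions below broadcast over numpy
arrays and are reused verbatim by the compiled engine kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import CompartmentParams, RyRParams, SercaParams

__all__ = [
    "CRUState",
    "ryr_rate_k12",
    "delta_k_camkii",
    "delta_k_ros",
    "serca_atp_factor",
    "serca_ros_factor",
    "plb_shift",
    "serca_flux",
    "ryr_cluster_step",
    "cru_flux_update",
    "buffer_factor",
    "total_calcium",
]


@dataclass
class CRUState:
    """Per-CRU compartment concentrations (uM) and channel-state occupancies.

    Arrays have one entry per CRU; ``ryr_open``/``lcc_open`` count open
    channels out of the fixed per-cluster totals.
    """

    ca_dyad: np.ndarray
    ca_sub: np.ndarray
    ca_cyt: np.ndarray
    ca_nsr: np.ndarray
    ca_jsr: np.ndarray
    ryr_open: np.ndarray
    ryr_refractory: np.ndarray
    lcc_open: np.ndarray
    n_ryr: int = 100
    n_lcc: int = 10

    @classmethod
    def resting(cls, n_cru: int, n_ryr: int = 100, n_lcc: int = 10) -> "CRUState":
        z = lambda v: np.full(n_cru, v, dtype=np.float64)
        return cls(
            ca_dyad=z(0.1), ca_sub=z(0.1), ca_cyt=z(0.1),
            ca_nsr=z(1000.0), ca_jsr=z(1000.0),
            ryr_open=np.zeros(n_cru, dtype=np.int64),
            ryr_refractory=np.zeros(n_cru, dtype=np.int64),
            lcc_open=np.zeros(n_cru, dtype=np.int64),
            n_ryr=n_ryr, n_lcc=n_lcc,
        )

    def validate(self) -> None:
        for name in ("ca_dyad", "ca_sub", "ca_cyt", "ca_nsr", "ca_jsr"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"negative concentration in {name}")
        if np.any(self.ryr_open < 0) or np.any(self.ryr_refractory < 0):
            raise ValueError("negative RyR state count")
        if np.any(self.ryr_open + self.ryr_refractory > self.n_ryr):
            raise ValueError("RyR state counts exceed n_ryr")
        if np.any(self.lcc_open < 0) or np.any(self.lcc_open > self.n_lcc):
            raise ValueError("LCC open count outside [0, n_lcc]")


# -- RyR gating -------------------------------------------------------------

def ryr_rate_k12(params: RyRParams, ca_dyad, dk_camkii=0.0, dk_ros=0.0):
    """RyR closed->open rate (ms^-1); quadratic in dyadic Ca2+ and linear in
    the combined CaMKII/ROS sensitization ``(1 + dk_camkii + dk_ros)``."""
    ca_dyad = np.asarray(ca_dyad, dtype=np.float64)
    if np.any(ca_dyad < 0) or np.any(np.asarray(dk_camkii) < 0) or np.any(np.asarray(dk_ros) < 0):
        raise ValueError("ca_dyad and sensitization increments must be >= 0")
    k = params.k_base * params.k_u * (1.0 + dk_camkii + dk_ros) * ca_dyad**2
    return np.minimum(k, params.k12_max)[()]


def delta_k_camkii(params: RyRParams, camkii_act):
    """CaMKII-dependent RyR sensitization, Hill saturating at dk_camk_max;
    0 in the limit of no activation."""
    a = np.asarray(camkii_act, dtype=np.float64)
    ah = a**params.h_cam_ryr
    return (params.dk_camk_max * ah / (ah + params.km_cam_ryr**params.h_cam_ryr))[()]


def delta_k_ros(params: RyRParams, ros_cyt):
    """ROS-dependent RyR sensitization; ``dk_ros_max = 0`` switches the
    redox arm off entirely."""
    r = np.asarray(ros_cyt, dtype=np.float64)
    rh = r**params.h_ros_ryr
    return (params.dk_ros_max * rh / (rh + params.km_ros_ryr**params.h_ros_ryr))[()]


# -- SERCA ------------------------------------------------------------------

def serca_atp_factor(params: SercaParams, atp, adp=0.0):
    """ATP/ADP dependence of SERCA, in (0, 1]; half-max at ATP = km_up_atp
    when ADP = 0."""
    atp = np.asarray(atp, dtype=np.float64)
    if np.any(atp <= 0):
        raise ValueError("ATP must be > 0 for the SERCA ATP factor")
    adp = np.asarray(adp, dtype=np.float64)
    return (
        1.0
        / (1.0 + adp / params.ki_up_prime + (1.0 + adp / params.ki_up) * params.km_up_atp / atp)
    )[()]


def serca_ros_factor(params: SercaParams, ros_cyt):
    """Redox factor on SERCA: 1 at zero ROS, 0.75 at saturating ROS,
    0.875 at ROS = kd_ros."""
    r = np.asarray(ros_cyt, dtype=np.float64)
    h = params.h_ros_serca
    rh = r**h
    kh = params.kd_ros**h
    return (kh / (kh + rh) + 0.75 * rh / (rh + kh))[()]


def plb_shift(params: SercaParams, camkii_act):
    """Phospholamban-mediated reduction (uM) of the SERCA half-max; saturating
    increasing function of CaMKII activation."""
    a = np.asarray(camkii_act, dtype=np.float64)
    ah = a**params.plb_h
    return (params.plb_max * ah / (ah + params.plb_k**params.plb_h))[()]


def serca_flux(params: SercaParams, ca_cyt, camkii_act=0.0, f_atp=1.0, f_ros=1.0):
    """SERCA uptake flux (uM/ms).  Higher CaMKII shrinks the effective
    half-max (via PLB) and raises uptake at fixed Ca2+."""
    ca = np.asarray(ca_cyt, dtype=np.float64)
    if np.any(ca < 0):
        raise ValueError("ca_cyt must be >= 0")
    k_eff = params.k_i - plb_shift(params, camkii_act)
    if np.any(np.asarray(k_eff) <= 0):
        raise ValueError("effective SERCA half-max must stay positive; check plb_max < k_i")
    return (params.v_up * f_atp * f_ros * ca**2 / (ca**2 + k_eff**2))[()]


# -- stochastic cluster update ---------------------------------------------

def ryr_cluster_step(
    state: CRUState,
    k12,
    dt: float,
    rng: np.random.Generator,
    k_close: float = 0.06,
    k_recover: float | None = None,
):
    """One binomial (tau-leap style) update of the RyR clusters.

    Channels open with per-channel probability ``1 - exp(-k12*dt)``; open
    channels close at ``k_close`` into a refractory state that recovers at
    ``k_recover`` (release restitution).  With ``k_recover=None`` closures
    return directly to the closed state (the 2-state limit).  Counts are
    conserved within each cluster.  Raises if a per-channel transition
    probability exceeds 0.5 (advice: smaller dt).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    k12 = np.broadcast_to(np.asarray(k12, dtype=np.float64), state.ryr_open.shape)
    if np.any(k12 * dt > 0.5) or k_close * dt > 0.5:
        raise RuntimeError(
            "per-channel transition probability exceeds 0.5; reduce dt"
        )
    p_open = -np.expm1(-k12 * dt)
    p_close = -np.expm1(-k_close * dt)
    n_closed = state.n_ryr - state.ryr_open - state.ryr_refractory
    opened = rng.binomial(n_closed, p_open)
    closed = rng.binomial(state.ryr_open, p_close)
    state.ryr_open = state.ryr_open + opened - closed
    if k_recover is None:
        return state
    recovered = rng.binomial(state.ryr_refractory, -np.expm1(-k_recover * dt))
    state.ryr_refractory = state.ryr_refractory + closed - recovered
    return state


# -- compartment fluxes -----------------------------------------------------

def buffer_factor(c, b, k):
    """Rapid-buffer factor beta(c) = 1 / (1 + B*K/(K + c)^2)."""
    c = np.asarray(c, dtype=np.float64)
    return (1.0 / (1.0 + b * k / (k + c) ** 2))[()]


def total_calcium(c, b, k):
    """Free plus instantaneously-buffered Ca2+ for one compartment (uM)."""
    c = np.asarray(c, dtype=np.float64)
    return (c + b * c / (k + c))[()]


def cru_flux_update(
    state: CRUState,
    ryr: RyRParams,
    serca: SercaParams,
    comp: CompartmentParams,
    dt: float,
    *,
    neighbors: np.ndarray | None = None,
    j_lcc=0.0,
    j_ncx=0.0,
    j_cab=0.0,
    j_mito_net=0.0,
    camkii_act: float = 0.0,
    f_atp: float = 1.0,
    ros_cyt=0.0,
) -> CRUState:
    """Explicit-Euler update of all CRU compartments over one step.

    Includes RyR release (JSR -> submembrane through the quasi-static dyad),
    SERCA uptake, NSR -> JSR refill, NSR leak, submembrane <-> cytosol
    transfer, nearest-neighbor cytosolic and NSR diffusion, rapid buffering,
    and externally supplied sarcolemmal (``j_lcc``, ``j_ncx``, ``j_cab``) and
    mitochondrial (``j_mito_net``, positive into the cytosol) fluxes, all in
    cytosol-volume uM/ms.  With every flux zero the state is unchanged; with
    sarcolemmal and mitochondrial fluxes zero, total Ca2+ is conserved up to
    Euler discretization error.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    po = state.ryr_open / ryr.n_per_cluster
    g_open = ryr.g_rel * po
    # quasi-static dyadic Ca2+
    cp = (state.ca_sub + ryr.a_dyad * (g_open * state.ca_jsr + j_lcc)) / (
        1.0 + ryr.a_dyad * g_open
    )
    j_rel = g_open * (state.ca_jsr - cp)
    j_si = comp.g_sub_cyt * (state.ca_sub - state.ca_cyt)
    f_ros = serca_ros_factor(serca, ros_cyt)
    j_up = serca_flux(serca, state.ca_cyt, camkii_act, f_atp, f_ros)
    j_tr = comp.g_tr * (state.ca_nsr - state.ca_jsr)
    j_leak = comp.g_leak * (state.ca_nsr - state.ca_cyt)

    lap_cyt = 0.0
    lap_nsr = 0.0
    if neighbors is not None:
        valid = neighbors >= 0
        deg = valid.sum(axis=1)
        idx = np.where(valid, neighbors, 0)
        lap_cyt = np.take(state.ca_cyt, idx)
        lap_cyt = np.where(valid, lap_cyt, 0.0).sum(axis=1) - deg * state.ca_cyt
        lap_nsr = np.take(state.ca_nsr, idx)
        lap_nsr = np.where(valid, lap_nsr, 0.0).sum(axis=1) - deg * state.ca_nsr

    beta_s = buffer_factor(state.ca_sub, comp.buf_sub_b, comp.buf_sub_k)
    beta_i = buffer_factor(state.ca_cyt, comp.buf_cyt_b, comp.buf_cyt_k)
    beta_j = buffer_factor(state.ca_jsr, comp.buf_jsr_b, comp.buf_jsr_k)

    state.ca_dyad = cp
    state.ca_sub = state.ca_sub + dt * beta_s * (
        (j_rel + j_lcc - j_si - j_ncx + j_cab) / comp.v_sub
    )
    state.ca_cyt = state.ca_cyt + dt * beta_i * (
        j_si - j_up + j_leak + j_mito_net + comp.d_cyt * lap_cyt
    )
    state.ca_nsr = state.ca_nsr + dt * (
        (j_up - j_tr - j_leak) / comp.v_nsr + comp.d_nsr * lap_nsr
    )
    state.ca_jsr = state.ca_jsr + dt * beta_j * ((j_tr - j_rel) / comp.v_jsr)

    if min(
        state.ca_sub.min(), state.ca_cyt.min(), state.ca_nsr.min(), state.ca_jsr.min()
    ) < -1e-9:
        raise RuntimeError("negative concentration: reduce dt or check parameters")
    return state
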