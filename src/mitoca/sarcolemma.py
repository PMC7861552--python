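"""Sarcolemmal membrane: voltage dynamics, ionic currents, pacing stimulus.

The membrane equation follows the convention

    Cm dV/dt = I_Na + I_Na,L + I_Ca,L + I_NCX + I_K1 + I_Kr + I_Ks
             + I_to,f + I_to,s + I_NaK + I_K,ATP + I_Ca,b - I_sti

in which a depolarizing stimulus has *negative* amplitude (default
-80 uA/cm^2 for 0.5 ms) and depolarizing ionic currents are *positive*.
This is the sign convention of the source model equation as printed; it is
the negative of the more common Cm dV/dt = -sum(I) form, and currents
reported here are negated accordingly (see docs/methods.md).

Current formulations are a reduced rabbit-type set: fast Na+ (Luo-Rudy
gates), late Na+, inward-rectifier, rapid/slow delayed rectifiers, fast and
slow transient outward, Na/K pump, ATP-sensitive K+, background Ca2+,
forward-mode Na/Ca exchange, and stochastic per-CRU L-type channels (handled
by the engine; here their whole-cell mean flux enters the current balance).
Quantitative AP morphology is a calibration choice, not a constraint.

The scalar helpers at the bottom are branch-light pure-arithmetic functions
shared with the compiled engine kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import PARAM_INDEX, MembraneParams, StimulusSpec

__all__ = [
    "MembraneState",
    "CurrentSet",
    "StimulusSpec",
    "CURRENT_NAMES",
    "GATE_NAMES",
    "membrane_derivative",
    "stimulus_waveform",
    "evolve_currents",
    "resting_gates",
    "InstabilityError",
]

RTF = 26.7  # RT/F at 37 C, mV

CURRENT_NAMES = (
    "i_na", "i_nal", "i_cal", "i_ncx", "i_k1", "i_kr",
    "i_ks", "i_tof", "i_tos", "i_nak", "i_katp", "i_cab",
)

GATE_NAMES = ("m", "h", "j", "hl", "xr", "xs", "xtf", "ytf", "xts", "yts", "flcc")


class InstabilityError(RuntimeError):
    """Numerical instability (gate escape / negative concentration / NaN)."""


@dataclass
class MembraneState:
    """Membrane potential plus Hodgkin-Huxley gating variables."""

    v: float = -85.0
    gates: np.ndarray = field(default_factory=lambda: resting_gates(-85.0))
    cm: float = 1.0

    def __post_init__(self) -> None:
        if self.cm <= 0:
            raise ValueError("membrane capacitance must be positive")
        self.gates = np.asarray(self.gates, dtype=np.float64)
        if self.gates.shape != (len(GATE_NAMES),):
            raise ValueError(f"expected {len(GATE_NAMES)} gating variables")


@dataclass
class CurrentSet:
    """Named current densities (uA/cm^2), depolarizing-positive convention."""

    i_na: float = 0.0
    i_nal: float = 0.0
    i_cal: float = 0.0
    i_ncx: float = 0.0
    i_k1: float = 0.0
    i_kr: float = 0.0
    i_ks: float = 0.0
    i_tof: float = 0.0
    i_tos: float = 0.0
    i_nak: float = 0.0
    i_katp: float = 0.0
    i_cab: float = 0.0

    @property
    def total(self) -> float:
        return float(sum(getattr(self, n) for n in CURRENT_NAMES))

    @classmethod
    def from_mapping(cls, currents: dict) -> "CurrentSet":
        missing = set(CURRENT_NAMES) - set(currents)
        if missing:
            raise ValueError(f"missing current entries: {sorted(missing)}")
        extra = set(currents) - set(CURRENT_NAMES)
        if extra:
            raise ValueError(f"unknown current entries: {sorted(extra)}")
        return cls(**{k: float(v) for k, v in currents.items()})


def membrane_derivative(
    state: MembraneState, currents: CurrentSet | dict, i_sti: float = 0.0
) -> float:
    """dV/dt (mV/ms) = (sum of currents - I_sti) / Cm.

    With all ionic currents zero, the default stimulus (-80 uA/cm^2) yields
    +80 mV/ms: the pulse is depolarizing.
    """
    if isinstance(currents, dict):
        currents = CurrentSet.from_mapping(currents)
    return (currents.total - i_sti) / state.cm


def stimulus_waveform(spec: StimulusSpec, t: float) -> float:
    """Stimulus current density at time ``t`` (ms): ``amplitude`` on
    [k*period, k*period + duration) for every beat k >= 0, else 0."""
    if t < 0:
        raise ValueError("t must be >= 0")
    return spec.amplitude if (t % spec.period) < spec.duration else 0.0


# ---------------------------------------------------------------------------
# scalar gate/current formulas (numba-compatible; also used by the engine)
# ---------------------------------------------------------------------------

def sodium_gate_rates(v):
    """Luo-Rudy fast Na+ gate rates (alpha_m, beta_m, a_h, b_h, a_j, b_j)."""
    dv = v + 47.13
    if abs(dv) < 1e-6:
        am = 3.2
    else:
        am = 0.32 * dv / (1.0 - math.exp(-0.1 * dv))
    bm = 0.08 * math.exp(-v / 11.0)
    if v >= -40.0:
        ah = 0.0
        bh = 1.0 / (0.13 * (1.0 + math.exp(-(v + 10.66) / 11.1)))
        aj = 0.0
        bj = 0.3 * math.exp(-2.535e-7 * v) / (1.0 + math.exp(-0.1 * (v + 32.0)))
    else:
        ah = 0.135 * math.exp(-(80.0 + v) / 6.8)
        bh = 3.56 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.35 * v)
        aj = (
            (-1.2714e5 * math.exp(0.2444 * v) - 3.474e-5 * math.exp(-0.04391 * v))
            * (v + 37.78)
            / (1.0 + math.exp(0.311 * (v + 79.23)))
        )
        bj = 0.1212 * math.exp(-0.01052 * v) / (1.0 + math.exp(-0.1378 * (v + 40.14)))
    return am, bm, ah, bh, aj, bj


def slow_gate_targets(v):
    """(steady, tau) pairs for hl, xr, xs, xtf, ytf, xts, yts in GATE_NAMES order."""
    hl_inf = 1.0 / (1.0 + math.exp((v + 91.0) / 6.1))
    xr_inf = 1.0 / (1.0 + math.exp(-(v + 21.5) / 7.5))
    tau_xr = 40.0 + 300.0 / (1.0 + math.exp((v + 30.0) / 10.0))
    xs_inf = 1.0 / (1.0 + math.exp(-(v - 1.5) / 16.7))
    xt_inf = 1.0 / (1.0 + math.exp(-(v + 3.0) / 15.0))
    yt_inf = 1.0 / (1.0 + math.exp((v + 33.5) / 10.0))
    return (
        hl_inf, 600.0,
        xr_inf, tau_xr,
        xs_inf, 300.0,
        xt_inf, 3.5,
        yt_inf, 20.0,
        xt_inf, 9.0,
        yt_inf, 800.0,
    )


def lcc_gate_target(v, P):
    """Voltage-inactivation gate of the L-type channels (steady, tau).

    Inactivation develops quickly at depolarized potentials (f_gate_tau) and
    recovers slowly near the resting potential (f_gate_tau_rec): availability
    restitution, one arm of the beat-to-beat voltage-Ca2+ coupling."""
    floor = P[IP_LCC_F_FLOOR]
    f_inf = floor + (1.0 - floor) / (
        1.0 + math.exp((v - P[IP_LCC_F_VHALF]) / P[IP_LCC_F_K])
    )
    tau = P[IP_LCC_F_TAU] + (P[IP_LCC_F_TAU_REC] - P[IP_LCC_F_TAU]) / (
        1.0 + math.exp((v + 60.0) / 5.0)
    )
    return f_inf, tau


def deterministic_currents(v, gates, cs_mean, atp, P):
    """Standard-convention (outward-positive) currents that do not depend on
    per-CRU stochastic state.  Returns the 10 deterministic entries of the
    current set in CURRENT_NAMES order minus i_cal/i_ncx."""
    m = gates[0]; h = gates[1]; jg = gates[2]; hl = gates[3]
    xr = gates[4]; xs = gates[5]; xtf = gates[6]; ytf = gates[7]
    xts = gates[8]; yts = gates[9]
    ena = RTF * math.log(P[IP_NAO] / P[IP_NAI])
    ek = RTF * math.log(P[IP_KO] / P[IP_KI_ION])
    eks = ek + 8.0
    kofac = math.sqrt(P[IP_KO] / 5.4)

    i_na = P[IP_G_NA] * m * m * m * h * jg * (v - ena)
    i_nal = P[IP_G_NAL] * m * m * m * hl * (v - ena)

    dvk = v - ek
    ak1 = 1.02 / (1.0 + math.exp(0.2385 * (dvk - 59.215)))
    bk1 = (
        0.49124 * math.exp(0.08032 * (dvk + 5.476))
        + math.exp(0.06175 * (dvk - 594.31))
    ) / (1.0 + math.exp(-0.5143 * (dvk + 4.753)))
    i_k1 = P[IP_G_K1] * kofac * (ak1 / (ak1 + bk1)) * dvk

    rkr = 1.0 / (1.0 + math.exp((v + 9.0) / 22.4))
    i_kr = P[IP_G_KR] * kofac * xr * rkr * dvk
    i_ks = P[IP_G_KS] * xs * xs * (v - eks)
    i_tof = P[IP_G_TOF] * xtf * ytf * dvk
    i_tos = P[IP_G_TOS] * xts * yts * dvk

    sigma = (math.exp(P[IP_NAO] / 67.3) - 1.0) / 7.0
    fnak = 1.0 / (
        1.0 + 0.1245 * math.exp(-0.1 * v / RTF) + 0.0365 * sigma * math.exp(-v / RTF)
    )
    fna = 1.0 / (1.0 + (10.0 / P[IP_NAI]) ** 1.5)
    i_nak = P[IP_I_NAK_MAX] * fnak * fna * P[IP_KO] / (P[IP_KO] + 1.5)

    fatp = 1.0 / (1.0 + (atp / P[IP_KATP_HALF]) ** P[IP_KATP_H])
    i_katp = P[IP_G_KATP] * fatp * kofac * dvk

    eca = 0.5 * RTF * math.log(P[IP_CAO] * 1000.0 / max(cs_mean, 1e-6))
    i_cab = P[IP_G_CAB] * (v - eca)

    return i_na, i_nal, i_k1, i_kr, i_ks, i_tof, i_tos, i_nak, i_katp, i_cab


def ncx_voltage_factor(v):
    """Forward-mode Na/Ca exchange driving factor, 1 at V = -80 mV."""
    return math.exp(-0.65 * (v + 80.0) / RTF)


def resting_gates(v: float = -85.0) -> np.ndarray:
    """Gate vector at voltage steady state (order: GATE_NAMES)."""
    am, bm, ah, bh, aj, bj = sodium_gate_rates(v)
    tg = slow_gate_targets(v)
    flcc = 0.05 + 0.95 / (1.0 + math.exp((v + 20.0) / 5.0))
    return np.array(
        [
            am / (am + bm),
            ah / (ah + bh) if (ah + bh) > 0 else 1.0,
            aj / (aj + bj) if (aj + bj) > 0 else 1.0,
            tg[0], tg[2], tg[4], tg[6], tg[8], tg[10], tg[12],
            flcc,
        ]
    )


def evolve_currents(
    state: MembraneState,
    local_concentrations: dict,
    dt: float,
    params: MembraneParams | None = None,
) -> CurrentSet:
    """Advance gating variables one Euler step and evaluate the current set.

    ``local_concentrations`` must provide ``cs`` (mean submembrane Ca2+, uM)
    and ``atp`` (mM); optional ``j_lcc`` and ``j_ncx`` (whole-cell mean Ca2+
    fluxes, uM/ms) fill the stochastic L-type and exchanger entries.

    Returned currents use the depolarizing-positive convention of the
    membrane equation.  Raises :class:`InstabilityError` if a gate leaves
    [0, 1] beyond tolerance (advice: reduce dt).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    params = params or MembraneParams()
    P = _params_vector(params)
    v = state.v
    g = state.gates

    am, bm, ah, bh, aj, bj = sodium_gate_rates(v)
    for idx, (a, b) in enumerate(((am, bm), (ah, bh), (aj, bj))):
        g[idx] += dt * (a * (1.0 - g[idx]) - b * g[idx])
    tg = slow_gate_targets(v)
    for k in range(7):
        inf, tau = tg[2 * k], tg[2 * k + 1]
        g[3 + k] += dt * (inf - g[3 + k]) / tau
    f_inf, f_tau = lcc_gate_target(v, P)
    g[10] += dt * (f_inf - g[10]) / f_tau

    tol = 1e-9
    if np.any(g < -tol) or np.any(g > 1.0 + tol):
        raise InstabilityError(
            "gating variable left [0, 1]; reduce the time step"
        )
    np.clip(g, 0.0, 1.0, out=g)

    cs = float(local_concentrations["cs"])
    atp = float(local_concentrations["atp"])
    det = deterministic_currents(v, g, cs, atp, P)
    j_lcc = float(local_concentrations.get("j_lcc", 0.0))
    j_ncx = float(local_concentrations.get("j_ncx", 0.0))
    i_cal_std = -j_lcc / params.flux_conv
    i_ncx_std = -0.5 * j_ncx / params.flux_conv  # one net charge per Ca2+ moved

    # negate standard-convention currents into the printed-equation convention
    return CurrentSet(
        i_na=-det[0], i_nal=-det[1], i_cal=-i_cal_std, i_ncx=-i_ncx_std,
        i_k1=-det[2], i_kr=-det[3], i_ks=-det[4], i_tof=-det[5],
        i_tos=-det[6], i_nak=-det[7], i_katp=-det[8], i_cab=-det[9],
    )


def _params_vector(params: MembraneParams):
    from .params import CellParams

    return CellParams(membrane=params).flatten()


# flat-vector index constants (compile-time constants inside the engine kernel)
IP_CM = PARAM_INDEX["membrane.cm"]
IP_G_NA = PARAM_INDEX["membrane.g_na"]
IP_G_NAL = PARAM_INDEX["membrane.g_nal"]
IP_G_K1 = PARAM_INDEX["membrane.g_k1"]
IP_G_KR = PARAM_INDEX["membrane.g_kr"]
IP_G_KS = PARAM_INDEX["membrane.g_ks"]
IP_G_TOF = PARAM_INDEX["membrane.g_tof"]
IP_G_TOS = PARAM_INDEX["membrane.g_tos"]
IP_I_NAK_MAX = PARAM_INDEX["membrane.i_nak_max"]
IP_G_KATP = PARAM_INDEX["membrane.g_katp"]
IP_KATP_HALF = PARAM_INDEX["membrane.katp_half"]
IP_KATP_H = PARAM_INDEX["membrane.katp_h"]
IP_G_CAB = PARAM_INDEX["membrane.g_cab"]
IP_V_NCX = PARAM_INDEX["membrane.v_ncx"]
IP_K_NCX = PARAM_INDEX["membrane.k_ncx"]
IP_NAI = PARAM_INDEX["membrane.nai"]
IP_NAO = PARAM_INDEX["membrane.nao"]
IP_KI_ION = PARAM_INDEX["membrane.ki_ion"]
IP_KO = PARAM_INDEX["membrane.ko"]
IP_CAO = PARAM_INDEX["membrane.cao"]
IP_FLUX_CONV = PARAM_INDEX["membrane.flux_conv"]
IP_LCC_F_TAU = PARAM_INDEX["lcc.f_gate_tau"]
IP_LCC_F_TAU_REC = PARAM_INDEX["lcc.f_gate_tau_rec"]
IP_LCC_F_VHALF = PARAM_INDEX["lcc.f_gate_vhalf"]
IP_LCC_F_K = PARAM_INDEX["lcc.f_gate_k"]
IP_LCC_F_FLOOR = PARAM_INDEX["lcc.f_gate_floor"]
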