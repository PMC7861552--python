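"""Model parameters, lattice presets, and structured-text configuration.

Every physical constant of the model lives in one of the dataclasses below.
``CellParams.flatten()`` packs them into a flat float64 vector consumed by the
compiled stepping kernel; ``PARAM_ORDER`` fixes the packing order and is the
single source of truth shared with :mod:`mitoca.engine._kernel`.

Units throughout: time ms, voltage mV, cytosolic/SR/dyadic Ca2+ uM,
ATP/ADP mM, current densities uA/cm^2.  Fluxes are expressed per CRU in
cytosolic-volume units (uM/ms) unless noted.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import numpy as np
import yaml

__all__ = [
    "RyRParams",
    "SercaParams",
    "LCCParams",
    "CompartmentParams",
    "MPTPParams",
    "MitoParams",
    "SignalingParams",
    "MembraneParams",
    "StimulusSpec",
    "CellParams",
    "PARAM_ORDER",
    "PARAM_INDEX",
    "LATTICE_PRESETS",
    "load_config",
    "save_config",
    "ConfigError",
]


class ConfigError(ValueError):
    """Raised for invalid or inconsistent configuration input."""


@dataclass
class RyRParams:
    """RyR cluster gating: closed->open rate k12 = k_base*k_u*(1+dk_CaMKII+dk_ROS)*[Ca]_p^2.

    Clusters are closed -> open -> closed-refractory -> closed chains: channels
    leave the open state at ``k_close`` into a refractory state and recover at
    ``k_recover`` (release restitution).  The CaMKII- and ROS-dependent
    increments on k12 are saturating Hill functions of CaMKII activation and
    cytosolic ROS; ``dk_ros_max = 0`` disables the redox arm on RyRs.
    """

    n_per_cluster: int = 100          # channels per CRU
    k_base: float = 1.0               # composite with k_u (units absorbed)
    k_u: float = 8.0e-6              # uM^-2 ms^-1, calibrated
    k_close: float = 0.1              # open->refractory rate, ms^-1
    k_recover: float = 1.5e-3         # refractory->closed recovery, ms^-1
    k12_max: float = 30.0             # saturation cap on k12, ms^-1
    dk_camk_max: float = 0.3
    km_cam_ryr: float = 0.15          # half-max CaMKII activation fraction
    h_cam_ryr: float = 2.0
    dk_ros_max: float = 1.0
    km_ros_ryr: float = 0.6           # uM
    h_ros_ryr: float = 2.0
    g_rel: float = 2.0e-3             # release conductance, ms^-1 (cyt units)
    a_dyad: float = 400.0              # quasi-static dyad gain, uM/(uM/ms)


@dataclass
class SercaParams:
    """SERCA uptake with ATP, ROS, and CaMKII (phospholamban) modulation.

    J_up = v_up * f_ATP * f_ROS * c^2 / (c^2 + (k_i - PLB(a))^2); PLB is a
    saturating increasing function of CaMKII activation, so CaMKII lowers the
    effective half-max and raises uptake.
    """

    v_up: float = 0.4                 # uM/ms
    k_i: float = 0.55                 # uM half-max
    kd_ros: float = 0.6               # uM
    h_ros_serca: float = 2.0
    km_up_atp: float = 0.1            # mM
    ki_up: float = 0.14               # mM (ADP inhibition)
    ki_up_prime: float = 5.1          # mM (ADP inhibition)
    plb_max: float = 0.25             # uM max reduction of k_i
    plb_k: float = 0.15               # activation at half effect
    plb_h: float = 2.0


@dataclass
class LCCParams:
    """Stochastic L-type Ca2+ channels, one small cluster per CRU."""

    n_per_cru: int = 10
    r_open: float = 0.25              # ms^-1 maximal opening rate
    v_half_act: float = -10.0         # mV
    k_act: float = 6.0                # mV slope
    r_close: float = 0.2              # ms^-1 baseline closing
    k_ca_close: float = 1.0e-3        # ms^-1 per uM dyadic Ca (Ca-dep. inactivation)
    flux_amp: float = 5.0e-2          # uM/ms per open channel at V = -80
    camk_avail: float = 0.3           # fractional availability gain at full CaMKII
    f_gate_tau: float = 70.0          # ms, voltage-inactivation onset (depolarized)
    f_gate_tau_rec: float = 350.0     # ms, recovery from inactivation at rest
    f_gate_vhalf: float = -20.0
    f_gate_k: float = 5.0
    f_gate_floor: float = 0.05


@dataclass
class CompartmentParams:
    """Volumes (relative to local cytosol = 1), transfer rates, buffers."""

    v_sub: float = 0.1
    v_nsr: float = 0.02
    v_jsr: float = 0.01
    g_sub_cyt: float = 0.033          # submembrane->cytosol transfer, ms^-1
    g_tr: float = 1.0e-4              # NSR->JSR refill conductance, ms^-1
    g_leak: float = 1.5e-5            # NSR->cytosol leak, ms^-1
    d_cyt: float = 0.15               # inter-CRU cytosolic coupling, ms^-1
    d_nsr: float = 0.05               # inter-CRU NSR coupling, ms^-1
    # instantaneous (rapid) buffers: capacity B (uM), dissociation K (uM)
    buf_cyt_b: float = 50.0
    buf_cyt_k: float = 0.6
    buf_sub_b: float = 42.0
    buf_sub_k: float = 13.0
    buf_jsr_b: float = 4800.0          # calsequestrin
    buf_jsr_k: float = 600.0


@dataclass
class MPTPParams:
    """3-state mitochondrial permeability transition pore: C0 <-> C1 <-> O.

    The C0->C1 rate is mitochondrial-Ca2+ dependent,
    k_c0c1 = alpha0*(1 + 199*ca^h/(ca^h + ca0^h)); the C1->O rate is
    alpha_mptp*kc1o0.  Defaults are calibrated so alpha_mptp = 1 gives
    near-zero open probability and alpha_mptp = 60 gives ~30% under pacing.
    """

    alpha0: float = 2.0e-5            # ms^-1
    h_mptp: float = 2.0
    ca0: float = 0.35                 # uM half-max mitochondrial Ca2+
    kc1o0: float = 5.0e-4             # ms^-1 base C1->O
    koc1: float = 1.0e-2              # ms^-1 O->C1
    kc1c0: float = 1.85e-2             # ms^-1 C1->C0
    alpha_mptp: float = 1.0           # dimensionless pre-factor (>= 0)


@dataclass
class MitoParams:
    """Mitochondrial Ca2+ fluxes, membrane potential, ROS/ATP source behavior."""

    v_mcu: float = 3.5e-2             # uM/ms maximal uniporter flux (per CRU)
    k_mcu: float = 1.0                # uM cytosolic half-max
    v_mncx: float = 5.0e-3            # uM/ms maximal Na-Ca exchange efflux
    k_mncx: float = 0.3               # uM mitochondrial half-max
    g_ptp_rel: float = 5.0e-4        # ms^-1 conductive efflux when pore open
    alpha_mcu: float = 1.0            # dimensionless MCU pre-factor
    mncx_scale: float = 1.0           # 1 = control, 0 disables mNCX
    v_mito: float = 10.0              # effective mito volume per coupled CRU
    psi_polarized: float = 180.0      # mV
    psi_depolarized: float = 20.0     # mV
    tau_psi_depol: float = 50.0       # ms
    tau_psi_repol: float = 120.0      # ms
    psi_mcu_floor: float = 0.6       # MCU driving factor at full depolarization


@dataclass
class SignalingParams:
    """Slow variables: cytosolic ROS field, CaMKII activation, ATP/ADP pool.

    CaMKII activation follows logistic (autocatalytic) growth toward a
    drive-dependent quasi-steady level; ATP relaxes toward a level set by the
    fraction of polarized (ATP-producing) mitochondria.
    """

    ros_emit_polarized: float = 1.0e-3    # uM/ms per CRU
    ros_emit_depolarized: float = 2.0e-2  # uM/ms per CRU
    k_ros_scav: float = 1.0e-2            # ms^-1 first-order scavenging
    d_ros: float = 0.05                   # inter-CRU ROS coupling, ms^-1
    camk_growth: float = 3.9e-5           # ms^-1 logistic growth rate
    camk_floor: float = 4.0e-3            # resting activation fraction
    camk_max: float = 0.85                # activation ceiling
    k_ros_camk: float = 0.44              # uM, ROS drive half-max
    h_ros_camk: float = 3.4
    w_ca_camk: float = 0.02               # weight of the Ca2+ drive
    k_ca_camk: float = 0.5                # uM
    atp_rest: float = 5.0                 # mM
    adenine_pool: float = 5.05            # mM total ATP + ADP
    tau_atp: float = 3.0e5                # ms
    atp_frac_exp: float = 2.47             # ATP target = atp_rest * frac^exp


@dataclass
class MembraneParams:
    """Sarcolemmal ionic current set (rabbit-type action potential).

    Quantitative AP morphology is calibration, not specification: gates follow
    standard Hodgkin-Huxley forms with conductances exposed here.  Intracellular
    Na+ and K+ are fixed.
    """

    cm: float = 1.0                   # uF/cm^2
    g_na: float = 12.0
    g_nal: float = 6.5e-3
    g_k1: float = 0.3
    g_kr: float = 0.04
    g_ks: float = 0.05
    g_tof: float = 0.04
    g_tos: float = 0.02
    i_nak_max: float = 1.3
    g_katp: float = 0.05
    katp_half: float = 0.25           # mM ATP at half activation of I_K,ATP
    katp_h: float = 2.0
    g_cab: float = 5.0e-5
    v_ncx: float = 0.4                # uM/ms forward-mode NCX scale
    k_ncx: float = 2.5                # uM submembrane half-max
    nai: float = 10.0                 # mM, fixed
    nao: float = 140.0
    ki_ion: float = 140.0
    ko: float = 5.4
    cao: float = 1.8                  # mM
    flux_conv: float = 0.01           # uM/ms per uA/cm^2 (z = 2 Ca current)


@dataclass
class StimulusSpec:
    """Rectangular pacing pulse: ``amplitude`` during the first ``duration``
    ms of every ``period`` (PCL) ms."""

    amplitude: float = -80.0          # uA/cm^2
    duration: float = 0.5             # ms
    period: float = 500.0             # ms (PCL)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigError("stimulus duration must be > 0")
        if self.period <= self.duration:
            raise ConfigError("stimulus period must exceed duration")


# packing order for the kernel parameter vector: (section, field) pairs
_SECTIONS = (
    ("ryr", RyRParams),
    ("serca", SercaParams),
    ("lcc", LCCParams),
    ("compartments", CompartmentParams),
    ("mptp", MPTPParams),
    ("mito", MitoParams),
    ("signaling", SignalingParams),
    ("membrane", MembraneParams),
    ("stimulus", StimulusSpec),
)

PARAM_ORDER: list[str] = [
    f"{sec}.{f.name}" for sec, cls in _SECTIONS for f in fields(cls)
]
PARAM_INDEX: dict[str, int] = {name: i for i, name in enumerate(PARAM_ORDER)}

LATTICE_PRESETS: dict[str, tuple[tuple[int, int, int], tuple[int, int, int]]] = {
    "full": ((64, 28, 12), (64, 14, 6)),
    "medium": ((32, 14, 6), (32, 7, 3)),
    "reduced": ((16, 8, 4), (16, 4, 2)),
    "small": ((8, 4, 2), (8, 2, 1)),
}


@dataclass
class CellParams:
    """Complete parameter set of the cell model."""

    ryr: RyRParams = field(default_factory=RyRParams)
    serca: SercaParams = field(default_factory=SercaParams)
    lcc: LCCParams = field(default_factory=LCCParams)
    compartments: CompartmentParams = field(default_factory=CompartmentParams)
    mptp: MPTPParams = field(default_factory=MPTPParams)
    mito: MitoParams = field(default_factory=MitoParams)
    signaling: SignalingParams = field(default_factory=SignalingParams)
    membrane: MembraneParams = field(default_factory=MembraneParams)
    stimulus: StimulusSpec = field(default_factory=StimulusSpec)

    def flatten(self) -> np.ndarray:
        """Pack all parameters into the kernel vector (PARAM_ORDER order)."""
        out = np.empty(len(PARAM_ORDER), dtype=np.float64)
        for i, name in enumerate(PARAM_ORDER):
            sec, f = name.split(".")
            out[i] = float(getattr(getattr(self, sec), f))
        return out

    def copy(self) -> "CellParams":
        return dataclasses.replace(
            self, **{sec: dataclasses.replace(getattr(self, sec)) for sec, _ in _SECTIONS}
        )

    def with_overrides(self, overrides: dict[str, Any]) -> "CellParams":
        """Return a copy with dotted-name overrides, e.g. ``{"mptp.alpha_mptp": 60}``."""
        new = self.copy()
        for name, value in overrides.items():
            if name not in PARAM_INDEX:
                raise ConfigError(f"unknown parameter {name!r}")
            sec, f = name.split(".")
            setattr(getattr(new, sec), f, type(getattr(getattr(new, sec), f))(value))
        return new

    def to_dict(self) -> dict[str, Any]:
        return {sec: dataclasses.asdict(getattr(self, sec)) for sec, _ in _SECTIONS}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "CellParams":
        kwargs = {}
        for sec, seccls in _SECTIONS:
            if sec in d:
                known = {f.name for f in fields(seccls)}
                bad = set(d[sec]) - known
                if bad:
                    raise ConfigError(f"unknown parameter(s) in [{sec}]: {sorted(bad)}")
                kwargs[sec] = seccls(**d[sec])
        return cls(**kwargs)


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML configuration file (sections: geometry, parameters,
    protocol, clamps, scan)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"configuration root must be a mapping, got {type(cfg).__name__}")
    return cfg


def save_config(cfg: dict[str, Any], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
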