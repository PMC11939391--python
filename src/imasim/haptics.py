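"""Dual-channel electrocautery force model with thermal modulation.

The tool–tissue interaction force is decomposed into three channels:

* normal resistance   F_n  = clamp(k_d·d + c_d·v_n, 0, 5 N)
* tangential drag     F_t  = clamp(μ·F_n + k_c·v_t, 0, 2 N)
* thermal modulation  F_th = k_t·P·exp(−α_t·d)   (cautery active only)

with d the contact penetration depth, v_n / v_t the scalar normal and
tangential tool-tip speeds, P the electrosurgical power (typically 30–50 W)
and α_t a thermal decay coefficient. The 5 N / 2 N caps are hard saturation
limits of the mechanical channels. Per-layer coefficient sets (fascia softer
than vessel wall) are engine defaults, not literature values; they are all
exposed in configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

NORMAL_CAP = 5.0      # N
TANGENTIAL_CAP = 2.0  # N

__all__ = [
    "ForceParams",
    "ContactState",
    "normal_force",
    "tangential_force",
    "thermal_force",
    "total_force",
    "force_timeline",
    "LAYER_DEFAULTS",
    "NORMAL_CAP",
    "TANGENTIAL_CAP",
]


@dataclass(frozen=True)
class ForceParams:
    """Per-tissue-layer force coefficients (SI units)."""

    tissue_stiffness: float = 300.0     # k_d, N/m
    damping: float = 2.0                # c_d, N*s/m
    friction: float = 0.3               # mu
    cutting_resistance: float = 10.0    # k_c, N*s/m
    thermal_coeff: float = 0.004        # k_t, N/W
    power: float = 40.0                 # P, W
    thermal_decay: float = 150.0        # alpha_t, 1/m
    normal_cap: float = NORMAL_CAP
    tangential_cap: float = TANGENTIAL_CAP

    def __post_init__(self) -> None:
        for name in ("tissue_stiffness", "damping", "friction",
                     "cutting_resistance", "thermal_coeff", "power",
                     "thermal_decay", "normal_cap", "tangential_cap"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


#: Non-canonical per-layer defaults shipped with the example scenario:
#: fascia is softer and more frictional than the stiffer vessel wall;
#: coagulation mode trades power for a higher thermal coefficient.
LAYER_DEFAULTS: dict[str, ForceParams] = {
    "fascia": ForceParams(tissue_stiffness=200.0, friction=0.35,
                          thermal_coeff=0.004, power=40.0),
    "fat": ForceParams(tissue_stiffness=120.0, friction=0.25,
                       thermal_coeff=0.005, power=35.0),
    "vessel": ForceParams(tissue_stiffness=500.0, friction=0.2,
                          thermal_coeff=0.003, power=30.0),
}


def coagulation_params(p: ForceParams) -> ForceParams:
    """Coagulation-mode variant: lower power, stronger thermal coupling."""
    return replace(p, power=0.75 * p.power, thermal_coeff=1.5 * p.thermal_coeff)


@dataclass
class ContactState:
    """Instantaneous tool–tissue contact: depth, speeds, layer and cautery flag."""

    penetration_depth: float = 0.0
    normal_velocity: float = 0.0
    tangential_velocity: float = 0.0
    tissue_layer: str = "fascia"
    cautery_active: bool = False
    in_contact: bool = True


def normal_force(params: ForceParams, contact: ContactState) -> float:
    """Perpendicular tissue resistance, clamped into [0, 5 N]."""
    if not contact.in_contact:
        return 0.0
    d = contact.penetration_depth
    if d < 0:
        raise ValueError("penetration depth must be >= 0 while in contact")
    raw = params.tissue_stiffness * d + params.damping * contact.normal_velocity
    return float(np.clip(raw, 0.0, params.normal_cap))


def tangential_force(params: ForceParams, f_n: float,
                     contact: ContactState) -> float:
    """Lateral cutting resistance μ·F_n + k_c·v_t, clamped into [0, 2 N]."""
    if not contact.in_contact:
        return 0.0
    raw = params.friction * f_n + params.cutting_resistance * contact.tangential_velocity
    return float(np.clip(raw, 0.0, params.tangential_cap))


def thermal_force(params: ForceParams, contact: ContactState) -> float:
    """Thermal modulation k_t·P·exp(−α_t·d); zero unless cautery is active."""
    if not contact.cautery_active or not contact.in_contact:
        return 0.0
    return float(params.thermal_coeff * params.power
                 * np.exp(-params.thermal_decay * contact.penetration_depth))


def total_force(params: ForceParams, contact: ContactState
                ) -> tuple[float, dict[str, float]]:
    """Total force and its per-channel breakdown; the breakdown sums exactly."""
    f_n = normal_force(params, contact)
    f_t = tangential_force(params, f_n, contact)
    f_th = thermal_force(params, contact)
    breakdown = {"normal": f_n, "tangential": f_t, "thermal": f_th}
    return f_n + f_t + f_th, breakdown


def force_timeline(layer_params: dict[str, ForceParams],
                   times: np.ndarray, contacts: list[ContactState],
                   substep: float = 0.001) -> pd.DataFrame:
    """Force log on a 1 ms sub-stepped clock interpolating framewise contacts.

    ``contacts[k]`` describes the contact state over frame k (sampled at
    ``times[k]``, nominally 60 Hz); scalar depth/velocities are linearly
    interpolated between frames, while the layer and cautery flags are held
    from the earlier frame. Returns columns time_s, layer, F_n, F_t, F_th,
    F_total, clamped_n, clamped_t.
    """
    times = np.asarray(times, dtype=float)
    if len(times) != len(contacts):
        raise ValueError("times and contacts must have equal length")
    rows = []
    grid = np.arange(times[0], times[-1] + 0.5 * substep, substep)
    depth = np.interp(grid, times, [c.penetration_depth for c in contacts])
    vn = np.interp(grid, times, [c.normal_velocity for c in contacts])
    vt = np.interp(grid, times, [c.tangential_velocity for c in contacts])
    idx = np.clip(np.searchsorted(times, grid, side="right") - 1, 0, len(times) - 1)
    for t, d, n_, t_, k in zip(grid, depth, vn, vt, idx):
        base = contacts[int(k)]
        c = ContactState(max(0.0, d), n_, t_, base.tissue_layer,
                         base.cautery_active, base.in_contact)
        p = layer_params[c.tissue_layer]
        if c.cautery_active and getattr(base, "coagulation", False):
            p = coagulation_params(p)
        total, br = total_force(p, c)
        raw_n = p.tissue_stiffness * c.penetration_depth + p.damping * c.normal_velocity
        raw_t = p.friction * br["normal"] + p.cutting_resistance * c.tangential_velocity
        rows.append({"time_s": t, "layer": c.tissue_layer,
                     "F_n": br["normal"], "F_t": br["tangential"],
                     "F_th": br["thermal"], "F_total": total,
                     "clamped_n": bool(c.in_contact and raw_n > p.normal_cap),
                     "clamped_t": bool(c.in_contact and raw_t > p.tangential_cap)})
    return pd.DataFrame(rows)
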