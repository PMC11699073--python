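"""Whale-vessel encounter kernel.

Expected number of close approaches (within one whale body length, 13.5 m)
between one randomly moving whale and one vessel transiting a grid cell,
under the classic 2-D random-movement (ideal-gas) encounter model. Both
movers are treated as points in a cell of area A; an encounter is the
vessel passing within the detection radius R of the whale.

The encounter rate is the Gerritsen-Strickler swept-path form

    lambda_e = (2 R / A) * v_eff,   v_eff = (u^2 + 3 v^2) / (3 v)  for v >= u,

with v the vessel speed and u the whale swim speed (v_eff is the mean
relative speed of two independent random movers, to second order). For a
stationary whale this reduces exactly to the swept strip 2 R L / A with
L = v * t the path length. The product lambda_e * t is an expected count;
it is clamped onto [0, 1] only where it is consumed as a Bernoulli
probability (see the engine).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class EncounterParams:
    """Geometry of the encounter kernel.

    radius: detection radius, m (one right whale body length by default).
    whale_speed: whale swim speed u, m/s.
    cell_area: area of the model cell, m^2.
    """

    radius: float = 13.5
    whale_speed: float = 1.0
    cell_area: float = 1e8

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be non-negative")
        if self.cell_area <= 0:
            raise ValueError("cell_area must be positive")
        if self.whale_speed < 0:
            raise ValueError("whale_speed must be non-negative")


def effective_relative_speed(vessel_speed, whale_speed):
    """Mean relative speed of vessel (v) and whale (u) with random headings.

    (u^2 + 3 v^2) / (3 v) for v >= u; symmetric in the arguments otherwise.
    Vectorized over ``vessel_speed``.
    """
    v = np.asarray(vessel_speed, dtype=float)
    u = float(whale_speed)
    fast = np.maximum(v, u)
    slow = np.minimum(v, u)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(fast > 0, (slow**2 + 3 * fast**2) / (3 * np.where(fast > 0, fast, 1.0)), 0.0)
    return out if out.ndim else float(out)


def encounter_probability(params: EncounterParams, vessel_speed, transit_time):
    """Expected per-capita encounters lambda_e * t for one cell transit.

    vessel_speed is m/s, transit_time the seconds spent crossing the cell.
    Returns a dimensionless expected count >= 0 (NOT clamped here);
    vectorized over vessel_speed/transit_time.
    """
    v = np.asarray(vessel_speed, dtype=float)
    t = np.asarray(transit_time, dtype=float)
    if np.any(v <= 0):
        raise ValueError("vessel_speed must be positive")
    if np.any(t <= 0):
        raise ValueError("transit_time must be positive")
    v_eff = effective_relative_speed(v, params.whale_speed)
    out = (2.0 * params.radius / params.cell_area) * v_eff * t
    return out if np.ndim(out) else float(out)
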