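"""Vertical dive avoidance of an oncoming vessel.

A whale that detects a vessel at some reaction distance dives at a constant
descent rate from a random start depth. By the time the vessel arrives, the
whale is at

    whale_depth = start_depth + descent_rate * reaction_distance / vessel_speed.

It escapes the strike iff it is then below the vessel's strike zone
(draft x propeller-suction scalar) AND the water column leaves room for its
body below that zone: bottom_depth > strike_zone + whale_height. Both
inequalities are strict -- a tie counts as struck. In water shallower than
strike_zone + whale_height avoidance is geometrically impossible (for an
OGV with a 30 m strike zone and a 3 m whale, any bottom depth under 33 m is
an unavoidable zone).

Start depth, descent rate and reaction distance are drawn independently and
uniformly on their configured ranges (defaults: start 0 to class max draft;
descent 0.81-2.0 m/s from tagged right whales; reaction 10-1200 m).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class AvoidanceDraw:
    """One realisation of the three random avoidance inputs (m, m/s, m)."""

    start_depth: float
    descent_rate: float
    reaction_distance: float


def sample_avoidance_draw(
    rng: np.random.Generator,
    max_start_depth: float,
    descent_rate_range: tuple[float, float] = (0.81, 2.0),
    reaction_distance_range: tuple[float, float] = (10.0, 1200.0),
) -> AvoidanceDraw:
    """Independent uniforms on the configured ranges."""
    return AvoidanceDraw(
        start_depth=rng.uniform(0.0, max_start_depth),
        descent_rate=rng.uniform(*descent_rate_range),
        reaction_distance=rng.uniform(*reaction_distance_range),
    )


def strike_zone(draft: float, suction_scalar: float) -> float:
    """Depth band within which a whale can be struck: draft x suction scalar.

    The scalar is 1 for vessels under 350 ft and 2 for OGVs, whose propeller
    suction effectively doubles the hazardous depth (15 m draft -> 30 m).
    """
    if draft < 0:
        raise ValueError("draft must be non-negative")
    if suction_scalar < 0:
        raise ValueError("suction_scalar must be non-negative")
    return draft * suction_scalar


def whale_depth_at_arrival(draw: AvoidanceDraw, vessel_speed: float) -> float:
    """Whale depth (m below surface) when the vessel reaches it."""
    if vessel_speed <= 0:
        raise ValueError("vessel_speed must be positive")
    return draw.start_depth + draw.descent_rate * draw.reaction_distance / vessel_speed


def avoid_outcome(whale_depth, strike_zone_m, bottom_depth, whale_height):
    """1 if the whale escaped, else 0. Vectorized over any argument.

    Escape requires whale_depth > strike_zone AND
    bottom_depth > strike_zone + whale_height (strict).
    """
    wd = np.asarray(whale_depth, dtype=float)
    out = (wd > np.asarray(strike_zone_m)) & (
        np.asarray(bottom_depth) > np.asarray(strike_zone_m) + np.asarray(whale_height)
    )
    return out.astype(int) if out.ndim else int(out)
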