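"""Probability that a whale sits within a vessel's draft depth.

Regional tag data give the proportion of time right whales spend above 5 m
and above 15 m. Vessels under 350 ft draw at most ~5 m, ocean-going vessels
up to ~15 m, so the exposure probability is read off the profile at the
depth matching the size class, and realised per transit as a Bernoulli draw.
"""

from __future__ import annotations

import numpy as np

from .grid_io import RegionDepthProfile, SIZE_CLASS_BINS


def p_strike_depth(profile: RegionDepthProfile, size_class: str) -> float:
    """Exposure probability for a size class in a region.

    SmallMedium and Large use time above 5 m; OGV uses time above 15 m.
    """
    if size_class in ("SmallMedium", "Large"):
        return profile.p_above_5m
    if size_class == "OGV":
        return profile.p_above_15m
    raise KeyError(f"unknown size class {size_class!r}; expected one of {sorted(SIZE_CLASS_BINS)}")


def draw_at_depth(p: float, rng: np.random.Generator) -> int:
    """Bernoulli indicator: 1 if the whale is at strike depth."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    return int(rng.random() < p)
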