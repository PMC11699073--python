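"""Probability a vessel strike kills the whale.

A logistic regression in vessel speed (knots), vessel size class
(categorical), a whale-species indicator (humpback vs other large whale),
and the speed x species interaction:

    logit P(death | strike) = b0 + b_v * speed + b_size[class]
                              + b_sp * I + b_vsp * speed * I.

Right whales take the non-humpback level (I = 1 by convention here).
Coefficients are config inputs; the shipped defaults are qualitative
placeholders (see LethalityCoefficients), not fitted values.
"""

from __future__ import annotations

import numpy as np

from .grid_io import LethalityCoefficients


def lethality_probability(
    coeffs: LethalityCoefficients,
    speed_kn,
    size_class,
    species_indicator: int = 1,
):
    """Inverse-logit of the linear predictor; strictly inside (0, 1).

    Vectorized over ``speed_kn`` (with a scalar size class) for engine use.
    """
    speed = np.asarray(speed_kn, dtype=float)
    if np.any(speed < 0):
        raise ValueError("speed must be non-negative")
    if isinstance(size_class, str):
        if size_class not in coeffs.beta_size:
            raise KeyError(f"unknown size class {size_class!r}")
        size_term = coeffs.beta_size[size_class]
    else:
        size_term = np.array([_size_term(coeffs, s) for s in size_class])
    eta = (
        coeffs.intercept
        + coeffs.beta_speed * speed
        + size_term
        + coeffs.beta_species * species_indicator
        + coeffs.beta_speed_species * speed * species_indicator
    )
    out = 1.0 / (1.0 + np.exp(-eta))
    return out if np.ndim(out) else float(out)


def _size_term(coeffs: LethalityCoefficients, size_class: str) -> float:
    if size_class not in coeffs.beta_size:
        raise KeyError(f"unknown size class {size_class!r}")
    return coeffs.beta_size[size_class]
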