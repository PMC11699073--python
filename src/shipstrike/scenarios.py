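"""Counterfactual traffic transforms and scenario comparison.

The "slow-all" counterfactual caps every non-exempt transit travelling over
10 knots at a speed drawn uniformly from 9.5-10.0 knots, mirroring a
universal speed restriction with the usual exemptions (military, federal,
state law-enforcement vessels). The elapsed cell-crossing time is recomputed
from the segment length at the new speed, so the model captures the
trade-off that a slower vessel is easier to avoid and less lethal but spends
longer in the cell (this recomputation is configurable).

Comparisons between the real-world and slow-all runs rely on the engine's
shared per-(iteration, transit) draw scheme: all random inputs except speed
are held equal, so per-class differences isolate the speed effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .engine import MortalityResult, apportion_risk
from .grid_io import KNOTS_TO_MS

SLOW_SPEED_RANGE_KN = (9.5, 10.0)
SLOW_THRESHOLD_KN = 10.0


def slow_all_transform(
    transits: pd.DataFrame,
    rng: np.random.Generator,
    recompute_elapsed: bool = True,
) -> pd.DataFrame:
    """Cap non-exempt transits over 10 kn at Uniform(9.5, 10.0) kn.

    Exempt transits and transits at or below 10 kn pass through unchanged,
    so the transform is idempotent. With ``recompute_elapsed`` (default) the
    elapsed time of slowed transits becomes segment_length / new_speed.
    """
    out = transits.copy()
    mask = (~out["exempt"].astype(bool)) & (out["speed_kn"] > SLOW_THRESHOLD_KN)
    n = int(mask.sum())
    if n:
        new_speed = rng.uniform(*SLOW_SPEED_RANGE_KN, size=n)
        out.loc[mask, "speed_kn"] = new_speed
        if recompute_elapsed:
            out.loc[mask, "elapsed_s"] = (
                out.loc[mask, "segment_length_m"].to_numpy() / (new_speed * KNOTS_TO_MS)
            )
    return out


@dataclass
class ScenarioComparison:
    """Per-class percent decrease in mean mortality plus the risk-share-
    weighted overall decrease (weights = real-world risk apportionment)."""

    per_class: pd.DataFrame
    overall_decrease_pct: float


def compare_scenarios(
    result_real: MortalityResult, result_slow: MortalityResult
) -> ScenarioComparison:
    """100 x (mean_real - mean_slow) / mean_real per class; NaN where the
    real-world mean is zero (decrease undefined)."""
    real = result_real.class_means()
    slow = result_slow.class_means()
    rows = []
    for sc, m_real in real.items():
        m_slow = slow.get(sc, 0.0)
        dec = 100.0 * (m_real - m_slow) / m_real if m_real > 0 else float("nan")
        rows.append(
            {"size_class": sc, "mean_real": m_real, "mean_slow": m_slow, "decrease_pct": dec}
        )
    df = pd.DataFrame(rows)
    if any(v > 0 for v in real.values()):
        shares = apportion_risk(real)
        overall = float(
            sum(
                shares[r["size_class"]] / 100.0 * r["decrease_pct"]
                for r in rows
                if np.isfinite(r["decrease_pct"])
            )
        )
    else:
        overall = float("nan")
    return ScenarioComparison(per_class=df, overall_decrease_pct=overall)


def derive_correction_factor(
    registered_counts: Mapping[str, float], ais_counts: Mapping[str, float]
) -> float:
    """AIS-undercount correction from registration data, one size class.

    Both arguments map vessel category (e.g. fishing, passenger) to unique
    vessel counts. The factor is the AIS-count-weighted mean of per-category
    registered/AIS ratios, which equals total registered / total AIS over
    the categories present in the AIS data. A category registered but never
    observed on AIS carries no usable ratio and raises.
    """
    total_reg = 0.0
    total_ais = 0.0
    for cat, reg in registered_counts.items():
        ais = float(ais_counts.get(cat, 0.0))
        if reg < 0 or ais < 0:
            raise ValueError(f"category {cat!r}: counts must be non-negative")
        if ais == 0 and reg > 0:
            raise ValueError(f"category {cat!r}: registered vessels but zero AIS observations")
        total_reg += float(reg)
        total_ais += ais
    if total_ais == 0:
        raise ValueError("no AIS-observed vessels in any category")
    return total_reg / total_ais
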