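"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's closed-form code paths: the
encounter oracle simulates actual moving points, and the mortality oracle
integrates the avoidance draws numerically. They exist so the analytic
implementations can be checked against first principles.
"""

from __future__ import annotations

import numpy as np


def encounter_mc(
    radius: float,
    whale_speed: float,
    cell_area: float,
    vessel_speed: float,
    transit_time: float,
    n_samples: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Moving-points encounter probability on a toroidal cell.

    The cell is a square of side sqrt(cell_area) with periodic boundaries
    (preserving the uniform whale density the ideal-gas model assumes). The
    vessel moves along +x at constant speed; the whale starts uniformly with
    a uniform random heading and swims straight. An encounter is the minimum
    separation over the transit dropping below ``radius``. The relative
    motion is linear, so the minimum distance to each periodic image is a
    closed-form point-to-segment distance; images are enumerated over a
    lattice window wide enough to cover the whole relative displacement.

    Returns (probability, Monte-Carlo standard error).
    """
    rng = np.random.default_rng(seed)
    side = float(np.sqrt(cell_area))
    theta = rng.uniform(0.0, 2.0 * np.pi, n_samples)
    # relative start position (whale - vessel), uniform on the torus
    p0 = rng.uniform(-side / 2.0, side / 2.0, size=(n_samples, 2))
    w = np.stack(
        [whale_speed * np.cos(theta) - vessel_speed, whale_speed * np.sin(theta)], axis=1
    )
    # lattice window: relative path length / side, plus the start offset
    max_disp = (whale_speed + vessel_speed) * transit_time
    k = int(np.ceil(max_disp / side)) + 1
    offs = np.arange(-k, k + 1) * side
    ox, oy = np.meshgrid(offs, offs)
    lattice = np.stack([ox.ravel(), oy.ravel()], axis=1)  # (m, 2)

    hit = np.zeros(n_samples, dtype=bool)
    w2 = np.einsum("ij,ij->i", w, w)
    chunk = 20_000
    for lo in range(0, n_samples, chunk):
        hi = min(lo + chunk, n_samples)
        a = p0[lo:hi, None, :] - lattice[None, :, :]          # (c, m, 2)
        wc = w[lo:hi, None, :]
        tau = -np.einsum("cmk,cmk->cm", a, wc) / np.maximum(w2[lo:hi, None], 1e-300)
        tau = np.clip(tau, 0.0, transit_time)
        d = a + wc * tau[..., None]
        dmin = np.sqrt(np.einsum("cmk,cmk->cm", d, d)).min(axis=1)
        hit[lo:hi] = dmin < radius
    p = hit.mean()
    se = float(np.sqrt(max(p * (1 - p), 1e-300) / n_samples))
    return float(p), se


def p_avoid_numeric(
    strike_zone_m: float,
    max_start_depth: float,
    bottom_depth: float,
    whale_height: float,
    vessel_speed_ms: float,
    descent_rate_range: tuple[float, float] = (0.81, 2.0),
    reaction_distance_range: tuple[float, float] = (10.0, 1200.0),
    n_grid: int = 400,
) -> float:
    """P(avoid) marginal over the three uniform draws, by midpoint quadrature.

    Avoidance requires bottom_depth > strike_zone + whale_height and
    start + rate * dist / v > strike_zone. Conditional on (rate, dist),
    P over the uniform start depth is clip(1 - (SZ - rate*dist/v)/Dmax, 0, 1).
    """
    if not bottom_depth > strike_zone_m + whale_height:
        return 0.0
    d_lo, d_hi = descent_rate_range
    r_lo, r_hi = reaction_distance_range
    rates = d_lo + (np.arange(n_grid) + 0.5) / n_grid * (d_hi - d_lo)
    dists = r_lo + (np.arange(n_grid) + 0.5) / n_grid * (r_hi - r_lo)
    added = np.outer(rates, dists) / vessel_speed_ms
    p_start = np.clip(1.0 - (strike_zone_m - added) / max_start_depth, 0.0, 1.0)
    return float(p_start.mean())


def expected_mortality(prep_rows: list[dict], config) -> float:
    """Analytic expected annual mortality for a tiny transit set.

    Each row needs: p_enc (clamped strike probability), p_lethal, strike
    zone, class max draft, bottom depth, vessel speed (m/s), n_w. Sums
    p_enc * (1 - P(avoid)) * p_lethal * n_w.
    """
    total = 0.0
    for r in prep_rows:
        pa = (
            p_avoid_numeric(
                r["strike_zone"], r["max_start"], r["bottom"], config.whale_height,
                r["v_ms"], config.descent_rate_range, config.reaction_distance_range,
            )
            if config.avoidance_enabled
            else 0.0
        )
        total += r["p_enc"] * (1.0 - pa) * r["p_lethal"] * r["n_w"]
    return total
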