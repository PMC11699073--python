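"""Per-transit mortality composition and the bootstrap simulation.

For every vessel transit k through cell j in month i, one stochastic
replicate computes

    M_ijk = strike * (1 - avoid) * lethal * N_w(i, j)

where ``strike`` is Bernoulli with p = clamp(lambda_e * t * p_strike_depth
* correction, 0, 1) (the correction factor applies to the Small/Medium
class only), ``avoid`` is the deterministic dive-avoidance outcome of one
random (start depth, descent rate, reaction distance) draw, and ``lethal``
is Bernoulli with the logistic lethality probability. N_w is a real-valued
expected whale count, so contributions -- and annual totals -- are real.

Annual mortality M_year is the triple sum over months, cells, and transits;
with several years, each iteration reports the across-year mean. A
bootstrap run repeats this n_iterations times with fresh draws.

Randomness: iteration ``it`` uses one Generator seeded by
SeedSequence([seed, it]); every transit consumes exactly five uniforms in
sorted-transit_id order whether or not a strike occurs. Two scenarios with
the same transit ids (e.g. real-world vs slow-all) therefore share every
random input except what the changed speeds themselves alter -- the paired
design behind the speed-restriction comparison.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .avoidance import AvoidanceDraw, avoid_outcome, strike_zone, whale_depth_at_arrival
from .depth_exposure import p_strike_depth
from .encounter import EncounterParams, encounter_probability
from .grid_io import (
    KNOTS_TO_MS,
    DensitySurface,
    GridCell,
    RegionDepthProfile,
    RunConfig,
    ValidationError,
    VesselTransit,
)
from .lethality import lethality_probability

logger = logging.getLogger(__name__)

SIZE_CLASSES = ("SmallMedium", "Large", "OGV")


@dataclass
class Scenario:
    """One complete model input set.

    cells: retained grid cells (>= 3 m) keyed by cell_id, regions assigned.
    densities: monthly whale surfaces.
    transits: validated transit table (grid_io schema).
    profiles: regional depth-exposure profiles.
    """

    cells: dict[str, GridCell]
    densities: list[DensitySurface]
    transits: pd.DataFrame
    profiles: dict[str, RegionDepthProfile]


@dataclass
class MortalityResult:
    """Bootstrap output.

    iteration_totals: one row per (iteration, size_class) with the
    year-averaged annual mortality for that replicate.
    cell_month_mean: per (cell_id, month, size_class) mean annual mortality
    (averaged over iterations and years).
    summary: mean/sd/median per size class over iterations.
    """

    iteration_totals: pd.DataFrame
    cell_month_mean: pd.DataFrame
    summary: pd.DataFrame
    seed: int
    config_hash: str

    def class_means(self) -> dict[str, float]:
        return dict(zip(self.summary["size_class"], self.summary["mean"]))

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.iteration_totals.to_csv(out / "iteration_totals.csv", index=False)
        self.cell_month_mean.to_csv(out / "cell_month_mean.csv", index=False)
        self.summary.to_csv(out / "summary.csv", index=False)
        (out / "run_metadata.txt").write_text(
            f"seed: {self.seed}\nconfig_hash: {self.config_hash}\n"
        )


# ---------------------------------------------------------------------------
# preparation


@dataclass
class _Prepared:
    """Per-transit static arrays, sorted by transit_id."""

    n: int
    p_enc: np.ndarray          # clamped strike probability
    p_lethal: np.ndarray
    strike_zone: np.ndarray    # m
    max_start: np.ndarray      # class max draft, m
    bottom: np.ndarray         # m
    v_ms: np.ndarray
    n_w: np.ndarray
    class_idx: np.ndarray      # index into SIZE_CLASSES
    yc_idx: np.ndarray         # index into (year, class) groups
    years: list[int]
    cell_ids: np.ndarray
    months: np.ndarray


def transit_strike_probability(
    speed_kn: np.ndarray,
    elapsed_s: np.ndarray,
    size_class: Sequence[str],
    region: Sequence[str],
    profiles: Mapping[str, RegionDepthProfile],
    config: RunConfig,
) -> np.ndarray:
    """clamp(lambda_e * t * p_strike_depth * correction, 0, 1), vectorized."""
    params = EncounterParams(config.encounter_radius, config.whale_speed, config.cell_area)
    lam_t = encounter_probability(params, np.asarray(speed_kn) * KNOTS_TO_MS, elapsed_s)
    p_depth = np.array([p_strike_depth(profiles[r], s) for r, s in zip(region, size_class)])
    corr = np.where(np.asarray(size_class) == "SmallMedium", config.correction_factor, 1.0)
    return np.clip(lam_t * p_depth * corr, 0.0, 1.0)


def _prepare(scenario: Scenario, config: RunConfig) -> _Prepared:
    df = scenario.transits
    if config.years is not None:
        df = df[df["year"].isin(config.years)]
    known = df["cell_id"].isin(scenario.cells.keys())
    if not known.all():
        logger.info("dropping %d transits in cells excluded by the depth filter", int((~known).sum()))
        df = df[known]
    df = df.sort_values("transit_id", kind="stable").reset_index(drop=True)
    if df.empty:
        years = list(config.years) if config.years else []
        return _Prepared(
            0, *[np.empty(0) for _ in range(8)], np.empty(0, dtype=int),
            years, np.empty(0, dtype=object), np.empty(0, dtype=int),
        )

    density_lookup: dict[tuple[int, int], dict[str, float]] = {}
    for s in scenario.densities:
        unknown = set(s.values) - set(scenario.cells)
        if unknown:
            raise ValidationError(
                f"density surface {s.month}/{s.year} references cells absent from the grid: "
                f"{sorted(unknown)[:5]}"
            )
        density_lookup[(s.month, s.year)] = s.values

    sc = df["size_class"].to_numpy()
    region = np.array([scenario.cells[c].region for c in df["cell_id"]])
    bottom = np.array([scenario.cells[c].mean_depth for c in df["cell_id"]])
    speed_kn = df["speed_kn"].to_numpy(dtype=float)
    elapsed = df["elapsed_s"].to_numpy(dtype=float)
    p_enc = transit_strike_probability(speed_kn, elapsed, sc, region, scenario.profiles, config)
    p_leth = lethality_probability(
        config.lethality_coefficients, speed_kn, list(sc), config.species_indicator
    )
    sz = np.array([strike_zone(config.class_draft[s], config.suction_scalar[s]) for s in sc])
    max_start = np.array([config.class_draft[s] for s in sc])
    n_w = np.array(
        [
            density_lookup.get((m, y), {}).get(c, 0.0)
            for m, y, c in zip(df["month"], df["year"], df["cell_id"])
        ]
    )
    years = sorted(config.years) if config.years is not None else sorted(df["year"].unique().tolist())
    class_idx = np.array([SIZE_CLASSES.index(s) for s in sc])
    year_idx = np.array([years.index(int(y)) for y in df["year"]])
    return _Prepared(
        n=len(df),
        p_enc=p_enc,
        p_lethal=np.asarray(p_leth, dtype=float),
        strike_zone=sz,
        max_start=max_start,
        bottom=bottom,
        v_ms=speed_kn * KNOTS_TO_MS,
        n_w=n_w,
        class_idx=class_idx,
        yc_idx=year_idx * len(SIZE_CLASSES) + class_idx,
        years=[int(y) for y in years],
        cell_ids=df["cell_id"].to_numpy(),
        months=df["month"].to_numpy(dtype=int),
    )


def _iteration_contributions(prep: _Prepared, config: RunConfig, u: np.ndarray) -> np.ndarray:
    """Per-transit mortality contributions for one iteration's uniforms.

    ``u`` has shape (n, 5): strike, start depth, descent rate, reaction
    distance, lethality -- the same block a scalar simulate_transit consumes.
    """
    d_lo, d_hi = config.descent_rate_range
    r_lo, r_hi = config.reaction_distance_range
    strike = u[:, 0] < prep.p_enc
    whale_depth = prep.max_start * u[:, 1] + (d_lo + u[:, 2] * (d_hi - d_lo)) * (
        r_lo + u[:, 3] * (r_hi - r_lo)
    ) / prep.v_ms
    if config.avoidance_enabled:
        avoided = (whale_depth > prep.strike_zone) & (
            prep.bottom > prep.strike_zone + config.whale_height
        )
    else:
        avoided = np.zeros(prep.n, dtype=bool)
    lethal = u[:, 4] < prep.p_lethal
    return np.where(strike & ~avoided & lethal, prep.n_w, 0.0)


# ---------------------------------------------------------------------------
# public operations


def simulate_transit(
    transit: VesselTransit,
    cell: GridCell,
    n_w: float,
    profiles: Mapping[str, RegionDepthProfile],
    config: RunConfig,
    rng: np.random.Generator,
) -> float:
    """One stochastic replicate of one transit's mortality contribution.

    Consumes exactly five uniforms so that a loop over transits with a
    shared Generator reproduces the vectorized engine path bit-for-bit.
    """
    if cell.mean_depth < 3.0:
        raise ValidationError(f"cell {cell.cell_id} should have been removed by the depth filter")
    if n_w < 0:
        raise ValidationError("n_w must be non-negative")
    u = rng.random(5)
    sc = str(getattr(transit.size_class, "value", transit.size_class))
    p_enc = transit_strike_probability(
        np.array([transit.speed_kn]), np.array([transit.elapsed_s]),
        [sc], [cell.region], profiles, config,
    )[0]
    if not u[0] < p_enc:
        return 0.0
    d_lo, d_hi = config.descent_rate_range
    r_lo, r_hi = config.reaction_distance_range
    draw = AvoidanceDraw(
        start_depth=config.class_draft[sc] * u[1],
        descent_rate=d_lo + u[2] * (d_hi - d_lo),
        reaction_distance=r_lo + u[3] * (r_hi - r_lo),
    )
    sz = strike_zone(config.class_draft[sc], config.suction_scalar[sc])
    wd = whale_depth_at_arrival(draw, transit.speed_kn * KNOTS_TO_MS)
    avoided = (
        avoid_outcome(wd, sz, cell.mean_depth, config.whale_height)
        if config.avoidance_enabled
        else 0
    )
    if avoided:
        return 0.0
    p_leth = lethality_probability(
        config.lethality_coefficients, transit.speed_kn, sc, config.species_indicator
    )
    return float(n_w) if u[4] < p_leth else 0.0


def simulate_year(
    transits: pd.DataFrame,
    densities: list[DensitySurface],
    cells: Mapping[str, GridCell],
    profiles: Mapping[str, RegionDepthProfile],
    config: RunConfig,
    rng: np.random.Generator,
) -> dict[str, float]:
    """One replicate of annual mortality per size class (sum over the
    months/cells/transits supplied). Deterministic given the Generator state."""
    scenario = Scenario(dict(cells), densities, transits, dict(profiles))
    prep = _prepare(scenario, config)
    if prep.n == 0:
        return {s: 0.0 for s in SIZE_CLASSES}
    contrib = _iteration_contributions(prep, config, rng.random((prep.n, 5)))
    totals = np.bincount(prep.class_idx, weights=contrib, minlength=len(SIZE_CLASSES))
    n_years = max(len(prep.years), 1)
    return {s: float(t) / n_years for s, t in zip(SIZE_CLASSES, totals)}


def bootstrap_run(scenario: Scenario, config: RunConfig) -> MortalityResult:
    """n_iterations independent annual replicates with summary statistics.

    Iteration i draws from Generator(SeedSequence([config.seed, i])). With
    multiple years, each iteration's per-class value is the across-year mean
    of M_year.
    """
    prep = _prepare(scenario, config)
    n_it = config.n_iterations
    n_years = max(len(prep.years), 1)
    per_class = np.zeros((n_it, len(SIZE_CLASSES)))
    contrib_sum = np.zeros(prep.n)
    n_groups = n_years * len(SIZE_CLASSES)
    for it in range(n_it):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, it]))
        if prep.n == 0:
            continue
        contrib = _iteration_contributions(prep, config, rng.random((prep.n, 5)))
        contrib_sum += contrib
        yc = np.bincount(prep.yc_idx, weights=contrib, minlength=n_groups)
        per_class[it] = yc.reshape(n_years, len(SIZE_CLASSES)).mean(axis=0)

    iteration_totals = pd.DataFrame(
        {
            "iteration": np.repeat(np.arange(n_it), len(SIZE_CLASSES)),
            "size_class": np.tile(SIZE_CLASSES, n_it),
            "mortality": per_class.ravel(),
        }
    )
    if prep.n:
        per_transit_mean = contrib_sum / n_it
        cm = (
            pd.DataFrame(
                {
                    "cell_id": prep.cell_ids,
                    "month": prep.months,
                    "size_class": np.array(SIZE_CLASSES)[prep.class_idx],
                    "mean_mortality": per_transit_mean / n_years,
                }
            )
            .groupby(["cell_id", "month", "size_class"], as_index=False)["mean_mortality"]
            .sum()
        )
    else:
        cm = pd.DataFrame(columns=["cell_id", "month", "size_class", "mean_mortality"])
    summary = pd.DataFrame(
        {
            "size_class": SIZE_CLASSES,
            "mean": per_class.mean(axis=0),
            "sd": per_class.std(axis=0, ddof=1) if n_it > 1 else np.zeros(len(SIZE_CLASSES)),
            "median": np.median(per_class, axis=0),
        }
    )
    return MortalityResult(
        iteration_totals=iteration_totals,
        cell_month_mean=cm,
        summary=summary,
        seed=config.seed,
        config_hash=config.config_hash(),
    )


def apportion_risk(class_means: Mapping[str, float]) -> dict[str, float]:
    """Percent of total risk per size class (class mean / sum x 100)."""
    total = float(sum(class_means.values()))
    if total <= 0:
        raise ValueError("risk apportionment undefined: all class means are zero")
    return {k: 100.0 * v / total for k, v in class_means.items()}


def sensitivity_sweep(
    scenario: Scenario,
    config: RunConfig,
    parameter_grid: Mapping[str, Sequence],
) -> pd.DataFrame:
    """One-at-a-time parameter sweep, all runs sharing the base seed.

    Each grid entry names a RunConfig field and a list of values; every
    value is run with all other parameters at their baseline. Returns rows
    (parameter, value, size_class, mean, sd) with a leading baseline row set.
    """
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    for name in parameter_grid:
        if name not in valid:
            raise KeyError(f"unknown config parameter {name!r}")
    rows = []

    def _append(param: str, value, cfg: RunConfig) -> None:
        res = bootstrap_run(scenario, cfg)
        for _, r in res.summary.iterrows():
            rows.append(
                {"parameter": param, "value": value, "size_class": r["size_class"],
                 "mean": r["mean"], "sd": r["sd"]}
            )

    _append("baseline", None, config)
    for name, values in parameter_grid.items():
        for value in values:
            _append(name, value, config.replace(**{name: value}))
    return pd.DataFrame(rows, columns=["parameter", "value", "size_class", "mean", "sd"])
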