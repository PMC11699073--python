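"""Synthetic scenario generator.

Builds complete, statistically plausible inputs -- shelf bathymetry, monthly
whale-density surfaces, class-specific vessel traffic, and regional depth
profiles -- so the full pipeline runs end-to-end without any external data.

What it emulates: a coastal shelf deepening offshore (including cells
shallower than 3 m, which the depth filter removes, and cells shallower than
33 m, where OGV strikes are unavoidable); seasonally shifting density
hotspots (population concentrated in southern cells in winter, northern
foraging cells in summer, with part of the population outside the modelled
domain in summer); ocean-going traffic concentrated in offshore lanes,
Small/Medium traffic nearshore and summer-peaking, Large traffic spread
across the shelf.

What it does not emulate: port-network routing, track-level vessel
behaviour, whale movement; traffic is generated directly as independent
cell-crossing segments with elapsed time = segment length / speed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .engine import Scenario
from .grid_io import (
    DEFAULT_DEPTH_PROFILES,
    KNOTS_TO_MS,
    GridCell,
    RegionDepthProfile,
    ValidationError,
    assign_cell_region,
    filter_cells_by_depth,
    latitude_band_regions,
    write_cells,
    write_density,
    write_depth_profiles,
    write_transits,
)

#: Fraction of the population inside the modelled domain, by month (1-12).
#: High November-April (whales in U.S. waters), low June-September (much of
#: the population on Canadian feeding grounds).
DEFAULT_IN_DOMAIN_FRACTION = (0.9, 0.9, 0.9, 0.9, 0.7, 0.4, 0.4, 0.4, 0.4, 0.6, 0.9, 0.9)

#: Seasonal traffic multipliers (mean 1 after normalisation). Small/Medium
#: traffic peaks May-September; the other classes are near-constant.
_SM_SEASON = np.array([0.5, 0.5, 0.7, 1.0, 1.5, 1.8, 2.0, 1.9, 1.5, 0.8, 0.5, 0.5])
_FLAT_SEASON = np.ones(12)

_CATEGORIES = {
    "SmallMedium": ("fishing", "recreational", "passenger"),
    "Large": ("ferry", "fishing_industrial", "towing"),
    "OGV": ("cargo", "tanker", "cruise"),
}

_DRAFT_RANGES = {"SmallMedium": (1.0, 3.0), "Large": (3.0, 6.0), "OGV": (10.0, 15.0)}
_LENGTH_RANGES = {"SmallMedium": (26.0, 65.0), "Large": (65.0, 350.0), "OGV": (351.0, 1100.0)}


@dataclass(frozen=True)
class Hotspot:
    """One Gaussian density hotspot: grid-unit centre, spread (cells), and a
    12-vector of relative monthly amplitudes."""

    center: tuple[float, float]
    spread: float
    monthly_amplitude: tuple[float, ...]


def _default_hotspots(nx: int, ny: int) -> tuple[Hotspot, ...]:
    winter = (1.0, 1.0, 0.9, 0.7, 0.4, 0.1, 0.1, 0.1, 0.2, 0.5, 0.9, 1.0)
    summer = tuple(round(1.05 - w, 2) for w in winter)
    return (
        Hotspot((0.20 * nx, 0.20 * ny), 0.12 * ny, winter),   # southern calving grounds
        Hotspot((0.25 * nx, 0.80 * ny), 0.15 * ny, summer),   # northern foraging grounds
    )


@dataclass
class ScenarioSpec:
    """Parameters of one synthetic study scenario.

    ``traffic_intensity`` is the expected number of transits per retained
    cell per month (before the seasonal multiplier), per size class.
    ``speed_distributions`` are (mean, sd) knots; generated speeds are
    clipped into [0.2, 50]. ``population_total`` scales the density
    surfaces: each monthly surface sums to population_total x the in-domain
    fraction for that month.
    """

    grid_shape: tuple[int, int] = (20, 20)
    shelf_min_depth: float = 1.0
    shelf_max_depth: float = 200.0
    shelf_exponent: float = 1.5
    hotspots: tuple[Hotspot, ...] | None = None
    population_total: float = 350.0
    in_domain_fraction: tuple[float, ...] = DEFAULT_IN_DOMAIN_FRACTION
    traffic_intensity: dict[str, float] = field(
        default_factory=lambda: {"SmallMedium": 3.0, "Large": 4.0, "OGV": 2.0}
    )
    speed_distributions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"SmallMedium": (17.0, 6.0), "Large": (9.5, 3.0), "OGV": (13.0, 3.5)}
    )
    exempt_fraction: float = 0.05
    years: tuple[int, ...] = (2021,)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_total <= 0:
            raise ValidationError("population_total must be positive")
        if any(v < 0 for v in self.traffic_intensity.values()):
            raise ValidationError("traffic intensities must be non-negative")
        if len(self.in_domain_fraction) != 12:
            raise ValidationError("in_domain_fraction needs 12 monthly values")
        if self.hotspots is None:
            self.hotspots = _default_hotspots(*self.grid_shape)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioSpec":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "hotspots" in raw and raw["hotspots"] is not None:
            raw["hotspots"] = tuple(
                Hotspot(tuple(h["center"]), float(h["spread"]), tuple(h["monthly_amplitude"]))
                for h in raw["hotspots"]
            )
        for key in ("grid_shape", "in_domain_fraction", "years"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "speed_distributions" in raw:
            raw["speed_distributions"] = {k: tuple(v) for k, v in raw["speed_distributions"].items()}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown scenario keys: {sorted(unknown)}")
        return cls(**raw)


def _cell_id(x: int, y: int) -> str:
    return f"c{x:03d}_{y:03d}"


def generate_bathymetry(spec: ScenarioSpec) -> list[GridCell]:
    """Shelf bathymetry: depth a monotone function of offshore column index.

    depth(x) = min + (max - min) * (x / (nx-1))^exponent, identical down each
    column, so depth strictly increases offshore whenever max > min.
    Returns ALL cells (unfiltered, regions unassigned).
    """
    nx, ny = spec.grid_shape
    frac = (np.arange(nx) / max(nx - 1, 1)) ** spec.shelf_exponent
    depths = spec.shelf_min_depth + (spec.shelf_max_depth - spec.shelf_min_depth) * frac
    return [
        GridCell(cell_id=_cell_id(x, y), x_index=x, y_index=y, mean_depth=float(depths[x]))
        for x in range(nx)
        for y in range(ny)
    ]


def _retained_cells_with_regions(spec: ScenarioSpec) -> dict[str, GridCell]:
    nx, ny = spec.grid_shape
    bands = latitude_band_regions(ny)
    out = {}
    for c in filter_cells_by_depth(generate_bathymetry(spec)):
        out[c.cell_id] = dataclasses.replace(c, region=assign_cell_region(c, bands))
    return out


def generate_density(spec: ScenarioSpec) -> list["DensitySurface"]:
    """Monthly density surfaces from the hotspot mixture.

    Whale mass is placed only on retained (>= 3 m) cells -- a whale cannot
    occupy shallower water -- and each month is normalised so the surface
    sums to population_total x in_domain_fraction[month]. Surfaces are
    deterministic given the spec and repeated identically for every year.
    """
    from .grid_io import DensitySurface

    cells = _retained_cells_with_regions(spec)
    xs = np.array([c.x_index for c in cells.values()], dtype=float)
    ys = np.array([c.y_index for c in cells.values()], dtype=float)
    ids = list(cells)
    out = []
    for year in spec.years:
        for month in range(1, 13):
            w = np.zeros(len(ids))
            for h in spec.hotspots:
                amp = h.monthly_amplitude[month - 1]
                if amp <= 0:
                    continue
                d2 = (xs - h.center[0]) ** 2 + (ys - h.center[1]) ** 2
                w = w + amp * np.exp(-0.5 * d2 / h.spread**2)
            total = spec.population_total * spec.in_domain_fraction[month - 1]
            if w.sum() > 0 and total > 0:
                w = w * (total / w.sum())
            else:
                w = np.zeros(len(ids))
            out.append(DensitySurface(month, year, dict(zip(ids, w))))
    return out


def _spatial_weight(size_class: str, x: np.ndarray, nx: int) -> np.ndarray:
    if size_class == "OGV":  # shipping lane crossing the shelf
        return np.exp(-0.5 * ((x - 0.40 * nx) / (0.10 * nx)) ** 2)
    if size_class == "SmallMedium":  # nearshore
        return np.exp(-0.5 * ((x - 0.15 * nx) / (0.12 * nx)) ** 2)
    return 1.0 / (1.0 + x / nx)  # Large: broad over the shelf, mild nearshore tilt


def generate_traffic(spec: ScenarioSpec) -> pd.DataFrame:
    """Cell-crossing transit segments per class, Poisson counts per cell-month.

    The per-cell-month Poisson mean is traffic_intensity[class] x a spatial
    weight (normalised to mean 1 over retained cells) x a seasonal
    multiplier (normalised to mean 1 over months; Small/Medium peaks in
    summer). Speeds are Normal(mean, sd) clipped to [0.2, 50] kn; segment
    lengths uniform 2-10 km; elapsed time = length / speed. Byte-identical
    under the same spec and seed.
    """
    rng = np.random.default_rng(spec.seed)
    nx, ny = spec.grid_shape
    cells = _retained_cells_with_regions(spec)
    ids = list(cells)
    x = np.array([c.x_index for c in cells.values()], dtype=float)
    rows: list[dict] = []
    counter = 0
    for size_class, intensity in sorted(spec.traffic_intensity.items()):
        w = np.asarray(_spatial_weight(size_class, x, nx), dtype=float)
        w = w * (len(w) / w.sum())
        season = _SM_SEASON if size_class == "SmallMedium" else _FLAT_SEASON
        season = season / season.mean()
        mean_kn, sd_kn = spec.speed_distributions[size_class]
        lo_len, hi_len = _LENGTH_RANGES[size_class]
        lo_dr, hi_dr = _DRAFT_RANGES[size_class]
        cats = _CATEGORIES.get(size_class, ("other",))
        for year in spec.years:
            for month in range(1, 13):
                counts = rng.poisson(intensity * w * season[month - 1])
                for ci in np.nonzero(counts)[0]:
                    for _ in range(int(counts[ci])):
                        speed = round(float(np.clip(rng.normal(mean_kn, sd_kn), 0.2, 50.0)), 2)
                        seg = float(rng.uniform(2000.0, 10000.0))
                        rows.append(
                            {
                                "transit_id": f"t{counter:07d}",
                                "cell_id": ids[ci],
                                "month": month,
                                "year": year,
                                "category": cats[int(rng.integers(len(cats)))],
                                "size_class": size_class,
                                "length_ft": round(float(rng.uniform(lo_len, hi_len)), 1),
                                "draft_m": round(float(rng.uniform(lo_dr, hi_dr)), 2),
                                "speed_kn": speed,
                                "segment_length_m": round(seg, 1),
                                "elapsed_s": round(seg / (speed * KNOTS_TO_MS), 1),
                                "exempt": bool(rng.random() < spec.exempt_fraction),
                            }
                        )
                        counter += 1
    from .grid_io import TRANSIT_COLUMNS

    return pd.DataFrame(rows, columns=TRANSIT_COLUMNS)


def generate_scenario(
    spec: ScenarioSpec,
    profiles: Mapping[str, RegionDepthProfile] | None = None,
) -> Scenario:
    """Full scenario: retained/labelled cells, densities, traffic, profiles."""
    return Scenario(
        cells=_retained_cells_with_regions(spec),
        densities=generate_density(spec),
        transits=generate_traffic(spec),
        profiles=dict(profiles or DEFAULT_DEPTH_PROFILES),
    )


def write_scenario(scenario: Scenario, out_dir: str | Path) -> None:
    """Write a scenario as the four CSVs grid_io reads back."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_cells(scenario.cells, out / "cells.csv")
    write_density(scenario.densities, out / "density.csv")
    write_transits(scenario.transits, out / "transits.csv")
    write_depth_profiles(scenario.profiles, out / "depth_profiles.csv")
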