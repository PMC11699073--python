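"""Spatial/tabular data model and input handling.

The simulator operates on a planar 10 x 10 km model grid. Every input is
delimited text:

* transit table -- one row per vessel track segment crossing one grid cell,
  with header ``transit_id, cell_id, month, year, category, size_class,
  length_ft, draft_m, speed_kn, segment_length_m, elapsed_s, exempt``;
* density surface -- ``cell_id, month, year, n_w`` (expected whales per cell);
* bathymetry / cell table -- ``cell_id, x_index, y_index, mean_depth_m``
  (``cell_id, mean_depth_m`` alone is accepted when geometry is not needed);
* regional depth profiles -- ``region, p_above_5m, p_above_15m``.

Depths are metres, positive downward. Cells shallower than 3 m are removed
before simulation (a right whale cannot physically occupy them).
"""

from __future__ import annotations

import dataclasses
import enum
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Point, Polygon

logger = logging.getLogger(__name__)

KNOTS_TO_MS = 0.514444

#: Vessel length bins (feet) defining the three size classes.
SIZE_CLASS_BINS = {"SmallMedium": (26.0, 65.0), "Large": (65.0, 350.0), "OGV": (350.0, float("inf"))}

#: Fixed tie-break order for region assignment (south to north).
REGION_ORDER = ("Southeast", "MidAtlantic", "CapeCodBay", "Northeast")

TRANSIT_COLUMNS = [
    "transit_id", "cell_id", "month", "year", "category", "size_class",
    "length_ft", "draft_m", "speed_kn", "segment_length_m", "elapsed_s", "exempt",
]

MIN_SPEED_KN = 0.2
MAX_SPEED_KN = 50.0
MIN_CELL_DEPTH_M = 3.0


class SizeClass(str, enum.Enum):
    """Vessel size class by overall length: 26-65 ft, 65-350 ft, >350 ft."""

    SmallMedium = "SmallMedium"
    Large = "Large"
    OGV = "OGV"


class ValidationError(ValueError):
    """Raised when an input file violates its documented schema."""


@dataclass(frozen=True)
class GridCell:
    """One 10 x 10 km model cell.

    ``mean_depth`` is metres below the sea surface; ``region`` is one of the
    four behavioural sub-areas (Northeast, CapeCodBay, MidAtlantic,
    Southeast) and is assigned to every retained cell.
    """

    cell_id: str
    x_index: int
    y_index: int
    mean_depth: float
    area: float = 1e8
    region: str | None = None

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValidationError(f"cell {self.cell_id}: area must be positive")


@dataclass
class DensitySurface:
    """Expected whale count per cell for one calendar month of one year."""

    month: int
    year: int
    values: dict[str, float]

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValidationError(f"month {self.month} outside 1-12")
        bad = {c: v for c, v in self.values.items() if v < 0 or not np.isfinite(v)}
        if bad:
            raise ValidationError(f"negative/non-finite density values: {sorted(bad)[:5]}")

    @property
    def total(self) -> float:
        return float(sum(self.values.values()))


@dataclass
class VesselTransit:
    """One cell-crossing segment of one vessel track."""

    transit_id: str
    cell_id: str
    month: int
    year: int
    category: str
    size_class: SizeClass
    length_ft: float
    draft_m: float
    speed_kn: float
    segment_length_m: float
    elapsed_s: float
    exempt: bool


@dataclass(frozen=True)
class RegionDepthProfile:
    """Proportion of time a whale spends above 5 m and above 15 m in a region.

    Time above 5 m is a subset of time above 15 m, so
    ``p_above_5m <= p_above_15m`` always.
    """

    region: str
    p_above_5m: float
    p_above_15m: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_above_5m <= self.p_above_15m <= 1.0):
            raise ValidationError(
                f"{self.region}: need 0 <= p_above_5m <= p_above_15m <= 1, "
                f"got ({self.p_above_5m}, {self.p_above_15m})"
            )


#: Tag-derived regional exposure defaults (duration-weighted proportions of
#: time above 5 m / 15 m from 146 depth-recording tags).
DEFAULT_DEPTH_PROFILES: dict[str, RegionDepthProfile] = {
    "Northeast": RegionDepthProfile("Northeast", 0.392, 0.587),
    "CapeCodBay": RegionDepthProfile("CapeCodBay", 0.910, 0.953),
    "MidAtlantic": RegionDepthProfile("MidAtlantic", 0.876, 0.969),
    "Southeast": RegionDepthProfile("Southeast", 0.564, 0.930),
}


@dataclass
class LethalityCoefficients:
    """Logistic-regression coefficients for P(death | strike).

    Linear predictor: ``intercept + beta_speed*speed + beta_size[class]
    + beta_species*I + beta_speed_species*speed*I`` with speed in knots and
    ``I`` the species indicator (1 = non-humpback large whale; right whales
    use 1). The reference size class carries offset 0.

    The shipped defaults are NOT fitted values from any published strike
    database; they are a documented placeholder calibrated qualitatively so
    that lethality rises steeply with speed for vessels under 350 ft while
    strikes by ocean-going vessels are near-certainly lethal at any speed.
    Supply fitted coefficients for quantitative work.
    """

    intercept: float = -4.0
    beta_speed: float = 0.35
    beta_size: dict[str, float] = field(
        default_factory=lambda: {"SmallMedium": 0.0, "Large": 1.0, "OGV": 4.0}
    )
    beta_species: float = 0.0
    beta_speed_species: float = 0.0

    def linear_predictor(self, speed_kn: float, size_class: str, species_indicator: int = 1) -> float:
        if size_class not in self.beta_size:
            raise KeyError(f"unknown size class {size_class!r}")
        return (
            self.intercept
            + self.beta_speed * speed_kn
            + self.beta_size[size_class]
            + self.beta_species * species_indicator
            + self.beta_speed_species * speed_kn * species_indicator
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "LethalityCoefficients":
        """Load a two-column ``term, value`` table; size offsets use terms
        ``size_SmallMedium`` etc."""
        df = pd.read_csv(path)
        terms = dict(zip(df["term"], df["value"].astype(float)))
        beta_size = {k.removeprefix("size_"): v for k, v in terms.items() if k.startswith("size_")}
        return cls(
            intercept=terms.get("intercept", 0.0),
            beta_speed=terms.get("speed", 0.0),
            beta_size=beta_size or {s: 0.0 for s in SIZE_CLASS_BINS},
            beta_species=terms.get("species", 0.0),
            beta_speed_species=terms.get("speed_species", 0.0),
        )


@dataclass
class RunConfig:
    """All tunable simulation parameters with their field defaults.

    Units: radii/depths/heights in metres, speeds in m/s unless the name says
    knots, areas in m^2. ``class_draft`` is the class maximum draft used both
    for the strike zone and as the upper bound of the random whale start
    depth. ``suction_scalar`` multiplies draft into the strike zone
    (propeller suction doubles it for OGVs). ``correction_factor`` inflates
    Small/Medium encounter exposure to compensate for vessels without AIS.
    """

    n_iterations: int = 1000
    seed: int = 0
    years: list[int] | None = None
    encounter_radius: float = 13.5
    whale_speed: float = 1.0
    whale_height: float = 3.0
    cell_area: float = 1e8
    class_draft: dict[str, float] = field(
        default_factory=lambda: {"SmallMedium": 5.0, "Large": 5.0, "OGV": 15.0}
    )
    suction_scalar: dict[str, float] = field(
        default_factory=lambda: {"SmallMedium": 1.0, "Large": 1.0, "OGV": 2.0}
    )
    descent_rate_range: tuple[float, float] = (0.81, 2.0)
    reaction_distance_range: tuple[float, float] = (10.0, 1200.0)
    lethality_coefficients: LethalityCoefficients = field(default_factory=LethalityCoefficients)
    species_indicator: int = 1
    correction_factor: float = 3.5
    avoidance_enabled: bool = True

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValidationError("n_iterations must be >= 1")
        for name in ("descent_rate_range", "reaction_distance_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValidationError(f"{name}: min {lo} > max {hi}")
        if any(d <= 0 for d in self.class_draft.values()):
            raise ValidationError("class drafts must be positive")
        if self.correction_factor < 1:
            raise ValidationError("correction_factor must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "lethality_coefficients" in raw and isinstance(raw["lethality_coefficients"], dict):
            raw["lethality_coefficients"] = LethalityCoefficients(**raw["lethality_coefficients"])
        for name in ("descent_rate_range", "reaction_distance_range"):
            if name in raw:
                raw[name] = tuple(raw[name])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)


# ---------------------------------------------------------------------------
# operations


def size_class_from_length(length_ft: float) -> str | None:
    """Map vessel length (feet) to its size class; None below 26 ft."""
    if length_ft < 26.0:
        return None
    if length_ft < 65.0:
        return "SmallMedium"
    if length_ft <= 350.0:
        return "Large"
    return "OGV"


def load_and_filter_transits(path: str | Path, config: RunConfig | None = None) -> pd.DataFrame:
    """Read the transit table, drop erroneous records, assign size classes.

    Filters (all applied on load, matching the AIS cleaning rules): speeds
    above 50 kn or below 0.2 kn, zero/negative elapsed times, and lengths
    under 26 ft (below the smallest modelled class). Rows with known length
    get ``size_class`` reassigned from the length bins. Dropped counts are
    logged. Optionally restricts to ``config.years``.
    """
    df = pd.read_csv(path, dtype={"transit_id": str, "cell_id": str})
    missing = [c for c in TRANSIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"transit table missing columns: {missing}")
    df = df[TRANSIT_COLUMNS].copy()
    for col in ("month", "year"):
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0])
            raise ValidationError(f"row {row}: missing required field {col!r}")
        df[col] = df[col].astype(int)
    if ((df["month"] < 1) | (df["month"] > 12)).any():
        row = int(df.index[(df["month"] < 1) | (df["month"] > 12)][0])
        raise ValidationError(f"row {row}: field 'month' outside 1-12")
    df["exempt"] = df["exempt"].astype(bool)

    n0 = len(df)
    bad_speed = df["speed_kn"].isna() | (df["speed_kn"] > MAX_SPEED_KN) | (df["speed_kn"] < MIN_SPEED_KN)
    bad_time = df["elapsed_s"].isna() | (df["elapsed_s"] <= 0)
    too_small = df["length_ft"].notna() & (df["length_ft"] < 26.0)
    df = df[~(bad_speed | bad_time | too_small)].copy()
    logger.info(
        "transit filter: %d read, %d bad speed, %d bad elapsed time, %d under 26 ft, %d retained",
        n0, int(bad_speed.sum()), int(bad_time.sum()), int(too_small.sum()), len(df),
    )

    known_len = df["length_ft"].notna()
    df.loc[known_len, "size_class"] = df.loc[known_len, "length_ft"].map(size_class_from_length)
    bad_class = ~df["size_class"].isin(SIZE_CLASS_BINS)
    if bad_class.any():
        row = int(df.index[bad_class][0])
        raise ValidationError(
            f"row {row}: unknown size class {df.loc[row, 'size_class']!r} and no usable length"
        )
    if config is not None and config.years is not None:
        df = df[df["year"].isin(config.years)].copy()
    return df.reset_index(drop=True)


def impute_vessel_characteristics(
    transits: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Fill missing length/draft by uniform draws from same-category donors.

    Records with complete attributes pass through untouched; with a fixed
    seed the output is bit-reproducible. A category whose every record lacks
    an attribute has no donor pool and raises.
    """
    out = transits.copy()
    for attr in ("length_ft", "draft_m"):
        miss = out[attr].isna()
        if not miss.any():
            continue
        for cat, idx in out.index[miss].to_series().groupby(out.loc[miss, "category"]).groups.items():
            donors = out.loc[(out["category"] == cat) & out[attr].notna(), attr].to_numpy()
            if donors.size == 0:
                raise ValidationError(f"no donors with known {attr} in category {cat!r}")
            out.loc[idx, attr] = rng.choice(donors, size=len(idx))
    known_len = out["length_ft"].notna()
    out.loc[known_len, "size_class"] = out.loc[known_len, "length_ft"].map(size_class_from_length)
    return out


def aggregate_density_grid(fine: np.ndarray) -> np.ndarray:
    """Sum a fine 5-km density raster onto the 10-km grid (2x2 blocks).

    Abundance is additive, so each coarse value is the sum of its four nested
    fine cells; total abundance is conserved exactly.
    """
    fine = np.asarray(fine, dtype=float)
    if fine.ndim != 2 or fine.shape[0] % 2 or fine.shape[1] % 2:
        raise ValidationError(f"fine grid shape {fine.shape} does not nest 2x2 into a coarse grid")
    ny, nx = fine.shape
    return fine.reshape(ny // 2, 2, nx // 2, 2).sum(axis=(1, 3))


def filter_cells_by_depth(cells: Iterable[GridCell]) -> list[GridCell]:
    """Drop cells with mean depth < 3 m (strictly); a whale cannot swim there."""
    out = []
    for c in cells:
        if c.mean_depth is None or not np.isfinite(c.mean_depth):
            raise ValidationError(f"cell {c.cell_id}: missing mean depth")
        if c.mean_depth >= MIN_CELL_DEPTH_M:
            out.append(c)
    return out


def assign_cell_region(
    cell: GridCell, region_boundaries: Mapping[str, Polygon]
) -> str:
    """Label a cell with the behavioural region containing its centroid.

    Boundaries are config-supplied polygons in grid coordinates (cell
    centres at x_index + 0.5, y_index + 0.5). A centroid lying on a shared
    boundary is resolved by the fixed region order Southeast, MidAtlantic,
    CapeCodBay, Northeast; a centroid outside every region is an error.
    """
    pt = Point(cell.x_index + 0.5, cell.y_index + 0.5)
    for region in REGION_ORDER:
        poly = region_boundaries.get(region)
        if poly is not None and poly.covers(pt):
            return region
    for region, poly in region_boundaries.items():
        if region not in REGION_ORDER and poly.covers(pt):
            return region
    raise ValidationError(f"cell {cell.cell_id} centroid {pt.coords[0]} outside all regions")


def latitude_band_regions(ny: int) -> dict[str, Polygon]:
    """Four horizontal bands partitioning a grid of ``ny`` rows, south at y=0.

    A convenience default for synthetic planar scenarios; real analyses
    supply their own polygons.
    """
    edges = np.linspace(0, ny, 5)
    wide = (-1e6, 1e6)
    bands = {}
    for region, (lo, hi) in zip(REGION_ORDER, zip(edges[:-1], edges[1:])):
        bands[region] = Polygon(
            [(wide[0], lo), (wide[1], lo), (wide[1], hi), (wide[0], hi)]
        )
    return bands


# ---------------------------------------------------------------------------
# readers / writers


def read_cells(
    path: str | Path,
    region_boundaries: Mapping[str, Polygon] | None = None,
    cell_area: float = 1e8,
) -> dict[str, GridCell]:
    """Load the cell/bathymetry table, apply the 3 m depth filter, assign regions.

    Returns retained cells keyed by cell_id. If the table lacks x/y indices,
    region assignment requires the table to carry a ``region`` column.
    """
    df = pd.read_csv(path, dtype={"cell_id": str})
    if "mean_depth_m" not in df.columns:
        raise ValidationError("cell table needs a mean_depth_m column")
    has_xy = {"x_index", "y_index"}.issubset(df.columns)
    cells = []
    for i, row in df.iterrows():
        if pd.isna(row["mean_depth_m"]):
            raise ValidationError(f"row {i}: missing mean_depth_m")
        cells.append(
            GridCell(
                cell_id=row["cell_id"],
                x_index=int(row["x_index"]) if has_xy else 0,
                y_index=int(row["y_index"]) if has_xy else 0,
                mean_depth=float(row["mean_depth_m"]),
                area=cell_area,
                region=row.get("region") if "region" in df.columns else None,
            )
        )
    retained = filter_cells_by_depth(cells)
    logger.info("depth filter: %d cells read, %d retained (>= 3 m)", len(cells), len(retained))
    out = {}
    for c in retained:
        region = c.region
        if region is None or (isinstance(region, float) and np.isnan(region)):
            if region_boundaries is None or not has_xy:
                raise ValidationError(f"cell {c.cell_id}: no region and no boundaries supplied")
            region = assign_cell_region(c, region_boundaries)
        out[c.cell_id] = dataclasses.replace(c, region=region)
    return out


def read_density(path: str | Path) -> list[DensitySurface]:
    """Load ``cell_id, month, year, n_w`` into monthly surfaces."""
    df = pd.read_csv(path, dtype={"cell_id": str})
    need = {"cell_id", "month", "year", "n_w"}
    if not need.issubset(df.columns):
        raise ValidationError(f"density table needs columns {sorted(need)}")
    out = []
    for (month, year), grp in df.groupby(["month", "year"]):
        out.append(
            DensitySurface(int(month), int(year), dict(zip(grp["cell_id"], grp["n_w"].astype(float))))
        )
    return out


def read_depth_profiles(path: str | Path) -> dict[str, RegionDepthProfile]:
    df = pd.read_csv(path)
    return {
        row["region"]: RegionDepthProfile(row["region"], float(row["p_above_5m"]), float(row["p_above_15m"]))
        for _, row in df.iterrows()
    }


def write_transits(transits: pd.DataFrame, path: str | Path) -> None:
    transits[TRANSIT_COLUMNS].to_csv(path, index=False)


def write_density(surfaces: Sequence[DensitySurface], path: str | Path) -> None:
    rows = [
        {"cell_id": c, "month": s.month, "year": s.year, "n_w": v}
        for s in surfaces
        for c, v in sorted(s.values.items())
    ]
    pd.DataFrame(rows, columns=["cell_id", "month", "year", "n_w"]).to_csv(path, index=False)


def write_cells(cells: Mapping[str, GridCell] | Iterable[GridCell], path: str | Path) -> None:
    it = cells.values() if isinstance(cells, Mapping) else cells
    rows = [
        {
            "cell_id": c.cell_id, "x_index": c.x_index, "y_index": c.y_index,
            "mean_depth_m": c.mean_depth, "region": c.region,
        }
        for c in it
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_depth_profiles(profiles: Mapping[str, RegionDepthProfile], path: str | Path) -> None:
    rows = [
        {"region": p.region, "p_above_5m": p.p_above_5m, "p_above_15m": p.p_above_15m}
        for p in profiles.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def frame_to_transits(df: pd.DataFrame) -> list[VesselTransit]:
    """Typed row view of a validated transit table."""
    return [
        VesselTransit(
            transit_id=str(r.transit_id), cell_id=str(r.cell_id), month=int(r.month),
            year=int(r.year), category=str(r.category), size_class=SizeClass(r.size_class),
            length_ft=float(r.length_ft), draft_m=float(r.draft_m), speed_kn=float(r.speed_kn),
            segment_length_m=float(r.segment_length_m), elapsed_s=float(r.elapsed_s),
            exempt=bool(r.exempt),
        )
        for r in df.itertuples()
    ]
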