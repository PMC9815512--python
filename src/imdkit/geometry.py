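"""Device-centric ROI geometry.

Around each drug-release reservoir the tissue response is quantified inside
a circular region expanded up to ``max_extent`` micrometres from the
reservoir centre and divided into concentric annular sub-ROIs of equal
``depth`` (defaults: 1200 µm split into four 300 µm rings).  Cells are
assigned exclusively to their nearest reservoir so that neighbouring
regions never double-count.

Coordinates are Cartesian micrometres, origin bottom-left, y up.  Areas are
reported in mm².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, box

__all__ = [
    "RingSpec",
    "SubROI",
    "DeviceLayout",
    "CELL_TABLE_COLUMNS",
    "MARKERS",
    "validate_cell_table",
    "build_rings",
    "assign_cells",
    "region_area",
]

#: canonical marker columns of a cell table
MARKERS = ("CD3", "CD8", "FOXP3")

#: required columns of a cell table
CELL_TABLE_COLUMNS = ("cell_id", "x", "y", "tumor_id", "CD3", "CD8", "FOXP3", "nucleus")

UM2_PER_MM2 = 1e6


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class RingSpec:
    """Concentric sub-ROI layout around a reservoir.

    Parameters
    ----------
    max_extent : float
        Outer radius of the analysis region in µm (default 1200).
    depth : float
        Depth of each annular sub-ROI in µm (default 300).  ``max_extent``
        must be an integer multiple of ``depth``; anything else is an error
        rather than a silent truncation.
    """

    max_extent: float = 1200.0
    depth: float = 300.0

    def __post_init__(self) -> None:
        if not (self.max_extent > 0 and self.depth > 0):
            raise ValidationError("max_extent and depth must be positive")
        ratio = self.max_extent / self.depth
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValidationError(
                f"max_extent ({self.max_extent}) is not divisible by depth ({self.depth})"
            )

    @property
    def n_rings(self) -> int:
        return int(round(self.max_extent / self.depth))


@dataclass(frozen=True)
class SubROI:
    """One annular sub-ROI of one reservoir, half-open in radius."""

    reservoir_id: int
    ring_index: int
    inner: float
    outer: float
    area_mm2: float

    def __post_init__(self) -> None:
        if not self.inner < self.outer:
            raise ValidationError("SubROI requires inner < outer")


@dataclass
class DeviceLayout:
    """Reservoir positions and condition labels of one implanted device.

    ``reservoirs`` is a DataFrame with columns
    ``reservoir_id, x, y, condition, is_control``; control reservoirs are
    the empty ones used as the internal normalisation reference.
    """

    device_id: str
    reservoirs: pd.DataFrame = field(repr=False)

    REQUIRED = ("reservoir_id", "x", "y", "condition", "is_control")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.reservoirs.columns]
        if missing:
            raise ValidationError(f"layout missing columns: {missing}")
        res = self.reservoirs.copy()
        res["reservoir_id"] = res["reservoir_id"].astype(int)
        res["is_control"] = res["is_control"].astype(bool)
        if res["reservoir_id"].duplicated().any():
            raise ValidationError("reservoir ids must be unique")
        if not np.isfinite(res[["x", "y"]].to_numpy(float)).all():
            raise ValidationError("reservoir coordinates must be finite")
        self.reservoirs = res.sort_values("reservoir_id").reset_index(drop=True)

    @classmethod
    def from_records(cls, device_id: str, records: Iterable[tuple]) -> "DeviceLayout":
        df = pd.DataFrame(records, columns=list(cls.REQUIRED))
        return cls(device_id, df)

    @property
    def controls(self) -> pd.DataFrame:
        return self.reservoirs[self.reservoirs["is_control"]]

    @property
    def conditions(self) -> list[str]:
        mask = ~self.reservoirs["is_control"]
        return sorted(self.reservoirs.loc[mask, "condition"].unique())

    def require_control(self) -> None:
        if self.controls.empty:
            raise ValidationError(
                f"device {self.device_id} has no empty control reservoir"
            )

    def to_geojson(self) -> dict:
        feats = []
        for _, r in self.reservoirs.iterrows():
            feats.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [float(r.x), float(r.y)]},
                    "properties": {
                        "reservoir_id": int(r.reservoir_id),
                        "condition": str(r.condition),
                        "is_control": bool(r.is_control),
                    },
                }
            )
        return {
            "type": "FeatureCollection",
            "features": feats,
            "properties": {"device_id": self.device_id, "units": "um"},
        }


def validate_cell_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Check the cell-table schema and coordinate finiteness."""
    missing = [c for c in CELL_TABLE_COLUMNS if c not in cells.columns]
    if missing:
        raise ValidationError(f"cell table missing columns: {missing}")
    xy = cells[["x", "y"]].to_numpy(float)
    if not np.isfinite(xy).all():
        raise ValidationError("cell coordinates must be finite")
    return cells


def build_rings(spec: RingSpec) -> list[tuple[float, float]]:
    """Half-open annuli ``[inner, outer)`` tiling ``[0, max_extent)``.

    ``RingSpec(1200, 300)`` gives ``[(0, 300), (300, 600), (600, 900),
    (900, 1200)]`` — the four 300 µm-deep sub-ROIs.
    """
    edges = np.arange(spec.n_rings + 1) * spec.depth
    return [(float(a), float(b)) for a, b in zip(edges[:-1], edges[1:])]


def assign_cells(
    cells: pd.DataFrame, layout: DeviceLayout, spec: RingSpec | None = None
) -> pd.DataFrame:
    """Assign each cell to its nearest reservoir and containing ring.

    Returns a copy of ``cells`` with columns ``reservoir_id`` (nullable int;
    <NA> for cells farther than ``max_extent`` from every reservoir),
    ``ring`` (nullable int) and ``distance`` (µm to the nearest reservoir).
    Ties in distance go to the lowest reservoir id.  Ring membership uses
    half-open intervals, so a cell at exactly 300 µm falls in ring 1.
    """
    spec = spec or RingSpec()
    if not {"x", "y"} <= set(cells.columns):
        raise ValidationError("cells need x and y columns")
    if layout.reservoirs.empty:
        raise ValidationError("empty device layout")
    res = layout.reservoirs  # already sorted by reservoir_id
    xy = cells[["x", "y"]].to_numpy(float)
    centers = res[["x", "y"]].to_numpy(float)
    # (n_cells, n_reservoirs) distances; argmin returns the first minimum,
    # which is the lowest reservoir_id because rows are id-sorted
    d = np.sqrt(((xy[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2))
    nearest = d.argmin(axis=1)
    dist = d[np.arange(len(xy)), nearest]
    out = cells.copy()
    out["distance"] = dist
    within = dist < spec.max_extent
    rid = pd.array(res["reservoir_id"].to_numpy()[nearest], dtype="Int64")
    rid[~within] = pd.NA
    ring = pd.array(np.floor(dist / spec.depth).astype(int), dtype="Int64")
    ring[~within] = pd.NA
    out["reservoir_id"] = rid
    out["ring"] = ring
    return out


def region_area(
    center: tuple[float, float],
    inner: float,
    outer: float,
    tissue_bounds: tuple[float, float, float, float] | None = None,
    quad_segs: int = 128,
) -> float:
    """Area (mm²) of an annulus clipped to rectangular tissue bounds.

    ``tissue_bounds`` is ``(xmin, ymin, xmax, ymax)`` in µm; ``None`` gives
    the unclipped analytic area.  Clipping uses a polygonal approximation of
    the circle whose relative error at the default resolution is < 1 %.
    """
    if not 0 <= inner < outer:
        raise ValidationError("require 0 <= inner < outer")
    if tissue_bounds is None:
        return float(np.pi * (outer**2 - inner**2) / UM2_PER_MM2)
    xmin, ymin, xmax, ymax = tissue_bounds
    if not (xmax > xmin and ymax > ymin):
        raise ValidationError("degenerate tissue bounds")
    cx, cy = center
    if (
        cx - outer >= xmin
        and cx + outer <= xmax
        and cy - outer >= ymin
        and cy + outer <= ymax
    ):
        # annulus entirely inside the tissue: closed form, no clipping
        return float(np.pi * (outer**2 - inner**2) / UM2_PER_MM2)
    disc = Point(center).buffer(outer, quad_segs=quad_segs)
    if inner > 0:
        disc = disc.difference(Point(center).buffer(inner, quad_segs=quad_segs))
    clipped = disc.intersection(box(xmin, ymin, xmax, ymax))
    return float(clipped.area / UM2_PER_MM2)


def sub_rois(
    layout: DeviceLayout,
    spec: RingSpec,
    tissue_bounds: tuple[float, float, float, float] | None = None,
) -> list[SubROI]:
    """All (reservoir, ring) sub-ROIs of a layout with clipped areas."""
    rings = build_rings(spec)
    rois = []
    for _, r in layout.reservoirs.iterrows():
        for i, (inner, outer) in enumerate(rings):
            area = region_area((r.x, r.y), inner, outer, tissue_bounds)
            rois.append(SubROI(int(r.reservoir_id), i, inner, outer, area))
    return rois


def sub_rois_geojson(layout: DeviceLayout, spec: RingSpec) -> dict:
    """Sub-ROIs as GeoJSON polygons (annuli with holes) for overlays."""
    feats = []
    for _, r in layout.reservoirs.iterrows():
        for i, (inner, outer) in enumerate(build_rings(spec)):
            ring = Point(r.x, r.y).buffer(outer, quad_segs=64)
            if inner > 0:
                ring = ring.difference(Point(r.x, r.y).buffer(inner, quad_segs=64))
            feats.append(
                {
                    "type": "Feature",
                    "geometry": ring.__geo_interface__,
                    "properties": {
                        "reservoir_id": int(r.reservoir_id),
                        "ring_index": i,
                        "inner_um": inner,
                        "outer_um": outer,
                    },
                }
            )
    return {"type": "FeatureCollection", "features": feats}
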