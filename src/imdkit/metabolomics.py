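"""Marker-guided paired-ROI spatial metabolomics.

The procedure links immune hotspots seen by multiplex IF to metabolite
abundance measured on a co-registered MALDI ion-count raster:

1. a kernel-smoothed marker-density map is built on the ion-image grid;
2. hotspots are the connected components above a density quantile, each
   converted to a fixed-area disc at its density-weighted centroid;
3. every hotspot is coupled with the nearest disjoint disc of equal area
   whose marker count is lower by at least ``min_fold`` log2 units — the
   matched marker-low control region;
4. raw ion counts per metabolite are extracted for both discs of each pair
   and compared with a paired two-tailed t test on per-pair log2 fold
   changes, BH-adjusted across metabolites;
5. significant lists feed the shared hypergeometric over-representation
   test, correlation "signature" matrices, and the opposite-trend screen
   between two marker populations.

All coordinates are µm (origin bottom-left, y up); areas mm².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .enrichment import bh_adjust, hypergeom_ora
from .geometry import ValidationError

__all__ = [
    "IonImage",
    "HotspotROI",
    "ROIPair",
    "density_map",
    "detect_hotspots",
    "pair_rois",
    "extract_ion_counts",
    "paired_stats",
    "signature_matrix",
    "opposite_trend",
    "PairedMetabolomicsModel",
    "PairedMetabolomicsResults",
]

UM2_PER_MM2 = 1e6


@dataclass
class IonImage:
    """Pixel raster of raw ion counts, one channel per metabolite.

    ``counts`` has shape ``(n_channels, ny, nx)``; pixel (row j, col i) is
    centred at ``origin + ((i + 0.5) * pixel_size, (j + 0.5) * pixel_size)``.
    """

    pixel_size: float
    counts: np.ndarray = field(repr=False)
    channels: list[str]
    origin: tuple[float, float] = (0.0, 0.0)
    mz: list[float] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3 or self.counts.shape[0] != len(self.channels):
            raise ValidationError("counts must be (n_channels, ny, nx)")
        if len(set(self.channels)) != len(self.channels):
            raise ValidationError("channel names must be unique")
        if (self.counts < 0).any():
            raise ValidationError("ion counts must be non-negative")
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        return self.counts[self.channels.index(name)]

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) µm coordinate arrays of pixel centres, shape (ny, nx)."""
        ny, nx = self.shape
        x = self.origin[0] + (np.arange(nx) + 0.5) * self.pixel_size
        y = self.origin[1] + (np.arange(ny) + 0.5) * self.pixel_size
        return np.meshgrid(x, y)

    def to_long(self) -> pd.DataFrame:
        """Long-format table (x, y, metabolite, count), the text dialect."""
        X, Y = self.pixel_centers()
        frames = []
        for c, name in enumerate(self.channels):
            frames.append(
                pd.DataFrame(
                    {
                        "x": X.ravel(),
                        "y": Y.ravel(),
                        "metabolite": name,
                        "count": self.counts[c].ravel(),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class HotspotROI:
    """A fixed-area disc at a marker-density hotspot (or its matched low)."""

    roi_id: int
    marker: str
    center: tuple[float, float]
    radius: float
    marker_count: int

    @property
    def area_mm2(self) -> float:
        return float(np.pi * self.radius**2 / UM2_PER_MM2)

    @property
    def centroid(self) -> tuple[float, float]:
        return self.center

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (x - self.center[0]) ** 2 + (y - self.center[1]) ** 2 <= self.radius**2

    def overlaps(self, other: "HotspotROI") -> bool:
        d = np.hypot(
            self.center[0] - other.center[0], self.center[1] - other.center[1]
        )
        return d < self.radius + other.radius


@dataclass(frozen=True)
class ROIPair:
    """A marker-high disc matched to an equal-area nearby marker-low disc."""

    high: HotspotROI
    low: HotspotROI
    marker: str

    @property
    def area_ratio(self) -> float:
        return self.high.area_mm2 / self.low.area_mm2

    @property
    def count_log2fc(self) -> float:
        return float(
            np.log2((self.high.marker_count + 0.5) / (self.low.marker_count + 0.5))
        )

    @property
    def separation(self) -> float:
        return float(
            np.hypot(
                self.high.center[0] - self.low.center[0],
                self.high.center[1] - self.low.center[1],
            )
        )


def density_map(
    cells: pd.DataFrame,
    marker: str,
    grid: IonImage,
    bandwidth: float = 250.0,
) -> np.ndarray:
    """Kernel-smoothed marker-positive cell density on the ion-image grid.

    Marker-positive cells are binned at the grid resolution and smoothed
    with a Gaussian of ``bandwidth`` µm; edge attenuation is corrected by
    dividing by the smoothed coverage mask and the map rescaled so it
    integrates exactly to the number of marker-positive cells on the grid.
    Returned units: cells/mm².
    """
    if bandwidth <= 0:
        raise ValidationError("bandwidth must be positive")
    ny, nx = grid.shape
    pos = cells[cells[marker].astype(bool)]
    x0, y0 = grid.origin
    px = grid.pixel_size
    hist, _, _ = np.histogram2d(
        pos["y"].to_numpy(float),
        pos["x"].to_numpy(float),
        bins=(ny, nx),
        range=((y0, y0 + ny * px), (x0, x0 + nx * px)),
    )
    total = hist.sum()
    if total == 0:
        warnings.warn(f"no {marker}-positive cells on the grid; density map is zero")
        return np.zeros((ny, nx))
    sigma = bandwidth / px
    smooth = ndimage.gaussian_filter(hist, sigma=sigma, mode="constant")
    cover = ndimage.gaussian_filter(np.ones_like(hist), sigma=sigma, mode="constant")
    dens = smooth / cover
    dens *= total / dens.sum()  # exact mass conservation after edge correction
    pixel_area_mm2 = px**2 / UM2_PER_MM2
    return dens / pixel_area_mm2


def _marker_count(cells: pd.DataFrame, marker: str, center, radius) -> int:
    pos = cells[cells[marker].astype(bool)]
    d2 = (pos["x"].to_numpy(float) - center[0]) ** 2 + (
        pos["y"].to_numpy(float) - center[1]
    ) ** 2
    return int((d2 <= radius**2).sum())


def detect_hotspots(
    dens: np.ndarray,
    grid: IonImage,
    cells: pd.DataFrame,
    marker: str,
    quantile: float = 0.95,
    min_area_mm2: float = 0.05,
    roi_radius: float = 400.0,
) -> list[HotspotROI]:
    """Hotspots = connected super-quantile regions → fixed-area discs.

    The density map is thresholded at its ``quantile``; connected components
    smaller than ``min_area_mm2`` are dropped; each surviving component
    becomes a disc of radius ``roi_radius`` at the component's
    density-weighted centroid, with the marker count re-measured from the
    cell table inside the disc.  Hotspots are ordered by descending marker
    count (ties by ascending roi id assignment order).
    """
    if not 0 < quantile < 1:
        raise ValidationError("quantile must be in (0, 1)")
    thr = np.quantile(dens, quantile)
    mask = dens > thr
    if not mask.any():
        return []
    labels, n = ndimage.label(mask)
    px_area = grid.pixel_size**2 / UM2_PER_MM2
    X, Y = grid.pixel_centers()
    out = []
    rid = 0
    for lab in range(1, n + 1):
        comp = labels == lab
        if comp.sum() * px_area < min_area_mm2:
            continue
        w = dens[comp]
        cx = float((X[comp] * w).sum() / w.sum())
        cy = float((Y[comp] * w).sum() / w.sum())
        count = _marker_count(cells, marker, (cx, cy), roi_radius)
        out.append(HotspotROI(rid, marker, (cx, cy), roi_radius, count))
        rid += 1
    out.sort(key=lambda h: (-h.marker_count, h.roi_id))
    return out


def pair_rois(
    hotspots: Sequence[HotspotROI],
    cells: pd.DataFrame,
    grid: IonImage,
    min_fold: float = 0.5,
    max_separation: float = 4000.0,
    n_angles: int = 16,
    step: float | None = None,
) -> list[ROIPair]:
    """Couple each hotspot with a nearby equal-area marker-low disc.

    Candidate disc centres are scanned outward from each hotspot on rings of
    increasing radius (``step`` defaults to the grid pixel size) and
    ``n_angles`` evenly spaced angles per ring, nearest first.  The first
    candidate that (a) does not overlap any hotspot or previously accepted
    region, (b) lies fully on the grid within ``max_separation``, and
    (c) satisfies ``log2((n_high + 0.5) / (n_low + 0.5)) >= min_fold`` on
    marker counts, is accepted.  Hotspots with no valid candidate are
    skipped (logged via warning).  Hotspots are processed by descending
    marker count, so richer hotspots claim low regions first; the scan
    order makes the outcome deterministic.
    """
    if min_fold < 0 or max_separation <= 0:
        raise ValidationError("invalid pairing parameters")
    step = step or grid.pixel_size
    ny, nx = grid.shape
    x0, y0 = grid.origin
    x1, y1 = x0 + nx * grid.pixel_size, y0 + ny * grid.pixel_size
    taken: list[HotspotROI] = list(hotspots)
    pairs: list[ROIPair] = []
    marker = hotspots[0].marker if hotspots else None
    for hs in sorted(hotspots, key=lambda h: (-h.marker_count, h.roi_id)):
        r = hs.radius
        found = None
        dist = 2 * r + step
        while found is None and dist <= max_separation:
            for k in range(n_angles):
                ang = 2 * np.pi * k / n_angles
                cx = hs.center[0] + dist * np.cos(ang)
                cy = hs.center[1] + dist * np.sin(ang)
                if not (x0 + r <= cx <= x1 - r and y0 + r <= cy <= y1 - r):
                    continue
                cand = HotspotROI(-1, marker, (cx, cy), r, 0)
                if any(cand.overlaps(t) for t in taken):
                    continue
                n_low = _marker_count(cells, marker, (cx, cy), r)
                fc = np.log2((hs.marker_count + 0.5) / (n_low + 0.5))
                if fc >= min_fold:
                    found = HotspotROI(
                        1000 + hs.roi_id, marker, (cx, cy), r, n_low
                    )
                    break
            dist += step
        if found is None:
            warnings.warn(f"hotspot {hs.roi_id}: no equal-area low region found")
            continue
        taken.append(found)
        pairs.append(ROIPair(hs, found, marker))
    return pairs


def extract_ion_counts(image: IonImage, roi: HotspotROI) -> pd.DataFrame:
    """Total and mean raw ion counts per metabolite over a disc ROI.

    A pixel belongs to the ROI when its centre falls inside the disc.
    """
    X, Y = image.pixel_centers()
    inside = roi.contains(X, Y)
    n_px = int(inside.sum())
    if n_px == 0:
        raise ValidationError("ROI covers no pixel centres of the grid")
    totals = image.counts[:, inside].sum(axis=1)
    return pd.DataFrame(
        {
            "metabolite": image.channels,
            "total": totals.astype(float),
            "mean": totals / n_px,
            "n_pixels": n_px,
        }
    )


def paired_stats(
    pairs: Sequence[ROIPair],
    image: IonImage,
    pseudocount: float = 0.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-metabolite paired enrichment of high vs matched low ROIs.

    For each metabolite the per-pair log2 fold change of mean raw counts
    (``log2((mean_high + c) / (mean_low + c))``) is tested against zero with
    a paired (one-sample) two-tailed t test.  Raw p-values drive the
    per-metabolite significance flag at ``alpha`` (as in the single-
    metabolite figures); BH-adjusted p-values are reported alongside for
    list-level use.
    """
    if len(pairs) < 2:
        raise ValidationError("paired statistics need at least 2 ROI pairs")
    highs = np.stack([extract_ion_counts(image, p.high)["mean"].to_numpy() for p in pairs])
    lows = np.stack([extract_ion_counts(image, p.low)["mean"].to_numpy() for p in pairs])
    fc = np.log2((highs + pseudocount) / (lows + pseudocount))  # (n_pairs, n_chan)
    mean_fc = fc.mean(axis=0)
    with np.errstate(invalid="ignore"):
        t, p = stats.ttest_1samp(fc, 0.0, axis=0)
    p = np.where(np.isfinite(p), p, 1.0)
    res = pd.DataFrame(
        {
            "metabolite": image.channels,
            "mean_log2fc": mean_fc,
            "t_statistic": t,
            "p_value": p,
            "n_pairs": len(pairs),
        }
    )
    res["p_adjusted"] = bh_adjust(res["p_value"])
    res["significant"] = res["p_value"] < alpha
    return res


def signature_matrix(
    abundances: pd.DataFrame,
    metabolites: Sequence[str] | None = None,
    log_transform: bool = True,
    pseudocount: float = 0.5,
) -> tuple[pd.DataFrame, pd.Series]:
    """Pearson correlation matrix + abundance categories across ROIs.

    ``abundances`` is ROI x metabolite mean raw counts.  Correlations are
    computed on log2-transformed values; metabolites are categorised
    low / intermediate / high by tertiles of their mean abundance.
    Constant metabolites yield NaN correlation rows (reported as missing).
    """
    if len(abundances) < 3:
        raise ValidationError("signature matrix needs >= 3 ROIs")
    sel = list(metabolites) if metabolites is not None else list(abundances.columns)
    a = abundances[sel].astype(float)
    vals = np.log2(a + pseudocount) if log_transform else a
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = vals.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    means = a.mean(axis=0)
    lo, hi = np.quantile(means, [1 / 3, 2 / 3])
    cats = pd.Series(
        np.where(means <= lo, "low", np.where(means <= hi, "intermediate", "high")),
        index=sel,
        name="abundance_category",
    )
    return corr, cats


def opposite_trend(
    stats_a: pd.DataFrame, stats_b: pd.DataFrame
) -> list[str]:
    """Metabolites significant in both analyses with opposite fold-change signs.

    Inputs are :func:`paired_stats` tables from two marker populations.
    Returns the sorted metabolite names significant in both with strictly
    opposite ``mean_log2fc`` signs.
    """
    common = set(stats_a["metabolite"]) & set(stats_b["metabolite"])
    if not common:
        warnings.warn("no shared metabolite namespace between the two analyses")
        return []
    a = stats_a.set_index("metabolite")
    b = stats_b.set_index("metabolite")
    out = [
        m
        for m in common
        if bool(a.loc[m, "significant"])
        and bool(b.loc[m, "significant"])
        and a.loc[m, "mean_log2fc"] * b.loc[m, "mean_log2fc"] < 0
    ]
    return sorted(out)


@dataclass
class PairedMetabolomicsResults:
    """Hotspot pairs and per-metabolite paired enrichment for one marker."""

    marker: str
    hotspots: list[HotspotROI]
    pairs: list[ROIPair]
    stats: pd.DataFrame
    abundances: pd.DataFrame = field(repr=False)  # ROI x metabolite means
    density: np.ndarray = field(repr=False, default=None)
    model: "PairedMetabolomicsModel" = field(repr=False, default=None)

    @property
    def significant(self) -> list[str]:
        return sorted(self.stats.loc[self.stats["significant"], "metabolite"])

    def ora(self, sets: Mapping[str, Sequence[str]]) -> pd.DataFrame:
        """Pathway over-representation of the significant metabolites."""
        return hypergeom_ora(self.significant, list(self.stats["metabolite"]), sets)

    def signature(self, metabolites=None):
        return signature_matrix(self.abundances, metabolites)

    def summary(self) -> str:
        sig = self.stats[self.stats["significant"]].sort_values("p_value")
        lines = [
            f"Paired metabolomics — marker {self.marker}",
            f"hotspots: {len(self.hotspots)}   matched pairs: {len(self.pairs)}",
            f"significant metabolites (raw p < 0.05): {len(sig)}",
        ]
        if len(sig):
            lines.append(
                sig[["metabolite", "mean_log2fc", "p_value", "p_adjusted"]].to_string(
                    index=False, float_format=lambda v: f"{v: .4f}"
                )
            )
        return "\n".join(lines)

    def volcano_table(self) -> pd.DataFrame:
        t = self.stats.copy()
        t["neg_log10_p"] = -np.log10(t["p_value"].clip(lower=1e-300))
        return t

    def plot_volcano(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.volcano_table()
        col = np.where(t["significant"], "#c44e52", "#777777")
        ax.scatter(t["mean_log2fc"], t["neg_log10_p"], c=col, s=18)
        ax.axhline(-np.log10(0.05), ls="--", lw=0.8, color="k")
        ax.set_xlabel("mean paired log2 FC (high vs low)")
        ax.set_ylabel("-log10 p")
        return ax


class PairedMetabolomicsModel:
    """Marker-guided paired-ROI metabolomics on one tissue section.

    Parameters mirror the procedure: density ``bandwidth`` (µm), hotspot
    ``quantile`` and ``min_area_mm2``, fixed ROI ``radius`` (µm), pairing
    ``min_fold`` (log2 units, default 0.5) and ``max_separation`` (µm).
    """

    def __init__(
        self,
        image: IonImage,
        cells: pd.DataFrame,
        marker: str,
        bandwidth: float = 250.0,
        quantile: float = 0.95,
        min_area_mm2: float = 0.05,
        radius: float = 400.0,
        min_fold: float = 0.5,
        max_separation: float = 4000.0,
        pseudocount: float = 0.5,
        alpha: float = 0.05,
    ) -> None:
        self.image = image
        self.cells = cells
        self.marker = marker
        self.bandwidth = bandwidth
        self.quantile = quantile
        self.min_area_mm2 = min_area_mm2
        self.radius = radius
        self.min_fold = min_fold
        self.max_separation = max_separation
        self.pseudocount = pseudocount
        self.alpha = alpha

    def fit(self) -> PairedMetabolomicsResults:
        dens = density_map(self.cells, self.marker, self.image, self.bandwidth)
        hotspots = detect_hotspots(
            dens,
            self.image,
            self.cells,
            self.marker,
            self.quantile,
            self.min_area_mm2,
            self.radius,
        )
        pairs = pair_rois(
            hotspots,
            self.cells,
            self.image,
            self.min_fold,
            self.max_separation,
        )
        st = paired_stats(pairs, self.image, self.pseudocount, self.alpha)
        rows = {}
        for p in pairs:
            rows[f"high_{p.high.roi_id}"] = extract_ion_counts(self.image, p.high).set_index("metabolite")["mean"]
            rows[f"low_{p.low.roi_id}"] = extract_ion_counts(self.image, p.low).set_index("metabolite")["mean"]
        abundances = pd.DataFrame(rows).T
        return PairedMetabolomicsResults(
            marker=self.marker,
            hotspots=hotspots,
            pairs=pairs,
            stats=st,
            abundances=abundances,
            density=dens,
            model=self,
        )
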