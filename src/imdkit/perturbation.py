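"""Marker response around drug-release reservoirs.

For every condition reservoir of a device the marker-positive cells inside
the 1,200 µm region are counted and expressed as the log2 fold change of
their density against the same tumor's internal control — the empty
reservoirs of the same device.  Per-tumor log2 fold changes are aggregated
across animals as mean ± SEM with a two-tailed unpaired Student's t test
against the device's control-vs-control fold changes (a null sample centred
at zero), producing one effect row per (condition, marker).

The headline effect pools the full 0–1,200 µm region; per-ring densities
are retained and screened for outliers (a ring whose density deviates more
than 3x from its neighbours is flagged, not excluded) because the sub-ROI
split exists to expose tissue damage and staining artefacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import (
    MARKERS,
    DeviceLayout,
    RingSpec,
    ValidationError,
    assign_cells,
    build_rings,
    region_area,
)

__all__ = [
    "fold_change",
    "percent_change",
    "condition_counts",
    "effect_table",
    "PerturbationModel",
    "PerturbationResults",
]


def fold_change(
    count_roi: float,
    area_roi: float,
    count_control: float,
    area_control: float,
    pseudocount: float = 0.0,
) -> float:
    """Log2 fold change of marker density, ROI vs internal control.

    ``log2(((count_roi + c) / area_roi) / ((count_control + c) / area_control))``
    with pseudocount ``c``; with equal areas this reduces to the plain count
    ratio, e.g. counts 35 vs 20 give ``log2(1.75) ≈ 0.807`` — a +75 % change.
    """
    if not (area_roi > 0 and area_control > 0):
        raise ValidationError("areas must be positive")
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    num = (count_roi + pseudocount) / area_roi
    den = (count_control + pseudocount) / area_control
    if num == 0 and den == 0:
        raise ValidationError("fold change undefined: both counts zero with pseudocount 0")
    if den == 0 or num == 0:
        raise ValidationError(
            "fold change undefined for a zero side; use a positive pseudocount"
        )
    return float(np.log2(num / den))


def percent_change(log2fc: float) -> float:
    """Percent change implied by a log2 fold change: ``(2**fc - 1) * 100``."""
    arr = np.asarray(log2fc, dtype=float)
    if not np.isfinite(arr).all():
        raise ValidationError("log2 fold change must be finite")
    return (2.0**arr - 1.0) * 100.0


def _ring_qc_flags(ring_density: np.ndarray, factor: float = 3.0) -> np.ndarray:
    """Flag rings deviating > ``factor``x from the median of the other rings.

    The median reference keeps a single damaged/artefactual ring from
    flagging its healthy neighbours.
    """
    n = len(ring_density)
    flags = np.zeros(n, dtype=bool)
    if n < 2:
        return flags
    for i in range(n):
        ref = float(np.median(np.delete(ring_density, i)))
        d = ring_density[i]
        if ref > 0 and (d > factor * ref or d < ref / factor):
            flags[i] = True
        elif ref == 0 and d > 0:
            flags[i] = True
    return flags


def condition_counts(
    cells: pd.DataFrame,
    layout: DeviceLayout,
    spec: RingSpec | None = None,
    markers: Sequence[str] = MARKERS,
    tissue_bounds: tuple[float, float, float, float] | None = None,
) -> pd.DataFrame:
    """Per (condition, marker) pooled ROI and control counts for one tumor.

    Returns one row per (tumor, condition, marker) with pooled 0–max_extent
    counts/areas for the condition reservoirs and the mean density over all
    empty-control reservoirs, plus the per-ring count breakdown and QC flags.
    """
    spec = spec or RingSpec()
    layout.require_control()
    assigned = assign_cells(cells, layout, spec)
    within = assigned["reservoir_id"].notna().to_numpy()
    res_ids = assigned["reservoir_id"].to_numpy(dtype=object)[within].astype(int)
    ring_ids = assigned["ring"].to_numpy(dtype=object)[within].astype(int)
    marker_flags = {m: assigned[m].to_numpy(bool)[within] for m in markers}
    res = layout.reservoirs
    tumor_id = cells["tumor_id"].iloc[0] if len(cells) else layout.device_id

    # per-reservoir pooled and per-ring marker counts and areas (vectorised:
    # bincount over a combined reservoir x ring code)
    rings = build_rings(spec)
    n_rings = spec.n_rings
    id_order = res["reservoir_id"].to_numpy(int)
    id_pos = {rid: k for k, rid in enumerate(id_order)}
    code = np.array([id_pos[r] for r in res_ids], dtype=int) * n_rings + ring_ids
    n_codes = len(id_order) * n_rings
    per_res: dict[int, dict] = {}
    for _, r in res.iterrows():
        rid = int(r.reservoir_id)
        ring_areas = np.array(
            [region_area((r.x, r.y), a, b, tissue_bounds) for a, b in rings]
        )
        k = id_pos[rid]
        counts = {}
        for m in markers:
            bc = np.bincount(code[marker_flags[m]], minlength=n_codes)
            counts[m] = bc[k * n_rings : (k + 1) * n_rings]
        per_res[rid] = {
            "condition": str(r.condition),
            "is_control": bool(r.is_control),
            "ring_areas": ring_areas,
            "counts": counts,
        }

    control_ids = [rid for rid, v in per_res.items() if v["is_control"]]
    rows = []
    conditions = layout.conditions
    for cond in conditions:
        cond_ids = [
            rid
            for rid, v in per_res.items()
            if not v["is_control"] and v["condition"] == cond
        ]
        for m in markers:
            croi = float(sum(per_res[rid]["counts"][m].sum() for rid in cond_ids))
            aroi = float(sum(per_res[rid]["ring_areas"].sum() for rid in cond_ids))
            cctl = float(sum(per_res[rid]["counts"][m].sum() for rid in control_ids))
            actl = float(sum(per_res[rid]["ring_areas"].sum() for rid in control_ids))
            ring_counts = np.sum(
                [per_res[rid]["counts"][m] for rid in cond_ids], axis=0
            )
            ring_areas = np.sum([per_res[rid]["ring_areas"] for rid in cond_ids], axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                ring_density = np.where(ring_areas > 0, ring_counts / ring_areas, 0.0)
            rows.append(
                {
                    "tumor_id": tumor_id,
                    "condition": cond,
                    "marker": m,
                    "count_roi": croi,
                    "area_roi": aroi,
                    "count_control": cctl,
                    "area_control": actl,
                    "ring_counts": ring_counts.tolist(),
                    "ring_areas": ring_areas.tolist(),
                    "qc_flags": _ring_qc_flags(ring_density).tolist(),
                }
            )
    # control-vs-control split for the null sample: odd- vs even-indexed
    # empty reservoirs (by id order); requires >= 2 controls
    for m in markers:
        if len(control_ids) >= 2:
            ids = sorted(control_ids)
            a_ids, b_ids = ids[0::2], ids[1::2]
            ca = float(sum(per_res[rid]["counts"][m].sum() for rid in a_ids))
            aa = float(sum(per_res[rid]["ring_areas"].sum() for rid in a_ids))
            cb = float(sum(per_res[rid]["counts"][m].sum() for rid in b_ids))
            ab = float(sum(per_res[rid]["ring_areas"].sum() for rid in b_ids))
            rows.append(
                {
                    "tumor_id": tumor_id,
                    "condition": "__control_split__",
                    "marker": m,
                    "count_roi": ca,
                    "area_roi": aa,
                    "count_control": cb,
                    "area_control": ab,
                    "ring_counts": None,
                    "ring_areas": None,
                    "qc_flags": None,
                }
            )
    return pd.DataFrame(rows)


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.005:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def effect_table(
    counts: pd.DataFrame,
    pseudocount: float = 0.0,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Aggregate per-tumor fold changes into the per-condition effect table.

    ``counts`` is the concatenation of :func:`condition_counts` over tumors.
    For each (condition, marker): mean log2FC ± SEM over tumors, percent
    change, and a two-tailed unpaired t test of the per-tumor condition
    log2FCs against the per-tumor control-vs-control log2FCs.  With a single
    tumor the effect is reported and the p-value marked unavailable (NaN).
    """
    df = counts.copy()
    df["log2fc"] = [
        fold_change(r.count_roi, r.area_roi, r.count_control, r.area_control, pseudocount)
        for r in df.itertuples()
    ]
    null_fc = df[df["condition"] == "__control_split__"]
    eff = df[df["condition"] != "__control_split__"]
    rows = []
    for (cond, m), grp in eff.groupby(["condition", "marker"], sort=True):
        fc = grp["log2fc"].to_numpy(float)
        n = len(fc)
        mean = float(np.mean(fc))
        sem = float(stats.sem(fc)) if n >= 2 else math.nan
        null = null_fc.loc[null_fc["marker"] == m, "log2fc"].to_numpy(float)
        if n >= 2 and len(null) >= 2:
            t, p = stats.ttest_ind(fc, null, equal_var=equal_var)
            t, p = float(t), float(p)
            if math.isnan(t) and np.allclose(fc.mean(), null.mean()):
                t, p = 0.0, 1.0  # zero variance, zero difference
        elif n >= 2:
            t, p = stats.ttest_1samp(fc, 0.0)
            t, p = float(t), float(p)
            if math.isnan(t) and np.allclose(fc.mean(), 0.0):
                t, p = 0.0, 1.0
        else:
            t, p = math.nan, math.nan
        rows.append(
            {
                "condition": cond,
                "marker": m,
                "mean_log2fc": mean,
                "sem": sem,
                "n_tumors": n,
                "t_statistic": t,
                "p_value": p,
                "percent_change": float(percent_change(mean)),
                "stars": _stars(p),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PerturbationResults:
    """Fitted marker-response effects, one row per (condition, marker)."""

    effects: pd.DataFrame
    per_tumor: pd.DataFrame = field(repr=False)
    model: "PerturbationModel" = field(repr=False, default=None)

    def summary(self) -> str:
        cols = [
            "condition",
            "marker",
            "mean_log2fc",
            "sem",
            "n_tumors",
            "p_value",
            "percent_change",
            "stars",
        ]
        body = self.effects[cols].to_string(
            index=False, float_format=lambda v: f"{v: .4f}"
        )
        head = "Marker response vs internal control (log2 fold change of density)"
        return f"{head}\n{'=' * len(head)}\n{body}\n(* p<0.05, ** p<0.005)"

    def to_csv(self, path) -> None:
        self.effects.to_csv(path, index=False)

    def plot(self, ax=None):
        """Bar chart of percent change per (condition, marker) with SEM."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        e = self.effects
        labels = e["condition"] + "/" + e["marker"]
        err = (2.0 ** (e["mean_log2fc"] + e["sem"]) - 2.0 ** e["mean_log2fc"]) * 100
        ax.bar(labels, e["percent_change"], yerr=err, color="#4878b0")
        ax.axhline(0, color="k", lw=0.8)
        ax.set_ylabel("% change vs control")
        ax.tick_params(axis="x", rotation=60)
        return ax


class PerturbationModel:
    """Marker-response model over a cohort of tumors.

    Parameters
    ----------
    cells : DataFrame
        Cell table for all tumors (``tumor_id`` column distinguishes them).
    layouts : mapping
        ``tumor_id -> DeviceLayout`` of the device implanted in that tumor.
    ring_spec : RingSpec
        ROI geometry (default 1,200 µm / 300 µm).
    markers : sequence of str
        Marker columns to quantify (default CD3, CD8, FOXP3).
    pseudocount : float
        Added to counts before the density ratio (default 0).
    equal_var : bool
        Student's (True, default) vs Welch's t test.
    tissue_bounds : per-tumor mapping or None
        Rectangles used to clip ring areas; None leaves areas analytic.
    """

    def __init__(
        self,
        cells: pd.DataFrame,
        layouts: Mapping[str, DeviceLayout],
        ring_spec: RingSpec | None = None,
        markers: Sequence[str] = MARKERS,
        pseudocount: float = 0.0,
        equal_var: bool = True,
        tissue_bounds: Mapping[str, tuple] | None = None,
    ) -> None:
        self.cells = cells
        self.layouts = dict(layouts)
        self.ring_spec = ring_spec or RingSpec()
        self.markers = tuple(markers)
        self.pseudocount = pseudocount
        self.equal_var = equal_var
        self.tissue_bounds = dict(tissue_bounds) if tissue_bounds else {}
        missing = set(self.cells["tumor_id"].unique()) - set(self.layouts)
        if missing:
            raise ValidationError(f"no layout for tumors: {sorted(missing)}")

    @classmethod
    def from_tumors(
        cls, tumors: Sequence[tuple[pd.DataFrame, DeviceLayout]], **kwargs
    ) -> "PerturbationModel":
        """Build from per-tumor (cells, layout) pairs as the generator emits."""
        cells = pd.concat([c for c, _ in tumors], ignore_index=True)
        layouts = {c["tumor_id"].iloc[0]: lay for c, lay in tumors}
        return cls(cells, layouts, **kwargs)

    def fit(self) -> PerturbationResults:
        per_tumor = []
        for tid, grp in self.cells.groupby("tumor_id", sort=True):
            per_tumor.append(
                condition_counts(
                    grp,
                    self.layouts[tid],
                    self.ring_spec,
                    self.markers,
                    self.tissue_bounds.get(tid),
                )
            )
        counts = pd.concat(per_tumor, ignore_index=True)
        effects = effect_table(counts, self.pseudocount, self.equal_var)
        return PerturbationResults(effects=effects, per_tumor=counts, model=self)
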