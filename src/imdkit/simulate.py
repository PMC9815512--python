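"""Synthetic tumors, devices, ion images and ST ROI tables.

The generators emulate the statistical structure the analysis stages
assume, with planted effect sizes expressed in the same units the pipeline
recovers, so every stage can be tested end-to-end without real data:

* ``gen_device_tumor`` — a device layout plus a segmented-cell point
  pattern: homogeneous Poisson tumor cells and marker-positive T cells
  from an inhomogeneous Poisson process whose intensity is lifted (or
  thinned) by a planted fractional change inside the 1,200 µm region
  around each condition reservoir.
* ``gen_ion_image`` — marker cells clustered at hotspot centres over a
  sparse background, plus a negative-binomial ion-count raster whose
  log2 mean carries the planted per-metabolite shifts inside hotspots.
* ``gen_st_rois`` — ST ROIs with CD8 positive indices drawn inside the
  three class bands and expression vectors with planted gene-set shifts
  in the CD8-high class.

Named presets plant the fractional changes the perturbation screen is
expected to recover (e.g. arginine → CD8 +0.75, sodium lactate → CD8
−0.50).  All randomness flows from the scenario seed; the same scenario
and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import CELL_TABLE_COLUMNS, DeviceLayout, ValidationError
from .metabolomics import IonImage
from .stclass import STROIData

__all__ = [
    "PerturbationScenario",
    "MetabolomicsScenario",
    "STScenario",
    "PERTURBATION_PRESETS",
    "OPPOSITE7_METABOLITES",
    "perturbation_scenario",
    "metabolomics_scenario",
    "opposite7_scenarios",
    "st_scenario",
    "default_gene_sets",
    "gen_device_tumor",
    "gen_experiment",
    "gen_ion_image",
    "gen_st_rois",
]

ROI_RADIUS_UM = 1200.0  # drug-diffusion extent around a reservoir


# --------------------------------------------------------------------------
# scenarios


@dataclass(frozen=True)
class PerturbationScenario:
    """Conditions of one simulated microdevice perturbation experiment.

    ``marker_effects`` maps markers to the planted fractional density
    change at the reservoir (+0.75 = +75 %); ``baseline_density`` gives the
    unperturbed marker-positive densities (cells/mm², CD3 counting all T
    cells).  The flat kernel makes the planted change directly recoverable
    as the pooled-ROI fold change; an exponential kernel with scale
    ``decay_length`` is available.
    """

    name: str
    marker_effects: Mapping[str, float] = field(default_factory=dict)
    decay_length: float = ROI_RADIUS_UM
    baseline_density: Mapping[str, float] = field(
        default_factory=lambda: {"CD3": 150.0, "CD8": 60.0, "FOXP3": 40.0}
    )
    tumor_cell_density: float = 800.0
    n_tumors: int = 6
    seed: int = 0
    kernel: str = "flat"  # or "exp"
    n_condition_reservoirs: int = 2
    n_control_reservoirs: int = 2
    reservoir_spacing: float = 2500.0

    def __post_init__(self) -> None:
        for m, e in self.marker_effects.items():
            if e <= -1:
                raise ValidationError(f"effect for {m} must be > -1 (got {e})")
        if any(v <= 0 for v in self.baseline_density.values()):
            raise ValidationError("baseline densities must be positive")
        if self.tumor_cell_density <= 0 or self.decay_length <= 0:
            raise ValidationError("densities and decay_length must be positive")
        if self.n_control_reservoirs < 1:
            raise ValidationError("need at least one empty control reservoir")
        if self.reservoir_spacing < 2 * ROI_RADIUS_UM:
            raise ValidationError(
                "reservoir spacing would overlap 1,200 um ROIs of distinct conditions"
            )

    def population_effects(self) -> dict[str, float]:
        """Planted effects of the three disjoint subpopulations.

        CD8+ and FOXP3+ populations carry their own planted effect,
        inheriting the CD3 effect when none is given; the CD3-only
        intensity is solved so the total CD3+ density changes by exactly
        the planted CD3 effect.
        """
        me = self.marker_effects
        b = self.baseline_density
        e_cd8 = me.get("CD8", me.get("CD3", 0.0))
        e_foxp3 = me.get("FOXP3", me.get("CD3", 0.0))
        b_only = b["CD3"] - b["CD8"] - b["FOXP3"]
        if b_only <= 0:
            raise ValidationError("CD3 density must exceed CD8 + FOXP3 densities")
        if "CD3" in me:
            lifted = (
                b["CD3"] * (1 + me["CD3"])
                - b["CD8"] * (1 + e_cd8)
                - b["FOXP3"] * (1 + e_foxp3)
            )
            if lifted < 0:
                raise ValidationError(
                    "marker effects imply a negative CD3-only intensity"
                )
            e_only = lifted / b_only - 1
        else:
            e_only = 0.0
        return {"CD8": e_cd8, "FOXP3": e_foxp3, "CD3_only": e_only}


@dataclass(frozen=True)
class MetabolomicsScenario:
    """Conditions of one simulated dual-modality (IF + MALDI) section."""

    name: str
    hotspot_marker: str = "CD8"
    metabolite_effects: Mapping[str, float] = field(default_factory=dict)
    n_hotspots: int = 6
    pixel_size: float = 125.0
    grid_extent: tuple[float, float] = (10000.0, 10000.0)
    count_noise: float = 0.05  # NB overdispersion alpha; 0 = Poisson
    baseline_counts: float = 200.0
    hotspot_radius: float = 400.0
    cells_per_hotspot: float = 120.0
    background_density: float = 5.0  # marker cells/mm² off-hotspot
    spatial_noise_sd: float = 0.15  # log2 units, smooth field
    n_fillers: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hotspots < 1:
            raise ValidationError("n_hotspots must be >= 1")
        if self.pixel_size <= 0 or self.hotspot_radius <= 0:
            raise ValidationError("pixel_size and hotspot_radius must be positive")
        if self.count_noise < 0:
            raise ValidationError("overdispersion must be >= 0")

    @property
    def channels(self) -> list[str]:
        fillers = [f"filler_{i:02d}" for i in range(1, self.n_fillers + 1)]
        return list(self.metabolite_effects) + fillers


@dataclass(frozen=True)
class STScenario:
    """Conditions of one simulated spatial-transcriptomics ROI cohort."""

    name: str
    class_counts: tuple[int, int, int] = (9, 12, 9)  # high, intermediate, low
    genes: tuple[str, ...] = ()
    pathway_effects: Mapping[str, float] = field(
        default_factory=lambda: {"amino_acid_metabolism": 1.0}
    )
    mean_nuclei: float = 2000.0
    expression_sd: float = 0.4  # log2 units per gene per ROI
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.class_counts):
            raise ValidationError("class counts must be >= 0")
        genes = self.genes or tuple(_default_genes())
        if len(genes) == 0:
            raise ValidationError("gene list must be non-empty")
        if len(set(genes)) != len(genes):
            raise ValidationError("gene names must be unique")
        object.__setattr__(self, "genes", tuple(genes))


# --------------------------------------------------------------------------
# presets (planted fractional changes of the perturbation screen)

PERTURBATION_PRESETS: dict[str, dict[str, float]] = {
    "ARG_CD8": {"CD8": 0.75},
    "CYS_CD8": {"CD8": 0.75},
    "LAC_CD8": {"CD8": -0.50},
    "PYR_FOXP3": {"FOXP3": 0.60},
    "ATP_FOXP3": {"FOXP3": -0.70},
    "GLN_CD3": {"CD3": 0.75},
    "ITA_CD3": {"CD3": 0.75},
    "GNE140_ALL": {"CD3": -0.75, "CD8": -0.75, "FOXP3": -0.75},
    "BSO": {"CD3": -0.50, "CD8": -0.75},
    "NULL": {},
}

#: metabolites planted with antagonistic signs between CD8 and FOXP3 hotspots
OPPOSITE7_METABOLITES = (
    "cystathionine",
    "d-Gluconate",
    "dCMP",
    "galacturonic acid",
    "glucose 1-phosphate",
    "mucic acid",
    "orotate",
)


def perturbation_scenario(preset: str, seed: int = 0, **overrides) -> PerturbationScenario:
    """Named perturbation preset → scenario (see ``PERTURBATION_PRESETS``)."""
    if preset not in PERTURBATION_PRESETS:
        raise ValidationError(f"unknown preset {preset!r}")
    sc = PerturbationScenario(
        name=preset, marker_effects=dict(PERTURBATION_PRESETS[preset]), seed=seed
    )
    return replace(sc, **overrides) if overrides else sc


def metabolomics_scenario(preset: str, seed: int = 0, **overrides) -> MetabolomicsScenario:
    """Named metabolomics preset → scenario.

    ``CD8_HOTSPOT`` plants glutathione and N-acetyl-cysteine up in CD8-high
    regions; ``FOXP3_HOTSPOT`` plants citrate up and the lipids myristic
    and oleic acid down; ``NULL_MET`` plants nothing.
    """
    presets = {
        "CD8_HOTSPOT": ("CD8", {"glutathione": 1.0, "N-acetyl-cysteine": 1.0}),
        "FOXP3_HOTSPOT": (
            "FOXP3",
            {"citrate": 1.0, "myristic acid": -1.0, "oleic acid": -1.0},
        ),
        "NULL_MET": ("CD8", {}),
    }
    if preset not in presets:
        raise ValidationError(f"unknown preset {preset!r}")
    marker, effects = presets[preset]
    sc = MetabolomicsScenario(
        name=preset, hotspot_marker=marker, metabolite_effects=effects, seed=seed
    )
    return replace(sc, **overrides) if overrides else sc


def opposite7_scenarios(
    seed: int = 0, effect: float = 1.0, **overrides
) -> tuple[MetabolomicsScenario, MetabolomicsScenario]:
    """The OPPOSITE7 preset: paired CD8 / FOXP3 sections.

    The seven listed metabolites are planted with antagonistic signs
    (up in CD8 hotspots, down in FOXP3 hotspots); glutathione is planted
    concordantly up in both; fillers carry no effect.
    """
    up = {m: effect for m in OPPOSITE7_METABOLITES}
    down = {m: -effect for m in OPPOSITE7_METABOLITES}
    concordant = {"glutathione": effect}
    cd8 = MetabolomicsScenario(
        name="OPPOSITE7_CD8",
        hotspot_marker="CD8",
        metabolite_effects={**up, **concordant},
        seed=seed,
        **overrides,
    )
    foxp3 = MetabolomicsScenario(
        name="OPPOSITE7_FOXP3",
        hotspot_marker="FOXP3",
        metabolite_effects={**down, **concordant},
        seed=seed + 1,
        **overrides,
    )
    return cd8, foxp3


def _default_genes() -> list[str]:
    aam = [f"AAM_{i:02d}" for i in range(1, 13)]
    gly = [f"GLY_{i:02d}" for i in range(1, 11)]
    hk = [f"HK_{i:02d}" for i in range(1, 11)]
    oth = [f"OTH_{i:02d}" for i in range(1, 19)]
    return aam + gly + hk + oth


def default_gene_sets() -> dict[str, list[str]]:
    """Gene sets matching the default synthetic gene panel."""
    genes = _default_genes()
    return {
        "amino_acid_metabolism": [g for g in genes if g.startswith("AAM")],
        "glycolysis": [g for g in genes if g.startswith("GLY")],
        "other_process": [g for g in genes if g.startswith("OTH")][:10],
    }


def default_target_group() -> list[str]:
    """Housekeeping genes used as the geometric-mean normalisation target."""
    return [g for g in _default_genes() if g.startswith("HK")]


def st_scenario(seed: int = 0, **overrides) -> STScenario:
    return STScenario(name="ST_DEFAULT", seed=seed, **overrides)


# --------------------------------------------------------------------------
# perturbation generator


def _device_layout(scenario: PerturbationScenario, tumor_index: int) -> tuple[DeviceLayout, tuple]:
    n = scenario.n_condition_reservoirs + scenario.n_control_reservoirs
    ncols = int(np.ceil(np.sqrt(n)))
    nrows = int(np.ceil(n / ncols))
    s = scenario.reservoir_spacing
    margin = ROI_RADIUS_UM + 100.0
    positions = [
        (margin + c * s, margin + r * s)
        for r in range(nrows)
        for c in range(ncols)
    ][:n]
    records = []
    for i, (x, y) in enumerate(positions):
        is_control = i >= scenario.n_condition_reservoirs
        records.append(
            (i + 1, x, y, "empty" if is_control else scenario.name, is_control)
        )
    bounds = (
        0.0,
        0.0,
        2 * margin + (ncols - 1) * s,
        2 * margin + (nrows - 1) * s,
    )
    layout = DeviceLayout.from_records(f"tumor_{tumor_index:02d}", records)
    return layout, bounds


def _kernel(dist: np.ndarray, scenario: PerturbationScenario) -> np.ndarray:
    """Spatial effect kernel k(r): flat or exponential, 0 beyond 1,200 µm."""
    inside = dist < ROI_RADIUS_UM
    if scenario.kernel == "flat":
        return inside.astype(float)
    if scenario.kernel == "exp":
        return np.where(inside, np.exp(-dist / scenario.decay_length), 0.0)
    raise ValidationError(f"unknown kernel {scenario.kernel!r}")


def _poisson_points(rng, rate_per_mm2, bounds) -> np.ndarray:
    xmin, ymin, xmax, ymax = bounds
    area_mm2 = (xmax - xmin) * (ymax - ymin) / 1e6
    n = rng.poisson(rate_per_mm2 * area_mm2)
    pts = np.column_stack(
        [rng.uniform(xmin, xmax, n), rng.uniform(ymin, ymax, n)]
    )
    return pts


def _thinned_marker_points(rng, base_rate, effect, cond_centers, scenario, bounds):
    """Inhomogeneous Poisson via thinning of a dominating homogeneous process."""
    M = max(1.0, 1.0 + effect)
    pts = _poisson_points(rng, base_rate * M, bounds)
    if len(pts) == 0 or len(cond_centers) == 0:
        return pts
    d = np.sqrt(
        ((pts[:, None, :] - np.asarray(cond_centers)[None, :, :]) ** 2).sum(axis=2)
    ).min(axis=1)
    lam_ratio = (1.0 + effect * _kernel(d, scenario)) / M
    keep = rng.uniform(size=len(pts)) < lam_ratio
    return pts[keep]


def gen_device_tumor(
    scenario: PerturbationScenario, tumor_index: int = 0, seed=None
) -> tuple[DeviceLayout, pd.DataFrame, tuple]:
    """One simulated tumor: device layout, cell table and tissue bounds.

    Tumor cells are a homogeneous Poisson process; each marker population
    is an inhomogeneous Poisson process with intensity
    ``baseline * (1 + effect * k(r))`` around the condition reservoirs,
    realised by thinning.  Control reservoirs see baseline intensity only.
    """
    layout, bounds = _device_layout(scenario, tumor_index)
    base_seed = scenario.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([base_seed, tumor_index]))
    cond = layout.reservoirs[~layout.reservoirs["is_control"]]
    cond_centers = cond[["x", "y"]].to_numpy(float)
    b = scenario.baseline_density
    eff = scenario.population_effects()
    b_only = b["CD3"] - b["CD8"] - b["FOXP3"]

    tumor_pts = _poisson_points(rng, scenario.tumor_cell_density, bounds)
    pops = {
        "CD8": _thinned_marker_points(rng, b["CD8"], eff["CD8"], cond_centers, scenario, bounds),
        "FOXP3": _thinned_marker_points(rng, b["FOXP3"], eff["FOXP3"], cond_centers, scenario, bounds),
        "CD3_only": _thinned_marker_points(rng, b_only, eff["CD3_only"], cond_centers, scenario, bounds),
    }
    frames = []
    tid = layout.device_id
    for pts, cd3, cd8, foxp3 in [
        (tumor_pts, False, False, False),
        (pops["CD8"], True, True, False),
        (pops["FOXP3"], True, False, True),
        (pops["CD3_only"], True, False, False),
    ]:
        frames.append(
            pd.DataFrame(
                {
                    "x": pts[:, 0],
                    "y": pts[:, 1],
                    "tumor_id": tid,
                    "CD3": cd3,
                    "CD8": cd8,
                    "FOXP3": foxp3,
                    "nucleus": True,
                }
            )
        )
    cells = pd.concat(frames, ignore_index=True)
    cells.insert(0, "cell_id", np.arange(len(cells)))
    return layout, cells[list(CELL_TABLE_COLUMNS)], bounds


def gen_experiment(
    scenario: PerturbationScenario,
) -> tuple[list[tuple[pd.DataFrame, DeviceLayout]], dict[str, tuple]]:
    """All ``n_tumors`` tumors of a scenario; returns (cells, layout) pairs
    plus the per-tumor tissue bounds."""
    tumors, bounds = [], {}
    for i in range(scenario.n_tumors):
        layout, cells, b = gen_device_tumor(scenario, i)
        tumors.append((cells, layout))
        bounds[layout.device_id] = b
    return tumors, bounds


# --------------------------------------------------------------------------
# metabolomics generator


def _hotspot_centers(scenario: MetabolomicsScenario, rng) -> np.ndarray:
    lx, ly = scenario.grid_extent
    r = scenario.hotspot_radius
    margin = 2 * r
    min_sep = 4 * r
    if lx - 2 * margin <= 0 or ly - 2 * margin <= 0:
        raise ValidationError("grid too small to hold any hotspot")
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < scenario.n_hotspots:
        tries += 1
        if tries > 20000:
            raise ValidationError(
                f"grid too small to hold {scenario.n_hotspots} disjoint hotspots"
            )
        cx = rng.uniform(margin, lx - margin)
        cy = rng.uniform(margin, ly - margin)
        if all(np.hypot(cx - x, cy - y) >= min_sep for x, y in centers):
            centers.append((cx, cy))
    return np.asarray(centers)


def _smooth_field(rng, shape, sd: float, sigma_px: float = 2.0) -> np.ndarray:
    field = ndimage.gaussian_filter(rng.normal(size=shape), sigma=sigma_px)
    s = field.std()
    return field * (sd / s) if s > 0 else field


def gen_ion_image(scenario: MetabolomicsScenario) -> tuple[IonImage, pd.DataFrame]:
    """One simulated dual-modality section: ion-count raster + cell table.

    Marker cells cluster at hotspot centres (Gaussian, sigma = radius/2)
    over a sparse uniform background.  Each metabolite channel's per-pixel
    counts are negative-binomial with
    ``log2 mean = log2(baseline) + effect * hotspot_membership + smooth
    spatial noise``; ``count_noise`` is the NB overdispersion (variance
    ``mu + alpha mu²``), with the Poisson limit at 0.
    """
    rng = np.random.default_rng(np.random.SeedSequence(scenario.seed))
    lx, ly = scenario.grid_extent
    px = scenario.pixel_size
    nx, ny = int(round(lx / px)), int(round(ly / px))
    centers = _hotspot_centers(scenario, rng)
    r = scenario.hotspot_radius

    # marker-positive cells: clustered + sparse background
    pts = [
        _poisson_points(rng, scenario.background_density, (0, 0, lx, ly))
    ]
    for cx, cy in centers:
        n = rng.poisson(scenario.cells_per_hotspot)
        p = rng.normal([cx, cy], r / 2, size=(n, 2))
        p[:, 0] = np.clip(p[:, 0], 0, lx - 1e-9)
        p[:, 1] = np.clip(p[:, 1], 0, ly - 1e-9)
        pts.append(p)
    pts = np.vstack(pts)
    marker = scenario.hotspot_marker
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(len(pts)),
            "x": pts[:, 0],
            "y": pts[:, 1],
            "tumor_id": scenario.name,
            "CD3": marker in ("CD3", "CD8", "FOXP3"),
            "CD8": marker == "CD8",
            "FOXP3": marker == "FOXP3",
            "nucleus": True,
        }
    )

    # per-pixel hotspot membership on the raster
    x = (np.arange(nx) + 0.5) * px
    y = (np.arange(ny) + 0.5) * px
    X, Y = np.meshgrid(x, y)
    member = np.zeros((ny, nx), dtype=bool)
    for cx, cy in centers:
        member |= (X - cx) ** 2 + (Y - cy) ** 2 <= r**2

    channels = scenario.channels
    effects = {c: float(scenario.metabolite_effects.get(c, 0.0)) for c in channels}
    counts = np.empty((len(channels), ny, nx))
    log2_base = np.log2(scenario.baseline_counts)
    alpha = scenario.count_noise
    for ci, ch in enumerate(channels):
        fieldv = _smooth_field(rng, (ny, nx), scenario.spatial_noise_sd)
        mu = 2.0 ** (log2_base + effects[ch] * member + fieldv)
        if alpha > 0:
            lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
            counts[ci] = rng.poisson(lam)
        else:
            counts[ci] = rng.poisson(mu)
    image = IonImage(pixel_size=px, counts=counts, channels=list(channels))
    return image, cells


# --------------------------------------------------------------------------
# ST generator

# index bands are drawn inside the class interiors so that rounding the CD8
# count against the nuclei count can never cross a class boundary
_BANDS = {"high": (0.22, 0.45), "intermediate": (0.07, 0.18), "low": (0.005, 0.04)}


def gen_st_rois(
    scenario: STScenario,
    gene_sets: Mapping[str, Sequence[str]] | None = None,
) -> STROIData:
    """Simulated ST ROI cohort with planted gene-set shifts in CD8-high ROIs."""
    rng = np.random.default_rng(np.random.SeedSequence(scenario.seed))
    gene_sets = gene_sets if gene_sets is not None else default_gene_sets()
    genes = list(scenario.genes)
    n_high, n_inter, n_low = scenario.class_counts

    roi_classes = (
        ["high"] * n_high + ["intermediate"] * n_inter + ["low"] * n_low
    )
    nuclei, cd8 = [], []
    for cls in roi_classes:
        nuc = max(int(rng.poisson(scenario.mean_nuclei)), 100)
        lo, hi = _BANDS[cls]
        idx = rng.uniform(lo, hi)
        nuclei.append(nuc)
        cd8.append(int(round(idx * nuc)))

    # per-gene baseline (log2) shared across ROIs; planted shift in high ROIs
    base = rng.uniform(4.0, 8.0, size=len(genes))
    shift = np.zeros(len(genes))
    for set_name, eff in scenario.pathway_effects.items():
        members = set(gene_sets.get(set_name, ()))
        shift += np.array([eff if g in members else 0.0 for g in genes])
    rows = []
    for cls in roi_classes:
        noise = rng.normal(0.0, scenario.expression_sd, size=len(genes))
        log2v = base + (shift if cls == "high" else 0.0) + noise
        rows.append(2.0**log2v)
    expr = pd.DataFrame(rows, columns=genes)
    roi_ids = [f"roi_{i:02d}" for i in range(len(roi_classes))]
    return STROIData.from_counts(
        roi_ids, cd8, nuclei, expr, target_group=default_target_group()
    )
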