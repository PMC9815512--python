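"""Readers, writers, run configuration and the pipeline driver.

File conventions (documented once, used everywhere): coordinates are
Cartesian micrometres with the origin bottom-left and y up; tables are
comma- or tab-delimited text with a header row; ion images travel either
as imzML (continuous mode, one "m/z" slot per metabolite channel) or as a
long-format text table with columns ``x, y, metabolite, count``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import CELL_TABLE_COLUMNS, DeviceLayout, RingSpec, ValidationError
from .metabolomics import IonImage

__all__ = [
    "read_cell_table",
    "write_cell_table",
    "read_device_layout",
    "write_device_layout",
    "read_ion_image",
    "write_ion_image",
    "read_ion_image_imzml",
    "write_ion_image_imzml",
    "read_st_table",
    "write_st_table",
    "RunConfig",
    "run_pipeline",
]


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


class SchemaError(ValidationError):
    """Input file violates the documented schema."""


# --------------------------------------------------------------------------
# cell tables


def read_cell_table(path) -> pd.DataFrame:
    """Read a segmented-cell table; malformed rows are reported by line.

    Required columns: ``cell_id, x, y, tumor_id, CD3, CD8, FOXP3, nucleus``.
    """
    df = pd.read_csv(path, sep=_sep_for(path), comment="#")
    missing = [c for c in CELL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    for col in ("x", "y"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            # +2: header line plus 1-based numbering
            lines = (df.index[bad] + 2).tolist()
            raise SchemaError(
                f"{path}: non-numeric {col!r} at line(s) {lines[:10]}"
            )
        df[col] = coerced
    if df[["x", "y"]].isna().any().any():
        raise SchemaError(f"{path}: missing coordinates")
    for col in ("CD3", "CD8", "FOXP3", "nucleus"):
        df[col] = df[col].astype(bool)
    return df[list(CELL_TABLE_COLUMNS)]


def write_cell_table(cells: pd.DataFrame, path) -> None:
    out = cells[list(CELL_TABLE_COLUMNS)].copy()
    for col in ("CD3", "CD8", "FOXP3", "nucleus"):
        out[col] = out[col].astype(bool)
    out.to_csv(path, sep=_sep_for(path), index=False)


# --------------------------------------------------------------------------
# device layouts


def read_device_layout(path, device_id: str | None = None) -> DeviceLayout:
    """Read a layout from delimited text or GeoJSON point features."""
    p = Path(path)
    if p.suffix.lower() in (".json", ".geojson"):
        gj = json.loads(p.read_text())
        rows = []
        for f in gj["features"]:
            x, y = f["geometry"]["coordinates"]
            pr = f["properties"]
            rows.append(
                (int(pr["reservoir_id"]), x, y, pr["condition"], bool(pr["is_control"]))
            )
        did = device_id or gj.get("properties", {}).get("device_id", p.stem)
        return DeviceLayout.from_records(did, rows)
    df = pd.read_csv(p, sep=_sep_for(p), comment="#")
    need = set(DeviceLayout.REQUIRED)
    if not need <= set(df.columns):
        raise SchemaError(f"{path}: layout needs columns {sorted(need)}")
    did = device_id or (
        str(df["device_id"].iloc[0]) if "device_id" in df.columns else p.stem
    )
    return DeviceLayout(did, df[list(DeviceLayout.REQUIRED)])


def write_device_layout(layout: DeviceLayout, path) -> None:
    p = Path(path)
    if p.suffix.lower() in (".json", ".geojson"):
        p.write_text(json.dumps(layout.to_geojson(), indent=1))
        return
    df = layout.reservoirs.copy()
    df.insert(0, "device_id", layout.device_id)
    df.to_csv(p, sep=_sep_for(p), index=False)


# --------------------------------------------------------------------------
# ion images


def write_ion_image(image: IonImage, path) -> None:
    """Write the long-format text dialect (x, y, metabolite, count)."""
    image.to_long().to_csv(path, sep=_sep_for(path), index=False)


def read_ion_image(path) -> IonImage:
    """Read an ion image from the long-format text dialect (or imzML).

    The (x, y) values must form a complete regular grid; duplicate
    (x, y, metabolite) rows are a format error.
    """
    p = Path(path)
    if p.suffix.lower() == ".imzml":
        return read_ion_image_imzml(p)
    df = pd.read_csv(p, sep=_sep_for(p), comment="#")
    need = {"x", "y", "metabolite", "count"}
    if not need <= set(df.columns):
        raise SchemaError(f"{path}: long format needs columns {sorted(need)}")
    if df.duplicated(["x", "y", "metabolite"]).any():
        raise SchemaError(f"{path}: duplicate (x, y, metabolite) rows")
    xs = np.sort(df["x"].unique())
    ys = np.sort(df["y"].unique())
    channels = sorted(df["metabolite"].unique())
    if len(xs) > 1:
        steps = np.diff(xs)
        if not np.allclose(steps, steps[0]):
            raise SchemaError(f"{path}: x coordinates are not a regular grid")
    step = float(np.diff(xs)[0]) if len(xs) > 1 else (
        float(np.diff(ys)[0]) if len(ys) > 1 else 1.0
    )
    nx, ny = len(xs), len(ys)
    if len(df) != nx * ny * len(channels):
        raise SchemaError(f"{path}: incomplete pixel grid")
    xi = pd.Index(xs).get_indexer(df["x"])
    yi = pd.Index(ys).get_indexer(df["y"])
    ci = pd.Index(channels).get_indexer(df["metabolite"])
    counts = np.zeros((len(channels), ny, nx))
    counts[ci, yi, xi] = df["count"].to_numpy(float)
    origin = (float(xs[0] - step / 2), float(ys[0] - step / 2))
    return IonImage(pixel_size=step, counts=counts, channels=channels, origin=origin)


def write_ion_image_imzml(image: IonImage, path) -> None:
    """Write an imzML/ibd pair (continuous mode, one m/z slot per channel)."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    mzs = (
        np.asarray(image.mz, dtype=float)
        if image.mz is not None
        else np.arange(1, len(image.channels) + 1, dtype=float) * 100.0
    )
    ny, nx = image.shape
    with ImzMLWriter(str(path), mode="continuous") as w:
        for j in range(ny):
            for i in range(nx):
                w.addSpectrum(mzs, image.counts[:, j, i], (i + 1, j + 1, 1))
    meta = {
        "pixel_size": image.pixel_size,
        "origin": list(image.origin),
        "channels": image.channels,
        "mz": mzs.tolist(),
    }
    Path(str(path)).with_suffix(".channels.json").write_text(json.dumps(meta))


def read_ion_image_imzml(path) -> IonImage:
    """Read an imzML/ibd pair written by :func:`write_ion_image_imzml`."""
    from pyimzml.ImzMLParser import ImzMLParser

    parser = ImzMLParser(str(path))
    side = Path(str(path)).with_suffix(".channels.json")
    meta = json.loads(side.read_text()) if side.exists() else {}
    xs = [c[0] for c in parser.coordinates]
    ys = [c[1] for c in parser.coordinates]
    nx, ny = max(xs), max(ys)
    first_mz, _ = parser.getspectrum(0)
    nchan = len(first_mz)
    channels = meta.get("channels", [f"mz_{m:.4f}" for m in first_mz])
    counts = np.zeros((nchan, ny, nx))
    for idx, (i, j, _) in enumerate(parser.coordinates):
        _, inten = parser.getspectrum(idx)
        counts[:, j - 1, i - 1] = inten
    return IonImage(
        pixel_size=float(meta.get("pixel_size", 1.0)),
        counts=counts,
        channels=list(channels),
        origin=tuple(meta.get("origin", (0.0, 0.0))),
        mz=list(first_mz),
    )


# --------------------------------------------------------------------------
# ST ROI tables


def write_st_table(data, path) -> None:
    """Write an ST ROI table: meta columns then one column per gene."""
    df = data.meta.drop(columns=["roi_id"]).join(data.expression)
    df.insert(0, "roi_id", data.meta["roi_id"])
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_st_table(path, target_group=None):
    from .stclass import STROIData

    df = pd.read_csv(path, sep=_sep_for(path), comment="#")
    need = {"roi_id", "cd8_count", "nuclei_count"}
    if not need <= set(df.columns):
        raise SchemaError(f"{path}: ST table needs columns {sorted(need)}")
    meta_cols = ["roi_id", "cd8_count", "nuclei_count", "positive_index", "cd8_class"]
    genes = [c for c in df.columns if c not in meta_cols]
    return STROIData.from_counts(
        df["roi_id"], df["cd8_count"], df["nuclei_count"], df[genes], target_group
    )


# --------------------------------------------------------------------------
# run configuration + pipeline


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    ``stages`` selects among ``simulate``, ``perturb``, ``metpair`` and
    ``stclass``; when ``simulate`` is included the named presets feed the
    later stages, otherwise the input paths must be given.
    """

    output_dir: str
    stages: list[str] = field(default_factory=list)
    seed: int = 0
    perturbation_preset: str = "ARG_CD8"
    metabolomics_preset: str = "CD8_HOTSPOT"
    n_tumors: int = 6
    ring_max_extent: float = 1200.0
    ring_depth: float = 300.0
    pseudocount: float = 0.0
    min_fold: float = 0.5
    max_separation: float = 4000.0
    quantile: float = 0.95
    cell_table: str | None = None
    layout: str | None = None
    ion_image: str | None = None
    st_table: str | None = None
    gene_sets: str | None = None
    target_group: list[str] | None = None

    KNOWN_STAGES = ("simulate", "perturb", "metpair", "stclass")

    def validate(self) -> None:
        for s in self.stages:
            if s not in self.KNOWN_STAGES:
                raise ValidationError(f"unknown stage {s!r}")
        RingSpec(self.ring_max_extent, self.ring_depth)
        if self.pseudocount < 0 or self.min_fold < 0 or self.max_separation <= 0:
            raise ValidationError("invalid pipeline parameters")
        if not 0 < self.quantile < 1:
            raise ValidationError("quantile must be in (0, 1)")
        if self.n_tumors < 1:
            raise ValidationError("n_tumors must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        cfg = cls(**yaml.safe_load(Path(path).read_text()))
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages and write a run manifest.

    Same config + seed reproduces identical outputs; every stage failure
    aborts with a stage-tagged error.
    """
    from . import simulate
    from .enrichment import read_gmt
    from .metabolomics import PairedMetabolomicsModel
    from .perturbation import PerturbationModel
    from .stclass import STClassificationModel

    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "software": {"name": "imdkit", "version": __version__},
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
        "outputs": [],
    }

    def _record(stage, *paths):
        manifest["stages"][stage] = "ok"
        manifest["outputs"].extend(str(p) for p in paths)

    spec = RingSpec(config.ring_max_extent, config.ring_depth)
    tumors = None
    image = cells_met = None
    try:
        if "simulate" in config.stages:
            sc = simulate.perturbation_scenario(
                config.perturbation_preset, seed=config.seed, n_tumors=config.n_tumors
            )
            tumors, _ = simulate.gen_experiment(sc)
            for cells, layout in tumors:
                write_cell_table(cells, out / f"cells_{layout.device_id}.csv")
                write_device_layout(layout, out / f"layout_{layout.device_id}.csv")
            msc = simulate.metabolomics_scenario(
                config.metabolomics_preset, seed=config.seed
            )
            image, cells_met = simulate.gen_ion_image(msc)
            write_ion_image(image, out / "ion_image.csv")
            write_cell_table(cells_met, out / "cells_metabolomics.csv")
            _record("simulate", *sorted(out.glob("cells_*.csv")), out / "ion_image.csv")
        if "perturb" in config.stages:
            if tumors is None:
                cells = read_cell_table(config.cell_table)
                layout = read_device_layout(config.layout)
                tumors = [
                    (grp, layout) for _, grp in cells.groupby("tumor_id", sort=True)
                ]
            model = PerturbationModel.from_tumors(
                tumors, ring_spec=spec, pseudocount=config.pseudocount
            )
            res = model.fit()
            res.to_csv(out / "effect_table.csv")
            _record("perturb", out / "effect_table.csv")
        if "metpair" in config.stages:
            if image is None:
                image = read_ion_image(config.ion_image)
                cells_met = read_cell_table(config.cell_table)
            marker = (
                simulate.metabolomics_scenario(config.metabolomics_preset).hotspot_marker
                if "simulate" in config.stages
                else "CD8"
            )
            mm = PairedMetabolomicsModel(
                image,
                cells_met,
                marker,
                quantile=config.quantile,
                min_fold=config.min_fold,
                max_separation=config.max_separation,
            )
            mres = mm.fit()
            mres.stats.to_csv(out / "metabolite_stats.csv", index=False)
            _record("metpair", out / "metabolite_stats.csv")
        if "stclass" in config.stages:
            if config.st_table:
                data = read_st_table(config.st_table, config.target_group)
            else:
                data = simulate.gen_st_rois(simulate.st_scenario(seed=config.seed))
            sres = STClassificationModel(data).fit()
            pd.Series(sres.class_counts).to_csv(out / "st_class_counts.csv")
            for (a, b), de in sres.de.items():
                de.to_csv(out / f"st_de_{a}_vs_{b}.csv", index=False)
            sets = (
                read_gmt(config.gene_sets)
                if config.gene_sets
                else simulate.default_gene_sets()
            )
            if ("high", "low") in sres.de:
                sres.enrichment(sets).to_csv(out / "st_enrichment.csv", index=False)
            _record("stclass", *sorted(out.glob("st_*.csv")))
    except Exception as exc:  # annotate with the failing stage
        done = set(manifest["stages"])
        pending = [s for s in config.stages if s not in done]
        stage = pending[0] if pending else "unknown"
        manifest["stages"][stage] = f"failed: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        raise ValidationError(f"stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
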