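"""End-to-end pipeline: preprocessing through densities, heatmap and stats.

One configuration document drives the whole analysis:

    background subtraction -> particle removal -> Otsu threshold ->
    small-object removal -> skeletonization -> counting frames ->
    per-frame densities -> per-ROI summaries -> density heatmap ->
    ANOVA / Tukey report

Every run writes a manifest with the configuration snapshot, per-stage
counts and wall-clock, and SHA-256 checksums of all outputs, so a run is
auditable stage by stage and reproducibility is checkable byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .densitometry import (
    RoiSpec,
    compute_density,
    density_heatmap,
    place_counting_frames,
    records_to_frame,
    roi_density,
    summaries_to_frame,
    summarize_density,
)
from .imageproc import (
    PreprocConfig,
    Raster2D,
    median_despeckle,
    otsu_threshold,
    read_tiff,
    remove_small_objects,
    skeletonize,
    subtract_background,
    write_mask,
)
from .regional_stats import build_stats_report

logger = logging.getLogger("atriadense")

__all__ = ["PipelineConfig", "RunManifest", "load_rois", "run_pipeline", "segment_image"]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for one quantification run.

    Defaults follow the published pipeline where it states a value
    (background radius 80 px, six counting frames, alpha 0.05); frame size
    (200x200 um) and placement strategy are artifact defaults recorded in
    the output manifest.
    """

    image: str
    pixel_size_um: float
    rois: str | None = None
    out_dir: str = "atriadense_out"
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    n_frames: int = 6
    frame_size_um: tuple[float, float] = (200.0, 200.0)
    frame_strategy: str = "grid"
    length_method: str = "pixel_count"
    tile_px: int = 64
    alpha: float = 0.05
    seed: int = 0
    heatmap_colormap: str = "turbo"

    def __post_init__(self) -> None:
        if not self.pixel_size_um or self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be a positive number")
        if self.n_frames < 2:
            raise ValueError("need >= 2 counting frames per ROI for a SEM")
        if self.length_method not in ("pixel_count", "diagonal_corrected"):
            raise ValueError(f"unknown length method {self.length_method!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        doc = dict(doc)
        if "pixel_size_um" not in doc:
            raise ValueError("config is missing required key 'pixel_size_um'")
        if "image" not in doc:
            raise ValueError("config is missing required key 'image'")
        if "preproc" in doc and isinstance(doc["preproc"], dict):
            doc["preproc"] = PreprocConfig(**doc["preproc"])
        if "frame_size_um" in doc:
            doc["frame_size_um"] = tuple(doc["frame_size_um"])
        return cls(**doc)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["version"] = __version__
        return d


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: list[dict] = field(default_factory=list)
    checksums: dict[str, str] = field(default_factory=dict)

    def add_stage(self, name: str, seconds: float, **counts) -> None:
        self.stages.append({"stage": name, "seconds": round(seconds, 4), **counts})

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# ROI loading


def load_rois(
    source: str | Path,
    image_shape: tuple[int, int],
    pixel_size_um: float = 1.0,
) -> list[RoiSpec]:
    """Load ROI definitions from a label image or a polygon JSON file.

    Label image: integer TIFF/PNG whose nonzero labels map to names via a
    sibling ``*_names.json`` / ``roi_names.json``.  Polygon JSON: a list of
    ``{"name", "include": [[x, y], ...] (um), "exclude": optional}``
    entries; polygons are rasterized at the given pixel size and clipped to
    the image bounds (with a log message when clipping occurs).
    """
    source = Path(source)
    if source.suffix.lower() == ".json":
        return _rois_from_polygons(source, image_shape, pixel_size_um)
    return _rois_from_labels(source, image_shape)


def _rois_from_labels(source: Path, image_shape: tuple[int, int]) -> list[RoiSpec]:
    import imageio.v3 as iio
    import tifffile

    if source.suffix.lower() in (".tif", ".tiff"):
        labels = tifffile.imread(source)
    else:
        labels = iio.imread(source)
    if labels.shape != image_shape:
        raise ValueError(f"ROI label image shape {labels.shape} != image shape {image_shape}")
    names_path = None
    for cand in (source.with_name(source.stem + "_names.json"), source.with_name("roi_names.json")):
        if cand.exists():
            names_path = cand
            break
    values = [int(v) for v in np.unique(labels) if v != 0]
    if names_path is not None:
        name_map = {int(k): str(v) for k, v in json.loads(names_path.read_text()).items()}
    else:
        name_map = {v: f"roi_{v}" for v in values}
    rois = []
    for v in values:
        name = name_map.get(v, f"roi_{v}")
        rois.append(RoiSpec(name, labels == v))
    if not rois:
        raise ValueError(f"{source}: label image contains no nonzero ROI labels")
    return rois


def _rois_from_polygons(
    source: Path, image_shape: tuple[int, int], pixel_size_um: float
) -> list[RoiSpec]:
    from skimage.draw import polygon as draw_polygon

    doc = json.loads(source.read_text())
    entries = doc["rois"] if isinstance(doc, dict) else doc
    h, w = image_shape
    rois = []
    claimed = np.zeros(image_shape, dtype=bool)
    for entry in entries:
        name = entry["name"]

        def rasterize(pts_um) -> np.ndarray:
            pts = np.asarray(pts_um, dtype=np.float64) / pixel_size_um
            if (pts < -0.5).any() or (pts[:, 0] > w - 0.5).any() or (pts[:, 1] > h - 0.5).any():
                logger.info("ROI %s: polygon extends outside image bounds; clipping", name)
            rr, cc = draw_polygon(pts[:, 1], pts[:, 0], shape=image_shape)
            mask = np.zeros(image_shape, dtype=bool)
            mask[rr, cc] = True
            return mask

        include = rasterize(entry["include"])
        exclude = rasterize(entry["exclude"]) if entry.get("exclude") else None
        overlap = claimed & include
        if overlap.any():
            logger.warning(
                "ROI %s overlaps a previously defined ROI on %d px; earlier ROI takes precedence",
                name,
                int(overlap.sum()),
            )
            include = include & ~claimed
        claimed |= include
        rois.append(RoiSpec(name, include, exclude))
    return rois


# ---------------------------------------------------------------------------
# pipeline


def segment_image(img: Raster2D, preproc: PreprocConfig):
    """Steps 1-4: background subtraction, particle removal, Otsu, size filter.

    Returns ``(skeleton, info)`` where ``info`` carries per-stage counts.
    """
    info: dict[str, float] = {}
    t0 = time.perf_counter()
    work = subtract_background(img, preproc.background_radius_px)
    info["background_s"] = time.perf_counter() - t0
    if preproc.despeckle:
        work = median_despeckle(work)
    threshold, mask = otsu_threshold(work, preproc.otsu_bins)
    info["otsu_threshold"] = threshold
    info["foreground_px"] = int(np.count_nonzero(mask.pixels))
    cleaned = remove_small_objects(mask, preproc.min_particle_area_px)
    info["removed_px"] = info["foreground_px"] - int(np.count_nonzero(cleaned.pixels))
    skel = skeletonize(cleaned)
    info["skeleton_px"] = int(np.count_nonzero(skel.pixels))
    return skel, info


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Execute the full analysis and write all artifacts plus a manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg.to_dict(), version=__version__)

    stage = "load_image"
    try:
        t0 = time.perf_counter()
        img = read_tiff(cfg.image, cfg.pixel_size_um)
        manifest.add_stage(stage, time.perf_counter() - t0, shape=list(img.shape))

        stage = "segment"
        t0 = time.perf_counter()
        skel, info = segment_image(img, cfg.preproc)
        manifest.add_stage(stage, time.perf_counter() - t0, **info)
        write_mask(out / "skeleton.tif", skel)

        stage = "load_rois"
        t0 = time.perf_counter()
        if cfg.rois:
            rois = load_rois(cfg.rois, img.shape, cfg.pixel_size_um)
        else:
            rois = [RoiSpec("image", np.ones(img.shape, dtype=bool))]
        manifest.add_stage(stage, time.perf_counter() - t0, n_rois=len(rois))

        stage = "counting_frames"
        t0 = time.perf_counter()
        fh = int(round(cfg.frame_size_um[0] / cfg.pixel_size_um))
        fw = int(round(cfg.frame_size_um[1] / cfg.pixel_size_um))
        frames = []
        for roi in rois:
            frames.extend(
                place_counting_frames(
                    roi, cfg.n_frames, (fh, fw), cfg.frame_strategy, cfg.seed
                )
            )
        placement = [dataclasses.asdict(f) for f in frames]
        (out / "frame_placement.json").write_text(
            json.dumps({"strategy": cfg.frame_strategy, "seed": cfg.seed, "frames": placement}, indent=1)
        )
        manifest.add_stage(stage, time.perf_counter() - t0, n_frames=len(frames))

        stage = "densities"
        t0 = time.perf_counter()
        records = compute_density(skel, frames, cfg.length_method)
        rec_df = records_to_frame(records)
        rec_df.to_csv(out / "density_records.csv", index=False, float_format="%.6f")
        summaries = summarize_density(records)
        roi_rows = []
        for s in summaries:
            roi = next(r for r in rois if r.name == s.roi)
            length, dens = roi_density(skel, roi, cfg.length_method)
            roi_rows.append({"roi": s.roi, "roi_length_um": length, "roi_density_um_per_mm2": dens})
        sum_df = summaries_to_frame(summaries).merge(pd.DataFrame(roi_rows), on="roi")
        sum_df.to_csv(out / "density_summary.csv", index=False, float_format="%.6f")
        manifest.add_stage(stage, time.perf_counter() - t0, n_records=len(records))

        stage = "heatmap"
        t0 = time.perf_counter()
        grid = density_heatmap(skel, cfg.tile_px, cfg.length_method)
        np.savetxt(out / "heatmap.csv", grid.densities, delimiter=",", fmt="%.6f")
        _render_heatmap_png(grid, out / "heatmap.png", cfg.heatmap_colormap)
        manifest.add_stage(stage, time.perf_counter() - t0, tiles=list(grid.densities.shape))

        stage = "stats"
        t0 = time.perf_counter()
        if len(rois) >= 2:
            report = build_stats_report(records, cfg.alpha)
            (out / "stats_report.json").write_text(report.to_json())
            report.tukey_frame().to_csv(out / "stats_report.csv", index=False, float_format="%.6g")
            manifest.add_stage(stage, time.perf_counter() - t0, anova_p=report.anova.p)
        else:
            manifest.add_stage(stage, 0.0, skipped="single ROI")
    except Exception as exc:
        manifest.stages.append({"stage": stage, "error": str(exc)})
        manifest.write(out / "manifest.json")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    for path in sorted(out.iterdir()):
        if path.name != "manifest.json" and path.is_file():
            manifest.checksums[path.name] = _sha256(path)
    manifest.write(out / "manifest.json")
    return manifest


def _render_heatmap_png(grid, path: Path, colormap: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(grid.densities, cmap=colormap, interpolation="nearest")
    fig.colorbar(im, ax=ax, label="axon density (μm/mm²)")
    ax.set_title("TH-IR axon density heatmap")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=120, metadata={"Software": "atriadense"})
    plt.close(fig)
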