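"""Axon length and areal density from skeleton masks.

The published statistic is axon length per tissue area, in um/mm^2: the
segmented axon mask is thinned to 1-px centerlines, skeleton pixels are
counted inside six counting frames per region of interest, pixel counts
are converted to um, and densities are averaged over frames (mean +/- SEM).

Two length estimators are provided:

``pixel_count``
    ``N_foreground * pixel_size_um`` — literally what the source pipeline
    measured.  Exact for axis-aligned lines, understates oblique ones (a
    45-degree run of pixels covers sqrt(2) um per pixel but counts 1).

``diagonal_corrected``
    The weight of a spanning forest of the 8-adjacency skeleton graph with
    edge weights 1 (orthogonal) / sqrt(2) (diagonal), plus one pixel per
    connected component (endpoint convention), times the pixel size.
    Unbiased for axis-aligned and 45-degree runs; known to overestimate
    intermediate orientations by up to ~8% (worst near 30/60 degrees).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree

from .imageproc import BinaryMask, SkeletonMask, has_thick_block

__all__ = [
    "RoiSpec",
    "CountingFrame",
    "DensityRecord",
    "DensitySummary",
    "HeatmapGrid",
    "FramePlacementError",
    "skeleton_length",
    "place_counting_frames",
    "compute_density",
    "summarize_density",
    "density_heatmap",
    "roi_density",
    "records_to_frame",
    "summaries_to_frame",
]

SQRT2 = math.sqrt(2.0)


class FramePlacementError(RuntimeError):
    """Raised when an ROI cannot accommodate the requested counting frames."""


@dataclass(frozen=True)
class RoiSpec:
    """A named region of interest with optional exclusion geometry.

    ``include`` / ``exclude`` are boolean pixel masks in image geometry.
    Excluded territory (e.g. large TH-IR bundles and intrinsic cardiac
    ganglia, which would otherwise inflate axon densities) never receives
    counting frames.
    """

    name: str
    include: np.ndarray
    exclude: np.ndarray | None = None

    def __post_init__(self) -> None:
        inc = np.asarray(self.include, dtype=bool)
        object.__setattr__(self, "include", inc)
        if self.exclude is not None:
            exc = np.asarray(self.exclude, dtype=bool)
            if exc.shape != inc.shape:
                raise ValueError(f"ROI {self.name!r}: exclude shape differs from include")
            object.__setattr__(self, "exclude", exc)
        if not np.any(self.allowed()):
            raise ValueError(f"ROI {self.name!r} is empty after exclusion")

    def allowed(self) -> np.ndarray:
        if self.exclude is None:
            return self.include
        return self.include & ~self.exclude


@dataclass(frozen=True)
class CountingFrame:
    """A fixed-size sampling window inside an ROI."""

    roi: str
    frame_id: int
    row0: int
    col0: int
    height_px: int
    width_px: int

    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row0, self.row0 + self.height_px),
            slice(self.col0, self.col0 + self.width_px),
        )

    def overlaps(self, other: "CountingFrame") -> bool:
        return not (
            self.row0 + self.height_px <= other.row0
            or other.row0 + other.height_px <= self.row0
            or self.col0 + self.width_px <= other.col0
            or other.col0 + other.width_px <= self.col0
        )


@dataclass(frozen=True)
class DensityRecord:
    roi: str
    frame_id: int
    axon_length_um: float
    frame_area_mm2: float
    density_um_per_mm2: float


@dataclass(frozen=True)
class DensitySummary:
    roi: str
    mean_density: float
    sem: float
    n_frames: int


@dataclass(frozen=True)
class HeatmapGrid:
    """Per-tile axon length (um) and density (um/mm^2) over a tiling."""

    tile_px: int
    lengths_um: np.ndarray
    densities: np.ndarray
    areas_mm2: np.ndarray
    colormap: str = "turbo"


# ---------------------------------------------------------------------------
# length estimation


def _check_skeleton(skel: SkeletonMask | BinaryMask) -> np.ndarray:
    m = skel.pixels
    if has_thick_block(m):
        raise ValueError("input is not a valid skeleton: contains a 2x2 foreground block")
    return m


def _forest_length_px(mask: np.ndarray) -> float:
    """Spanning-forest length of the 8-adjacency graph, in pixel units.

    Builds the graph over foreground pixels with weights 1 (N/E/S/W) and
    sqrt(2) (diagonals), takes a minimum spanning forest, and adds 1 px per
    connected component (so an L-pixel straight chain measures exactly L).
    """
    coords = np.argwhere(mask)
    n = len(coords)
    if n == 0:
        return 0.0
    index = -np.ones(mask.shape, dtype=np.int64)
    index[coords[:, 0], coords[:, 1]] = np.arange(n)
    rows_i: list[np.ndarray] = []
    cols_j: list[np.ndarray] = []
    wts: list[np.ndarray] = []
    h, w = mask.shape
    # right, down, down-right, down-left cover each undirected edge once
    for dr, dc, wgt in ((0, 1, 1.0), (1, 0, 1.0), (1, 1, SQRT2), (1, -1, SQRT2)):
        rr = coords[:, 0] + dr
        cc = coords[:, 1] + dc
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        ok[ok] &= mask[rr[ok], cc[ok]]
        if not np.any(ok):
            continue
        rows_i.append(index[coords[ok, 0], coords[ok, 1]])
        cols_j.append(index[rr[ok], cc[ok]])
        wts.append(np.full(int(ok.sum()), wgt))
    if not rows_i:
        return float(n)  # isolated pixels only: 1 px each
    graph = coo_matrix(
        (np.concatenate(wts), (np.concatenate(rows_i), np.concatenate(cols_j))), shape=(n, n)
    ).tocsr()
    forest = minimum_spanning_tree(graph)
    n_comp, _ = connected_components(graph, directed=False)
    return float(forest.sum()) + float(n_comp)


def skeleton_length(skel: SkeletonMask, method: str = "pixel_count") -> float:
    """Total skeleton length in micrometres.

    ``method`` is ``"pixel_count"`` (the published statistic) or
    ``"diagonal_corrected"`` (spanning-forest estimator, see module notes).
    """
    mask = _check_skeleton(skel)
    if method == "pixel_count":
        return float(np.count_nonzero(mask)) * skel.pixel_size_um
    if method == "diagonal_corrected":
        return _forest_length_px(mask) * skel.pixel_size_um
    raise ValueError(f"unknown length method {method!r}")


# ---------------------------------------------------------------------------
# counting frames


def _frame_fits(allowed_sums: np.ndarray, r: int, c: int, h: int, w: int) -> bool:
    # allowed_sums is the 2-D inclusive prefix sum of the allowed mask
    total = (
        allowed_sums[r + h, c + w]
        - allowed_sums[r, c + w]
        - allowed_sums[r + h, c]
        + allowed_sums[r, c]
    )
    return total == h * w


def place_counting_frames(
    roi: RoiSpec,
    n: int = 6,
    frame_px: tuple[int, int] = (200, 200),
    strategy: str = "grid",
    seed: int = 0,
) -> list[CountingFrame]:
    """Place ``n`` disjoint frames fully inside the ROI's allowed territory.

    ``grid`` packs candidate positions on a regular lattice of the frame
    size and picks ``n`` evenly spaced candidates (deterministic);
    ``random`` rejection-samples disjoint positions from a seeded stream.
    Raises :class:`FramePlacementError` if the ROI cannot host ``n`` frames.
    """
    fh, fw = frame_px
    allowed = roi.allowed()
    H, W = allowed.shape
    if fh > H or fw > W:
        raise FramePlacementError(
            f"ROI {roi.name!r}: frame {frame_px} exceeds image extent {allowed.shape}"
        )
    sums = np.zeros((H + 1, W + 1), dtype=np.int64)
    np.cumsum(np.cumsum(allowed, axis=0), axis=1, out=sums[1:, 1:])

    frames: list[CountingFrame] = []
    if strategy == "grid":
        candidates = [
            (r, c)
            for r in range(0, H - fh + 1, fh)
            for c in range(0, W - fw + 1, fw)
            if _frame_fits(sums, r, c, fh, fw)
        ]
        if len(candidates) < n:
            raise FramePlacementError(
                f"ROI {roi.name!r}: only {len(candidates)} grid positions for {n} frames"
            )
        pick = np.unique(np.round(np.linspace(0, len(candidates) - 1, n)).astype(int))
        i = 0
        while len(pick) < n:  # resolve rounding collisions
            if i not in pick:
                pick = np.sort(np.append(pick, i))
            i += 1
        for k, idx in enumerate(pick[:n]):
            r, c = candidates[int(idx)]
            frames.append(CountingFrame(roi.name, k, r, c, fh, fw))
    elif strategy == "random":
        rng = np.random.default_rng(seed)
        tries = 0
        while len(frames) < n and tries < 20000:
            tries += 1
            r = int(rng.integers(0, H - fh + 1))
            c = int(rng.integers(0, W - fw + 1))
            cand = CountingFrame(roi.name, len(frames), r, c, fh, fw)
            if _frame_fits(sums, r, c, fh, fw) and not any(cand.overlaps(f) for f in frames):
                frames.append(cand)
        if len(frames) < n:
            raise FramePlacementError(
                f"ROI {roi.name!r}: random placement found {len(frames)}/{n} disjoint frames"
            )
    else:
        raise ValueError(f"unknown placement strategy {strategy!r}")
    return frames


# ---------------------------------------------------------------------------
# densities


def _frame_length_um(skel: SkeletonMask, frame: CountingFrame, method: str) -> float:
    sub = skel.pixels[frame.slices()]
    if method == "pixel_count":
        return float(np.count_nonzero(sub)) * skel.pixel_size_um
    if method == "diagonal_corrected":
        return _forest_length_px(sub) * skel.pixel_size_um
    raise ValueError(f"unknown length method {method!r}")


def compute_density(
    skel: SkeletonMask,
    frames: list[CountingFrame],
    method: str = "pixel_count",
) -> list[DensityRecord]:
    """One density record per counting frame, in um/mm^2."""
    _check_skeleton(skel)
    H, W = skel.shape
    for i, f in enumerate(frames):
        if f.row0 < 0 or f.col0 < 0 or f.row0 + f.height_px > H or f.col0 + f.width_px > W:
            raise ValueError(f"frame {f.roi}/{f.frame_id} lies outside the raster")
        for g in frames[i + 1 :]:
            if f.roi == g.roi and f.overlaps(g):
                raise ValueError(f"frames {f.frame_id} and {g.frame_id} in ROI {f.roi!r} overlap")
    records = []
    px = skel.pixel_size_um
    for f in frames:
        length = _frame_length_um(skel, f, method)
        area_mm2 = f.height_px * f.width_px * px**2 / 1e6
        records.append(
            DensityRecord(f.roi, f.frame_id, length, area_mm2, length / area_mm2)
        )
    return records


def roi_density(
    skel: SkeletonMask, roi: RoiSpec, method: str = "pixel_count"
) -> tuple[float, float]:
    """Whole-ROI (length_um, density_um_per_mm2) over the allowed territory."""
    allowed = roi.allowed()
    masked = SkeletonMask(skel.pixels & allowed, skel.pixel_size_um)
    length = skeleton_length(masked, method)
    area_mm2 = float(np.count_nonzero(allowed)) * skel.pixel_size_um**2 / 1e6
    return length, length / area_mm2


def summarize_density(records: list[DensityRecord]) -> list[DensitySummary]:
    """Per-ROI mean and SEM over frames, ordered from high to low mean."""
    by_roi: dict[str, list[float]] = {}
    for rec in records:
        by_roi.setdefault(rec.roi, []).append(rec.density_um_per_mm2)
    out = []
    for roi, vals in by_roi.items():
        if len(vals) < 2:
            raise ValueError(f"ROI {roi!r} has a single frame: SEM undefined")
        arr = np.asarray(vals, dtype=np.float64)
        sem = float(arr.std(ddof=1) / math.sqrt(len(arr)))
        out.append(DensitySummary(roi, float(arr.mean()), sem, len(arr)))
    out.sort(key=lambda s: -s.mean_density)
    return out


def density_heatmap(
    skel: SkeletonMask, tile_px: int = 64, method: str = "pixel_count"
) -> HeatmapGrid:
    """Tile the raster and report per-tile axon length and density.

    Ragged edge tiles are kept and use their true pixel area, so borders
    are not artificially cold.  Under ``pixel_count`` the tile lengths sum
    exactly to the whole-image skeleton length.
    """
    if tile_px < 8:
        raise ValueError("tile_px must be >= 8")
    _check_skeleton(skel)
    H, W = skel.shape
    nr = math.ceil(H / tile_px)
    nc = math.ceil(W / tile_px)
    lengths = np.zeros((nr, nc))
    areas = np.zeros((nr, nc))
    px = skel.pixel_size_um
    for i in range(nr):
        for j in range(nc):
            sub = skel.pixels[i * tile_px : min((i + 1) * tile_px, H), j * tile_px : min((j + 1) * tile_px, W)]
            if method == "pixel_count":
                lengths[i, j] = np.count_nonzero(sub) * px
            else:
                lengths[i, j] = _forest_length_px(sub) * px
            areas[i, j] = sub.size * px**2 / 1e6
    return HeatmapGrid(tile_px, lengths, lengths / areas, areas)


# ---------------------------------------------------------------------------
# tabular views


def records_to_frame(records: list[DensityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "roi": r.roi,
                "frame_id": r.frame_id,
                "length_um": r.axon_length_um,
                "area_mm2": r.frame_area_mm2,
                "density_um_per_mm2": r.density_um_per_mm2,
            }
            for r in records
        ]
    )


def summaries_to_frame(summaries: list[DensitySummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "roi": s.roi,
                "mean_density_um_per_mm2": s.mean_density,
                "sem_um_per_mm2": s.sem,
                "n_frames": s.n_frames,
            }
            for s in summaries
        ]
    )
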