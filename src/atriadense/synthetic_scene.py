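"""Synthetic flat-mount scene generator with exact ground truth.

Generates 2-D fluorescence images that emulate TH-immunoreactive atrial
flat-mounts — thin varicose branching axons, bright ~20 um principal
somata, small (<10 um) intensely fluorescent (SIF) cell clusters of 3-8,
large dim adipocyte autofluorescence blobs, smooth uneven illumination and
Poisson + Gaussian noise — together with the exact analytic ground truth
(axon polylines with per-region lengths, full cell inventory) needed to
validate every downstream densitometry stage.

Axon arbors grow as a persistent-turning random walk with Poisson
branching; the growth budget is spent exactly, so the true total length per
region is controlled analytically rather than measured from pixels.

All randomness flows from a single scene seed through named streams
(:mod:`atriadense._rng`), so e.g. enabling the adipocyte distractor class
never perturbs axon geometry.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi

from ._rng import stream_rng
from .imageproc import Raster2D, write_tiff

__all__ = [
    "ArborGrowthParams",
    "CellPopulationParams",
    "OpticsParams",
    "RegionDef",
    "SceneConfig",
    "CellTruth",
    "Arbor",
    "SceneTruth",
    "simulate_arbor",
    "simulate_scene",
    "render_scene",
    "export_fixture",
    "import_fixture",
    "polyline_length",
    "region_lengths_from_rects",
    "region_lengths_from_labels",
    "write_swc",
]


# ---------------------------------------------------------------------------
# parameter blocks


@dataclass(frozen=True)
class ArborGrowthParams:
    """Growth model for one axon arbor.

    A tip advances in steps of ``step_um``; its heading receives Gaussian
    turns of standard deviation ``(1 - persistence) * pi/2`` radians per
    step, so ``persistence=1`` grows a straight axon.  Bifurcations occur
    as a Poisson process with rate ``branch_rate_per_um``.  Growth stops
    when the total deposited length reaches ``max_total_length_um`` (spent
    exactly, the final step being trimmed).
    """

    n_roots: int = 1
    step_um: float = 4.0
    persistence: float = 0.95
    branch_rate_per_um: float = 0.01
    max_total_length_um: float = 500.0
    varicosity_spacing_um: float = 6.0
    axon_width_um: float = 1.0
    mean_arbor_length_um: float = 400.0  # regional budget per root in simulate_scene
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_roots < 1:
            raise ValueError("n_roots must be >= 1")
        if not self.step_um > 0:
            raise ValueError("step_um must be > 0")
        if not self.max_total_length_um > 0:
            raise ValueError("max_total_length_um must be > 0")
        if not 0.0 <= self.persistence <= 1.0:
            raise ValueError("persistence must be in [0, 1]")
        if self.branch_rate_per_um < 0:
            raise ValueError("branch_rate_per_um must be >= 0")
        if not (self.varicosity_spacing_um > 0 and self.axon_width_um > 0):
            raise ValueError("varicosity spacing and axon width must be > 0")
        if not self.mean_arbor_length_um > 0:
            raise ValueError("mean_arbor_length_um must be > 0")


@dataclass(frozen=True)
class CellPopulationParams:
    """Soma populations: principal ICG neurons (~20 um) and SIF cells.

    SIF diameters are drawn truncated below 10 um and principal diameters
    truncated above 14 um, so the two classes have non-overlapping support
    and classification ground truth is unambiguous.  ``th_positive_fraction``
    is the probability that a principal neuron is TH-positive (the study
    organism shows roughly 18-30%).
    """

    n_principal: int = 20
    principal_diameter_um: float = 20.0
    principal_diameter_sd_um: float = 2.0
    sif_cluster_count: int = 3
    sif_cluster_size_range: tuple[int, int] = (3, 8)
    sif_diameter_um: float = 7.0
    sif_diameter_sd_um: float = 1.0
    sif_intensity_gain: float = 1.8
    th_positive_fraction: float = 0.24

    _PRINCIPAL_DIAM_BOUNDS = (14.0, 28.0)
    _SIF_DIAM_BOUNDS = (4.0, 9.5)

    def __post_init__(self) -> None:
        if self.n_principal < 0 or self.sif_cluster_count < 0:
            raise ValueError("cell counts must be >= 0")
        lo, hi = self.sif_cluster_size_range
        if not (1 <= lo <= hi):
            raise ValueError("sif_cluster_size_range must satisfy 1 <= lo <= hi")
        if not (self.principal_diameter_um > 0 and self.sif_diameter_um > 0):
            raise ValueError("diameters must be > 0")
        if self.sif_diameter_um >= 10.0:
            raise ValueError("sif_diameter_um must be < 10 um")
        if not self.sif_intensity_gain > 1.0:
            raise ValueError("sif_intensity_gain must be > 1")
        if not 0.0 <= self.th_positive_fraction <= 1.0:
            raise ValueError("th_positive_fraction must be in [0, 1]")


@dataclass(frozen=True)
class OpticsParams:
    """Rendering and acquisition model.

    Signal amplitudes are in camera intensity units of the target bit
    depth.  Photon shot noise is modeled as ``Poisson(I * g) / g`` with
    ``g = poisson_gain`` photons per intensity unit; ``gaussian_sigma`` is
    additive read noise.  The point-spread function is an isotropic
    Gaussian of ``psf_sigma_um``.
    """

    pixel_size_um: float = 0.5
    background_level: float = 30.0
    illumination_gradient_amplitude: float = 0.2
    poisson_gain: float = 0.5
    gaussian_sigma: float = 2.0
    psf_sigma_um: float = 1.0
    bit_depth: int = 8
    axon_intensity: float = 120.0
    varicosity_gain: float = 2.0
    soma_intensity: float = 120.0
    th_negative_intensity_fraction: float = 0.15
    n_fat_blobs: int = 6
    fat_intensity: float = 35.0
    fat_sigma_um_range: tuple[float, float] = (25.0, 60.0)

    def __post_init__(self) -> None:
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        for name in ("background_level", "illumination_gradient_amplitude", "poisson_gain",
                     "gaussian_sigma", "psf_sigma_um", "fat_intensity"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class RegionDef:
    """A rectangular region of interest with a target true axon density."""

    name: str
    rect_um: tuple[float, float, float, float]  # x0, y0, x1, y1
    density_um_per_mm2: float

    def area_mm2(self) -> float:
        x0, y0, x1, y1 = self.rect_um
        return (x1 - x0) * (y1 - y0) / 1e6

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.rect_um
        if not (x1 > x0 and y1 > y0):
            raise ValueError(f"degenerate rect for region {self.name!r}")
        if self.density_um_per_mm2 < 0:
            raise ValueError("density must be >= 0")


@dataclass(frozen=True)
class SceneConfig:
    """Full scene recipe: canvas, regions, growth model, cells, optics."""

    shape_px: tuple[int, int] = (2048, 2048)
    regions: tuple[RegionDef, ...] = ()
    arbor: ArborGrowthParams = field(default_factory=ArborGrowthParams)
    cells: CellPopulationParams | None = field(default_factory=CellPopulationParams)
    optics: OpticsParams = field(default_factory=OpticsParams)
    seed: int = 0


# ---------------------------------------------------------------------------
# ground truth containers


@dataclass
class CellTruth:
    center_um: tuple[float, float]  # (x, y)
    diameter_um: float
    cell_class: str  # "principal" | "SIF"
    th_positive: bool


@dataclass
class Arbor:
    """A rooted tree of 2-D nodes; parent -1 marks the root."""

    nodes_um: np.ndarray  # (N, 2) x, y
    parents: np.ndarray  # (N,) int
    region: str = "scene"

    def polylines(self) -> list[np.ndarray]:
        """Maximal unbranched chains (root/branch point to branch point/leaf).

        Every edge belongs to exactly one chain, so summed chain lengths
        equal the arbor's total edge length.
        """
        n = len(self.parents)
        children: list[list[int]] = [[] for _ in range(n)]
        for i, p in enumerate(self.parents):
            if p >= 0:
                children[p].append(i)
        chains: list[np.ndarray] = []
        breakpoints = [i for i in range(n) if self.parents[i] == -1 or len(children[i]) >= 2]
        for b in breakpoints:
            for k in children[b]:
                path = [b, k]
                cur = k
                while len(children[cur]) == 1:
                    cur = children[cur][0]
                    path.append(cur)
                chains.append(self.nodes_um[np.array(path)])
        return chains

    def total_length_um(self) -> float:
        valid = self.parents >= 0
        child = self.nodes_um[valid]
        par = self.nodes_um[self.parents[valid]]
        return float(np.linalg.norm(child - par, axis=1).sum())


@dataclass
class SceneTruth:
    """Exact ground truth for one simulated scene."""

    polylines: list[tuple[str, np.ndarray]]
    per_region_length_um: dict[str, float]
    soma_inventory: list[CellTruth]
    seed: int
    params: dict
    arbors: list[Arbor] = field(default_factory=list)
    pixel_size_um: float | None = None
    shape_px: tuple[int, int] | None = None

    def total_length_um(self) -> float:
        return float(sum(self.per_region_length_um.values()))


def polyline_length(vertices: np.ndarray) -> float:
    v = np.asarray(vertices, dtype=np.float64)
    if len(v) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(v, axis=0), axis=1).sum())


# ---------------------------------------------------------------------------
# arbor growth


def _grow_arbor(
    params: ArborGrowthParams,
    rng: np.random.Generator,
    bounds_um: tuple[float, float, float, float] | None,
    roots_um: np.ndarray | None,
) -> Arbor:
    turn_sd = (1.0 - params.persistence) * (math.pi / 2.0)
    if roots_um is None:
        if bounds_um is None:
            roots_um = np.zeros((params.n_roots, 2))
        else:
            x0, y0, x1, y1 = bounds_um
            roots_um = np.column_stack(
                [rng.uniform(x0, x1, params.n_roots), rng.uniform(y0, y1, params.n_roots)]
            )
    nodes: list[tuple[float, float]] = [tuple(r) for r in np.asarray(roots_um, dtype=float)]
    parents: list[int] = [-1] * len(nodes)
    # tips: (node index, heading)
    tips: list[list[float]] = [[i, rng.uniform(0.0, 2.0 * math.pi)] for i in range(len(nodes))]
    spent = 0.0
    budget = params.max_total_length_um
    cursor = 0
    while tips and budget - spent > 1e-9:
        tip = tips[cursor % len(tips)]
        step = min(params.step_um, budget - spent)
        node_idx = int(tip[0])
        heading = tip[1]
        if turn_sd > 0:
            heading += rng.normal(0.0, turn_sd)
        x, y = nodes[node_idx]
        nx, ny = x + step * math.cos(heading), y + step * math.sin(heading)
        if bounds_um is not None:
            x0, y0, x1, y1 = bounds_um
            if not (x0 <= nx <= x1 and y0 <= ny <= y1):
                # steer toward the region interior (mirror reflection makes
                # grazing tips slide along walls and overlap themselves)
                cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
                heading = math.atan2(cy - y, cx - x) + rng.normal(0.0, 0.4)
                nx, ny = x + step * math.cos(heading), y + step * math.sin(heading)
            if not (x0 <= nx <= x1 and y0 <= ny <= y1):
                # cramped region relative to the step: retire this tip
                tips.pop(cursor % len(tips))
                continue
        nodes.append((nx, ny))
        parents.append(node_idx)
        new_idx = len(nodes) - 1
        tip[0] = new_idx
        tip[1] = heading
        spent += step
        if params.branch_rate_per_um > 0 and rng.random() < params.branch_rate_per_um * step:
            # bifurcation divergence 34-69 degrees: daughters separate
            # quickly enough that their rendered tubes stay resolvable
            sign = 1.0 if rng.random() < 0.5 else -1.0
            tips.append([new_idx, heading + sign * rng.uniform(0.6, 1.2)])
        cursor += 1
    return Arbor(np.asarray(nodes, dtype=np.float64), np.asarray(parents, dtype=int))


def simulate_arbor(
    params: ArborGrowthParams,
    bounds_um: tuple[float, float, float, float] | None = None,
    region_label: str = "scene",
    rng: np.random.Generator | None = None,
) -> SceneTruth:
    """Grow one arbor set and return its exact polyline ground truth.

    Deterministic: identical ``params`` (including ``params.seed``) yield
    bit-identical vertex lists.  The summed polyline length never exceeds
    ``params.max_total_length_um`` and equals it exactly when growth is not
    boxed into a corner.
    """
    if rng is None:
        rng = stream_rng(params.seed, f"arbor/{region_label}")
    arbor = _grow_arbor(params, rng, bounds_um, roots_um=None)
    arbor.region = region_label
    polys = [(region_label, p) for p in arbor.polylines()]
    length = float(sum(polyline_length(p) for _, p in polys))
    return SceneTruth(
        polylines=polys,
        per_region_length_um={region_label: length},
        soma_inventory=[],
        seed=params.seed,
        params={"arbor": dataclasses.asdict(params)},
        arbors=[arbor],
    )


# ---------------------------------------------------------------------------
# region length measurement


def region_lengths_from_rects(
    polylines: list[tuple[str, np.ndarray]],
    rects_um: dict[str, tuple[float, float, float, float]],
) -> dict[str, float]:
    """Exact per-region polyline length by continuous segment clipping."""
    from shapely.geometry import LineString, box

    out = {name: 0.0 for name in rects_um}
    for name, (x0, y0, x1, y1) in rects_um.items():
        region = box(x0, y0, x1, y1)
        for _, verts in polylines:
            if len(verts) < 2:
                continue
            inter = LineString(verts).intersection(region)
            out[name] += float(inter.length)
    return out


def region_lengths_from_labels(
    polylines: list[tuple[str, np.ndarray]],
    label_img: np.ndarray,
    pixel_size_um: float,
    names: dict[int, str],
    step_px: float = 0.25,
) -> dict[str, float]:
    """Per-region length by midpoint sampling on a label raster.

    Each segment is split into sub-steps of at most ``step_px`` pixels and
    the sub-length is attributed to the label under the sub-segment
    midpoint (nearest pixel).  Documented approximation; the error is
    bounded by the total length of segments crossing label boundaries.
    """
    h, w = label_img.shape
    out = {name: 0.0 for name in names.values()}
    for _, verts in polylines:
        v = np.asarray(verts, dtype=np.float64) / pixel_size_um  # px coords (x, y)
        for a, b in zip(v[:-1], v[1:]):
            seg = np.linalg.norm(b - a)
            if seg == 0:
                continue
            n = max(1, int(math.ceil(seg / step_px)))
            t = (np.arange(n) + 0.5) / n
            mids = a[None, :] + t[:, None] * (b - a)[None, :]
            cols = np.clip(np.round(mids[:, 0]).astype(int), 0, w - 1)
            rows = np.clip(np.round(mids[:, 1]).astype(int), 0, h - 1)
            labels = label_img[rows, cols]
            ds = seg * pixel_size_um / n
            for lab in np.unique(labels):
                if int(lab) in names:
                    out[names[int(lab)]] += float(np.count_nonzero(labels == lab)) * ds
    return out


# ---------------------------------------------------------------------------
# scene assembly and rendering


_GROWTH_MARGIN_UM = 1.0  # keep polylines strictly interior to their region


def simulate_scene(config: SceneConfig) -> tuple[Raster2D, SceneTruth]:
    """Simulate arbors per region, then render the scene.

    Each region's growth budget is ``density * area``, so the true density
    is controlled exactly.  Returns the rendered raster and its truth.
    """
    h, w = config.shape_px
    px = config.optics.pixel_size_um
    regions = config.regions
    if not regions:
        regions = (
            RegionDef("scene", (0.0, 0.0, w * px, h * px), 400.0),
        )
    polylines: list[tuple[str, np.ndarray]] = []
    per_region: dict[str, float] = {}
    arbors: list[Arbor] = []
    for reg in regions:
        budget = reg.density_um_per_mm2 * reg.area_mm2()
        if budget <= 0:
            per_region[reg.name] = 0.0
            continue
        n_roots = max(1, int(round(budget / config.arbor.mean_arbor_length_um)))
        p = replace(
            config.arbor,
            n_roots=n_roots,
            max_total_length_um=budget,
        )
        x0, y0, x1, y1 = reg.rect_um
        m = min(_GROWTH_MARGIN_UM, (x1 - x0) / 4, (y1 - y0) / 4)
        rng = stream_rng(config.seed, f"arbor/{reg.name}")
        arbor = _grow_arbor(p, rng, (x0 + m, y0 + m, x1 - m, y1 - m), roots_um=None)
        arbor.region = reg.name
        arbors.append(arbor)
        polys = [(reg.name, pl) for pl in arbor.polylines()]
        polylines.extend(polys)
        per_region[reg.name] = float(sum(polyline_length(pl) for _, pl in polys))
    truth = SceneTruth(
        polylines=polylines,
        per_region_length_um=per_region,
        soma_inventory=[],
        seed=config.seed,
        params={
            "shape_px": list(config.shape_px),
            "regions": [dataclasses.asdict(r) for r in regions],
            "arbor": dataclasses.asdict(config.arbor),
            "cells": dataclasses.asdict(config.cells) if config.cells else None,
            "optics": dataclasses.asdict(config.optics),
        },
        arbors=arbors,
    )
    raster, truth = render_scene(truth, config.cells, config.optics, config.shape_px)
    return raster, truth


def _splat_polyline(canvas: np.ndarray, verts_px: np.ndarray, density: float, step_px: float = 0.25) -> None:
    """Deposit ``density`` units per pixel-length along a polyline (bilinear)."""
    h, w = canvas.shape
    for a, b in zip(verts_px[:-1], verts_px[1:]):
        seg = float(np.linalg.norm(b - a))
        if seg == 0:
            continue
        n = max(1, int(math.ceil(seg / step_px)))
        t = (np.arange(n) + 0.5) / n
        pts = a[None, :] + t[:, None] * (b - a)[None, :]
        _splat_points(canvas, pts, np.full(n, density * seg / n))


def _splat_points(canvas: np.ndarray, pts_px: np.ndarray, weights: np.ndarray) -> None:
    h, w = canvas.shape
    x, y = pts_px[:, 0], pts_px[:, 1]
    c0 = np.floor(x).astype(int)
    r0 = np.floor(y).astype(int)
    fx, fy = x - c0, y - r0
    for dr, dc, wgt in (
        (0, 0, (1 - fx) * (1 - fy)),
        (0, 1, fx * (1 - fy)),
        (1, 0, (1 - fx) * fy),
        (1, 1, fx * fy),
    ):
        rr, cc = r0 + dr, c0 + dc
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        np.add.at(canvas, (rr[ok], cc[ok]), weights[ok] * wgt[ok])


def _draw_disk(canvas: np.ndarray, center_px: tuple[float, float], radius_px: float, value: float) -> None:
    h, w = canvas.shape
    cx, cy = center_px
    r0 = max(0, int(math.floor(cy - radius_px - 1)))
    r1 = min(h, int(math.ceil(cy + radius_px + 2)))
    c0 = max(0, int(math.floor(cx - radius_px - 1)))
    c1 = min(w, int(math.ceil(cx + radius_px + 2)))
    if r1 <= r0 or c1 <= c0:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius_px**2
    canvas[r0:r1, c0:c1][inside] += value


def _place_cells(
    cells: CellPopulationParams,
    extent_um: tuple[float, float],
    rng: np.random.Generator,
) -> list[CellTruth]:
    wx, wy = extent_um
    inventory: list[CellTruth] = []

    def place(center: np.ndarray, spread: float, diameter: float) -> tuple[float, float]:
        # somata are solid bodies: resample until the new cell clears its
        # neighbors (small gap included so rendered disks stay separable)
        for _ in range(40):
            pos = np.clip(center + rng.normal(0.0, spread, 2), (0, 0), (wx, wy))
            ok = all(
                np.hypot(pos[0] - c.center_um[0], pos[1] - c.center_um[1])
                >= (diameter + c.diameter_um) / 2.0 + 2.0
                for c in inventory
            )
            if ok:
                break
        return float(pos[0]), float(pos[1])

    # principal neurons cluster into a few ganglia
    n_ganglia = max(1, cells.n_principal // 10)
    centers = np.column_stack(
        [rng.uniform(0.1 * wx, 0.9 * wx, n_ganglia), rng.uniform(0.1 * wy, 0.9 * wy, n_ganglia)]
    )
    lo_d, hi_d = cells._PRINCIPAL_DIAM_BOUNDS
    for i in range(cells.n_principal):
        d = float(np.clip(rng.normal(cells.principal_diameter_um, cells.principal_diameter_sd_um), lo_d, hi_d))
        pos = place(centers[i % n_ganglia], 40.0, d)
        th = bool(rng.random() < cells.th_positive_fraction)
        inventory.append(CellTruth(pos, d, "principal", th))
    lo_s, hi_s = cells._SIF_DIAM_BOUNDS
    lo_n, hi_n = cells.sif_cluster_size_range
    for _ in range(cells.sif_cluster_count):
        c = np.array([rng.uniform(0.1 * wx, 0.9 * wx), rng.uniform(0.1 * wy, 0.9 * wy)])
        n = int(rng.integers(lo_n, hi_n + 1))
        for _ in range(n):
            d = float(np.clip(rng.normal(cells.sif_diameter_um, cells.sif_diameter_sd_um), lo_s, hi_s))
            inventory.append(CellTruth(place(c, 14.0, d), d, "SIF", True))
    return inventory


def render_scene(
    truth: SceneTruth,
    cells: CellPopulationParams | None,
    optics: OpticsParams,
    shape_px: tuple[int, int],
    noise_seed: int | None = None,
) -> tuple[Raster2D, SceneTruth]:
    """Render a truth scene into a noisy raster.

    Deterministic for a fixed truth seed: cell placement, adipocyte blobs,
    illumination and noise each draw from their own named stream.  Pass
    ``noise_seed`` to draw replicate noisy acquisitions of the same scene
    (only the shot/read-noise stream changes).  If the ideal image exceeds
    the bit depth it is clipped (with a warning).
    """
    h, w = shape_px
    px = optics.pixel_size_um
    sigma_psf_px = optics.psf_sigma_um / px

    # --- axon emission (blurred by PSF (+) axon cross-section)
    sigma_axon_px = math.sqrt(optics.psf_sigma_um**2 + truth_axon_width(truth) ** 2) / px
    axon_layer = np.zeros((h, w), dtype=np.float64)
    line_density = optics.axon_intensity * math.sqrt(2.0 * math.pi) * max(sigma_axon_px, 1e-6)
    vrng = stream_rng(truth.seed, "varicosities")
    spacing_px = truth_varicosity_spacing(truth) / px
    bouton_mass = (optics.varicosity_gain - 1.0) * optics.axon_intensity * 2.0 * math.pi * sigma_axon_px**2
    for _, verts in truth.polylines:
        v = np.asarray(verts, dtype=np.float64) / px
        _splat_polyline(axon_layer, v, line_density)
        if bouton_mass > 0 and len(v) >= 2:
            _splat_boutons(axon_layer, v, spacing_px, bouton_mass, vrng)
    if sigma_axon_px > 0:
        axon_layer = ndi.gaussian_filter(axon_layer, sigma_axon_px, mode="constant")

    # --- cells
    cell_layer = np.zeros((h, w), dtype=np.float64)
    inventory: list[CellTruth] = list(truth.soma_inventory)
    if cells is not None and not inventory:
        inventory = _place_cells(cells, (w * px, h * px), stream_rng(truth.seed, "cells"))
    for cell in inventory:
        cx, cy = cell.center_um[0] / px, cell.center_um[1] / px
        amp = optics.soma_intensity
        if cell.cell_class == "SIF":
            amp *= cells.sif_intensity_gain if cells is not None else 1.8
        if not cell.th_positive:
            amp *= optics.th_negative_intensity_fraction
        _draw_disk(cell_layer, (cx, cy), cell.diameter_um / 2.0 / px, amp)

    # --- adipocyte autofluorescence blobs
    fat_layer = np.zeros((h, w), dtype=np.float64)
    if optics.n_fat_blobs > 0 and optics.fat_intensity > 0:
        frng = stream_rng(truth.seed, "fat")
        lo_s, hi_s = optics.fat_sigma_um_range
        yy, xx = np.mgrid[0:h, 0:w]
        for _ in range(optics.n_fat_blobs):
            cx, cy = frng.uniform(0, w), frng.uniform(0, h)
            s = frng.uniform(lo_s, hi_s) / px
            fat_layer += optics.fat_intensity * np.exp(
                -(((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * s**2))
            )

    # --- smooth uneven illumination
    background = np.full((h, w), float(optics.background_level))
    if optics.illumination_gradient_amplitude > 0:
        irng = stream_rng(truth.seed, "illumination")
        theta = irng.uniform(0.0, 2.0 * math.pi)
        yy, xx = np.mgrid[0:h, 0:w]
        g = (xx / max(w - 1, 1) - 0.5) * math.cos(theta) + (yy / max(h - 1, 1) - 0.5) * math.sin(theta)
        background *= 1.0 + optics.illumination_gradient_amplitude * g

    ideal = background + axon_layer + ndi.gaussian_filter(cell_layer + fat_layer, max(sigma_psf_px, 1e-6), mode="nearest")

    # --- noise
    img = ideal
    if optics.poisson_gain > 0 or optics.gaussian_sigma > 0:
        nrng = stream_rng(truth.seed if noise_seed is None else noise_seed, "noise")
        if optics.poisson_gain > 0:
            img = nrng.poisson(np.clip(img, 0, None) * optics.poisson_gain).astype(np.float64) / optics.poisson_gain
        if optics.gaussian_sigma > 0:
            img = img + nrng.normal(0.0, optics.gaussian_sigma, img.shape)

    maxval = 2**optics.bit_depth - 1
    if img.max() > maxval:
        warnings.warn(
            f"rendered intensities exceed {optics.bit_depth}-bit range; clipping", stacklevel=2
        )
    img = np.clip(np.round(img), 0, maxval)
    dtype = np.uint8 if optics.bit_depth == 8 else np.uint16
    truth.soma_inventory = inventory
    truth.pixel_size_um = px
    truth.shape_px = (h, w)
    return Raster2D(img.astype(dtype), px), truth


def truth_axon_width(truth: SceneTruth) -> float:
    arbor = truth.params.get("arbor") or {}
    return float(arbor.get("axon_width_um", 1.0))


def truth_varicosity_spacing(truth: SceneTruth) -> float:
    arbor = truth.params.get("arbor") or {}
    return float(arbor.get("varicosity_spacing_um", 6.0))


def _splat_boutons(
    canvas: np.ndarray,
    verts_px: np.ndarray,
    spacing_px: float,
    mass: float,
    rng: np.random.Generator,
) -> None:
    """Point boutons at exponential spacing along the polyline arc length."""
    seglen = np.linalg.norm(np.diff(verts_px, axis=0), axis=1)
    total = float(seglen.sum())
    if total <= 0:
        return
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    s = rng.exponential(spacing_px)
    positions = []
    while s < total:
        i = int(np.searchsorted(cum, s, side="right")) - 1
        i = min(i, len(seglen) - 1)
        t = (s - cum[i]) / max(seglen[i], 1e-12)
        positions.append(verts_px[i] + t * (verts_px[i + 1] - verts_px[i]))
        s += rng.exponential(spacing_px)
    if positions:
        pts = np.asarray(positions)
        _splat_points(canvas, pts, np.full(len(pts), mass))


# ---------------------------------------------------------------------------
# fixture export / import


def write_swc(path: str | Path, arbors: list[Arbor], radius_um: float = 0.5) -> None:
    """Write arbors as standard 7-column SWC (type code 2 = axon, z = 0)."""
    lines = ["# SWC export of simulated axon arbors", "# id type x y z radius parent"]
    next_id = 1
    for arbor in arbors:
        offset = next_id
        for i, (xy, parent) in enumerate(zip(arbor.nodes_um, arbor.parents)):
            pid = -1 if parent < 0 else parent + offset
            lines.append(
                f"{i + offset} 2 {xy[0]:.6f} {xy[1]:.6f} 0.000000 {radius_um:.6f} {pid}"
            )
        next_id += len(arbor.parents)
    Path(path).write_text("\n".join(lines) + "\n")


def _region_label_image(
    regions: list[dict], shape_px: tuple[int, int], pixel_size_um: float
) -> tuple[np.ndarray, dict[int, str]]:
    h, w = shape_px
    labels = np.zeros((h, w), dtype=np.uint8)
    names: dict[int, str] = {}
    for i, reg in enumerate(regions, start=1):
        x0, y0, x1, y1 = (np.asarray(reg["rect_um"]) / pixel_size_um).tolist()
        r0, r1 = int(round(y0)), int(round(y1))
        c0, c1 = int(round(x0)), int(round(x1))
        labels[max(r0, 0) : min(r1, h), max(c0, 0) : min(c1, w)] = i
        names[i] = reg["name"]
    return labels, names


def export_fixture(truth: SceneTruth, raster: Raster2D, directory: str | Path) -> dict[str, Path]:
    """Write a self-contained fixture: TIFF image, truth JSON, SWC, ROI labels.

    Re-loading with :func:`import_fixture` reproduces the truth exactly
    (JSON floats round-trip bit-for-bit through ``repr``).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": directory / "scene.tif",
        "truth": directory / "truth.json",
        "swc": directory / "arbors.swc",
        "roi_labels": directory / "roi_labels.png",
        "roi_names": directory / "roi_names.json",
    }
    write_tiff(paths["image"], raster)
    write_swc(paths["swc"], truth.arbors, radius_um=truth_axon_width(truth) / 2.0)
    doc = {
        "seed": truth.seed,
        "params": truth.params,
        "pixel_size_um": truth.pixel_size_um,
        "shape_px": list(truth.shape_px) if truth.shape_px else None,
        "per_region_length_um": truth.per_region_length_um,
        "polylines": [
            {"region": name, "vertices_um": verts.tolist()} for name, verts in truth.polylines
        ],
        "soma_inventory": [dataclasses.asdict(c) for c in truth.soma_inventory],
    }
    paths["truth"].write_text(json.dumps(doc, indent=1))
    regions = truth.params.get("regions")
    if regions and truth.shape_px and truth.pixel_size_um:
        labels, names = _region_label_image(regions, truth.shape_px, truth.pixel_size_um)
        iio.imwrite(paths["roi_labels"], labels)
        paths["roi_names"].write_text(json.dumps({str(k): v for k, v in names.items()}, indent=1))
    else:
        paths.pop("roi_labels")
        paths.pop("roi_names")
    return paths


def import_fixture(directory: str | Path) -> tuple[Raster2D, SceneTruth]:
    """Load a fixture written by :func:`export_fixture`."""
    directory = Path(directory)
    doc = json.loads((directory / "truth.json").read_text())
    px = float(doc["pixel_size_um"])
    import tifffile

    raster = Raster2D(tifffile.imread(directory / "scene.tif"), px)
    truth = SceneTruth(
        polylines=[
            (p["region"], np.asarray(p["vertices_um"], dtype=np.float64))
            for p in doc["polylines"]
        ],
        per_region_length_um={k: float(v) for k, v in doc["per_region_length_um"].items()},
        soma_inventory=[
            CellTruth(tuple(c["center_um"]), c["diameter_um"], c["cell_class"], c["th_positive"])
            for c in doc["soma_inventory"]
        ],
        seed=int(doc["seed"]),
        params=doc["params"],
        pixel_size_um=px,
        shape_px=tuple(doc["shape_px"]) if doc.get("shape_px") else None,
    )
    return raster, truth
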