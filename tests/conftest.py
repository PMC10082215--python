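"""Shared fixtures: small synthetic scenes and reusable oracles."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from atriadense import synthetic_scene as sc

# the renderer warns when bright SIF cells saturate the 8-bit range; that
# is expected behaviour, not a test failure
warnings.filterwarnings("ignore", message="rendered intensities exceed")


def quadrant_regions(extent_um: float, densities: dict[str, float]) -> tuple[sc.RegionDef, ...]:
    """Four equal quadrant ROIs covering a square field."""
    h = extent_um / 2.0
    rects = {
        "SAN": (0.0, 0.0, h, h),
        "AVN": (h, 0.0, extent_um, h),
        "auricle": (0.0, h, h, extent_um),
        "IVC": (h, h, extent_um, extent_um),
    }
    return tuple(sc.RegionDef(n, rects[n], densities[n]) for n in rects)


# regional densities reported for the right atrium (um/mm^2); adjacent
# values are separated by >= 25%, which the recovery tests rely on
RA_DENSITIES = {"SAN": 687.3, "AVN": 401.7, "auricle": 243.4, "IVC": 113.6}


def make_scene(
    seed: int,
    shape_px: tuple[int, int] = (1024, 1024),
    pixel_size_um: float = 2.0,
    densities: dict[str, float] | None = None,
    cells: sc.CellPopulationParams | None = None,
    arbor: sc.ArborGrowthParams | None = None,
    **optics_kw,
):
    """A quadrant scene at the default noise conditions."""
    densities = densities or RA_DENSITIES
    extent = shape_px[1] * pixel_size_um
    regions = quadrant_regions(extent, densities)
    optics = sc.OpticsParams(pixel_size_um=pixel_size_um, **optics_kw)
    cfg = sc.SceneConfig(shape_px=shape_px, regions=regions,
                         arbor=arbor or sc.ArborGrowthParams(),
                         cells=cells, optics=optics, seed=seed)
    raster, truth = sc.simulate_scene(cfg)
    return raster, truth, regions


def quadrant_masks(regions, shape_px, pixel_size_um):
    out = {}
    for reg in regions:
        x0, y0, x1, y1 = (np.asarray(reg.rect_um) / pixel_size_um).round().astype(int)
        m = np.zeros(shape_px, dtype=bool)
        m[y0:y1, x0:x1] = True
        out[reg.name] = m
    return out


@pytest.fixture(scope="session")
def small_scene():
    """A 512x512 px quadrant scene with cells, reused by read-only tests."""
    return make_scene(11, shape_px=(512, 512), pixel_size_um=2.0)
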