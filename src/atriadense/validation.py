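"""Self-validation experiments: the package measured against its own truth.

These routines drive the full pipeline over synthetic scenes with exact
ground truth and report recovery quality, estimator calibration on digital
straight lines, and the error rates of the regional statistics.  They are
used both by the test suite and by the repository's acceptance script.

Scale note: recovery scenes are 512x512 px at 2 um/px — a 1.05 mm^2 field,
the package's desk-scale stand-in for one montage region — with the four
regional ground-truth densities set to the right-atrium values reported
for this preparation (687.3, 401.7, 243.4, 113.6 um/mm^2; adjacent values
separated by >= 25%).  Background subtraction uses a 40 um (20 px) disk,
the physical-scale equivalent of the published 80 px at the original
magnification.
"""

from __future__ import annotations

import math
import numpy as np

from . import synthetic_scene as sc
from .densitometry import RoiSpec, roi_density, skeleton_length
from .imageproc import PreprocConfig, SkeletonMask
from .pipeline_io import segment_image
from .regional_stats import GroupedSamples, one_way_anova, tukey_hsd

RA_DENSITIES = {"SAN": 687.3, "AVN": 401.7, "auricle": 243.4, "IVC": 113.6}

RECOVERY_SHAPE_PX = (512, 512)
RECOVERY_PIXEL_UM = 2.0
RECOVERY_RADIUS_PX = 20  # 40 um disk


def quadrant_scene_config(seed: int, densities: dict[str, float] | None = None) -> sc.SceneConfig:
    densities = densities or RA_DENSITIES
    h, w = RECOVERY_SHAPE_PX
    ext = w * RECOVERY_PIXEL_UM
    half = ext / 2.0
    rects = {
        "SAN": (0.0, 0.0, half, half),
        "AVN": (half, 0.0, ext, half),
        "auricle": (0.0, half, half, ext),
        "IVC": (half, half, ext, ext),
    }
    regions = tuple(sc.RegionDef(n, rects[n], densities[n]) for n in rects)
    return sc.SceneConfig(
        shape_px=RECOVERY_SHAPE_PX,
        regions=regions,
        cells=None,
        optics=sc.OpticsParams(pixel_size_um=RECOVERY_PIXEL_UM),
        seed=seed,
    )


def recover_scene_densities(
    seed: int, densities: dict[str, float] | None = None, method: str = "diagonal_corrected"
) -> tuple[dict[str, float], dict[str, float]]:
    """Simulate one quadrant scene, run the pipeline, estimate ROI densities.

    Returns ``(estimated, true)`` densities in um/mm^2 (whole-ROI, i.e.
    skeleton length inside the region over region area).
    """
    cfg = quadrant_scene_config(seed, densities)
    raster, truth = sc.simulate_scene(cfg)
    skel, _ = segment_image(raster, PreprocConfig(background_radius_px=RECOVERY_RADIUS_PX))
    est: dict[str, float] = {}
    true: dict[str, float] = {}
    for reg in cfg.regions:
        x0, y0, x1, y1 = (np.asarray(reg.rect_um) / RECOVERY_PIXEL_UM).round().astype(int)
        mask = np.zeros(raster.shape, dtype=bool)
        mask[y0:y1, x0:x1] = True
        _, est[reg.name] = roi_density(skel, RoiSpec(reg.name, mask), method)
        true[reg.name] = truth.per_region_length_um[reg.name] / reg.area_mm2()
    return est, true


def recovery_experiment(n_scenes: int = 100, seed0: int = 0) -> dict:
    """Rank recovery and mean absolute relative density error over scenes."""
    rank_ok = 0
    errs: list[float] = []
    for i in range(n_scenes):
        est, true = recover_scene_densities(seed0 + i)
        errs.extend(abs(est[k] / true[k] - 1.0) for k in true)
        rank_ok += sorted(est, key=est.get) == sorted(true, key=true.get)
    return {
        "n_scenes": n_scenes,
        "rank_correct_frac": rank_ok / n_scenes,
        "mean_abs_rel_error": float(np.mean(errs)),
    }


# ---------------------------------------------------------------------------
# digital line calibration


def digital_line(angle_deg: float, length_um: float = 100.0) -> SkeletonMask:
    """A half-open Bresenham chain representing a segment of ``length_um``
    at 1 um/px (the end pixel is dropped, so a 0-degree line of 100 um is
    exactly 100 pixels)."""
    from skimage.draw import line as sk_line

    theta = math.radians(angle_deg)
    dc = int(round(length_um * math.cos(theta)))
    dr = int(round(length_um * math.sin(theta)))
    rr, cc = sk_line(0, 0, dr, dc)
    rr, cc = rr[:-1], cc[:-1]  # half-open
    pad = 2
    mask = np.zeros((abs(dr) + 2 * pad + 1, abs(dc) + 2 * pad + 1), dtype=bool)
    mask[rr + pad, cc + pad] = True
    return SkeletonMask(mask, 1.0)


def line_calibration(angles=(0.0, 30.0, 45.0, 60.0, 90.0), length_um: float = 100.0) -> dict:
    """Relative error of both estimators on digital straight lines."""
    out = {}
    for a in angles:
        skel = digital_line(a, length_um)
        theta = math.radians(a)
        true = math.hypot(
            round(length_um * math.cos(theta)), round(length_um * math.sin(theta))
        )
        out[a] = {
            "pixel_count": skeleton_length(skel, "pixel_count") / true - 1.0,
            "diagonal_corrected": skeleton_length(skel, "diagonal_corrected") / true - 1.0,
        }
    return out


# ---------------------------------------------------------------------------
# statistical calibration (frame densities modeled as normal per ROI)


def anova_type_i_rate(
    n_reps: int = 500, seed: int = 0, k: int = 4, n: int = 6,
    mean: float = 300.0, cv: float = 0.15, alpha: float = 0.05,
) -> float:
    """ANOVA rejection rate when every ROI has the same generating density."""
    rng = np.random.default_rng(seed)
    rej = 0
    for _ in range(n_reps):
        g = GroupedSamples({f"r{i}": rng.normal(mean, cv * mean, n) for i in range(k)})
        rej += one_way_anova(g).p < alpha
    return rej / n_reps


def tukey_triple_density_power(
    n_reps: int = 100, seed: int = 0, n: int = 6,
    base: float = 300.0, cv: float = 0.15, alpha: float = 0.05,
) -> float:
    """Fraction of replicates where the 3x-density ROI beats every other ROI."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        groups = {
            "hot": rng.normal(3.0 * base, cv * 3.0 * base, n),
            "b": rng.normal(base, cv * base, n),
            "c": rng.normal(base, cv * base, n),
            "d": rng.normal(base, cv * base, n),
        }
        comps = tukey_hsd(GroupedSamples(groups), alpha)
        hits += all(c.reject for c in comps if "hot" in (c.group_a, c.group_b))
    return hits / n_reps


def tukey_matches_t_test(n_datasets: int = 50, seed: int = 0, alpha: float = 0.05) -> bool:
    """k = 2 Tukey decisions coincide with the pooled two-sample t test."""
    from scipy import stats as sps

    rng = np.random.default_rng(seed)
    for _ in range(n_datasets):
        a = rng.normal(0.0, 1.0, int(rng.integers(4, 9)))
        b = rng.normal(rng.uniform(0.0, 2.0), 1.0, int(rng.integers(4, 9)))
        (comp,) = tukey_hsd(GroupedSamples({"a": a, "b": b}), alpha)
        t = sps.ttest_ind(a, b)
        if comp.reject != (t.pvalue < alpha):
            return False
        if not math.isclose(comp.p_adj, t.pvalue, rel_tol=1e-6, abs_tol=1e-12):
            return False
    return True
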