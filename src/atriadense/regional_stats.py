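"""Regional comparison statistics: Shapiro-Wilk, one-way ANOVA, Tukey HSD.

Regional axon densities (six counting frames per region) are compared with
a one-way ANOVA followed by Tukey's honestly-significant-difference test at
alpha = 0.05; a Shapiro-Wilk test per region is reported as a normality
diagnostic.  Normality results never switch the test — they are reported
alongside it (optionally with a warning).

The Tukey test uses the Tukey-Kramer harmonic-mean form, so unequal frame
counts are tolerated; for balanced data it reduces to the classic test.
Studentized-range tail probabilities come from
:data:`scipy.stats.studentized_range` (numeric integration).
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .densitometry import DensityRecord

__all__ = [
    "GroupedSamples",
    "AnovaResult",
    "TukeyComparison",
    "StatsReport",
    "shapiro_wilk",
    "one_way_anova",
    "tukey_hsd",
    "build_stats_report",
]


@dataclass(frozen=True)
class GroupedSamples:
    """Observations (densities, um/mm^2) grouped by ROI label."""

    groups: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")
        clean = {}
        for name, vals in self.groups.items():
            arr = np.asarray(vals, dtype=np.float64)
            if arr.ndim != 1 or len(arr) < 2:
                raise ValueError(f"group {name!r} needs >= 2 observations")
            clean[name] = arr
        object.__setattr__(self, "groups", clean)

    @property
    def k(self) -> int:
        return len(self.groups)

    @property
    def n_total(self) -> int:
        return sum(len(v) for v in self.groups.values())


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    ms_within: float
    degenerate: bool = False  # zero within-group variance with unequal means


@dataclass(frozen=True)
class TukeyComparison:
    group_a: str
    group_b: str
    mean_diff: float  # mean_a - mean_b
    q: float
    p_adj: float
    reject: bool


@dataclass(frozen=True)
class StatsReport:
    alpha: float
    n_per_group: dict[str, int]
    shapiro: dict[str, tuple[float, float]]
    anova: AnovaResult
    tukey: list[TukeyComparison]
    top_roi: str
    top_roi_significant: bool  # top-density ROI above every other ROI at alpha

    def tukey_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "group_a": c.group_a,
                    "group_b": c.group_b,
                    "mean_diff": c.mean_diff,
                    "q": c.q,
                    "p_adj": c.p_adj,
                    "reject": c.reject,
                }
                for c in self.tukey
            ]
        )

    def to_json(self, indent: int = 1) -> str:
        return json.dumps(
            {
                "alpha": self.alpha,
                "n_per_group": self.n_per_group,
                "shapiro": {k: {"W": w, "p": p} for k, (w, p) in self.shapiro.items()},
                "anova": {
                    "F": self.anova.F if math.isfinite(self.anova.F) else None,
                    "df_between": self.anova.df_between,
                    "df_within": self.anova.df_within,
                    "p": self.anova.p,
                    "degenerate": self.anova.degenerate,
                },
                "tukey": [
                    {
                        "group_a": c.group_a,
                        "group_b": c.group_b,
                        "mean_diff": round(c.mean_diff, 9),
                        "q": round(c.q, 9) if math.isfinite(c.q) else None,
                        "p_adj": round(c.p_adj, 9),
                        "reject": c.reject,
                    }
                    for c in self.tukey
                ],
                "top_roi": self.top_roi,
                "top_roi_significant": self.top_roi_significant,
            },
            indent=indent,
            allow_nan=False,
            default=str,
        )


def shapiro_wilk(x: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk W and p for a single sample (3 <= n <= 5000).

    Uses the Royston AS R94 coefficient approximation (valid over this n
    range) via :func:`scipy.stats.shapiro`.
    """
    arr = np.asarray(x, dtype=np.float64)
    if len(arr) < 3:
        raise ValueError("Shapiro-Wilk requires n >= 3")
    if len(arr) > 5000:
        raise ValueError("Shapiro-Wilk coefficient approximation limited to n <= 5000")
    res = sps.shapiro(arr)
    return float(res.statistic), float(res.pvalue)


def one_way_anova(g: GroupedSamples) -> AnovaResult:
    """Classic fixed-effects one-way ANOVA from group sums of squares."""
    arrays = list(g.groups.values())
    all_vals = np.concatenate(arrays)
    grand = all_vals.mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df1 = g.k - 1
    df2 = g.n_total - g.k
    ms_between = ss_between / df1
    ms_within = ss_within / df2
    if ms_within == 0.0:
        if ms_between == 0.0:
            return AnovaResult(0.0, df1, df2, 1.0, 0.0)
        # perfectly separated groups: flag rather than raise
        return AnovaResult(math.inf, df1, df2, 0.0, 0.0, degenerate=True)
    F = ms_between / ms_within
    p = float(sps.f.sf(F, df1, df2))
    return AnovaResult(float(F), df1, df2, p, float(ms_within))


def tukey_hsd(g: GroupedSamples, alpha: float = 0.05) -> list[TukeyComparison]:
    """All pairwise Tukey(-Kramer) HSD comparisons.

    For groups i, j: ``q = |m_i - m_j| / sqrt(MS_within/2 * (1/n_i + 1/n_j))``
    with the adjusted p from the studentized range distribution with k
    groups and the ANOVA within-group degrees of freedom.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    anova = one_way_anova(g)
    names = list(g.groups)
    out = []
    for a, b in itertools.combinations(names, 2):
        xa, xb = g.groups[a], g.groups[b]
        diff = float(xa.mean() - xb.mean())
        if anova.ms_within == 0.0:
            q = math.inf if diff != 0 else 0.0
            p_adj = 0.0 if diff != 0 else 1.0
        else:
            se = math.sqrt(anova.ms_within / 2.0 * (1.0 / len(xa) + 1.0 / len(xb)))
            q = abs(diff) / se
            p_adj = float(sps.studentized_range.sf(q, g.k, anova.df_within))
            p_adj = min(max(p_adj, 0.0), 1.0)
        out.append(TukeyComparison(a, b, diff, q, p_adj, p_adj < alpha))
    return out


def build_stats_report(
    records: list[DensityRecord] | pd.DataFrame,
    alpha: float = 0.05,
    warn_nonnormal: bool = False,
) -> StatsReport:
    """Assemble the full regional comparison report from density records."""
    if isinstance(records, pd.DataFrame):
        df = records
        grouped = {
            str(roi): sub["density_um_per_mm2"].to_numpy(dtype=np.float64)
            for roi, sub in df.groupby("roi", sort=False)
        }
    else:
        grouped = {}
        for rec in records:
            grouped.setdefault(rec.roi, []).append(rec.density_um_per_mm2)
        grouped = {k: np.asarray(v) for k, v in grouped.items()}
    g = GroupedSamples(grouped)

    shapiro: dict[str, tuple[float, float]] = {}
    for name, vals in g.groups.items():
        if len(vals) >= 3 and np.ptp(vals) > 0:
            shapiro[name] = shapiro_wilk(vals)
            if warn_nonnormal and shapiro[name][1] < alpha:
                warnings.warn(
                    f"ROI {name!r}: Shapiro-Wilk rejects normality (p={shapiro[name][1]:.3g})",
                    stacklevel=2,
                )
    anova = one_way_anova(g)
    tukey = tukey_hsd(g, alpha)
    means = {name: float(v.mean()) for name, v in g.groups.items()}
    top = max(means, key=means.get)
    top_sig = all(
        c.reject for c in tukey if top in (c.group_a, c.group_b)
    )
    return StatsReport(
        alpha=alpha,
        n_per_group={k: len(v) for k, v in g.groups.items()},
        shapiro=shapiro,
        anova=anova,
        tukey=tukey,
        top_roi=top,
        top_roi_significant=top_sig,
    )
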