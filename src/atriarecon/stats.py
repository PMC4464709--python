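"""Agreement and comparison statistics, plus endocardial border sharpness.

Bland-Altman limits of agreement are reported as mean +/- 2*SD of the
paired differences (the convention used on the validation plots this
package mirrors, not 1.96*SD). Percent differences use the pairwise mean
as the denominator: ``100*(a-b)/((a+b)/2)``.

For a 2x2 within-subject design (alignment x reconstruction method,
subjects = phantom shapes) the repeated-measures ANOVA reduces exactly to
paired t-tests on within-subject contrasts; the interaction F equals the
squared paired-t statistic of the double difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage, stats
from shapely.geometry import LineString, Point, Polygon

from .contours import Contour

__all__ = [
    "StatisticsError",
    "AgreementStats",
    "bland_altman",
    "paired_t",
    "RMAnova2x2",
    "rm_anova_2x2",
    "EBSMeasure",
    "endocardial_border_sharpness",
]


class StatisticsError(ValueError):
    """Statistic undefined for the given input."""


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman agreement of method ``a`` against reference ``b``."""

    n: int
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    mean_pct_diff: float
    sd_pct_diff: float
    slope: float
    intercept: float
    r2: float


def bland_altman(a, b) -> AgreementStats:
    """Paired agreement: differences a-b, +/-2*SD limits, percent, regression.

    The regression is of ``a`` on ``b`` (method on reference).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise StatisticsError("inputs must be equal-length 1D arrays")
    n = len(a)
    if n < 2:
        raise StatisticsError("need n >= 2 pairs")
    d = a - b
    mean_diff = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1))
    pct = 100.0 * d / ((a + b) / 2.0)
    if np.ptp(b) > 0:
        reg = stats.linregress(b, a)
        slope, intercept, r2 = float(reg.slope), float(reg.intercept), float(reg.rvalue**2)
    else:
        slope, intercept, r2 = np.nan, np.nan, np.nan
    return AgreementStats(
        n=n,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - 2.0 * sd_diff,
        loa_high=mean_diff + 2.0 * sd_diff,
        mean_pct_diff=float(np.mean(pct)),
        sd_pct_diff=float(np.std(pct, ddof=1)),
        slope=slope,
        intercept=intercept,
        r2=r2,
    )


def paired_t(a, b) -> tuple[float, int, float]:
    """Two-sided paired t-test; returns (t, df, p).

    Identical samples give (0, n-1, 1); a zero-variance non-zero shift has
    no defined t statistic and raises.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise StatisticsError("need two equal-length samples with n >= 2")
    d = a - b
    if np.std(d, ddof=1) == 0.0:
        if np.mean(d) == 0.0:
            return 0.0, len(d) - 1, 1.0
        raise StatisticsError("zero-variance differences: t undefined")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), len(d) - 1, float(res.pvalue)


@dataclass(frozen=True)
class RMAnova2x2:
    """Within-subject 2x2 ANOVA summary (df = (1, n_subjects-1) throughout)."""

    n_subjects: int
    f_factor_a: float
    p_factor_a: float
    f_factor_b: float
    p_factor_b: float
    f_interaction: float
    p_interaction: float


def _contrast_f(c: np.ndarray) -> tuple[float, float]:
    sd = np.std(c, ddof=1)
    if sd == 0.0:
        return 0.0, 1.0
    t = np.mean(c) / (sd / np.sqrt(len(c)))
    p = 2.0 * stats.t.sf(abs(t), len(c) - 1)
    return float(t**2), float(p)


def rm_anova_2x2(table: np.ndarray) -> RMAnova2x2:
    """Two-way repeated-measures ANOVA on a complete 2x2 design.

    ``table`` has shape (n_subjects, 2, 2) with axes (factor A level,
    factor B level). Each effect is tested by the paired t-test on the
    corresponding within-subject contrast, which is exact for 2x2: the
    interaction uses the double difference
    ``(x00 - x01) - (x10 - x11)``.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 3 or x.shape[1:] != (2, 2):
        raise StatisticsError(f"expected shape (n, 2, 2), got {x.shape}")
    if np.isnan(x).any():
        raise StatisticsError("missing cells in the repeated-measures table")
    n = x.shape[0]
    if n < 3:
        raise StatisticsError("need >= 3 subjects")
    eff_a = x[:, 0, :].mean(axis=1) - x[:, 1, :].mean(axis=1)
    eff_b = x[:, :, 0].mean(axis=1) - x[:, :, 1].mean(axis=1)
    inter = (x[:, 0, 0] - x[:, 0, 1]) - (x[:, 1, 0] - x[:, 1, 1])
    fa, pa = _contrast_f(eff_a)
    fb, pb = _contrast_f(eff_b)
    fi, pi = _contrast_f(inter)
    return RMAnova2x2(
        n_subjects=n,
        f_factor_a=fa,
        p_factor_a=pa,
        f_factor_b=fb,
        p_factor_b=pb,
        f_interaction=fi,
        p_interaction=pi,
    )


# ----------------------------------------------------------------------
# endocardial border sharpness
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class EBSMeasure:
    """Mean reciprocal 20-80 % edge-transition width over 8 radial profiles."""

    per_profile: tuple[float, ...]
    ebs: float
    dropped_rays: int = 0


def _edge_width_px(profile: np.ndarray, s: np.ndarray) -> Optional[float]:
    """20-80 % transition width of one radial intensity profile (pixels)."""
    k = max(1, len(s) // 4)
    i_in = float(np.mean(profile[:k]))
    i_out = float(np.mean(profile[-k:]))
    if i_in == i_out:
        return None
    t = (profile - i_in) / (i_out - i_in)  # 0 at the inside level, 1 outside
    # first crossing of 0.2 and last-before crossing of 0.8 around the edge

    def crossing(level: float) -> Optional[float]:
        above = t >= level
        idx = np.nonzero(above[1:] != above[:-1])[0]
        if len(idx) == 0:
            return None
        i = idx[0]
        frac = (level - t[i]) / (t[i + 1] - t[i])
        return float(s[i] + frac * (s[i + 1] - s[i]))

    s20 = crossing(0.2)
    s80 = crossing(0.8)
    if s20 is None or s80 is None:
        return None
    return abs(s80 - s20)


def endocardial_border_sharpness(
    image: np.ndarray,
    contour: Contour,
    center: tuple[float, float],
    half_window_px: float = 10.0,
    step_px: float = 0.25,
) -> EBSMeasure:
    """Border sharpness (1/pixels) from 8 radial profiles across the wall.

    Eight rays at 45 degree spacing run from ``center`` (given as (row,
    col)) through the contour; each intensity profile is sampled at
    ``step_px`` over +/-``half_window_px`` around the wall crossing, and
    the per-ray sharpness is the reciprocal of the 20-80 % edge-transition
    width, capped at 1. Rays that exit the image (or show no transition)
    are dropped and counted.
    """
    img = np.asarray(image, dtype=float)
    poly = Polygon(contour.points)  # (row, col) vertex order
    c = np.asarray(center, dtype=float)
    if not poly.contains(Point(c)):
        raise StatisticsError("center must lie inside the contour")
    reach = float(np.hypot(*img.shape)) + 1.0
    values = []
    dropped = 0
    for ang in np.deg2rad(np.arange(0, 360, 45)):
        d = np.array([np.cos(ang), np.sin(ang)])
        ray = LineString([c, c + reach * d])
        hit = ray.intersection(poly.exterior)
        if hit.is_empty:
            dropped += 1
            continue
        pts = [hit] if hit.geom_type == "Point" else list(hit.geoms)
        r0 = min(np.hypot(p.x - c[0], p.y - c[1]) for p in pts)
        s = np.arange(-half_window_px, half_window_px + step_px / 2, step_px)
        coords = c[:, None] + d[:, None] * (r0 + s)
        inside = (
            (coords[0] >= 0)
            & (coords[0] <= img.shape[0] - 1)
            & (coords[1] >= 0)
            & (coords[1] <= img.shape[1] - 1)
        )
        if not inside.all():
            dropped += 1
            continue
        profile = ndimage.map_coordinates(img, coords, order=1)
        width = _edge_width_px(profile, s)
        if width is None:
            dropped += 1
            continue
        values.append(min(1.0 / width, 1.0) if width > 0 else 1.0)
    if not values:
        raise StatisticsError("no usable radial profile")
    return EBSMeasure(
        per_profile=tuple(values), ebs=float(np.mean(values)), dropped_rays=dropped
    )
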