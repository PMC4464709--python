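"""Closed 2D chamber contours: extraction from masks, smoothing, planar geometry.

A :class:`Contour` is an ordered list of (row, col) vertices with fractional
pixel precision, implicitly closed. Contours come either from an exchange
file (delineated upstream) or from binary segmentation masks via sub-pixel
marching squares at iso-level 0.5.

All metric geometry (areas, distances) is done in mm after applying the
plane's pixel spacing; areas are mm^2, volumes elsewhere are ml = mm^3/1000.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import shapely
from scipy.optimize import minimize_scalar
from shapely.geometry import Point, Polygon
from skimage import measure

__all__ = [
    "ContourError",
    "Contour",
    "mask_to_contour",
    "smooth_contour",
    "polygon_area",
    "signed_distance_2d",
]


class ContourError(ValueError):
    """Degenerate or inconsistent contour input."""


@dataclass(frozen=True)
class Contour:
    """A closed planar curve in fractional (row, col) pixel coordinates.

    The last vertex connects implicitly back to the first; the stored list
    never repeats the first vertex.
    """

    points: np.ndarray  # (n, 2) float, columns (row, col)
    plane_id: str = ""
    frame: int = 0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ContourError(f"contour points must be (n, 2), got {pts.shape}")
        # drop an explicitly repeated closing vertex, then consecutive duplicates
        if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) > 1:
            keep = np.r_[True, np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-12]
            pts = pts[keep]
        if len(pts) < 3:
            raise ContourError(f"a closed contour needs >= 3 distinct points, got {len(pts)}")
        pts.flags.writeable = False
        object.__setattr__(self, "points", pts)
        if self.frame < 0:
            raise ContourError("frame index must be >= 0")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def orientation(self) -> int:
        """+1 for counter-clockwise in (col, row) axes, -1 for clockwise."""
        xy = self.points[:, ::-1]
        x, y = xy[:, 0], xy[:, 1]
        area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        return 1 if area2 > 0 else -1

    def to_mm(self, spacing: tuple[float, float]) -> np.ndarray:
        """Vertices as in-plane (u, v) mm coordinates: u = col*cs, v = row*rs."""
        rs, cs = spacing
        return np.column_stack([self.points[:, 1] * cs, self.points[:, 0] * rs])

    def resampled(self, n: int) -> "Contour":
        """Arc-length uniform periodic resampling to ``n`` vertices."""
        pts = np.vstack([self.points, self.points[:1]])
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.r_[0.0, np.cumsum(seg)]
        t = np.linspace(0.0, s[-1], n, endpoint=False)
        out = np.column_stack(
            [np.interp(t, s, pts[:, 0]), np.interp(t, s, pts[:, 1])]
        )
        return replace(self, points=out)


# ----------------------------------------------------------------------
# mask -> contour
# ----------------------------------------------------------------------

def mask_to_contour(
    mask: np.ndarray,
    component_policy: str = "largest",
    plane_id: str = "",
    frame: int = 0,
) -> Contour:
    """Extract the closed sub-pixel boundary of a binary mask.

    Marching squares at iso-level 0.5 on the (optionally largest) connected
    component; the returned vertices are fractional (row, col) positions.

    Parameters
    ----------
    component_policy:
        ``"largest"`` keeps the biggest connected component,
        ``"error_if_multiple"`` raises when more than one is present.
    """
    mask = np.asarray(mask) > 0
    if mask.ndim != 2:
        raise ContourError("mask must be 2D")
    if not mask.any():
        raise ContourError("mask is empty: no foreground pixels")
    labels, n_comp = measure.label(mask, return_num=True)
    if n_comp > 1:
        if component_policy == "error_if_multiple":
            raise ContourError(f"mask has {n_comp} connected components")
        if component_policy != "largest":
            raise ContourError(f"unknown component policy {component_policy!r}")
        sizes = np.bincount(labels.ravel())[1:]
        mask = labels == (int(np.argmax(sizes)) + 1)
    # pad so components touching the border still close
    padded = np.pad(mask.astype(float), 1)
    loops = measure.find_contours(padded, 0.5)
    if not loops:  # pragma: no cover - non-empty mask always yields a loop
        raise ContourError("no iso-contour found")
    longest = max(loops, key=len)
    return Contour(points=longest - 1.0, plane_id=plane_id, frame=frame)


# ----------------------------------------------------------------------
# smoothing: periodic penalised least squares, GCV-chosen parameter,
# robust (bisquare) reweighting
# ----------------------------------------------------------------------

def _periodic_eigenvalues(n: int) -> np.ndarray:
    # eigenvalues of the circulant second-difference penalty D'D
    return (2.0 - 2.0 * np.cos(2.0 * np.pi * np.arange(n) / n)) ** 2


def _filter_periodic(y: np.ndarray, s: float, lam: np.ndarray) -> np.ndarray:
    gain = 1.0 / (1.0 + s * lam)
    return np.real(np.fft.ifft(np.fft.fft(y, axis=0) * gain[:, None], axis=0))


def _gcv_score(log_s: float, y: np.ndarray, lam: np.ndarray) -> float:
    s = 10.0**log_s
    n = len(y)
    smoothed = _filter_periodic(y, s, lam)
    rss = float(np.sum((y - smoothed) ** 2))
    tr_h = float(np.sum(1.0 / (1.0 + s * lam)))
    denom = max(n - tr_h, 1e-12)
    return n * rss / denom**2


def smooth_contour(
    c: Contour,
    smoothing: float | str = "auto",
    robust_iters: int = 5,
) -> Contour:
    """Smooth a closed contour by periodic penalised least squares.

    The two coordinate channels are filtered jointly with a circulant
    second-difference roughness penalty, so there are no endpoint
    artefacts. ``smoothing="auto"`` picks the penalty weight by generalised
    cross-validation; ``smoothing=0`` is the identity. Up to
    ``robust_iters`` bisquare reweighting passes down-weight outlier
    vertices (the weighted problem is solved by iterating the unweighted
    filter on weight-blended data).
    """
    if len(c) < 8:
        raise ContourError("smoothing needs a closed contour with >= 8 points")
    y = np.asarray(c.points, dtype=float)
    if smoothing == 0 or (isinstance(smoothing, (int, float)) and float(smoothing) == 0.0):
        return replace(c, points=y.copy())
    n = len(y)
    lam = _periodic_eigenvalues(n)
    if smoothing == "auto":
        res = minimize_scalar(
            _gcv_score, bounds=(-6.0, 5.0), args=(y, lam), method="bounded"
        )
        s = 10.0**float(res.x)
    else:
        s = float(smoothing)
        if s < 0:
            raise ContourError("smoothing parameter must be >= 0")
    z = _filter_periodic(y, s, lam)
    for _ in range(max(0, robust_iters)):
        r = np.linalg.norm(y - z, axis=1)
        mad = np.median(np.abs(r - np.median(r)))
        if mad < 1e-12:
            break
        u = r / (6.0 * 1.4826 * mad)
        w = np.where(u < 1.0, (1.0 - u**2) ** 2, 0.0)
        z_new = z
        for _ in range(3):  # inner fixed-point solves the weighted problem
            z_new = _filter_periodic(w[:, None] * (y - z_new) + z_new, s, lam)
        if np.max(np.abs(z_new - z)) < 1e-9:
            z = z_new
            break
        z = z_new
    return replace(c, points=z)


# ----------------------------------------------------------------------
# planar primitives
# ----------------------------------------------------------------------

def polygon_area(c: Contour, spacing: tuple[float, float] = (1.0, 1.0)) -> float:
    """Enclosed area in mm^2 (shoelace; orientation independent)."""
    xy = c.to_mm(spacing)
    x, y = xy[:, 0], xy[:, 1]
    return float(abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)) / 2.0)


def _polygon(points_mm: np.ndarray) -> Polygon:
    poly = Polygon(points_mm)
    if poly.is_empty or poly.area == 0:
        raise ContourError("degenerate polygon")
    return poly


def signed_distance_2d(points_mm: np.ndarray, q) -> float:
    """Signed distance (mm) from point ``q=(u, v)`` to a closed polygon.

    Positive inside, negative outside, 0 on the boundary; boundary points
    count as inside.
    """
    poly = _polygon(np.asarray(points_mm, dtype=float))
    pt = Point(float(q[0]), float(q[1]))
    dist = poly.exterior.distance(pt)
    return dist if poly.intersects(pt) else -dist


def signed_distance_many(points_mm: np.ndarray, qs: np.ndarray) -> np.ndarray:
    """Vectorised :func:`signed_distance_2d` for ``qs`` of shape (n, 2)."""
    poly = _polygon(np.asarray(points_mm, dtype=float))
    pts = shapely.points(np.asarray(qs, dtype=float))
    shapely.prepare(poly)
    dist = shapely.distance(poly.exterior, pts)
    inside = shapely.intersects(poly, pts)
    return np.where(inside, dist, -dist)
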