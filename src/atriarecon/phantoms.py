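"""Synthetic LA phantoms with analytic reference volumes and slicing strategies.

Five implicit shape families mimic the spectrum of left-atrial morphology:
a large and a small oval (end-systolic / end-diastolic LA), an oblique oval
(LA with oblique connection to the LV), a sphere, and a curved oval (LA
indented by the aortic root). Every family is an affinely or isometrically
deformed ellipsoid, so the enclosed volume is (4/3)*pi*a*b*c exactly:

* the oblique family shears the long axis relative to the mitral plane
  (unit shear determinant, volume preserved);
* the curved family bends the long axis along a circular arc; each
  cross-section's centroid rides on the neutral arc, so by the slab-wise
  Pappus argument the volume is preserved exactly.

Calibration to a target volume therefore scales the semi-axes in closed
form. A brute-force voxelisation oracle is provided for verification.

Slicing strategies reproduce the three acquisition rows used on each shape:
row 1 long-axis planes aligned with the true LA long axis and short-axis
planes perpendicular to it; row 2 aligned long axis but tilted (default
20 deg) short-axis planes; row 3 long-axis planes rotated off the true axis
(default 25 deg, anchored at the mitral mid-point, as a mis-planned
acquisition would be) with short-axis planes perpendicular to the acquired
axis. Each strategy yields 2 long-axis + 3 short-axis slices.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation
from skimage import measure

from .contours import Contour
from .function import indices_from_volumes
from .geometry import ImagePlane, frame_from_normal
from .io import ContourDataset

__all__ = [
    "PhantomError",
    "Phantom",
    "SliceStrategy",
    "make_phantom",
    "slice_phantom",
    "generate_strategy",
    "generate_cine_phantom",
    "STANDARD_PHANTOMS",
]

#: the five standard shapes with their reference volumes (ml)
STANDARD_PHANTOMS: dict[str, tuple[str, float]] = {
    "oval_big": ("oval", 54.0),
    "oval_small": ("oval", 51.0),
    "oval_oblique": ("oblique_oval", 61.0),
    "spherical": ("sphere", 55.0),
    "curved": ("curved", 70.0),
}


class PhantomError(ValueError):
    """Infeasible phantom parameters."""


@dataclass(frozen=True)
class Phantom:
    """An implicit LA-shaped solid with exact analytic volume.

    ``value(pts) > 0`` inside, ``< 0`` outside, ``= 0`` on the surface.
    The shape is a closed solid (as a carved physical phantom would be);
    the mitral plane is a labelled landmark at the valve end of the long
    axis, not an open boundary.
    """

    family: str
    semi_axes: tuple[float, float, float]
    center: np.ndarray
    rotation: np.ndarray  # 3x3, base -> patient
    shear: float = 0.0  # oblique family: d(base z)/d(base x) of the axis tilt
    bend_radius_mm: float = 0.0  # curved family
    scale: float = 1.0  # cine self-similar scaling about the centre

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float).reshape(3))
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float).reshape(3, 3))
        a, b, c = self.semi_axes
        if min(a, b, c) <= 0:
            raise PhantomError("semi-axes must be positive")
        if self.family == "curved":
            if self.bend_radius_mm <= c:
                raise PhantomError("bend radius must exceed the z semi-axis")
            if a / self.bend_radius_mm >= np.pi:
                raise PhantomError("bend angle too large: shape self-intersects")

    # -- implicit function ------------------------------------------------
    def _base_coords(self, pts: np.ndarray) -> np.ndarray:
        """Map patient points to the straight base-ellipsoid frame."""
        q = (np.atleast_2d(pts) - self.center) @ self.rotation / self.scale
        if self.family == "oblique_oval":
            q = q.copy()
            q[:, 2] = q[:, 2] - self.shear * q[:, 0]
        elif self.family == "curved":
            rb = self.bend_radius_mm
            r = np.hypot(q[:, 0], rb - q[:, 2])
            theta = np.arctan2(q[:, 0], rb - q[:, 2])
            q = np.column_stack([rb * theta, q[:, 1], rb - r])
        return q

    def value(self, pts) -> np.ndarray:
        """Quasi-signed implicit value: 1 - scaled radius (exact zero set)."""
        pts = np.asarray(pts, dtype=float)
        q = self._base_coords(pts)
        ax = np.asarray(self.semi_axes)
        v = 1.0 - np.linalg.norm(q / ax, axis=1)
        return v if pts.ndim > 1 else float(v[0])

    def inside(self, pts) -> np.ndarray:
        return self.value(pts) >= 0

    # -- derived geometry -------------------------------------------------
    @property
    def volume_ml(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c * self.scale**3 / 1000.0

    @property
    def long_axis(self) -> np.ndarray:
        """Unit direction of the anatomical long axis (patient frame)."""
        if self.family == "oblique_oval":
            d = np.array([1.0, 0.0, self.shear])
        else:
            # curved: tangent at the arc centre is the base x direction
            d = np.array([1.0, 0.0, 0.0])
        d = self.rotation @ (d / np.linalg.norm(d))
        return d

    @property
    def mitral_point(self) -> np.ndarray:
        """Patient-space mitral valve mid-position (valve end of the axis)."""
        a = self.semi_axes[0]
        if self.family == "oblique_oval":
            base = np.array([-a, 0.0, -self.shear * a])
        elif self.family == "curved":
            rb = self.bend_radius_mm
            base = np.array([-rb * np.sin(a / rb), 0.0, rb * (1.0 - np.cos(a / rb))])
        else:
            base = np.array([-a, 0.0, 0.0])
        return self.center + self.rotation @ (base * self.scale)

    def scaled(self, s: float) -> "Phantom":
        """Self-similar scaling about the centre (cine motion model)."""
        if s <= 0:
            raise PhantomError("scale must be positive")
        return replace(self, scale=self.scale * s)

    def transformed(self, rotation, translation) -> "Phantom":
        """The same solid after a rigid patient-space motion."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float).reshape(3)
        return replace(self, center=R @ self.center + t, rotation=R @ self.rotation)

    # -- oracle -----------------------------------------------------------
    def bounding_radius(self) -> float:
        """Max distance from the centre to the surface (coarse sampled + margin)."""
        reach = (max(self.semi_axes) + self.bend_radius_mm) * self.scale + 2.0
        ax = np.arange(-reach, reach + 2.5, 2.5)
        xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
        pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
        inside = self.inside(pts + self.center)
        r = np.linalg.norm(pts[inside], axis=1)
        return float(r.max()) + 3.0

    def voxelized_volume_ml(self, step_mm: float = 0.5) -> float:
        """Brute-force volume by dense voxel counting (verification oracle)."""
        reach = (max(self.semi_axes) + self.bend_radius_mm) * self.scale + 2.0
        ax = np.arange(-reach, reach + step_mm, step_mm)
        total = 0
        for x in ax:  # slab-wise to bound memory
            yy, zz = np.meshgrid(ax, ax, indexing="ij")
            pts = np.column_stack(
                [np.full(yy.size, x), yy.ravel(), zz.ravel()]
            ) + self.center
            total += int(np.count_nonzero(self.inside(pts)))
        return total * step_mm**3 / 1000.0


def make_phantom(
    family: str,
    target_volume_ml: float,
    axis_ratios: Optional[tuple[float, float, float]] = None,
    shear: Optional[float] = None,
    bend_radius_mm: float = 70.0,
    center=(0.0, 0.0, 0.0),
    rotation: Optional[np.ndarray] = None,
) -> Phantom:
    """Build a phantom of the given family calibrated to a target volume.

    The semi-axes are scaled in closed form so the analytic volume equals
    ``target_volume_ml`` exactly.
    """
    if target_volume_ml <= 0:
        raise PhantomError("target volume must be positive")
    defaults = {
        "oval": (1.5, 1.2, 1.0),
        "oblique_oval": (1.6, 1.1, 1.0),
        "sphere": (1.0, 1.0, 1.0),
        "curved": (1.8, 1.0, 0.95),
    }
    if family not in defaults:
        raise PhantomError(f"unknown phantom family {family!r}")
    ratios = np.asarray(axis_ratios if axis_ratios is not None else defaults[family], float)
    if np.min(ratios) <= 0:
        raise PhantomError("axis ratios must be positive")
    s = (target_volume_ml * 1000.0 * 3.0 / (4.0 * np.pi * np.prod(ratios))) ** (1.0 / 3.0)
    semi = tuple(float(r * s) for r in ratios)
    if shear is None:
        shear = 0.45 if family == "oblique_oval" else 0.0
    return Phantom(
        family=family,
        semi_axes=semi,
        center=np.asarray(center, float),
        rotation=np.eye(3) if rotation is None else np.asarray(rotation, float),
        shear=float(shear),
        bend_radius_mm=float(bend_radius_mm) if family == "curved" else 0.0,
    )


# ----------------------------------------------------------------------
# slicing
# ----------------------------------------------------------------------

def slice_phantom(
    phantom: Phantom, plane: ImagePlane, sample_step: float = 0.75
) -> Optional[Contour]:
    """Sub-pixel contour of the phantom's cross-section on one plane.

    The implicit function is sampled on an in-plane lattice at
    ``sample_step`` mm and contoured at level 0 (marching squares), so the
    section area converges to the analytic one as O(sample_step^2).
    Returns None when the plane misses the shape.
    """
    rs, cs = plane.spacing
    width = (plane.n_cols - 1) * cs
    height = (plane.n_rows - 1) * rs
    us = np.arange(0.0, width + sample_step / 2, sample_step)
    vs = np.arange(0.0, height + sample_step / 2, sample_step)
    uu, vv = np.meshgrid(us, vs, indexing="ij")  # F[iu, iv]
    pts = plane.plane_to_patient(np.column_stack([uu.ravel(), vv.ravel()]))
    f = phantom.value(pts).reshape(uu.shape)
    if not (f > 0).any():
        return None
    loops = measure.find_contours(f, 0.0)
    closed = [l for l in loops if np.allclose(l[0], l[-1])]
    if not closed:
        return None
    best = max(closed, key=lambda l: len(l))
    # lattice index -> mm -> fractional pixel (row from v, col from u)
    u_mm = best[:, 0] * sample_step
    v_mm = best[:, 1] * sample_step
    return Contour(
        points=np.column_stack([v_mm / rs, u_mm / cs]),
        plane_id=plane.plane_id,
        frame=0,
    )


@dataclass(frozen=True)
class SliceStrategy:
    """One acquisition-planning row: 2 long-axis + 3 short-axis planes.

    ``code`` follows the shape-letter/row-number convention (e.g. "D1");
    only the row digit changes the geometry.
    """

    code: str = "1"
    misalign_deg: float = 25.0  # long-axis rotation off the true axis (row 3)
    tilt_deg: float = 20.0  # short-axis tilt off perpendicular (row 2)
    #: proximal/mid/distal short-axis positions along the chamber span
    sax_fractions: tuple[float, ...] = (0.2, 0.5, 0.8)

    @property
    def row(self) -> int:
        row = int(self.code[-1])
        if row not in (1, 2, 3):
            raise PhantomError(f"strategy row must be 1, 2 or 3, got {self.code!r}")
        return row

    @property
    def long_axis_aligned(self) -> bool:
        return self.row in (1, 2)

    @property
    def short_axis_perpendicular(self) -> bool:
        return self.row in (1, 3)


def _axis_extent(phantom: Phantom, origin: np.ndarray, direction: np.ndarray) -> float:
    """Length of the in-shape segment from origin along direction (mm)."""
    ts = np.arange(0.5, 4.0 * max(phantom.semi_axes) * phantom.scale
                   + phantom.bend_radius_mm + 1, 0.5)
    inside = phantom.inside(origin + ts[:, None] * direction)
    if not inside.any():
        raise PhantomError("acquired axis misses the phantom")
    t_lo = ts[np.nonzero(inside)[0][-1]]
    t_hi = t_lo + 0.5
    for _ in range(30):
        mid = 0.5 * (t_lo + t_hi)
        if phantom.inside(origin + mid * direction):
            t_lo = mid
        else:
            t_hi = mid
    return float(0.5 * (t_lo + t_hi))


def _span_along(
    phantom: Phantom, anchor: np.ndarray, direction: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """The shape's extent along a direction (relative to anchor) and centroid."""
    reach = phantom.bounding_radius()
    ax = np.arange(-reach, reach + 2.0, 2.0)
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()]) + phantom.center
    pts = pts[phantom.inside(pts)]
    t = (pts - anchor) @ direction
    return float(t.min()), float(t.max()), pts.mean(axis=0)


def _make_plane(
    center_pt: np.ndarray,
    u_dir: np.ndarray,
    v_dir: np.ndarray,
    size_mm: float,
    spacing: tuple[float, float],
    plane_id: str,
) -> ImagePlane:
    rs, cs = spacing
    n_cols = int(np.ceil(size_mm / cs)) + 1
    n_rows = int(np.ceil(size_mm / rs)) + 1
    origin = center_pt - ((n_cols - 1) / 2) * cs * u_dir - ((n_rows - 1) / 2) * rs * v_dir
    return ImagePlane(
        origin=origin,
        u_dir=u_dir,
        v_dir=v_dir,
        spacing=spacing,
        n_rows=n_rows,
        n_cols=n_cols,
        plane_id=plane_id,
    )


def strategy_planes(
    phantom: Phantom,
    strategy: SliceStrategy,
    spacing: tuple[float, float] = (1.5, 1.5),
) -> tuple[dict[str, ImagePlane], dict]:
    """Pose the 5 acquisition planes for a strategy row on a phantom.

    Long-axis planes are anchored at the mitral mid-point (as planned on a
    scanner); a mis-aligned acquisition rotates the planned axis about that
    anchor.
    """
    mitral = phantom.mitral_point
    axis = phantom.long_axis
    if np.dot(phantom.center - mitral, axis) < 0:
        axis = -axis
    e_perp = frame_from_normal(axis)[0]
    if not strategy.long_axis_aligned:
        rot = Rotation.from_rotvec(np.deg2rad(strategy.misalign_deg) * e_perp)
        axis = rot.apply(axis)
    extent = _axis_extent(phantom, mitral, axis)
    e1, e2 = frame_from_normal(axis)
    mid = mitral + 0.5 * extent * axis
    # generous FOV: the plane rectangle must cover the whole shape even for
    # mis-aligned acquisitions of bent phantoms
    size = 2.0 * (np.linalg.norm(mid - phantom.center) + phantom.bounding_radius()) + 20.0
    planes: dict[str, ImagePlane] = {}
    planes["LAX1"] = _make_plane(mid, axis, e1, size, spacing, "LAX1")
    planes["LAX2"] = _make_plane(mid, axis, e2, size, spacing, "LAX2")
    sax_normal = axis
    if not strategy.short_axis_perpendicular:
        rot = Rotation.from_rotvec(np.deg2rad(strategy.tilt_deg) * e1)
        sax_normal = rot.apply(axis)
    su, sv = frame_from_normal(sax_normal)
    # short-axis slices are planned over the visible atrium: proximal, mid
    # and distal fractions of the chamber's span along the stack normal
    t_lo, t_hi, centroid = _span_along(phantom, mitral, sax_normal)
    for k, frac in enumerate(strategy.sax_fractions, start=1):
        t = t_lo + frac * (t_hi - t_lo)
        c = centroid + (t - float((centroid - mitral) @ sax_normal)) * sax_normal
        planes[f"SAX{k}"] = _make_plane(c, su, sv, size, spacing, f"SAX{k}")
    info = {
        "acquired_axis": axis.tolist(),
        "axis_extent_mm": extent,
        "sax_span_mm": [t_lo, t_hi],
        "mitral_point": mitral.tolist(),
        "misalign_deg": 0.0 if strategy.long_axis_aligned else strategy.misalign_deg,
        "sax_tilt_deg": 0.0 if strategy.short_axis_perpendicular else strategy.tilt_deg,
    }
    return planes, info


def generate_strategy(
    phantom: Phantom,
    strategy: SliceStrategy,
    noise_mm: float = 0.0,
    seed: Optional[int] = None,
    spacing: tuple[float, float] = (1.5, 1.5),
    sample_step: float = 0.75,
) -> ContourDataset:
    """Slice a phantom per one strategy row into a contour-exchange dataset.

    Optional i.i.d. Gaussian vertex noise (``noise_mm``, seeded) emulates
    segmentation jitter. The dataset carries the ground-truth volume and
    the per-plane mitral landmark (for area-length measurements).
    """
    planes, info = strategy_planes(phantom, strategy, spacing=spacing)
    rng = np.random.default_rng(seed)
    contours = []
    skipped = []
    for pid, plane in planes.items():
        c = slice_phantom(phantom, plane, sample_step=sample_step)
        if c is None:
            skipped.append(pid)
            continue
        pts = c.points.copy()
        if noise_mm > 0:
            rs, cs = plane.spacing
            pts = pts + rng.normal(0.0, noise_mm, pts.shape) / np.array([rs, cs])
        contours.append(Contour(points=pts, plane_id=pid, frame=0))
    mitral_uv = {}
    for pid in ("LAX1", "LAX2"):
        pp = planes[pid].patient_to_plane(phantom.mitral_point)
        mitral_uv[pid] = list(pp.uv)
    return ContourDataset(
        planes=planes,
        contours=contours,
        metadata={
            "strategy": strategy.code,
            "row": strategy.row,
            "noise_mm": noise_mm,
            "seed": seed,
            "sample_step_mm": sample_step,
            "skipped_planes": skipped,
            **info,
        },
        ground_truth={
            "volume_ml": phantom.volume_ml,
            "family": phantom.family,
            "mitral_uv": mitral_uv,
        },
    )


# ----------------------------------------------------------------------
# cine
# ----------------------------------------------------------------------

def prescribe_curve(
    v_max: float,
    v_min: float,
    v_pre_a: float,
    n_frames: int = 34,
    dt_ms: float = 30.0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """A physiological one-cycle LA volume curve hitting the three landmarks.

    Frame 0 is v_min (end of atrial contraction); the reservoir phase rises
    to v_max, passive emptying eases into a diastasis shoulder at v_pre_a,
    and the atrial kick returns to v_min. Cosine segments give zero slope
    at every landmark, so the shoulder is a genuine flat point.
    """
    if not (0 < v_min <= v_pre_a <= v_max):
        raise PhantomError("need 0 < v_min <= v_pre_a <= v_max")
    if n_frames < 8:
        raise PhantomError("need >= 8 frames")
    i_max = int(round(0.4 * n_frames))
    i_pre = int(round(0.75 * n_frames))
    v = np.empty(n_frames)

    def seg(i0, i1, a, b):
        tau = (np.arange(i0, i1) - i0) / (i1 - i0)
        v[i0:i1] = a + (b - a) * (1.0 - np.cos(np.pi * tau)) / 2.0

    seg(0, i_max, v_min, v_max)
    seg(i_max, i_pre, v_max, v_pre_a)
    seg(i_pre, n_frames, v_pre_a, v_min)
    t = np.arange(n_frames) * dt_ms
    marks = {"i_max": i_max, "i_pre_a": i_pre, "i_min": 0, "rr_ms": n_frames * dt_ms}
    return t, v, marks


def generate_cine_phantom(
    phantom: Phantom,
    v_max: float,
    v_min: float,
    v_pre_a: float,
    n_frames: int = 34,
    dt_ms: float = 30.0,
    strategy: Optional[SliceStrategy] = None,
    noise_mm: float = 0.0,
    seed: Optional[int] = None,
    spacing: tuple[float, float] = (1.5, 1.5),
    sample_step: float = 0.75,
) -> ContourDataset:
    """Animate a phantom through a prescribed volume curve and slice every frame.

    The motion model is pure self-similar scaling about the centre: the
    frame scale is ``(V(t)/V_ref)^(1/3)``, so each frame's true volume is
    V(t) exactly. The plane set is fixed across frames (sized for the
    largest frame) and the ground-truth curve and indices ride along.
    """
    strategy = strategy or SliceStrategy("1")
    t, v, marks = prescribe_curve(v_max, v_min, v_pre_a, n_frames, dt_ms)
    s_max = (v_max / phantom.volume_ml) ** (1.0 / 3.0)
    planes, info = strategy_planes(phantom.scaled(s_max), strategy, spacing=spacing)
    rng = np.random.default_rng(seed)
    contours = []
    for f in range(n_frames):
        frame_phantom = phantom.scaled((v[f] / phantom.volume_ml) ** (1.0 / 3.0))
        for pid, plane in planes.items():
            c = slice_phantom(frame_phantom, plane, sample_step=sample_step)
            if c is None:
                continue
            pts = c.points.copy()
            if noise_mm > 0:
                rs, cs = plane.spacing
                pts = pts + rng.normal(0.0, noise_mm, pts.shape) / np.array([rs, cs])
            contours.append(Contour(points=pts, plane_id=pid, frame=f))
    gt_indices = indices_from_volumes(
        v_max,
        v_min,
        v_pre_a if v_pre_a > v_min else None,
        t_max=t[marks["i_max"]],
        t_pre_a=t[marks["i_pre_a"]],
        t_min=marks["rr_ms"],
        rr_ms=marks["rr_ms"],
    )
    return ContourDataset(
        planes=planes,
        contours=contours,
        metadata={
            "strategy": strategy.code,
            "noise_mm": noise_mm,
            "seed": seed,
            "dt_ms": dt_ms,
            "n_frames": n_frames,
            **info,
        },
        ground_truth={
            "volume_ml": phantom.volume_ml,
            "times_ms": t.tolist(),
            "volumes_ml": v.tolist(),
            "v_max": v_max,
            "v_min": v_min,
            "v_pre_a": v_pre_a,
            "phase_frames": marks,
            "indices": gt_indices.as_dict(),
        },
    )
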