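"""Slice-plane geometry in the DICOM patient coordinate convention.

An acquired 2D slice is described the way a DICOM header describes it: the
patient-space position of the centre of the pixel at (row 0, col 0)
(``ImagePositionPatient``), the unit direction cosines of increasing column
and row index (``ImageOrientationPatient``), and the pixel spacing in mm.
All patient coordinates are LPS (left-posterior-superior); converters from
other conventions belong in I/O code, never here.

Pixel indices are 0-based and refer to pixel centres, and may be fractional
(sub-pixel contour vertices).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "GeometryError",
    "ImagePlane",
    "PlanePoint",
    "pixel_to_patient",
    "patient_to_plane",
]

#: direction cosines farther than this from unit/orthogonal are rejected
_HARD_TOL = 1e-3
#: deviations below this are accepted silently; between the two we re-normalise
_SOFT_TOL = 1e-6


class GeometryError(ValueError):
    """Invalid slice-plane geometry (degenerate or non-orthonormal frame)."""


@dataclass(frozen=True)
class PlanePoint:
    """A patient-space point expressed relative to a slice plane.

    ``uv`` are the in-plane coordinates in mm (along the column and row
    direction cosines, measured from the plane origin); ``d`` is the signed
    out-of-plane distance in mm, positive along the plane normal.
    """

    uv: tuple[float, float]
    d: float


@dataclass(frozen=True)
class ImagePlane:
    """Geometry of one acquired slice, DICOM-style.

    Parameters
    ----------
    origin:
        Patient-space position (mm) of the centre of pixel (row 0, col 0).
    u_dir, v_dir:
        Unit direction cosines of increasing column and row index.
    spacing:
        (row spacing, column spacing) in mm/pixel.
    n_rows, n_cols:
        Image matrix size.
    thickness:
        Slice thickness in mm; metadata only, no partial-volume model.
    plane_id:
        Label used to join contours to planes in the exchange format.
    """

    origin: np.ndarray
    u_dir: np.ndarray
    v_dir: np.ndarray
    spacing: tuple[float, float] = (1.5, 1.5)
    n_rows: int = 128
    n_cols: int = 128
    thickness: float = 6.0
    plane_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float).reshape(3))
        u = np.asarray(self.u_dir, dtype=float).reshape(3)
        v = np.asarray(self.v_dir, dtype=float).reshape(3)
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if abs(nu - 1.0) > _HARD_TOL or abs(nv - 1.0) > _HARD_TOL:
            raise GeometryError(
                f"direction cosines are not unit vectors (|u|={nu:.6f}, |v|={nv:.6f})"
            )
        u = u / nu
        v = v / nv
        dot = float(np.dot(u, v))
        if abs(dot) > _HARD_TOL:
            raise GeometryError(f"direction cosines are not orthogonal (u.v={dot:.6f})")
        if abs(dot) > _SOFT_TOL:
            # rounded header values: re-orthogonalise v against u
            v = v - dot * u
            v = v / np.linalg.norm(v)
        u.flags.writeable = False
        v.flags.writeable = False
        self.origin.flags.writeable = False
        object.__setattr__(self, "u_dir", u)
        object.__setattr__(self, "v_dir", v)
        rs, cs = self.spacing
        if rs <= 0 or cs <= 0:
            raise GeometryError(f"pixel spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "spacing", (float(rs), float(cs)))
        if self.n_rows < 1 or self.n_cols < 1:
            raise GeometryError("image matrix size must be positive")

    @property
    def normal(self) -> np.ndarray:
        """Unit plane normal ``u_dir x v_dir`` (recomputed, never stored)."""
        n = np.cross(self.u_dir, self.v_dir)
        return n / np.linalg.norm(n)

    # ------------------------------------------------------------------
    def pixel_to_patient(self, row, col) -> np.ndarray:
        """Map (fractional) pixel indices to 3D patient coordinates in mm.

        ``origin + col * col_spacing * u_dir + row * row_spacing * v_dir``.
        Accepts scalars or broadcastable arrays; returns shape ``(..., 3)``.
        """
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        rs, cs = self.spacing
        p = (
            self.origin
            + col[..., None] * cs * self.u_dir
            + row[..., None] * rs * self.v_dir
        )
        return p if p.ndim > 1 else p.reshape(3)

    def patient_to_plane(self, p) -> PlanePoint:
        """Express a patient-space point in plane coordinates (uv, d)."""
        uv, d = self.patient_to_plane_arrays(p)
        return PlanePoint(uv=(float(uv[..., 0]), float(uv[..., 1])), d=float(d))

    def patient_to_plane_arrays(self, p) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised (uv, d) for an array of points with shape (..., 3)."""
        dp = np.asarray(p, dtype=float) - self.origin
        u = dp @ self.u_dir
        v = dp @ self.v_dir
        d = dp @ self.normal
        return np.stack([u, v], axis=-1), d

    def plane_to_patient(self, uv) -> np.ndarray:
        """Map in-plane mm coordinates (u, v) back to patient space."""
        uv = np.asarray(uv, dtype=float)
        p = self.origin + uv[..., 0, None] * self.u_dir + uv[..., 1, None] * self.v_dir
        return p if p.ndim > 1 else p.reshape(3)

    # ------------------------------------------------------------------
    def transformed(self, rotation: np.ndarray, translation: Sequence[float]) -> "ImagePlane":
        """The same plane after a rigid patient-space motion."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float).reshape(3)
        return replace(
            self,
            origin=R @ self.origin + t,
            u_dir=R @ self.u_dir,
            v_dir=R @ self.v_dir,
        )


def pixel_to_patient(plane: ImagePlane, row, col) -> np.ndarray:
    """Functional form of :meth:`ImagePlane.pixel_to_patient`."""
    return plane.pixel_to_patient(row, col)


def patient_to_plane(plane: ImagePlane, p) -> PlanePoint:
    """Functional form of :meth:`ImagePlane.patient_to_plane`."""
    return plane.patient_to_plane(p)


def frame_from_normal(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """A deterministic orthonormal in-plane basis (u, v) for a plane normal.

    Picks the world axis least parallel to ``normal`` as the seed so the
    result is stable under small perturbations of the normal.
    """
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    seed = np.zeros(3)
    seed[int(np.argmin(np.abs(n)))] = 1.0
    u = np.cross(seed, n)
    u = u / np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v
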