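"""Contour-exchange I/O: JSON datasets, curve CSV, mesh export, NIfTI masks.

The contour-exchange JSON is the package's interchange format::

    {"planes":   [{"plane_id", "origin", "u_dir", "v_dir", "spacing",
                   "n_rows", "n_cols", "thickness"}, ...],
     "contours": [{"plane_id", "frame", "points_rowcol": [[r, c], ...],
                   "closed": true}, ...],
     "metadata": {...}, "ground_truth": {...}}

Patient coordinates are DICOM LPS throughout; NIfTI affines (RAS) are
converted on ingestion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .contours import Contour, mask_to_contour
from .geometry import ImagePlane

__all__ = ["ContourDataset", "read_contours", "write_contours", "read_curve",
           "write_curve", "write_mesh", "masks_from_nifti"]


@dataclass
class ContourDataset:
    """Planes, their contours (possibly many frames), and bookkeeping."""

    planes: dict[str, ImagePlane]
    contours: list[Contour]
    metadata: dict = field(default_factory=dict)
    ground_truth: dict = field(default_factory=dict)

    def frames(self) -> list[int]:
        return sorted({c.frame for c in self.contours})

    def frame_set(self, frame: int) -> tuple[list[ImagePlane], list[Contour]]:
        cs = sorted(
            (c for c in self.contours if c.frame == frame), key=lambda c: c.plane_id
        )
        return [self.planes[c.plane_id] for c in cs], cs


def _plane_to_json(p: ImagePlane) -> dict:
    return {
        "plane_id": p.plane_id,
        "origin": list(p.origin),
        "u_dir": list(p.u_dir),
        "v_dir": list(p.v_dir),
        "spacing": list(p.spacing),
        "n_rows": p.n_rows,
        "n_cols": p.n_cols,
        "thickness": p.thickness,
    }


def _plane_from_json(d: dict) -> ImagePlane:
    return ImagePlane(
        origin=np.array(d["origin"]),
        u_dir=np.array(d["u_dir"]),
        v_dir=np.array(d["v_dir"]),
        spacing=tuple(d["spacing"]),
        n_rows=int(d["n_rows"]),
        n_cols=int(d["n_cols"]),
        thickness=float(d.get("thickness", 6.0)),
        plane_id=str(d["plane_id"]),
    )


def write_contours(dataset: ContourDataset, path: str | Path) -> None:
    doc = {
        "planes": [_plane_to_json(p) for p in dataset.planes.values()],
        "contours": [
            {
                "plane_id": c.plane_id,
                "frame": c.frame,
                "points_rowcol": np.asarray(c.points).tolist(),
                "closed": True,
            }
            for c in dataset.contours
        ],
        "metadata": dataset.metadata,
        "ground_truth": dataset.ground_truth,
    }
    Path(path).write_text(json.dumps(doc))


def read_contours(path: str | Path) -> ContourDataset:
    doc = json.loads(Path(path).read_text())
    planes = {d["plane_id"]: _plane_from_json(d) for d in doc["planes"]}
    contours = []
    for d in doc["contours"]:
        if not d.get("closed", True):
            raise ValueError(f"open contour on plane {d['plane_id']!r} is not supported")
        contours.append(
            Contour(
                points=np.array(d["points_rowcol"], dtype=float),
                plane_id=str(d["plane_id"]),
                frame=int(d.get("frame", 0)),
            )
        )
    return ContourDataset(
        planes=planes,
        contours=contours,
        metadata=doc.get("metadata", {}),
        ground_truth=doc.get("ground_truth", {}),
    )


def write_curve(curve, path: str | Path) -> None:
    """Time-volume curve as CSV with columns frame, time_ms, volume_ml."""
    pd.DataFrame(
        {
            "frame": np.arange(len(curve.times_ms)),
            "time_ms": curve.times_ms,
            "volume_ml": curve.volumes_ml,
        }
    ).to_csv(path, index=False)


def read_curve(path: str | Path):
    from .function import TimeVolumeCurve

    df = pd.read_csv(path)
    return TimeVolumeCurve(
        times_ms=df["time_ms"].to_numpy(float),
        volumes_ml=df["volume_ml"].to_numpy(float),
    )


def write_mesh(mesh, path: str | Path) -> None:
    """Export a reconstructed surface as STL/PLY (by file extension)."""
    mesh.to_trimesh().export(str(path))


def masks_from_nifti(
    path: str | Path, plane: ImagePlane, component_policy: str = "largest"
) -> list[Contour]:
    """Contours from a NIfTI mask volume: one 2D slab, frames on the last axis.

    The in-plane geometry is taken from ``plane`` (the upstream layout may
    abuse the third axis for time, so the NIfTI affine is not trusted for
    plane placement).
    """
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim == 2:
        data = data[..., None]
    if data.ndim != 3:
        raise ValueError(f"expected a 2D+time mask volume, got shape {data.shape}")
    out = []
    for f in range(data.shape[-1]):
        sl = data[..., f]
        if not (sl > 0).any():
            continue
        out.append(
            mask_to_contour(
                sl, component_policy=component_policy, plane_id=plane.plane_id, frame=f
            )
        )
    return out
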