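"""Bundled worked-example measurements from the LA volumetry validation study.

Three small tables ship with the package as fixtures for the statistics and
functional-index machinery:

* :func:`phantom_validation_measurements` — LA volumes of the five carved
  phantoms measured from the cine acquisition with both reconstruction
  methods under each of the three slice-orientation strategies, against the
  water-displacement reference volume;
* :func:`patient_volume_measurements` — per-patient cine LA volume against
  the high-resolution 3D reference at the matched mid-diastolic phase;
* :func:`patient_function_inputs` — the landmark volumes (v_max, v_min,
  pre-contraction volume) and LV stroke volume per patient, the inputs of
  the LA function index arithmetic.

Strategy codes follow the letter/row convention: letter = shape, row 1 =
long-axis aligned + short-axis perpendicular, row 2 = aligned +
non-perpendicular, row 3 = not-aligned + perpendicular.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "phantom_validation_measurements",
    "patient_volume_measurements",
    "patient_function_inputs",
]

_SHAPES = ["oval_big", "oval_small", "oval_oblique", "spherical", "curved"]
_LETTERS = ["A", "B", "C", "D", "E"]
_REFERENCE_ML = {"oval_big": 54.0, "oval_small": 51.0, "oval_oblique": 61.0,
                 "spherical": 55.0, "curved": 70.0}

# measured phantom volumes (ml) per strategy row: non-model-based 3D
# reconstruction and model-based bi-plane area-length, both from the same
# cine acquisitions
_RECON_ML = {
    "oval_big": (51.0, 50.9, 52.8),
    "oval_small": (45.7, 46.4, 46.5),
    "oval_oblique": (55.3, 55.3, 54.4),
    "spherical": (48.2, 47.2, 49.8),
    "curved": (65.8, 67.5, 65.3),
}
_AREA_LENGTH_ML = {
    "oval_big": (52.67, 50.29, 46.51),
    "oval_small": (48.38, 47.76, 45.03),
    "oval_oblique": (55.92, 57.28, 42.57),
    "spherical": (50.10, 51.66, 49.96),
    "curved": (61.02, 63.23, 54.29),
}


def phantom_validation_measurements() -> pd.DataFrame:
    """The 5 shapes x 3 strategies x 2 methods phantom validation table.

    Columns: shape, strategy, row, aligned, perpendicular, method
    ("reconstruction" | "area_length"), measured_ml, reference_ml.
    """
    rows = []
    for shape, letter in zip(_SHAPES, _LETTERS):
        for row_idx in (1, 2, 3):
            for method, table in (
                ("reconstruction", _RECON_ML),
                ("area_length", _AREA_LENGTH_ML),
            ):
                rows.append(
                    {
                        "shape": shape,
                        "strategy": f"{letter}{row_idx}",
                        "row": row_idx,
                        "aligned": row_idx in (1, 2),
                        "perpendicular": row_idx in (1, 3),
                        "method": method,
                        "measured_ml": table[shape][row_idx - 1],
                        "reference_ml": _REFERENCE_ML[shape],
                    }
                )
    return pd.DataFrame(rows)


def patient_volume_measurements() -> pd.DataFrame:
    """Cine vs high-resolution-reference LA volume (ml) in three patients."""
    return pd.DataFrame(
        {
            "patient": [1, 2, 3],
            "cine_ml": [62.5, 61.5, 395.0],
            "reference_ml": [59.0, 71.0, 397.0],
        }
    )


def patient_function_inputs() -> dict[int, dict]:
    """Landmark LA volumes and LV stroke volume per patient.

    Patient 3 (mechanical mitral prosthesis, no atrial kick on the curve)
    has no pre-contraction volume: ``v_pre_a`` is None.
    """
    return {
        1: {"v_max": 82.6, "v_min": 43.6, "v_pre_a": 64.4, "lv_sv": 104.0},
        2: {"v_max": 70.6, "v_min": 40.6, "v_pre_a": 61.9, "lv_sv": 73.7},
        3: {"v_max": 418.0, "v_min": 376.0, "v_pre_a": None, "lv_sv": 66.4},
    }
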