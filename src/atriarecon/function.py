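"""Left-atrial function indices from a time-volume curve.

Over one cardiac cycle the LA fills during ventricular systole (reservoir,
up to v_max), empties passively during early diastole (conduit, down to the
pre-contraction volume v_pre_a at diastasis), and empties actively with the
atrial kick (booster, down to v_min). The derived indices:

    total emptying  = v_max - v_min        (total conduit volume)
    passive         = v_max - v_pre_a
    active          = v_pre_a - v_min
    total EF        = 100 * total / v_max
    fractions       = 100 * passive/total, 100 * active/total
    rates           = phase volume / phase duration (ml/ms)
    "passive LA flow" = LV stroke volume - total emptying

When no atrial contraction exists (atrial fibrillation, paced rhythm, or a
flat diastasis) v_pre_a coincides with v_min: active emptying is 0 and the
passive fraction is 100 %.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "FunctionError",
    "TimeVolumeCurve",
    "PhaseIndices",
    "LAFunctionIndices",
    "locate_phases",
    "compute_indices",
    "indices_from_volumes",
]


class FunctionError(ValueError):
    """The time-volume curve does not support the requested analysis."""


@dataclass(frozen=True)
class TimeVolumeCurve:
    """LA volume (ml) per cardiac phase over one full cycle."""

    times_ms: np.ndarray
    volumes_ml: np.ndarray
    rr_ms: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times_ms, dtype=float)
        v = np.asarray(self.volumes_ml, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise FunctionError("times and volumes must be matching 1D arrays")
        if len(t) and np.any(np.diff(t) <= 0):
            raise FunctionError("times must be strictly increasing")
        if np.any(v <= 0):
            raise FunctionError("volumes must be positive")
        object.__setattr__(self, "times_ms", t)
        object.__setattr__(self, "volumes_ml", v)
        if self.rr_ms is None and len(t) > 1:
            object.__setattr__(self, "rr_ms", float(t[-1] - t[0] + np.mean(np.diff(t))))

    def __len__(self) -> int:
        return len(self.times_ms)


@dataclass(frozen=True)
class PhaseIndices:
    i_max: int
    i_min: int
    i_pre_a: int
    low_confidence: bool = False


def _cyclic_range(start: int, stop: int, n: int) -> list[int]:
    """Frames strictly between start and stop walking forward cyclically."""
    out = []
    i = (start + 1) % n
    while i != stop:
        out.append(i)
        i = (i + 1) % n
    return out


def locate_phases(curve: TimeVolumeCurve, pre_a_frame: Optional[int] = None) -> PhaseIndices:
    """Find the frames of v_max, v_min and the pre-contraction shoulder.

    v_min is taken after v_max in cyclic order (the emptying limb). The
    pre-contraction frame, when not supplied, is the flattest point of the
    curve (minimal |dV/dt|) on the emptying limb, restricted to volumes
    away from both extremes so plateaus around v_max/v_min are not mistaken
    for the diastasis shoulder. When no such interior shoulder exists the
    result coincides with v_min and is flagged low-confidence.
    """
    v = curve.volumes_ml
    t = curve.times_ms
    n = len(v)
    if n < 8:
        raise FunctionError("need >= 8 frames to locate cardiac phases")
    if v.max() - v.min() < 0.01 * v.mean():
        raise FunctionError("no cardiac variation: curve is flat")
    i_max = int(np.argmax(v))
    # minimal volume after the maximum, cyclically
    order = [(i_max + k) % n for k in range(1, n)]
    i_min = min(order, key=lambda i: v[i])
    if pre_a_frame is not None:
        return PhaseIndices(i_max=i_max, i_min=i_min, i_pre_a=int(pre_a_frame))
    # periodic central-difference slope; the wrapped time step uses the RR
    dt_wrap = (np.roll(t, -1) - np.roll(t, 1)) % (curve.rr_ms or (t[-1] - t[0]))
    dt_wrap[dt_wrap == 0] = np.mean(np.diff(t)) * 2
    dvdt = (np.roll(v, -1) - np.roll(v, 1)) / dt_wrap
    span = v.max() - v.min()
    lo, hi = v.min() + 0.05 * span, v.max() - 0.05 * span
    candidates = [i for i in _cyclic_range(i_max, i_min, n) if lo < v[i] < hi]
    if not candidates:
        return PhaseIndices(i_max=i_max, i_min=i_min, i_pre_a=i_min, low_confidence=True)
    i_pre_a = min(candidates, key=lambda i: abs(dvdt[i]))
    # a monotone limb with no real shoulder still returns its flattest frame
    flat = abs(dvdt[i_pre_a]) > 0.25 * np.max(np.abs(dvdt))
    return PhaseIndices(i_max=i_max, i_min=i_min, i_pre_a=i_pre_a, low_confidence=flat)


@dataclass(frozen=True)
class LAFunctionIndices:
    """The Table-style LA function report; volumes ml, fractions %, rates ml/ms."""

    v_max: float
    v_min: float
    v_pre_a: Optional[float]
    total_emptying: float
    passive_emptying: float
    active_emptying: float
    total_ef: float
    passive_fraction: float
    active_fraction: float
    passive_rate: Optional[float] = None
    active_rate: Optional[float] = None
    lv_sv: Optional[float] = None
    passive_la_flow: Optional[float] = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def indices_from_volumes(
    v_max: float,
    v_min: float,
    v_pre_a: Optional[float] = None,
    lv_sv: Optional[float] = None,
    t_max: Optional[float] = None,
    t_pre_a: Optional[float] = None,
    t_min: Optional[float] = None,
    rr_ms: Optional[float] = None,
) -> LAFunctionIndices:
    """Index arithmetic from the three landmark volumes (and optional timings).

    ``v_pre_a=None`` encodes absent atrial contraction: all emptying is
    passive. Rates are reported only when the phase timings are given and
    the phase exists.
    """
    if not (0 < v_min <= v_max):
        raise FunctionError("need 0 < v_min <= v_max")
    if v_pre_a is not None and not (v_min <= v_pre_a <= v_max):
        raise FunctionError("v_pre_a must lie between v_min and v_max")
    total = v_max - v_min
    if total <= 0:
        raise FunctionError("no emptying: v_max equals v_min")
    vpa = v_min if v_pre_a is None else v_pre_a
    passive = v_max - vpa
    active = vpa - v_min
    passive_rate = active_rate = None

    def _dur(t0, t1):
        if t0 is None or t1 is None:
            return None
        d = t1 - t0
        if d <= 0 and rr_ms:
            d += rr_ms
        return d if d and d > 0 else None

    dp = _dur(t_max, t_pre_a)
    da = _dur(t_pre_a, t_min)
    if dp is not None and passive > 0:
        passive_rate = passive / dp
    if da is not None and active > 0:
        active_rate = active / da
    return LAFunctionIndices(
        v_max=v_max,
        v_min=v_min,
        v_pre_a=v_pre_a,
        total_emptying=total,
        passive_emptying=passive,
        active_emptying=active,
        total_ef=100.0 * total / v_max,
        passive_fraction=100.0 * passive / total,
        active_fraction=100.0 * active / total,
        passive_rate=passive_rate,
        active_rate=active_rate,
        lv_sv=lv_sv,
        passive_la_flow=None if lv_sv is None else lv_sv - total,
    )


def compute_indices(
    curve: TimeVolumeCurve,
    pre_a_frame: Optional[int] = None,
    lv_sv: Optional[float] = None,
) -> LAFunctionIndices:
    """Locate the phases on a curve and derive the full index report.

    The curve is treated as periodic, so the result is invariant to a
    rotation of the starting frame.
    """
    ph = locate_phases(curve, pre_a_frame=pre_a_frame)
    v, t = curve.volumes_ml, curve.times_ms
    no_kick = ph.i_pre_a == ph.i_min
    return indices_from_volumes(
        v_max=float(v[ph.i_max]),
        v_min=float(v[ph.i_min]),
        v_pre_a=None if no_kick else float(v[ph.i_pre_a]),
        lv_sv=lv_sv,
        t_max=float(t[ph.i_max]),
        t_pre_a=float(t[ph.i_pre_a]),
        t_min=float(t[ph.i_min]),
        rr_ms=curve.rr_ms,
    )
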