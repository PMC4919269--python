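"""Input-function AUC, total body clearance, and group fold-changes.

Total body clearance (TBC) of a tracer that is not metabolised is the
injected dose per kilogram body weight divided by the area under the
plasma (image-derived) input function over the scan:

    TBC = ID / AUC(0-90 min)        [mL/min/kg]

Frame values are time-averages, so the AUC uses the frame-rectangle rule
(value x duration), which reconstructs the integral of the underlying
continuous curve exactly; frames partially inside the window contribute
proportionally to their overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cohort import SubjectRecord, TimeActivityCurve, ValidationError

__all__ = ["ClearanceResult", "auc", "tbc", "fold_change"]


@dataclass(frozen=True)
class ClearanceResult:
    auc_0_90: float  # kBq*min/mL
    id_per_kg: float  # kBq/kg
    tbc: float  # mL/min/kg


def auc(tac: TimeActivityCurve, t0_min: float, t1_min: float) -> float:
    """Area under the TAC between ``t0_min`` and ``t1_min`` (kBq*min/mL)."""
    if t1_min <= t0_min:
        raise ValidationError("t1 must exceed t0")
    start = tac.schedule.frame_start_s / 60.0
    end = tac.schedule.frame_end_s / 60.0
    if t0_min < start[0] - 1e-9 or t1_min > end[-1] + 1e-9:
        raise ValidationError("[t0, t1] must lie within the schedule span")
    overlap = np.clip(np.minimum(end, t1_min) - np.maximum(start, t0_min), 0.0, None)
    return float(np.sum(tac.values * overlap))


def tbc(subject: SubjectRecord, idif: TimeActivityCurve, t1_min: float = 90.0) -> ClearanceResult:
    """Total body clearance from the image-derived input function."""
    if idif.units_mode != "concentration":
        raise ValidationError("TBC requires the IDIF in concentration units")
    area = auc(idif, 0.0, t1_min)
    if area <= 0:
        raise ValidationError("input-function AUC must be > 0")
    id_per_kg = subject.injected_dose_kBq / (subject.body_weight_g / 1000.0)
    return ClearanceResult(auc_0_90=area, id_per_kg=id_per_kg, tbc=id_per_kg / area)


def fold_change(group_a: Sequence[float], group_b: Sequence[float], geometric: bool = False) -> float:
    """Ratio of group means, mean(a) / mean(b).

    ``geometric=True`` switches to the ratio of geometric means.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    if geometric:
        if np.any(a <= 0) or np.any(b <= 0):
            raise ValidationError("geometric fold-change requires positive values")
        return float(np.exp(np.mean(np.log(a)) - np.mean(np.log(b))))
    mb = float(np.mean(b))
    if mb == 0:
        raise ValidationError("denominator group mean is zero")
    return float(np.mean(a) / mb)
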