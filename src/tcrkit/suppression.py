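"""Treg suppression-assay statistic.

Suppression is computed from CellTrace-style proliferation readouts as

    suppression% = 100 − (treated / control × 100)

where *treated* is the percentage of proliferated conventional T cells in a
Treg co-culture and *control* the percentage in the Tconv-only condition
(which therefore defines 0% suppression).  Curves summarise replicate wells
per Treg:Tconv ratio as mean ± standard error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

CONTROL = "control"


class UndefinedStatisticError(ValueError):
    pass


class InputError(ValueError):
    pass


@dataclass
class ProliferationMeasurement:
    condition: str  # e.g. "1:1", "1:2", "1:4", "1:8" or "control"
    replicate: str
    percent_proliferated: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_proliferated <= 100.0:
            raise InputError(
                f"percent_proliferated {self.percent_proliferated} outside [0, 100]"
            )


@dataclass
class SuppressionPoint:
    condition: str
    mean: float
    sem: float
    n: int
    values: list[float]


def suppression_pct(treated: float, control: float) -> float:
    """Suppression % = 100 − (treated/control × 100).

    ``treated == control`` yields exactly 0 (the control convention).
    Values above the control give negative suppression; these are reported
    as-is with a warning, never clamped.
    """
    if control == 0:
        raise UndefinedStatisticError("suppression undefined for control proliferation of 0")
    s = 100.0 - (treated / control * 100.0)
    if s < 0:
        warnings.warn(f"negative suppression ({s:.2f}%): treated exceeds control", stacklevel=2)
    return s


def suppression_curve(
    measurements: Sequence[ProliferationMeasurement], paired: bool = False
) -> list[SuppressionPoint]:
    """Per-ratio suppression summary over replicates.

    By default each replicate is referenced to the pooled mean of the control
    replicates; ``paired=True`` instead pairs each treated replicate with the
    control replicate of the same id (requiring one to exist).
    """
    controls = {m.replicate: m.percent_proliferated for m in measurements if m.condition == CONTROL}
    if not controls:
        raise InputError("no control (Tconv-only) replicate present")
    pooled = sum(controls.values()) / len(controls)

    by_cond: dict[str, list[ProliferationMeasurement]] = {}
    order: list[str] = []
    for m in measurements:
        if m.condition == CONTROL:
            continue
        if m.condition not in by_cond:
            order.append(m.condition)
        by_cond.setdefault(m.condition, []).append(m)

    out = []
    for cond in order:
        vals = []
        for m in by_cond[cond]:
            if paired:
                if m.replicate not in controls:
                    raise InputError(f"no control replicate paired with {m.replicate!r}")
                ref = controls[m.replicate]
            else:
                ref = pooled
            vals.append(suppression_pct(m.percent_proliferated, ref))
        mean = sum(vals) / len(vals)
        if len(vals) > 1:
            var = sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)
            sem = math.sqrt(var / len(vals))
        else:
            sem = 0.0
        out.append(SuppressionPoint(condition=cond, mean=mean, sem=sem, n=len(vals), values=vals))
    return out
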