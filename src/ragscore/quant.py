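"""Validation-assay arithmetic: 2^-ddCt relative expression and
spheroid-attachment percentages."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Union


@dataclass(frozen=True)
class CtMeasurement:
    """Cycle thresholds for a target gene and its housekeeping reference."""

    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for name, v in (("ct_target", self.ct_target), ("ct_reference", self.ct_reference)):
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class AttachmentCount:
    attached: int
    total: int

    def __post_init__(self) -> None:
        if self.total < 1:
            raise ValueError("total must be a positive integer")
        if not 0 <= self.attached <= self.total:
            raise ValueError(f"attached must be in [0, total], got {self.attached}/{self.total}")


def delta_ct(m: CtMeasurement) -> float:
    """Target Ct normalized to the housekeeping gene: ct_target - ct_reference."""
    return m.ct_target - m.ct_reference


def mean_ct(replicates: Iterable[float]) -> float:
    """Arithmetic mean of replicate Ct values (triplicates averaged before dCt)."""
    values = list(replicates)
    if not values or not all(math.isfinite(v) for v in values):
        raise ValueError("replicates must be a non-empty sequence of finite values")
    return sum(values) / len(values)


def relative_expression(delta_ct_experimental: float, delta_ct_control: float) -> float:
    """Fold change by the 2^-ddCt method; ddCt = experimental dCt - control dCt."""
    for v in (delta_ct_experimental, delta_ct_control):
        if not math.isfinite(v):
            raise ValueError(f"delta Ct must be finite, got {v}")
    return 2.0 ** -(delta_ct_experimental - delta_ct_control)


def percent_attached(c: AttachmentCount) -> float:
    """100 x attached / total."""
    return 100.0 * c.attached / c.total


def percent_reduction(treated: float, control: float, relative: bool = False) -> float:
    """Reduction of an attachment percentage under treatment.

    Default is the percentage-point difference ``control - treated``;
    ``relative=True`` gives the relative reduction ``100 x (control - treated) / control``.
    """
    for name, v in (("treated", treated), ("control", control)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} must be a percentage in [0, 100], got {v}")
    if relative:
        if control == 0:
            raise ValueError("relative reduction undefined for control = 0")
        return 100.0 * (control - treated) / control
    return control - treated
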