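"""Relative-quantification arithmetic for qPCR and dual-reporter assays.

Plasma miRNA levels are normalised to a spiked-in control (cel-miR-39, added
at a fixed amount per fixed plasma volume) and expressed as
``2^-(Ct_target - Ct_spike)``. Tissue mRNA uses a housekeeping gene the same
way on triplicate-mean Cts. Reporter assays form per-well channel ratios
(reporter / normalizer luciferase), average wells per condition, and report
fold change against a control condition. All values are dimensionless
relative units; a value of 1 means target and normalizer Cts were equal.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import statistics
from typing import Mapping, Sequence

__all__ = [
    "RelativeExpression",
    "aggregate_ct",
    "spike_in_expression",
    "housekeeping_expression",
    "group_fold_change",
    "reporter_fold_change",
]

logger = logging.getLogger(__name__)

NORMALIZERS = ("spike_in", "housekeeping", "reporter_control")


@dataclasses.dataclass(frozen=True)
class RelativeExpression:
    sample_id: str
    assay_id: str
    value: float
    normalizer: str

    def __post_init__(self) -> None:
        if self.normalizer not in NORMALIZERS:
            raise ValueError(f"unknown normalizer tag {self.normalizer!r}")
        if not (self.value > 0 and math.isfinite(self.value)):
            raise ValueError(f"relative expression must be finite and > 0, got {self.value}")


def aggregate_ct(
    ct_values: Sequence[float], max_spread: float = 1.0
) -> float | None:
    """Mean replicate Ct after the outlier rule.

    If the max pairwise spread of the (<= 3) replicates exceeds ``max_spread``
    cycles, the single replicate farthest from the median is dropped before
    averaging. Missing replicates (None/NaN) are ignored; returns None when
    none remain.
    """
    cts = [c for c in ct_values if c is not None and math.isfinite(c)]
    if not cts:
        return None
    if len(cts) > 1 and max(cts) - min(cts) > max_spread:
        med = statistics.median(cts)
        worst_idx = max(range(len(cts)), key=lambda i: (abs(cts[i] - med), cts[i]))
        worst = cts.pop(worst_idx)
        logger.info("dropped outlier replicate Ct %.3f (spread > %.2f)", worst, max_spread)
    return sum(cts) / len(cts)


def spike_in_expression(
    ct_target: float | None,
    ct_spike: float | None,
    sample_id: str = "",
    assay_id: str = "",
) -> RelativeExpression | None:
    """Spike-in normalised expression: 2^-(Ct_target - Ct_spike).

    Missing Cts propagate to a missing (None) result, logged.
    """
    if ct_target is None or ct_spike is None:
        logger.info("sample %r/%r: missing Ct, expression not computed", sample_id, assay_id)
        return None
    for name, ct in (("target", ct_target), ("spike-in", ct_spike)):
        if not (0 < ct <= 45):
            raise ValueError(f"{name} Ct {ct} outside (0, 45]")
    return RelativeExpression(
        sample_id, assay_id, 2.0 ** -(ct_target - ct_spike), "spike_in"
    )


def housekeeping_expression(
    ct_target: Sequence[float],
    ct_housekeeping: Sequence[float],
    sample_id: str = "",
    assay_id: str = "",
    max_spread: float = 1.0,
) -> RelativeExpression | None:
    """Housekeeping-normalised expression from replicate Cts.

    Replicates are aggregated by mean after the outlier rule; the value is
    2^-dCt with dCt = mean Ct_target - mean Ct_housekeeping.
    """
    t = aggregate_ct(ct_target, max_spread)
    h = aggregate_ct(ct_housekeeping, max_spread)
    if t is None or h is None:
        logger.info("sample %r/%r: all replicates missing", sample_id, assay_id)
        return None
    return RelativeExpression(sample_id, assay_id, 2.0 ** -(t - h), "housekeeping")


def group_fold_change(
    test_values: Sequence[float], reference_values: Sequence[float]
) -> float:
    """Fold change between groups = ratio of group mean expression values."""
    if not test_values or not reference_values:
        raise ValueError("both groups must be non-empty")
    ref_mean = sum(reference_values) / len(reference_values)
    if ref_mean <= 0:
        raise ValueError("reference group mean must be > 0")
    return (sum(test_values) / len(test_values)) / ref_mean


def reporter_fold_change(
    conditions: Mapping[str, Sequence[tuple[float, float]]],
    control: str,
    ratio_orientation: str = "first_over_second",
) -> dict[str, float]:
    """Dual-reporter fold changes relative to a control condition.

    Each well is a (channel_1, channel_2) luminescence pair; the per-well
    ratio is channel_1/channel_2 (or the reverse with
    ``ratio_orientation='second_over_first'``, e.g. Renilla/Firefly for 3'UTR
    constructs). A condition's value is the mean well ratio; fold change is
    the condition value over the control condition's value.
    """
    if ratio_orientation not in ("first_over_second", "second_over_first"):
        raise ValueError(f"bad ratio_orientation {ratio_orientation!r}")
    if control not in conditions:
        raise ValueError(f"control condition {control!r} not among conditions")
    means = {}
    for name, wells in conditions.items():
        if not wells:
            raise ValueError(f"condition {name!r} has no wells")
        ratios = []
        for w1, w2 in wells:
            if w1 <= 0 or w2 <= 0:
                raise ValueError(f"condition {name!r}: non-positive luminescence reading")
            ratios.append(w1 / w2 if ratio_orientation == "first_over_second" else w2 / w1)
        means[name] = sum(ratios) / len(ratios)
    control_mean = means[control]
    return {name: mean / control_mean for name, mean in means.items()}
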