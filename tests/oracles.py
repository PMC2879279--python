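"""Independent brute-force oracles, deliberately naive and separate from the
implementation code paths they check."""

from __future__ import annotations

import math
from typing import Mapping, Sequence


def brute_force_dq(
    sample_areas: Mapping[str, float],
    control_areas: Sequence[Mapping[str, float]],
    target_id: str,
    reference_ids: Sequence[str],
) -> tuple[float | None, float | None, int]:
    """Plain double loop over (reference, control) pairs; mean, sample SD, n."""
    values = []
    for ref_id in reference_ids:
        for ctrl in control_areas:
            tar_s = sample_areas.get(target_id)
            ref_s = sample_areas.get(ref_id)
            tar_c = ctrl.get(target_id)
            ref_c = ctrl.get(ref_id)
            if any(v is None or v <= 0 for v in (tar_s, ref_s, tar_c, ref_c)):
                continue
            values.append((tar_s / ref_s) / (tar_c / ref_c))
    if not values:
        return None, None, 0
    n = len(values)
    mean = sum(values) / n
    sd = 0.0 if n == 1 else math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    return mean, sd, n


def literal_segmental(dqs: Sequence[float], delta: float, fraction_rule: bool) -> str:
    """Word-for-word transcription of the segmental clauses.

    A region is a deletion (gain) if the DQs of at least 2 consecutive loci
    are delta below (above) 1; with the fraction rule, also when more than
    75% of the loci show a decrease (increase) of at least 0.15.
    """
    for i in range(len(dqs) - 1):
        if dqs[i] <= 1 - delta and dqs[i + 1] <= 1 - delta:
            return "loss"
        if dqs[i] >= 1 + delta and dqs[i + 1] >= 1 + delta:
            return "gain"
    if fraction_rule and dqs:
        n = len(dqs)
        if sum(1 for d in dqs if d <= 1 - 0.15) / n > 0.75:
            return "loss"
        if sum(1 for d in dqs if d >= 1 + 0.15) / n > 0.75:
            return "gain"
    return "normal"


def literal_whole_chromosome(p: Sequence[float], q: Sequence[float]) -> str:
    """Word-for-word numerical clause: at least 75% of the DQs of both the p
    and q arm below (above) 1, and more than half of the DQs deviating by at
    least 0.1."""
    both = list(p) + list(q)
    for cmp_side, cmp_dev, verdict in (
        (lambda v: v < 1, lambda v: v <= 0.9, "loss"),
        (lambda v: v > 1, lambda v: v >= 1.1, "gain"),
    ):
        if (
            sum(1 for v in p if cmp_side(v)) / len(p) >= 0.75
            and sum(1 for v in q if cmp_side(v)) / len(q) >= 0.75
            and sum(1 for v in both if cmp_dev(v)) / len(both) > 0.5
        ):
            return verdict
    return "normal"


def literal_mycn(dqs: Sequence[float], required: int) -> str:
    """The MYCN DQs (all of them) must increase by at least 3."""
    if len(dqs) < required:
        return "no_data"
    return "amplified" if all(d >= 4.0 for d in dqs) else "normal"


def mann_whitney_auc(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> float:
    """Pairwise-comparison probability over all positive-negative pairs (percent)."""
    wins = 0.0
    for p in pos_scores:
        for n in neg_scores:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return 100.0 * wins / (len(pos_scores) * len(neg_scores))
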