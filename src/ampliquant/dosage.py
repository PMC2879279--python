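"""Dosage-quotient computation.

The dosage quotient (DQ) of a target amplicon is the double ratio

    DQ = [TarA(s) / RefA(s)] / [TarA(ctr) / RefA(ctr)]

of target to reference peak area in the test sample, relative to the same
ratio in a normal control. Per-amplicon PCR efficiency and per-sample input
amount both cancel, so in the noise-free limit the DQ equals the target copy
number over the (diploid) baseline: 1.0 for two copies, 0.5 for one, 1.5 for
three, far above 1 for amplification.

The final DQ of a target is the arithmetic mean of the pairwise DQs over the
full Cartesian product of reference amplicons and control samples; its
standard deviation (sample SD, n-1 denominator) measures stability.
Combinations in which any of the four areas is missing or non-positive are
excluded rather than imputed.

Note the normalization caveat central to near-triploid tumors: when reference
loci are themselves co-aberrant with the rest of the genome, the double ratio
cancels the shared ploidy and all DQs collapse toward 1, masking whole-
chromosome changes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ConfigurationError
from .panel import Amplicon, PanelDefinition, ROLE_TARGET
from .peaks import SampleRun

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DosageQuotient:
    """Aggregated DQ of one target amplicon in one sample.

    ``n_combinations == 0`` marks a no-data target (all combinations invalid);
    ``dq_mean``/``dq_sd`` are then NaN.
    """

    sample_id: str
    amplicon_id: str
    dq_mean: float
    dq_sd: float
    n_combinations: int

    @property
    def is_no_data(self) -> bool:
        return self.n_combinations == 0

    @staticmethod
    def no_data(sample_id: str, amplicon_id: str) -> "DosageQuotient":
        return DosageQuotient(sample_id, amplicon_id, math.nan, math.nan, 0)


def pairwise_dq(tar_s: float, ref_s: float, tar_ctr: float, ref_ctr: float) -> float:
    """The double ratio for a single (reference amplicon, control sample) pair.

    All four areas must be present and strictly positive; otherwise the
    combination is undefined and a ValueError is raised (callers skip it).
    """
    for name, area in (("tar_s", tar_s), ("ref_s", ref_s), ("tar_ctr", tar_ctr), ("ref_ctr", ref_ctr)):
        if area is None or not area > 0:
            raise ValueError(f"undefined DQ combination: {name} = {area!r}")
    return (tar_s / ref_s) / (tar_ctr / ref_ctr)


def aggregate_dq(
    sample: SampleRun,
    controls: Sequence[SampleRun],
    panel: PanelDefinition,
    target: Amplicon,
) -> DosageQuotient:
    """Mean/SD of pairwise DQs over all valid (reference, control) combinations."""
    if target.role != ROLE_TARGET:
        raise ConfigurationError(f"amplicon {target.id} is not a target")
    if not controls:
        raise ConfigurationError("at least one control sample is required")
    tar_s = sample.areas.get(target.id)
    values: list[float] = []
    n_skipped = 0
    for ref in panel.references:
        ref_s = sample.areas.get(ref.id)
        for ctr in controls:
            tar_ctr = ctr.areas.get(target.id)
            ref_ctr = ctr.areas.get(ref.id)
            if any(a is None or not a > 0 for a in (tar_s, ref_s, tar_ctr, ref_ctr)):
                n_skipped += 1
                continue
            values.append(pairwise_dq(tar_s, ref_s, tar_ctr, ref_ctr))
    if n_skipped:
        logger.debug(
            "sample %s target %s: %d invalid (reference, control) combination(s) skipped",
            sample.sample_id, target.id, n_skipped,
        )
    if not values:
        return DosageQuotient.no_data(sample.sample_id, target.id)
    n = len(values)
    mean = sum(values) / n
    if n == 1:
        sd = 0.0
    else:
        sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    return DosageQuotient(sample.sample_id, target.id, mean, sd, n)


def dq_profile(
    sample: SampleRun,
    controls: Sequence[SampleRun],
    panel: PanelDefinition,
) -> list[DosageQuotient]:
    """One DosageQuotient per target amplicon, in genomic order.

    Targets without a single valid combination appear as no-data entries so
    that profile positions stay aligned with the panel.
    """
    if not controls:
        raise ConfigurationError("dq_profile requires at least one control sample")
    return [aggregate_dq(sample, controls, panel, target) for target in panel.targets_sorted()]
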