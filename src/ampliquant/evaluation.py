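"""Diagnostic-performance and repeatability statistics.

Calls are compared region by region against a gold-standard table (in the
assay's validation, genome-wide array CGH segmented with CBS at +/-0.3).
A call counts as positive only when it matches the region's expected
aberration direction (loss for 1p/3p/11q, gain for 17q, amplification for
MYCN; either direction for whole chromosomes); a no-data status on either
side excludes the pair. Undefined ratios (zero denominators) are reported
as not-available (None), never coerced to 0 or 100.

Two AUC flavors are exposed: the two-point ROC through a single operating
point, (sensitivity + specificity) / 2, for rule-based calls; and a
threshold-swept trapezoidal AUC over a continuous per-region score (maximum
DQ deviation toward the expected direction), equivalent to the Mann-Whitney
pairwise-comparison probability.

Repeatability uses Bland-Altman limits of agreement on paired replicate DQs:
bias = mean difference, limits = 1.96 x SD of the differences, and the
coefficient of repeatability reported as |bias| + 1.96 x SD.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .errors import ConfigurationError
from .scoring import (
    RegionCall,
    STATUS_AMPLIFIED,
    STATUS_GAIN,
    STATUS_LOSS,
    STATUS_NO_DATA,
    STATUS_NORMAL,
)

logger = logging.getLogger(__name__)

GOLD_POSITIVE = "positive"
GOLD_NEGATIVE = "negative"
GOLD_NO_DATA = "no_data"

#: Expected aberration direction per prognostic region; whole-chromosome
#: regions ("chr1", ...) accept either direction.
DEFAULT_POSITIVE_STATUSES: dict[str, frozenset[str]] = {
    "1p": frozenset({STATUS_LOSS}),
    "3p": frozenset({STATUS_LOSS}),
    "11q": frozenset({STATUS_LOSS}),
    "17q": frozenset({STATUS_GAIN}),
    "MYCN": frozenset({STATUS_AMPLIFIED}),
}


def positive_statuses_for(region: str) -> frozenset[str]:
    if region in DEFAULT_POSITIVE_STATUSES:
        return DEFAULT_POSITIVE_STATUSES[region]
    return frozenset({STATUS_LOSS, STATUS_GAIN})


@dataclass(frozen=True)
class GoldStandardTable:
    """(sample, region) -> positive/negative/no_data reference statuses."""

    entries: Mapping[tuple[str, str], str]
    provenance: str = ""

    def __post_init__(self) -> None:
        for key, status in self.entries.items():
            if status not in (GOLD_POSITIVE, GOLD_NEGATIVE, GOLD_NO_DATA):
                raise ConfigurationError(f"gold standard {key}: invalid status {status!r}")

    def status(self, sample_id: str, region: str) -> str:
        return self.entries.get((sample_id, region), GOLD_NO_DATA)

    def regions(self) -> list[str]:
        seen: list[str] = []
        for _, region in self.entries:
            if region not in seen:
                seen.append(region)
        return seen

    def samples(self) -> list[str]:
        seen: list[str] = []
        for sample, _ in self.entries:
            if sample not in seen:
                seen.append(sample)
        return seen


def read_gold_table(path: str | Path, provenance: str = "") -> GoldStandardTable:
    entries: dict[tuple[str, str], str] = {}
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t") if r and not r[0].startswith("#")]
    if not rows or [c.strip() for c in rows[0][:3]] != ["sample_id", "region", "status"]:
        raise ConfigurationError(f"{path}: gold table must have header sample_id<TAB>region<TAB>status")
    for row in rows[1:]:
        key = (row[0], row[1])
        if key in entries:
            raise ConfigurationError(f"{path}: duplicate gold entry for {key}")
        entries[key] = row[2]
    return GoldStandardTable(entries, provenance=provenance)


def write_gold_table(gold: GoldStandardTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        if gold.provenance:
            fh.write(f"# {gold.provenance}\n")
        fh.write("sample_id\tregion\tstatus\n")
        for (sample_id, region), status in gold.entries.items():
            fh.write(f"{sample_id}\t{region}\t{status}\n")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fn: int = 0
    tn: int = 0
    fp: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ConfigurationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fn + other.fn, self.tn + other.tn, self.fp + other.fp)


def confusion_counts(
    calls: Iterable[RegionCall],
    gold: GoldStandardTable,
    region: str,
    positive_statuses: frozenset[str] | None = None,
) -> ConfusionCounts:
    """Tally one region's calls against the gold standard.

    Pairs with no_data on either side are excluded (and logged).
    """
    if region not in gold.regions():
        raise ConfigurationError(f"region {region!r} absent from the gold standard")
    positive_statuses = positive_statuses or positive_statuses_for(region)
    tp = fp = tn = fn = excluded = 0
    for call in calls:
        if call.region != region:
            continue
        truth = gold.status(call.sample_id, region)
        if call.status == STATUS_NO_DATA or truth == GOLD_NO_DATA:
            excluded += 1
            continue
        called_positive = call.status in positive_statuses
        if truth == GOLD_POSITIVE:
            tp += called_positive
            fn += not called_positive
        else:
            fp += called_positive
            tn += not called_positive
    if excluded:
        logger.info("region %s: %d (sample, region) pair(s) excluded as no_data", region, excluded)
    return ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)


@dataclass(frozen=True)
class PerformanceMetrics:
    """Sensitivity/specificity/PPV/NPV as percentages; None when undefined."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None


def _pct(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def performance_metrics(counts: ConfusionCounts) -> PerformanceMetrics:
    return PerformanceMetrics(
        sensitivity=_pct(counts.tp, counts.tp + counts.fn),
        specificity=_pct(counts.tn, counts.tn + counts.fp),
        ppv=_pct(counts.tp, counts.tp + counts.fp),
        npv=_pct(counts.tn, counts.tn + counts.fn),
    )


def binary_auc(counts: ConfusionCounts) -> float | None:
    """AUC of the two-point ROC through (1 - specificity, sensitivity).

    For a single operating point this is (sensitivity + specificity) / 2.
    """
    m = performance_metrics(counts)
    if m.sensitivity is None or m.specificity is None:
        return None
    return (m.sensitivity + m.specificity) / 2.0


def region_score(
    dq_means: Sequence[float],
    region: str,
) -> float:
    """Continuous per-sample score for a region: max DQ deviation toward the
    region's expected aberration direction (negative when the profile deviates
    the opposite way only)."""
    if not dq_means:
        return math.nan
    positive = positive_statuses_for(region)
    deviations = []
    for dq in dq_means:
        if STATUS_LOSS in positive and STATUS_GAIN in positive:
            deviations.append(abs(dq - 1.0))
        elif STATUS_GAIN in positive or STATUS_AMPLIFIED in positive:
            deviations.append(dq - 1.0)
        else:
            deviations.append(1.0 - dq)
    return max(deviations)


def continuous_auc(
    scores: Mapping[str, float],
    gold: GoldStandardTable,
    region: str,
) -> float | None:
    """Threshold-swept (trapezoidal) ROC AUC over continuous region scores.

    Equivalent to the Mann-Whitney probability that a random positive sample
    scores above a random negative one, with ties counted half. Returns None
    when the gold standard holds a single class for this region.
    """
    y, s = [], []
    for sample_id, score in scores.items():
        truth = gold.status(sample_id, region)
        if truth == GOLD_NO_DATA or (isinstance(score, float) and math.isnan(score)):
            continue
        y.append(1 if truth == GOLD_POSITIVE else 0)
        s.append(score)
    if len(set(y)) < 2:
        return None
    return 100.0 * float(roc_auc_score(y, s))


def macro_average_auc(per_region_auc: Sequence[float | None]) -> float | None:
    """Unweighted mean AUC over regions; None entries are not allowed in, an
    empty list yields None."""
    values = [v for v in per_region_auc if v is not None]
    if not values:
        return None
    return float(np.mean(values))


def error_rates(counts: Iterable[ConfusionCounts]) -> tuple[float | None, float | None]:
    """Pooled false-positive and false-negative rates (percent) across regions."""
    pooled = ConfusionCounts()
    for c in counts:
        pooled = pooled + c
    fpr = _pct(pooled.fp, pooled.fp + pooled.tn)
    fnr = _pct(pooled.fn, pooled.fn + pooled.tp)
    return fpr, fnr


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float            # mean paired difference
    sd: float              # SD of the differences (n-1)
    limit: float           # 1.96 * sd
    cr: float              # |bias| + 1.96 * sd
    n: int


def bland_altman_cr(
    replicate_a: Sequence[float],
    replicate_b: Sequence[float],
) -> BlandAltmanResult | None:
    """Bland-Altman repeatability of paired replicate DQ measurements.

    Pairs with a missing (NaN) value are excluded; fewer than 2 usable pairs
    -> None (not available).
    """
    if len(replicate_a) != len(replicate_b):
        raise ConfigurationError("replicate lists must be paired (equal length)")
    diffs = [
        a - b
        for a, b in zip(replicate_a, replicate_b)
        if not (math.isnan(a) or math.isnan(b))
    ]
    if len(diffs) < 2:
        return None
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    limit = 1.96 * sd
    return BlandAltmanResult(bias=bias, sd=sd, limit=limit, cr=abs(bias) + limit, n=len(diffs))


@dataclass(frozen=True)
class RegionPerformance:
    region: str
    counts: ConfusionCounts
    metrics: PerformanceMetrics
    auc: float | None


@dataclass(frozen=True)
class PerformanceReport:
    per_region: tuple[RegionPerformance, ...]
    fpr: float | None
    fnr: float | None
    macro_auc: float | None


def evaluate_performance(
    calls: Iterable[RegionCall],
    gold: GoldStandardTable,
    regions: Sequence[str] | None = None,
) -> PerformanceReport:
    """Full Table-style report: per-region metrics, pooled error rates, macro AUC."""
    calls = list(calls)
    if regions is None:
        call_regions = {c.region for c in calls}
        regions = [r for r in gold.regions() if r in call_regions]
    if not regions:
        raise ConfigurationError("no region is shared between calls and gold standard")
    per_region = []
    for region in regions:
        counts = confusion_counts(calls, gold, region)
        per_region.append(
            RegionPerformance(region, counts, performance_metrics(counts), binary_auc(counts))
        )
    fpr, fnr = error_rates([rp.counts for rp in per_region])
    macro = macro_average_auc([rp.auc for rp in per_region if rp.auc is not None])
    return PerformanceReport(tuple(per_region), fpr, fnr, macro)


def _fmt(value: float | None) -> str:
    return "NA" if value is None else f"{value:.1f}"


def write_performance_report(report: PerformanceReport, path: str | Path) -> None:
    """Human-readable TSV mirroring the usual validation-table layout."""
    with open(path, "w") as fh:
        fh.write("region\ttp\tfn\ttn\tfp\tauc\tsensitivity\tspecificity\tppv\tnpv\n")
        for rp in report.per_region:
            c, m = rp.counts, rp.metrics
            fh.write(
                f"{rp.region}\t{c.tp}\t{c.fn}\t{c.tn}\t{c.fp}\t{_fmt(rp.auc)}\t"
                f"{_fmt(m.sensitivity)}\t{_fmt(m.specificity)}\t{_fmt(m.ppv)}\t{_fmt(m.npv)}\n"
            )
        fh.write(f"# pooled_fpr\t{_fmt(report.fpr)}\n")
        fh.write(f"# pooled_fnr\t{_fmt(report.fnr)}\n")
        fh.write(f"# macro_auc\t{_fmt(report.macro_auc)}\n")
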