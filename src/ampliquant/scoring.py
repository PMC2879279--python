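"""Rule-based scoring of DQ profiles.

Two published rule sets are bundled:

* **MAQ** — a segmental loss (gain) requires at least 2 consecutive loci with
  DQ at least 0.2 below (above) 1; MYCN amplification requires all 3 MYCN
  loci to increase by at least 3 (DQ >= 4).
* **MLPA** — the consecutive-locus threshold is 0.25, with an additional
  fraction clause: more than 75% of an arm's loci deviating by at least 0.15
  in the same direction also calls; MYCN needs 2 loci at DQ >= 4.

Both rule sets share the whole-chromosome (numerical) clause: at least 75%
of the DQs on *both* arms sit below (above) 1, and more than half of the
chromosome's DQs deviate by at least 0.1. Numerical scoring is only
attempted when the sample shows no segmental call anywhere (segmental
aberrations take global precedence, mirroring how the assay separates
prognostically unfavorable segmental tumors from favorable numerical ones).

All "at least" thresholds are inclusive; the "more than 75%" / "more than
half" clauses are strict. A locus with no DQ data breaks adjacency for the
consecutive rule and is excluded from fraction denominators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .dosage import DosageQuotient
from .errors import ConfigurationError
from .panel import MYCN_REGION, PanelDefinition, _chrom_key

logger = logging.getLogger(__name__)

STATUS_LOSS = "loss"
STATUS_GAIN = "gain"
STATUS_AMPLIFIED = "amplified"
STATUS_NORMAL = "normal"
STATUS_NO_DATA = "no_data"

SCOPE_SEGMENTAL = "segmental"
SCOPE_WHOLE_CHROMOSOME = "whole_chromosome"

CATEGORY_SEGMENTAL = "segmental"
CATEGORY_NUMERICAL = "numerical"
CATEGORY_NONE = "none"


@dataclass(frozen=True)
class RuleSet:
    """Thresholds of one scoring scheme; see module docstring for semantics."""

    name: str
    segmental_delta: float
    segmental_min_consecutive: int = 2
    fraction_rule_enabled: bool = False
    fraction_rule_fraction: float = 0.75   # strict ">"
    fraction_rule_delta: float = 0.15
    numerical_arm_fraction: float = 0.75   # inclusive ">="
    numerical_majority_delta: float = 0.1
    numerical_majority_fraction: float = 0.5  # strict ">"
    mycn_delta: float = 3.0                # amplified when DQ >= 1 + mycn_delta
    mycn_required_loci: int = 2

    def __post_init__(self) -> None:
        for attr in ("segmental_delta", "fraction_rule_delta", "numerical_majority_delta", "mycn_delta"):
            if getattr(self, attr) <= 0:
                raise ConfigurationError(f"RuleSet {self.name}: {attr} must be > 0")
        for attr in ("fraction_rule_fraction", "numerical_arm_fraction", "numerical_majority_fraction"):
            if not 0 < getattr(self, attr) <= 1:
                raise ConfigurationError(f"RuleSet {self.name}: {attr} must be in (0, 1]")
        if self.segmental_min_consecutive < 2:
            raise ConfigurationError(f"RuleSet {self.name}: segmental_min_consecutive must be >= 2")


MAQ_RULES = RuleSet(name="MAQ", segmental_delta=0.2, fraction_rule_enabled=False, mycn_required_loci=3)
MLPA_RULES = RuleSet(name="MLPA", segmental_delta=0.25, fraction_rule_enabled=True, mycn_required_loci=2)

_PRESETS = {"MAQ": MAQ_RULES, "MLPA": MLPA_RULES}


def get_ruleset(name_or_path: str) -> RuleSet:
    """Look up a bundled preset ("MAQ"/"MLPA") or load a YAML rule file."""
    if name_or_path in _PRESETS:
        return _PRESETS[name_or_path]
    return load_ruleset(name_or_path)


def load_ruleset(path: str | Path) -> RuleSet:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "name" not in data:
        raise ConfigurationError(f"rule file {path} must be a mapping with at least a 'name' key")
    try:
        return RuleSet(**data)
    except TypeError as exc:
        raise ConfigurationError(f"rule file {path}: {exc}") from exc


def save_ruleset(rules: RuleSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(rules), fh, sort_keys=False)


@dataclass(frozen=True)
class RegionCall:
    sample_id: str
    region: str
    status: str
    scope: str
    rule_fired: str = ""
    supporting_loci: tuple[str, ...] = ()


@dataclass(frozen=True)
class SampleClassification:
    """Sample-level verdict: segmental vs numerical vs no aberration."""

    sample_id: str
    category: str
    mycn_amplified: bool | None  # None = no data
    region_calls: tuple[RegionCall, ...]


def _numeric(dqs: Sequence[DosageQuotient]) -> list[DosageQuotient]:
    return [d for d in dqs if not d.is_no_data]


def score_segmental(
    dqs: Sequence[DosageQuotient],
    rules: RuleSet,
    *,
    region: str = "",
    sample_id: str = "",
) -> RegionCall:
    """Score one arm region from its position-ordered DQ list.

    Loss (gain) fires when at least ``segmental_min_consecutive`` adjacent
    loci all deviate by ``segmental_delta`` in the same direction; a no-data
    locus breaks adjacency. Under MLPA rules, a same-direction deviation of
    at least ``fraction_rule_delta`` in more than ``fraction_rule_fraction``
    of the numeric loci also fires. Fewer than 2 numeric loci -> no_data.
    """
    numeric = _numeric(dqs)
    if len(numeric) < 2:
        return RegionCall(sample_id, region, STATUS_NO_DATA, SCOPE_SEGMENTAL, "insufficient_data")

    lo = 1.0 - rules.segmental_delta
    hi = 1.0 + rules.segmental_delta
    need = rules.segmental_min_consecutive

    # consecutive clause: single positional scan; the first run of `need`
    # adjacent same-direction deviant loci wins. A no-data or normal locus,
    # or a direction flip, breaks the run.
    run: list[DosageQuotient] = []
    run_status = ""
    for d in dqs:
        if d.is_no_data:
            status = ""
        elif d.dq_mean <= lo:
            status = STATUS_LOSS
        elif d.dq_mean >= hi:
            status = STATUS_GAIN
        else:
            status = ""
        if status and status == run_status:
            run.append(d)
        elif status:
            run, run_status = [d], status
        else:
            run, run_status = [], ""
        if len(run) >= need:
            return RegionCall(
                sample_id, region, run_status, SCOPE_SEGMENTAL,
                f"consecutive_{run_status}",
                tuple(x.amplicon_id for x in run),
            )

    if rules.fraction_rule_enabled:
        n = len(numeric)
        down = [d for d in numeric if d.dq_mean <= 1.0 - rules.fraction_rule_delta]
        up = [d for d in numeric if d.dq_mean >= 1.0 + rules.fraction_rule_delta]
        if len(down) / n > rules.fraction_rule_fraction:
            return RegionCall(sample_id, region, STATUS_LOSS, SCOPE_SEGMENTAL,
                              "fraction_loss", tuple(d.amplicon_id for d in down))
        if len(up) / n > rules.fraction_rule_fraction:
            return RegionCall(sample_id, region, STATUS_GAIN, SCOPE_SEGMENTAL,
                              "fraction_gain", tuple(d.amplicon_id for d in up))

    return RegionCall(sample_id, region, STATUS_NORMAL, SCOPE_SEGMENTAL, "no_rule")


def score_whole_chromosome(
    dqs_p: Sequence[DosageQuotient],
    dqs_q: Sequence[DosageQuotient],
    rules: RuleSet,
    *,
    region: str = "",
    sample_id: str = "",
) -> RegionCall:
    """Score a whole-chromosome (numerical) change from both arms' DQ lists.

    Requires directional consistency of at least ``numerical_arm_fraction``
    of each arm's DQs (below/above 1) plus a strict majority of the
    chromosome's DQs deviating by at least ``numerical_majority_delta``.
    """
    p = _numeric(dqs_p)
    q = _numeric(dqs_q)
    if not p or not q:
        return RegionCall(sample_id, region, STATUS_NO_DATA, SCOPE_WHOLE_CHROMOSOME, "insufficient_data")
    both = p + q

    def arm_frac(arm: list[DosageQuotient], cond) -> float:
        return sum(1 for d in arm if cond(d.dq_mean)) / len(arm)

    for status, side, dev in (
        (STATUS_LOSS, lambda v: v < 1.0, lambda v: v <= 1.0 - rules.numerical_majority_delta),
        (STATUS_GAIN, lambda v: v > 1.0, lambda v: v >= 1.0 + rules.numerical_majority_delta),
    ):
        if (
            arm_frac(p, side) >= rules.numerical_arm_fraction
            and arm_frac(q, side) >= rules.numerical_arm_fraction
            and sum(1 for d in both if dev(d.dq_mean)) / len(both) > rules.numerical_majority_fraction
        ):
            return RegionCall(
                sample_id, region, status, SCOPE_WHOLE_CHROMOSOME,
                f"numerical_{status}",
                tuple(d.amplicon_id for d in both if dev(d.dq_mean)),
            )
    return RegionCall(sample_id, region, STATUS_NORMAL, SCOPE_WHOLE_CHROMOSOME, "no_rule")


def score_mycn(dqs: Sequence[DosageQuotient], rules: RuleSet) -> str:
    """MYCN status: amplified when all required MYCN loci reach DQ >= 1 + mycn_delta.

    Fewer numeric loci than the rule set requires -> no_data.
    """
    numeric = _numeric(dqs)
    if len(numeric) < rules.mycn_required_loci:
        return STATUS_NO_DATA
    threshold = 1.0 + rules.mycn_delta
    if all(d.dq_mean >= threshold for d in numeric):
        return STATUS_AMPLIFIED
    return STATUS_NORMAL


def classify_sample(
    profiles: Mapping[str, Sequence[DosageQuotient]],
    panels: Mapping[str, PanelDefinition],
    rules: RuleSet,
    *,
    sample_id: str = "",
    segmental_regions: Iterable[str] | None = None,
) -> SampleClassification:
    """Combine per-kit DQ profiles into region calls and a sample category.

    ``profiles`` maps kit id -> DQ profile from :func:`~ampliquant.dosage.dq_profile`
    (DQs are never pooled across kits before scoring; each chromosome lives in
    exactly one kit). Segmental scoring runs on every arm region (all target
    region labels except the MYCN core, or the subset in ``segmental_regions``);
    any segmental loss/gain sets the category and suppresses whole-chromosome
    evaluation. MYCN amplification is scored independently of the category.
    When MYCN is amplified its loci are excluded from chromosome-2 numerical
    scoring, where they would trivially mimic a whole-chromosome gain.
    """
    # index DQs by amplicon id, remember per-kit metadata
    dq_by_amp: dict[str, DosageQuotient] = {}
    amp_meta = {}
    for kit_id, profile in profiles.items():
        panel = panels[kit_id]
        by_id = panel.by_id
        for d in profile:
            dq_by_amp[d.amplicon_id] = d
            amp_meta[d.amplicon_id] = by_id[d.amplicon_id]

    def region_dqs(region: str) -> list[DosageQuotient]:
        amps = sorted(
            (a for a in amp_meta.values() if a.region == region),
            key=lambda a: (_chrom_key(a.chromosome), a.position),
        )
        return [dq_by_amp[a.id] for a in amps]

    all_regions = []
    for a in sorted(amp_meta.values(), key=lambda a: (_chrom_key(a.chromosome), a.position)):
        if a.role == "target" and a.region not in all_regions:
            all_regions.append(a.region)
    seg_regions = [r for r in all_regions if r != MYCN_REGION]
    if segmental_regions is not None:
        wanted = list(segmental_regions)
        seg_regions = [r for r in seg_regions if r in wanted]

    calls: list[RegionCall] = [
        score_segmental(region_dqs(r), rules, region=r, sample_id=sample_id) for r in seg_regions
    ]
    has_segmental = any(c.status in (STATUS_LOSS, STATUS_GAIN) for c in calls)

    mycn_dqs = region_dqs(MYCN_REGION)
    mycn_status = score_mycn(mycn_dqs, rules) if mycn_dqs else STATUS_NO_DATA
    if mycn_dqs:
        calls.append(
            RegionCall(
                sample_id, MYCN_REGION, mycn_status, SCOPE_SEGMENTAL,
                "mycn_all_loci" if mycn_status == STATUS_AMPLIFIED else "no_rule",
                tuple(d.amplicon_id for d in _numeric(mycn_dqs)) if mycn_status == STATUS_AMPLIFIED else (),
            )
        )

    has_numerical = False
    if not has_segmental:
        chromosomes = sorted({a.chromosome for a in amp_meta.values() if a.role == "target"}, key=_chrom_key)
        for chrom in chromosomes:
            amps = [a for a in amp_meta.values() if a.role == "target" and a.chromosome == chrom]
            if mycn_status == STATUS_AMPLIFIED:
                amps = [a for a in amps if a.region != MYCN_REGION]
            p = sorted((a for a in amps if a.arm == "p"), key=lambda a: a.position)
            q = sorted((a for a in amps if a.arm == "q"), key=lambda a: a.position)
            call = score_whole_chromosome(
                [dq_by_amp[a.id] for a in p],
                [dq_by_amp[a.id] for a in q],
                rules,
                region=f"chr{chrom}",
                sample_id=sample_id,
            )
            calls.append(call)
            if call.status in (STATUS_LOSS, STATUS_GAIN):
                has_numerical = True

    if has_segmental:
        category = CATEGORY_SEGMENTAL
    elif has_numerical:
        category = CATEGORY_NUMERICAL
    else:
        category = CATEGORY_NONE
        if all(c.status == STATUS_NO_DATA for c in calls):
            logger.warning("sample %s: no region evaluable", sample_id)

    mycn_amplified: bool | None
    if mycn_status == STATUS_NO_DATA:
        mycn_amplified = None
    else:
        mycn_amplified = mycn_status == STATUS_AMPLIFIED

    return SampleClassification(sample_id, category, mycn_amplified, tuple(calls))


def write_calls(calls: Iterable[RegionCall], path: str | Path, header_comment: str | None = None) -> None:
    """Export region calls as TSV (supporting loci comma-joined)."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("sample_id\tregion\tscope\tstatus\trule_fired\tsupporting_loci\n")
        for c in calls:
            fh.write(
                f"{c.sample_id}\t{c.region}\t{c.scope}\t{c.status}\t{c.rule_fired}\t"
                f"{','.join(c.supporting_loci)}\n"
            )


def read_calls(path: str | Path) -> list[RegionCall]:
    import csv

    calls: list[RegionCall] = []
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t") if r and not r[0].startswith("#")]
    if not rows:
        return calls
    header = rows[0]
    idx = {name: header.index(name) for name in ("sample_id", "region", "scope", "status", "rule_fired", "supporting_loci")}
    for row in rows[1:]:
        loci = tuple(x for x in row[idx["supporting_loci"]].split(",") if x)
        calls.append(
            RegionCall(
                row[idx["sample_id"]], row[idx["region"]], row[idx["status"]],
                row[idx["scope"]], row[idx["rule_fired"]], loci,
            )
        )
    return calls
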