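"""Thin orchestration: peak tables -> DQ profiles -> region calls per sample."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .dosage import DosageQuotient, dq_profile
from .errors import ConfigurationError
from .panel import PanelDefinition
from .peaks import KIND_CONTROL, KIND_TUMOR, SampleRun
from .scoring import RegionCall, RuleSet, SampleClassification, classify_sample


@dataclass(frozen=True)
class CallResult:
    profiles: Mapping[str, Mapping[str, tuple[DosageQuotient, ...]]]  # sample -> kit -> profile
    classifications: tuple[SampleClassification, ...]

    @property
    def calls(self) -> list[RegionCall]:
        return [c for cls in self.classifications for c in cls.region_calls]


def call_samples(
    panels: Mapping[str, PanelDefinition],
    runs: Mapping[str, Sequence[SampleRun]],
    rules: RuleSet,
) -> CallResult:
    """Analyze every tumor run against the control runs of its kit.

    ``runs`` maps kit id -> SampleRun collection (tumors and controls mixed;
    the ``kind`` attribute separates them). DQs are computed per kit and never
    pooled across kits before scoring.
    """
    missing = [k for k in runs if k not in panels]
    if missing:
        raise ConfigurationError(f"no panel supplied for kit(s): {', '.join(missing)}")

    controls = {kit: [r for r in kit_runs if r.kind == KIND_CONTROL] for kit, kit_runs in runs.items()}
    for kit, ctrls in controls.items():
        if not ctrls:
            raise ConfigurationError(f"kit {kit}: no control samples in the run")

    tumor_ids: list[str] = []
    for kit_runs in runs.values():
        for r in kit_runs:
            if r.kind == KIND_TUMOR and r.sample_id not in tumor_ids:
                tumor_ids.append(r.sample_id)

    profiles: dict[str, dict[str, tuple[DosageQuotient, ...]]] = {}
    classifications: list[SampleClassification] = []
    for sample_id in tumor_ids:
        sample_profiles: dict[str, tuple[DosageQuotient, ...]] = {}
        for kit, kit_runs in runs.items():
            run = next((r for r in kit_runs if r.sample_id == sample_id and r.kind == KIND_TUMOR), None)
            if run is None:
                continue
            sample_profiles[kit] = tuple(dq_profile(run, controls[kit], panels[kit]))
        profiles[sample_id] = sample_profiles
        classifications.append(
            classify_sample(sample_profiles, panels, rules, sample_id=sample_id)
        )
    return CallResult(profiles=profiles, classifications=tuple(classifications))
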