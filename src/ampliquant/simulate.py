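"""Synthetic fragment-data cohorts for end-to-end testing of the caller.

The generator emulates the copy-number structure of neuroblastoma genomes:

* *Segmental* tumors — a diploid (or near-triploid) background carrying one
  or more single-copy arm-level losses (1p, 3p, 11q) and/or a 17q gain,
  optionally with high-level MYCN amplification.
* *Numerical* tumors — near-triploid genomes made of whole-chromosome
  changes. Crucially, the reference chromosomes are co-aberrant: they sit at
  the same modal ploidy as the rest of the genome, so the dosage-quotient
  double ratio cancels the shared ploidy and the profile collapses to DQ~1.
  This reproduces the normalization confound that makes whole-chromosome
  changes hard for ratio-based assays while leaving segmental calls clean.

Peak areas are proportional to locus copy number over the diploid baseline,
scaled by a fixed per-amplicon efficiency (constant across samples, so it
cancels in the DQ) and multiplied by lognormal noise:

    area = baseline * efficiency(amplicon) * (copies / 2) * exp(N(0, sigma^2))

Multiplicative noise is the natural choice for fluorescence peak areas:
they are positive and their error scales with signal. The default sigma of
0.05 keeps the simulated DQ scatter within the repeatability coefficient
(~0.1) a well-run capillary assay achieves.

The gold-standard table is derived from the simulated truth (the event list),
never from caller output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import __version__
from .errors import ConfigurationError
from .evaluation import GOLD_NEGATIVE, GOLD_POSITIVE, GoldStandardTable, write_gold_table
from .panel import MYCN_REGION, PanelDefinition, builtin_nb_panels
from .peaks import KIND_CONTROL, KIND_TUMOR, PeakRecord, SampleRun, write_peak_table, write_sample_sheet

SCOPE_SEGMENTAL = "segmental"
SCOPE_NUMERICAL = "numerical"

#: The five scored prognostic regions and the direction of their expected event.
SEGMENTAL_EVENT_MENU = {"1p": -1, "3p": -1, "11q": -1, "17q": +1}


@dataclass(frozen=True)
class CopyNumberEvent:
    """A copy change on an arm region (segmental) or a whole chromosome (numerical)."""

    target: str          # region label ("1p") or chromosome ("17")
    change: int          # signed copies added to the background
    scope: str = SCOPE_SEGMENTAL


@dataclass(frozen=True)
class SimulatedGenome:
    sample_id: str
    background_ploidy: int = 2
    events: tuple[CopyNumberEvent, ...] = ()
    mycn_copies: int | None = None
    reference_aberrations: Mapping[str, int] = field(default_factory=dict)  # chromosome -> copies


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal noise plus fixed per-amplicon efficiencies."""

    sigma: float = 0.05
    efficiencies: Mapping[str, float] | None = None  # amplicon id -> factor; None = 1.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ConfigurationError("sigma must be >= 0")
        if self.efficiencies is not None and any(e <= 0 for e in self.efficiencies.values()):
            raise ConfigurationError("amplicon efficiencies must be > 0")

    def efficiency(self, amplicon_id: str) -> float:
        if self.efficiencies is None:
            return 1.0
        return self.efficiencies.get(amplicon_id, 1.0)


def draw_efficiencies(
    panels: Mapping[str, PanelDefinition], rng: np.random.Generator, spread: float = 0.3
) -> dict[str, float]:
    """Lognormal per-amplicon efficiency factors, fixed for a whole run."""
    effs: dict[str, float] = {}
    for panel in panels.values():
        for amp in panel.amplicons:
            effs[amp.id] = float(np.exp(rng.normal(0.0, spread)))
    return effs


def simulate_copy_numbers(
    genome: SimulatedGenome, panels: Mapping[str, PanelDefinition]
) -> dict[str, int]:
    """Integer copy number of every panel amplicon implied by a genome spec.

    Background ploidy everywhere; events applied additively (segmental events
    by region label, numerical events to every amplicon of the chromosome,
    references included); MYCN loci then set to ``mycn_copies``; explicit
    reference overrides applied last.
    """
    copies: dict[str, int] = {}
    region_events = {e.target: e for e in genome.events if e.scope == SCOPE_SEGMENTAL}
    chrom_events = {e.target: e for e in genome.events if e.scope == SCOPE_NUMERICAL}
    known_regions = {a.region for p in panels.values() for a in p.amplicons}
    known_chroms = {a.chromosome for p in panels.values() for a in p.amplicons}
    for e in genome.events:
        if e.scope == SCOPE_SEGMENTAL and e.target not in known_regions:
            raise ConfigurationError(f"segmental event targets unknown region {e.target!r}")
        if e.scope == SCOPE_NUMERICAL and e.target not in known_chroms:
            raise ConfigurationError(f"numerical event targets unknown chromosome {e.target!r}")
    for panel in panels.values():
        for amp in panel.amplicons:
            c = genome.background_ploidy
            if amp.chromosome in chrom_events:
                c += chrom_events[amp.chromosome].change
            if amp.region in region_events:
                c += region_events[amp.region].change
            if genome.mycn_copies is not None and amp.region == MYCN_REGION:
                c = genome.mycn_copies
            if amp.role == "reference" and amp.chromosome in genome.reference_aberrations:
                c = genome.reference_aberrations[amp.chromosome]
            if c < 0:
                raise ConfigurationError(
                    f"genome {genome.sample_id}: amplicon {amp.id} ends at negative copy number"
                )
            copies[amp.id] = c
    return copies


def simulate_peaks(
    copies: Mapping[str, int],
    noise: NoiseModel,
    rng: np.random.Generator,
    *,
    sample_id: str,
    kind: str = KIND_TUMOR,
    baseline_area: float = 10_000.0,
) -> SampleRun:
    """Draw one sample's peak areas from its per-amplicon copy numbers."""
    if baseline_area <= 0:
        raise ConfigurationError("baseline_area must be > 0")
    areas: dict[str, float] = {}
    for amp_id in copies:
        factor = 1.0 if noise.sigma == 0 else float(np.exp(rng.normal(0.0, noise.sigma)))
        area = baseline_area * noise.efficiency(amp_id) * (copies[amp_id] / 2.0) * factor
        if area > 0:
            areas[amp_id] = area
        # zero copies -> no amplification product -> absent peak
    return SampleRun(sample_id=sample_id, kind=kind, areas=areas)


@dataclass(frozen=True)
class CohortSpec:
    """Composition of a simulated validation cohort.

    Defaults mirror the structure of the assay's validation series: 35
    segmental samples (15 of them on a near-triploid numerical background),
    17 numerical-only near-triploid samples, 22 of the segmental samples
    MYCN-amplified, two diploid control samples per experiment.
    """

    n_segmental: int = 35
    n_numerical: int = 17
    n_triploid_background: int = 15
    n_mycn_amplified: int = 22
    n_controls: int = 2
    sigma: float = 0.05
    baseline_area: float = 10_000.0
    efficiency_spread: float = 0.3
    event_probabilities: Mapping[str, float] = field(
        default_factory=lambda: {"1p": 0.5, "3p": 0.35, "11q": 0.45, "17q": 0.7}
    )
    mycn_copies_range: tuple[int, int] = (15, 40)

    def __post_init__(self) -> None:
        if min(self.n_segmental, self.n_numerical, self.n_controls) < 0:
            raise ConfigurationError("cohort counts must be >= 0")
        if self.n_triploid_background > self.n_segmental:
            raise ConfigurationError("n_triploid_background cannot exceed n_segmental")
        if self.n_mycn_amplified > self.n_segmental:
            raise ConfigurationError("n_mycn_amplified cannot exceed n_segmental")


@dataclass(frozen=True)
class Cohort:
    """A fully simulated cohort: truth, measurements, and derived gold standard."""

    spec: CohortSpec
    seed: int
    genomes: tuple[SimulatedGenome, ...]
    runs: Mapping[str, tuple[SampleRun, ...]]  # kit id -> runs (tumors then controls)
    sample_kinds: Mapping[str, str]
    gold: GoldStandardTable


def _draw_segmental_genome(
    sample_id: str,
    rng: np.random.Generator,
    spec: CohortSpec,
    triploid: bool,
    mycn: bool,
) -> SimulatedGenome:
    menu = list(SEGMENTAL_EVENT_MENU.items())
    while True:
        events = tuple(
            CopyNumberEvent(region, change, SCOPE_SEGMENTAL)
            for region, change in menu
            if rng.random() < spec.event_probabilities.get(region, 0.0)
        )
        if events:
            break
    mycn_copies = int(rng.integers(*spec.mycn_copies_range)) if mycn else None
    return SimulatedGenome(
        sample_id=sample_id,
        background_ploidy=3 if triploid else 2,
        events=events,
        mycn_copies=mycn_copies,
    )


def simulate_cohort(
    spec: CohortSpec | None = None,
    panels: Mapping[str, PanelDefinition] | None = None,
    seed: int = 0,
) -> Cohort:
    """Generate a reproducible cohort of tumor and control runs for every kit.

    Numerical-only samples are uniformly near-triploid with co-aberrant
    reference chromosomes (see module docstring): their DQ profiles are
    centred on 1 and their gold entries, which record deviations from the
    modal ploidy, are negative — the masking regime of ratio normalization.
    """
    spec = spec or CohortSpec()
    panels = panels or builtin_nb_panels()
    rng = np.random.default_rng(seed)
    effs = draw_efficiencies(panels, rng, spec.efficiency_spread)
    noise = NoiseModel(sigma=spec.sigma, efficiencies=effs)

    genomes: list[SimulatedGenome] = []
    triploid_flags = np.zeros(spec.n_segmental, dtype=bool)
    triploid_flags[: spec.n_triploid_background] = True
    rng.shuffle(triploid_flags)
    mycn_flags = np.zeros(spec.n_segmental, dtype=bool)
    mycn_flags[: spec.n_mycn_amplified] = True
    rng.shuffle(mycn_flags)
    for i in range(spec.n_segmental):
        genomes.append(
            _draw_segmental_genome(
                f"SEG-{i + 1:02d}", rng, spec, bool(triploid_flags[i]), bool(mycn_flags[i])
            )
        )
    for i in range(spec.n_numerical):
        genomes.append(
            SimulatedGenome(sample_id=f"NUM-{i + 1:02d}", background_ploidy=3, events=())
        )

    chromosomes = sorted({a.chromosome for p in panels.values() for a in p.targets})
    gold_entries: dict[tuple[str, str], str] = {}
    for g in genomes:
        event_regions = {e.target for e in g.events if e.scope == SCOPE_SEGMENTAL}
        for region in SEGMENTAL_EVENT_MENU:
            gold_entries[(g.sample_id, region)] = (
                GOLD_POSITIVE if region in event_regions else GOLD_NEGATIVE
            )
        gold_entries[(g.sample_id, MYCN_REGION)] = (
            GOLD_POSITIVE if g.mycn_copies is not None else GOLD_NEGATIVE
        )
        if g.sample_id.startswith("NUM-"):
            event_chroms = {e.target for e in g.events if e.scope == SCOPE_NUMERICAL}
            for chrom in chromosomes:
                gold_entries[(g.sample_id, f"chr{chrom}")] = (
                    GOLD_POSITIVE if chrom in event_chroms else GOLD_NEGATIVE
                )
    gold = GoldStandardTable(gold_entries, provenance="simulated truth (event list)")

    runs: dict[str, list[SampleRun]] = {p: [] for p in panels}
    sample_kinds: dict[str, str] = {}
    for g in genomes:
        copies = simulate_copy_numbers(g, panels)
        sample_kinds[g.sample_id] = KIND_TUMOR
        for kit_id, panel in panels.items():
            kit_copies = {a.id: copies[a.id] for a in panel.amplicons}
            runs[kit_id].append(
                simulate_peaks(
                    kit_copies, noise, rng,
                    sample_id=g.sample_id, kind=KIND_TUMOR, baseline_area=spec.baseline_area,
                )
            )
    for i in range(spec.n_controls):
        ctrl_id = f"CTRL-{i + 1:02d}"
        sample_kinds[ctrl_id] = KIND_CONTROL
        for kit_id, panel in panels.items():
            copies = {a.id: 2 for a in panel.amplicons}
            runs[kit_id].append(
                simulate_peaks(
                    copies, noise, rng,
                    sample_id=ctrl_id, kind=KIND_CONTROL, baseline_area=spec.baseline_area,
                )
            )

    return Cohort(
        spec=spec,
        seed=seed,
        genomes=tuple(genomes),
        runs={k: tuple(v) for k, v in runs.items()},
        sample_kinds=sample_kinds,
        gold=gold,
    )


def runs_to_peak_records(
    runs: Sequence[SampleRun], panel: PanelDefinition, rng: np.random.Generator | None = None,
    size_jitter: float = 0.1,
) -> list[PeakRecord]:
    """Flatten sample runs into sized peaks, with optional sub-bp size jitter."""
    records: list[PeakRecord] = []
    by_id = panel.by_id
    for run in runs:
        for amp_id, area in run.areas.items():
            size = by_id[amp_id].expected_length
            if rng is not None and size_jitter > 0:
                size += float(rng.uniform(-size_jitter, size_jitter))
            records.append(PeakRecord(run.sample_id, size, area))
    return records


def write_cohort(
    cohort: Cohort, panels: Mapping[str, PanelDefinition], outdir: str | Path
) -> dict[str, Path]:
    """Emit peak tables (one per kit), sample sheet, gold standard, and manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    jitter_rng = np.random.default_rng(cohort.seed + 1)
    paths: dict[str, Path] = {}
    comment = f"ampliquant {__version__} simulated cohort, seed={cohort.seed}"
    for kit_id, panel in panels.items():
        records = runs_to_peak_records(cohort.runs[kit_id], panel, jitter_rng)
        path = outdir / f"peaks_{kit_id}.tsv"
        write_peak_table(records, path, header_comment=comment)
        paths[f"peaks_{kit_id}"] = path
    sheet = outdir / "samples.tsv"
    write_sample_sheet(cohort.sample_kinds, sheet)
    paths["samples"] = sheet
    gold_path = outdir / "gold_standard.tsv"
    write_gold_table(cohort.gold, gold_path)
    paths["gold"] = gold_path
    manifest = outdir / "manifest.yaml"
    with open(manifest, "w") as fh:
        yaml.safe_dump(
            {
                "tool": "ampliquant",
                "version": __version__,
                "seed": cohort.seed,
                "spec": _spec_dict(cohort.spec),
                "kits": list(panels),
            },
            fh,
            sort_keys=False,
        )
    paths["manifest"] = manifest
    return paths


def _spec_dict(spec: CohortSpec) -> dict:
    d = asdict(spec)
    d["event_probabilities"] = dict(d["event_probabilities"])
    d["mycn_copies_range"] = list(d["mycn_copies_range"])
    return d


def load_cohort_spec(path: str | Path) -> CohortSpec:
    """Read a cohort composition YAML (keys matching CohortSpec fields)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "mycn_copies_range" in data:
        data["mycn_copies_range"] = tuple(data["mycn_copies_range"])
    try:
        return CohortSpec(**data)
    except TypeError as exc:
        raise ConfigurationError(f"cohort spec {path}: {exc}") from exc
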