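"""Multiplex amplicon panel definitions.

A panel (one PCR "kit") is an ordered set of amplicons, each a single
primer-pair locus of unique designed fragment length. Amplicons are either
*targets*, placed in chromosomal regions whose copy number the assay
interrogates, or *references*, placed in regions rarely altered in the tumor
type, which serve as the normalization denominator of the dosage quotient.

Coordinates are 1-based point positions: an amplicon is a point probe, not an
interval, and only ordering and arm membership matter for scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import PanelFormatError, PanelValidationError, RegionNotFoundError

ARMS = ("p", "q")
ROLE_TARGET = "target"
ROLE_REFERENCE = "reference"

#: Region label of the amplicons sitting in the MYCN amplicon core on 2p.
MYCN_REGION = "MYCN"

PANEL_COLUMNS = [
    "id",
    "chromosome",
    "arm",
    "position",
    "expected_length",
    "role",
    "region",
]


def _chrom_key(chromosome: str) -> tuple[int, str]:
    """Natural sort key: numeric chromosomes first, then X/Y/other lexically."""
    try:
        return (int(chromosome), "")
    except ValueError:
        return (1000, chromosome)


@dataclass(frozen=True)
class Amplicon:
    """One primer-pair locus of a multiplex kit.

    ``region`` groups target amplicons into scoreable units: the arm label
    ("1p", "17q", ...) for ordinary targets and references, or ``"MYCN"`` for
    the amplicons inside the MYCN core region on 2p.
    """

    id: str
    chromosome: str
    arm: str
    position: int
    expected_length: float
    role: str
    region: str

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise PanelValidationError(f"amplicon {self.id}: arm must be 'p' or 'q', got {self.arm!r}")
        if self.position <= 0:
            raise PanelValidationError(f"amplicon {self.id}: position must be > 0")
        if self.expected_length <= 0:
            raise PanelValidationError(f"amplicon {self.id}: expected_length must be > 0")
        if self.role not in (ROLE_TARGET, ROLE_REFERENCE):
            raise PanelValidationError(f"amplicon {self.id}: role must be target|reference, got {self.role!r}")
        if not self.region:
            raise PanelValidationError(f"amplicon {self.id}: region label must be non-empty")
        if self.role == ROLE_REFERENCE and self.region != f"{self.chromosome}{self.arm}":
            raise PanelValidationError(
                f"amplicon {self.id}: reference amplicons must carry their arm label "
                f"as region ({self.chromosome}{self.arm}), got {self.region!r}"
            )

    @property
    def arm_label(self) -> str:
        return f"{self.chromosome}{self.arm}"


@dataclass(frozen=True)
class RegionOfInterest:
    """A named scoreable region: an arm-level locus set or the MYCN locus set."""

    name: str
    chromosome: str
    arm: str
    kind: str = "segmental_locus_set"  # or "mycn_locus_set"


@dataclass(frozen=True)
class PanelDefinition:
    """A validated multiplex kit: unique fragment lengths, >=1 target, >=1 reference."""

    kit_id: str
    amplicons: tuple[Amplicon, ...]
    length_tolerance: float = 0.5

    def __post_init__(self) -> None:
        if self.length_tolerance < 0:
            raise PanelValidationError("length_tolerance must be non-negative")
        lengths: dict[float, str] = {}
        for amp in self.amplicons:
            if amp.expected_length in lengths:
                raise PanelValidationError(
                    f"panel {self.kit_id}: amplicons {lengths[amp.expected_length]!r} and "
                    f"{amp.id!r} share expected_length {amp.expected_length}"
                )
            lengths[amp.expected_length] = amp.id
        ids = [a.id for a in self.amplicons]
        if len(set(ids)) != len(ids):
            raise PanelValidationError(f"panel {self.kit_id}: duplicate amplicon ids")
        if not self.targets:
            raise PanelValidationError(f"panel {self.kit_id}: no target amplicons")
        if not self.references:
            raise PanelValidationError(f"panel {self.kit_id}: no reference amplicons")

    @property
    def targets(self) -> tuple[Amplicon, ...]:
        return tuple(a for a in self.amplicons if a.role == ROLE_TARGET)

    @property
    def references(self) -> tuple[Amplicon, ...]:
        return tuple(a for a in self.amplicons if a.role == ROLE_REFERENCE)

    @property
    def by_id(self) -> dict[str, Amplicon]:
        return {a.id: a for a in self.amplicons}

    def targets_sorted(self) -> list[Amplicon]:
        """All targets in deterministic genomic order (chromosome, position)."""
        return sorted(self.targets, key=lambda a: (_chrom_key(a.chromosome), a.position))

    def arm_targets(self, chromosome: str, arm: str) -> list[Amplicon]:
        """Targets on one chromosome arm, ascending position."""
        return sorted(
            (a for a in self.targets if a.chromosome == chromosome and a.arm == arm),
            key=lambda a: a.position,
        )

    def region_targets(self, region: str) -> list[Amplicon]:
        """Targets carrying a given region label, ascending position."""
        amps = sorted(
            (a for a in self.targets if a.region == region),
            key=lambda a: (_chrom_key(a.chromosome), a.position),
        )
        return amps

    def target_regions(self) -> list[str]:
        """Distinct target region labels in genomic order."""
        seen: list[str] = []
        for a in self.targets_sorted():
            if a.region not in seen:
                seen.append(a.region)
        return seen

    def chromosomes(self) -> list[str]:
        """Chromosomes carrying target amplicons, natural order."""
        return sorted({a.chromosome for a in self.targets}, key=_chrom_key)


def resolve_region(panel: PanelDefinition, region: RegionOfInterest | str) -> list[Amplicon]:
    """Target amplicons of a region, position-sorted.

    Accepts either a :class:`RegionOfInterest` or a bare region label.
    Raises :class:`RegionNotFoundError` if the region has no target amplicons
    in this panel.
    """
    name = region.name if isinstance(region, RegionOfInterest) else region
    amps = panel.region_targets(name)
    if not amps:
        raise RegionNotFoundError(f"region {name!r} has no target amplicons in panel {panel.kit_id}")
    return amps


def read_panel(path: str | Path, length_tolerance: float = 0.5, kit_id: str | None = None) -> PanelDefinition:
    """Read a panel TSV (columns: id, chromosome, arm, position, expected_length, role, region)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"chromosome": str, "id": str, "region": str})
    except Exception as exc:  # noqa: BLE001 - surface as a format error
        raise PanelFormatError(f"cannot parse panel file {path}: {exc}") from exc
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise PanelFormatError(f"panel file {path} lacks columns: {', '.join(missing)}")
    amps = []
    for row in df.itertuples(index=False):
        try:
            amps.append(
                Amplicon(
                    id=str(row.id),
                    chromosome=str(row.chromosome),
                    arm=str(row.arm),
                    position=int(row.position),
                    expected_length=float(row.expected_length),
                    role=str(row.role),
                    region=str(row.region),
                )
            )
        except (TypeError, ValueError) as exc:
            raise PanelFormatError(f"panel file {path}, amplicon {row.id!r}: {exc}") from exc
    return PanelDefinition(
        kit_id=kit_id if kit_id is not None else path.stem,
        amplicons=tuple(amps),
        length_tolerance=length_tolerance,
    )


def write_panel(panel: PanelDefinition, path: str | Path) -> None:
    """Write a panel as TSV; round-trips bit-exactly through :func:`read_panel`."""
    df = pd.DataFrame(
        [
            {
                "id": a.id,
                "chromosome": a.chromosome,
                "arm": a.arm,
                "position": a.position,
                "expected_length": a.expected_length,
                "role": a.role,
                "region": a.region,
            }
            for a in panel.amplicons
        ],
        columns=PANEL_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def write_bed(panel: PanelDefinition, path: str | Path) -> None:
    """Export amplicon loci as BED (0-based half-open) for genome-browser use."""
    with open(path, "w") as fh:
        for a in sorted(panel.amplicons, key=lambda a: (_chrom_key(a.chromosome), a.position)):
            fh.write(f"{a.chromosome}\t{a.position - 1}\t{a.position}\t{a.id}\n")


# ---------------------------------------------------------------------------
# Built-in neuroblastoma panels
# ---------------------------------------------------------------------------

_REF_SITES = {
    "5q": (100_000_000, 120_000_000, 140_000_000),
    "13q": (40_000_000, 60_000_000),
    "21q": (20_000_000, 35_000_000),
    "22q": (25_000_000, 40_000_000),
}


def _build_kit(kit_id: str, target_spec: Sequence[tuple[str, str, str, Sequence[int]]],
               n_references: int, length_start: float = 100.0, length_step: float = 4.0) -> PanelDefinition:
    amps: list[Amplicon] = []
    length = length_start
    for chromosome, arm, region, positions in target_spec:
        for i, pos in enumerate(positions, start=1):
            amps.append(
                Amplicon(
                    id=f"{kit_id}-{region}-{i:02d}",
                    chromosome=chromosome,
                    arm=arm,
                    position=pos,
                    expected_length=length,
                    role=ROLE_TARGET,
                    region=region,
                )
            )
            length += length_step
    # References distributed round-robin over the four low-alteration arms
    # (5q, 13q, 21q, 22q); the published kits carry 8 or 9 reference amplicons
    # but their per-arm split is a design assumption here.
    ref_slots = [
        (arm_label, pos)
        for arm_label, positions in _REF_SITES.items()
        for pos in positions
    ]
    counts: dict[str, int] = {}
    for arm_label, pos in ref_slots[:n_references]:
        chromosome, arm = arm_label[:-1], arm_label[-1]
        counts[arm_label] = counts.get(arm_label, 0) + 1
        amps.append(
            Amplicon(
                id=f"{kit_id}-REF-{arm_label}-{counts[arm_label]:02d}",
                chromosome=chromosome,
                arm=arm,
                position=pos,
                expected_length=length,
                role=ROLE_REFERENCE,
                region=arm_label,
            )
        )
        length += length_step
    return PanelDefinition(kit_id=kit_id, amplicons=tuple(amps))


def builtin_nb_panels() -> dict[str, PanelDefinition]:
    """Three bundled neuroblastoma kits mirroring the published assay structure.

    * ``NB-MAQ1`` — 21 targets on chromosomes 3 and 17 (both arms), 9 references.
    * ``NB-MAQ2`` — 19 targets on chromosomes 1 and 11 (both arms), 9 references.
    * ``NB-MAQ3`` — 9 targets on chromosome 2 (3 MYCN-core loci plus flanking 2p
      and opposite-arm 2q loci), 8 references. MYCN sits in its own kit because
      high-level amplification swamps co-amplified targets in a multiplex PCR.

    Coordinates are synthetic but plausible: only ordering and arm membership
    carry meaning downstream.
    """
    mb = 1_000_000
    kit1 = _build_kit(
        "NB-MAQ1",
        [
            ("3", "p", "3p", [10 * mb, 25 * mb, 40 * mb, 55 * mb, 70 * mb, 85 * mb]),
            ("3", "q", "3q", [100 * mb, 120 * mb, 140 * mb, 160 * mb, 190 * mb]),
            ("17", "p", "17p", [3 * mb, 8 * mb, 14 * mb, 20 * mb]),
            ("17", "q", "17q", [28 * mb, 35 * mb, 45 * mb, 55 * mb, 65 * mb, 75 * mb]),
        ],
        n_references=9,
    )
    kit2 = _build_kit(
        "NB-MAQ2",
        [
            ("1", "p", "1p", [2 * mb, 8 * mb, 15 * mb, 25 * mb, 35 * mb, 50 * mb]),
            ("1", "q", "1q", [150 * mb, 170 * mb, 200 * mb, 230 * mb]),
            ("11", "p", "11p", [5 * mb, 15 * mb, 25 * mb, 40 * mb]),
            ("11", "q", "11q", [60 * mb, 75 * mb, 90 * mb, 105 * mb, 120 * mb]),
        ],
        n_references=9,
    )
    kit3 = _build_kit(
        "NB-MAQ3",
        [
            ("2", "p", MYCN_REGION, [15_900_000, 16_000_000, 16_100_000]),
            ("2", "p", "2p", [30 * mb, 50 * mb]),
            ("2", "q", "2q", [100 * mb, 130 * mb, 160 * mb, 190 * mb]),
        ],
        n_references=8,
    )
    return {p.kit_id: p for p in (kit1, kit2, kit3)}


def nb_regions_of_interest() -> list[RegionOfInterest]:
    """The five prognostically relevant neuroblastoma regions."""
    return [
        RegionOfInterest("1p", "1", "p"),
        RegionOfInterest(MYCN_REGION, "2", "p", kind="mycn_locus_set"),
        RegionOfInterest("3p", "3", "p"),
        RegionOfInterest("11q", "11", "q"),
        RegionOfInterest("17q", "17", "q"),
    ]
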