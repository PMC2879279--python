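"""Fragment-analysis peak tables and length-keyed peak-to-amplicon matching.

The assay is demultiplexed purely by fragment length: every amplicon in a kit
has a unique designed length, so a sized peak is attributed to the amplicon
whose expected length is nearest, within the panel's length tolerance.

Missing amplicons are represented as *absent* entries in a sample's area map,
never as zero areas — a zero would silently corrupt downstream dosage ratios,
whereas an absent entry propagates as "no data".
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

from .errors import PeakTableError
from .panel import PanelDefinition

if TYPE_CHECKING:  # pragma: no cover
    from .dosage import DosageQuotient

logger = logging.getLogger(__name__)

KIND_TUMOR = "tumor"
KIND_CONTROL = "control"


@dataclass(frozen=True)
class PeakRecord:
    """One sized fluorescence peak from capillary electrophoresis."""

    sample_id: str
    fragment_size: float
    peak_area: float

    def __post_init__(self) -> None:
        if self.fragment_size <= 0:
            raise PeakTableError(f"sample {self.sample_id}: fragment_size must be > 0")
        if self.peak_area < 0:
            raise PeakTableError(f"sample {self.sample_id}: peak_area must be >= 0")


@dataclass
class SampleRun:
    """Per-sample map of amplicon id -> peak area for one kit.

    ``areas`` may lack entries for amplicons that failed to amplify.
    """

    sample_id: str
    kind: str = KIND_TUMOR
    areas: dict[str, float] = field(default_factory=dict)


def read_peak_table(path: str | Path) -> list[PeakRecord]:
    """Parse a tab-delimited peak table (sample_id, fragment_size, peak_area).

    Malformed rows raise :class:`PeakTableError` naming the offending row;
    an empty table is returned as an empty list with a warning.
    """
    path = Path(path)
    records: list[PeakRecord] = []
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t") if r and not r[0].startswith("#")]
    if not rows:
        logger.warning("peak table %s is empty", path)
        return records
    header = rows[0]
    required = ["sample_id", "fragment_size", "peak_area"]
    if [c.strip() for c in header[:3]] != required:
        raise PeakTableError(f"{path}: header must start with {required}, got {header[:3]}")
    for lineno, row in enumerate(rows[1:], start=2):
        try:
            records.append(
                PeakRecord(
                    sample_id=row[0],
                    fragment_size=float(row[1]),
                    peak_area=float(row[2]),
                )
            )
        except (IndexError, ValueError, PeakTableError) as exc:
            raise PeakTableError(f"{path}, row {lineno}: {exc}") from exc
    if not records:
        logger.warning("peak table %s contains a header but no data rows", path)
    return records


def write_peak_table(records: Iterable[PeakRecord], path: str | Path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("sample_id\tfragment_size\tpeak_area\n")
        for rec in records:
            fh.write(f"{rec.sample_id}\t{rec.fragment_size!r}\t{rec.peak_area!r}\n")


def read_sample_sheet(path: str | Path) -> dict[str, str]:
    """Parse a sample sheet TSV (sample_id, kind) into a mapping."""
    path = Path(path)
    kinds: dict[str, str] = {}
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t") if r and not r[0].startswith("#")]
    if not rows or [c.strip() for c in rows[0][:2]] != ["sample_id", "kind"]:
        raise PeakTableError(f"{path}: sample sheet must have header sample_id<TAB>kind")
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) < 2 or row[1] not in (KIND_TUMOR, KIND_CONTROL):
            raise PeakTableError(f"{path}, row {lineno}: kind must be tumor|control")
        kinds[row[0]] = row[1]
    return kinds


def write_sample_sheet(kinds: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tkind\n")
        for sample_id, kind in kinds.items():
            fh.write(f"{sample_id}\t{kind}\n")


def match_peaks(
    records: Iterable[PeakRecord],
    panel: PanelDefinition,
    kinds: Mapping[str, str] | None = None,
) -> list[SampleRun]:
    """Assign peaks to panel amplicons by nearest expected fragment length.

    A peak is assigned to the amplicon whose expected length is closest to the
    observed size, provided the gap is within ``panel.length_tolerance``;
    otherwise it is logged and dropped. When two peaks of one sample hit the
    same amplicon, the larger area wins (the dominant peak is the amplicon
    product; minor peaks are stutter) and a warning is logged.

    ``kinds`` optionally maps sample ids to tumor/control; unmapped samples
    default to tumor. Runs are returned in first-seen sample order.
    """
    amps = sorted(panel.amplicons, key=lambda a: a.expected_length)
    runs: dict[str, SampleRun] = {}
    n_dropped = 0
    for rec in records:
        # nearest expected length by linear scan over the (small) sorted panel
        best = min(amps, key=lambda a: abs(a.expected_length - rec.fragment_size))
        if abs(best.expected_length - rec.fragment_size) > panel.length_tolerance:
            n_dropped += 1
            logger.info(
                "dropping peak %s@%.2fbp: nearest amplicon %s (%.2fbp) outside tolerance %.2f",
                rec.sample_id, rec.fragment_size, best.id, best.expected_length, panel.length_tolerance,
            )
            continue
        run = runs.setdefault(
            rec.sample_id,
            SampleRun(sample_id=rec.sample_id, kind=(kinds or {}).get(rec.sample_id, KIND_TUMOR)),
        )
        if best.id in run.areas:
            logger.warning(
                "sample %s: two peaks matched amplicon %s; keeping the larger area",
                rec.sample_id, best.id,
            )
            run.areas[best.id] = max(run.areas[best.id], rec.peak_area)
        else:
            run.areas[best.id] = rec.peak_area
    if n_dropped:
        logger.info("match_peaks: %d peak(s) dropped as unassignable", n_dropped)
    return list(runs.values())


def write_dq_table(
    dqs: Iterable["DosageQuotient"],
    panel: PanelDefinition,
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Write dosage quotients as TSV, rows ordered by sample then genomic position."""
    by_id = panel.by_id
    order = {a.id: i for i, a in enumerate(panel.targets_sorted())}
    rows = sorted(dqs, key=lambda d: (d.sample_id, order.get(d.amplicon_id, len(order))))
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("sample_id\tamplicon_id\tregion\tdq_mean\tdq_sd\tn_combinations\n")
        for d in rows:
            region = by_id[d.amplicon_id].region if d.amplicon_id in by_id else ""
            mean = "NA" if d.is_no_data else f"{d.dq_mean:.6g}"
            sd = "NA" if d.is_no_data else f"{d.dq_sd:.6g}"
            fh.write(f"{d.sample_id}\t{d.amplicon_id}\t{region}\t{mean}\t{sd}\t{d.n_combinations}\n")
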