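"""Plate-level assay records, CSV I/O, and the raw score transforms.

The unit of observation is one assay plate of (nominally 10) worms.  Exit
assays (multisensory foraging-risk, unisensory osmotic avoidance) record how
many worms remain inside an aversive fructose ring after 15 min; chemotaxis
assays record how many worms reached the odor spot versus the control spot.
Scores — percent exiting and chemotaxis index — are always computed on demand
from the counts, never stored, so the counts stay the single source of truth.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "Assay",
    "Score",
    "PlateRecord",
    "GroupKey",
    "GroupSample",
    "ExperimentTable",
    "PlateValidationError",
    "percent_exiting",
    "chemotaxis_index",
    "read_plates",
    "write_plates",
    "group_samples",
]


class PlateValidationError(ValueError):
    """A plate record (or CSV row) violates the assay-data invariants."""


class Condition(str, enum.Enum):
    FED = "fed"
    FOOD_DEPRIVED = "food_deprived"


class Assay(str, enum.Enum):
    MULTISENSORY = "multisensory"
    OSMOTIC_ONLY = "osmotic_only"
    CHEMOTAXIS = "chemotaxis"


class Score(str, enum.Enum):
    PERCENT_EXITING = "percent_exiting"
    CHEMOTAXIS_INDEX = "chemotaxis_index"


def percent_exiting(worms_remaining: int, worms_placed: int) -> float:
    """Percent of placed worms that exited the ring.

    ``100 * (placed - remaining) / placed``; with the standard 10-worm plate
    this is ``(10 - remaining) * 10``.
    """
    if worms_placed < 1:
        raise PlateValidationError(f"worms_placed must be >= 1, got {worms_placed}")
    if worms_remaining < 0 or worms_remaining > worms_placed:
        raise PlateValidationError(
            f"worms_remaining={worms_remaining} outside [0, {worms_placed}]"
        )
    return 100.0 * (worms_placed - worms_remaining) / worms_placed


def chemotaxis_index(at_odor: int, at_control: int, total: int) -> float:
    """Chemotaxis index ``(at_odor - at_control) / total`` in [-1, 1].

    Worms at neither spot still count in ``total``.
    """
    if total < 1:
        raise PlateValidationError(f"total must be >= 1, got {total}")
    if at_odor < 0 or at_control < 0:
        raise PlateValidationError("counts must be non-negative")
    if at_odor + at_control > total:
        raise PlateValidationError(
            f"at_odor + at_control = {at_odor + at_control} exceeds total {total}"
        )
    return (at_odor - at_control) / total


@dataclass(frozen=True)
class PlateRecord:
    """One assay plate: strain identity, feeding condition, and end-point counts.

    ``control_group`` links a mutant line to its matched wild-type cohort
    (controls tested on the same days).  ``deprivation_minutes`` is 0 for fed
    plates; ``condition`` is authoritative when both are present.
    """

    plate_id: str
    strain: str
    control_group: str
    condition: Condition
    assay: Assay
    worms_placed: int
    worms_remaining: int | None = None
    worms_at_odor: int | None = None
    worms_at_control: int | None = None
    fructose_molarity: float | None = None
    deprivation_minutes: float = 0.0
    batch: str = ""

    def __post_init__(self) -> None:
        if self.worms_placed < 1:
            raise PlateValidationError(
                f"plate {self.plate_id!r}: worms_placed must be >= 1"
            )
        if self.assay is Assay.CHEMOTAXIS:
            if self.worms_at_odor is None or self.worms_at_control is None:
                raise PlateValidationError(
                    f"plate {self.plate_id!r}: chemotaxis plates need "
                    "worms_at_odor and worms_at_control"
                )
            if self.worms_at_odor < 0 or self.worms_at_control < 0:
                raise PlateValidationError(
                    f"plate {self.plate_id!r}: negative chemotaxis counts"
                )
            if self.worms_at_odor + self.worms_at_control > self.worms_placed:
                raise PlateValidationError(
                    f"plate {self.plate_id!r}: worms at odor + control exceed placed"
                )
        else:
            if self.worms_remaining is None:
                raise PlateValidationError(
                    f"plate {self.plate_id!r}: exit-assay plates need worms_remaining"
                )
            if not 0 <= self.worms_remaining <= self.worms_placed:
                raise PlateValidationError(
                    f"plate {self.plate_id!r}: worms_remaining="
                    f"{self.worms_remaining} outside [0, {self.worms_placed}]"
                )
        if self.condition is Condition.FED and self.deprivation_minutes not in (0, 0.0):
            raise PlateValidationError(
                f"plate {self.plate_id!r}: fed plate with nonzero deprivation_minutes"
            )

    def score(self, score: Score) -> float:
        if score is Score.PERCENT_EXITING:
            if self.assay is Assay.CHEMOTAXIS:
                raise PlateValidationError(
                    f"plate {self.plate_id!r}: percent exiting undefined for chemotaxis"
                )
            return percent_exiting(self.worms_remaining, self.worms_placed)
        if self.assay is not Assay.CHEMOTAXIS:
            raise PlateValidationError(
                f"plate {self.plate_id!r}: chemotaxis index undefined for exit assays"
            )
        return chemotaxis_index(
            self.worms_at_odor, self.worms_at_control, self.worms_placed
        )


@dataclass(frozen=True)
class GroupKey:
    """Identity of one cell of the design: who, under what condition, in which assay."""

    strain: str
    control_group: str
    condition: Condition
    assay: Assay
    fructose_molarity: float | None
    deprivation_minutes: float


@dataclass(frozen=True)
class GroupSample:
    """Per-plate scores for one (strain, condition, assay-parameters) cell."""

    key: GroupKey
    values: np.ndarray  # float vector, one entry per plate

    @property
    def n(self) -> int:
        return len(self.values)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float)
        )
        if self.values.ndim != 1:
            raise PlateValidationError("GroupSample values must be a 1-D vector")


# CSV schema: column order is fixed so write(read(x)) == x byte-for-byte.
CSV_COLUMNS = (
    "plate_id",
    "strain",
    "control_group",
    "condition",
    "assay",
    "fructose_molarity",
    "deprivation_minutes",
    "worms_placed",
    "worms_remaining",
    "worms_at_odor",
    "worms_at_control",
    "batch",
)


def _fmt_float(x: float | None) -> str:
    if x is None:
        return ""
    return repr(float(x))


def _parse_opt_int(s: str, what: str, row: int) -> int | None:
    if s == "":
        return None
    try:
        return int(s)
    except ValueError:
        raise PlateValidationError(f"row {row}: unparseable {what} {s!r}") from None


def _parse_opt_float(s: str, what: str, row: int) -> float | None:
    if s == "":
        return None
    try:
        return float(s)
    except ValueError:
        raise PlateValidationError(f"row {row}: unparseable {what} {s!r}") from None


@dataclass
class ExperimentTable:
    """A validated collection of plate records (one experiment / dataset)."""

    records: list[PlateRecord]
    schema_version: str = "1"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.plate_id in seen:
                raise PlateValidationError(f"duplicate plate_id {rec.plate_id!r}")
            seen.add(rec.plate_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PlateRecord]:
        return iter(self.records)

    def validate_controls(self, wildtype: str = "WT") -> None:
        """Every mutant line's control_group must contain wild-type plates."""
        groups_with_wt = {
            r.control_group for r in self.records if r.strain == wildtype
        }
        for rec in self.records:
            if rec.strain != wildtype and rec.control_group not in groups_with_wt:
                raise PlateValidationError(
                    f"plate {rec.plate_id!r}: control_group {rec.control_group!r} "
                    f"has no {wildtype!r} plates"
                )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "plate_id": r.plate_id,
                    "strain": r.strain,
                    "control_group": r.control_group,
                    "condition": r.condition.value,
                    "assay": r.assay.value,
                    "fructose_molarity": r.fructose_molarity,
                    "deprivation_minutes": r.deprivation_minutes,
                    "worms_placed": r.worms_placed,
                    "worms_remaining": r.worms_remaining,
                    "worms_at_odor": r.worms_at_odor,
                    "worms_at_control": r.worms_at_control,
                    "batch": r.batch,
                }
            )
        return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def read_plates(path, *, delimiter: str = ",") -> ExperimentTable:
    """Read a plate CSV into a validated :class:`ExperimentTable`.

    Unknown extra columns are ignored; rows violating plate invariants raise
    :class:`PlateValidationError` naming the offending row (1-based data row).
    """
    records: list[PlateRecord] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise PlateValidationError(f"{path}: empty file, no header")
        missing = [c for c in CSV_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise PlateValidationError(f"{path}: missing columns {missing}")
        for i, row in enumerate(reader, start=1):
            try:
                condition = Condition(row["condition"])
            except ValueError:
                raise PlateValidationError(
                    f"row {i}: unknown condition {row['condition']!r}"
                ) from None
            try:
                assay = Assay(row["assay"])
            except ValueError:
                raise PlateValidationError(
                    f"row {i}: unknown assay {row['assay']!r}"
                ) from None
            placed = _parse_opt_int(row["worms_placed"], "worms_placed", i)
            if placed is None:
                raise PlateValidationError(f"row {i}: worms_placed is required")
            depr = _parse_opt_float(row["deprivation_minutes"], "deprivation_minutes", i)
            try:
                rec = PlateRecord(
                    plate_id=row["plate_id"],
                    strain=row["strain"],
                    control_group=row["control_group"],
                    condition=condition,
                    assay=assay,
                    worms_placed=placed,
                    worms_remaining=_parse_opt_int(
                        row["worms_remaining"], "worms_remaining", i
                    ),
                    worms_at_odor=_parse_opt_int(
                        row["worms_at_odor"], "worms_at_odor", i
                    ),
                    worms_at_control=_parse_opt_int(
                        row["worms_at_control"], "worms_at_control", i
                    ),
                    fructose_molarity=_parse_opt_float(
                        row["fructose_molarity"], "fructose_molarity", i
                    ),
                    deprivation_minutes=0.0 if depr is None else depr,
                    batch=row["batch"],
                )
            except PlateValidationError as exc:
                raise PlateValidationError(f"row {i}: {exc}") from None
            records.append(rec)
    return ExperimentTable(records)


def write_plates(table: ExperimentTable, path, *, delimiter: str = ",") -> None:
    """Write the table to CSV; round-trips bit-exactly with :func:`read_plates`."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(CSV_COLUMNS)
        for r in table.records:
            writer.writerow(
                [
                    r.plate_id,
                    r.strain,
                    r.control_group,
                    r.condition.value,
                    r.assay.value,
                    _fmt_float(r.fructose_molarity),
                    _fmt_float(r.deprivation_minutes),
                    str(r.worms_placed),
                    "" if r.worms_remaining is None else str(r.worms_remaining),
                    "" if r.worms_at_odor is None else str(r.worms_at_odor),
                    "" if r.worms_at_control is None else str(r.worms_at_control),
                    r.batch,
                ]
            )


def group_samples(
    table: ExperimentTable, score: Score | str
) -> dict[GroupKey, GroupSample]:
    """Group plates into design cells and score each plate.

    Every record lands in exactly one group, so group sizes sum to the record
    count.  Requesting a chemotaxis score for exit-assay records (or vice
    versa) is an error.
    """
    score = Score(score)
    buckets: dict[GroupKey, list[float]] = {}
    for rec in table.records:
        key = GroupKey(
            strain=rec.strain,
            control_group=rec.control_group,
            condition=rec.condition,
            assay=rec.assay,
            fructose_molarity=rec.fructose_molarity,
            deprivation_minutes=rec.deprivation_minutes,
        )
        buckets.setdefault(key, []).append(rec.score(score))
    return {
        key: GroupSample(key=key, values=np.asarray(vals, dtype=float))
        for key, vals in buckets.items()
    }
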