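"""Dietary reference values (EAR/UL) for calcium by life-stage group.

Life-stage groups follow the IOM DRI structure used for population
assessment: children up to age 9 are not split by sex, older subjects are
stratified by sex, and pregnant women have their own rows.  Age intervals
are half-open, ``age_min <= age < age_max``, so a child who just turned 4
belongs to the 4-to-9 group.

The default table covers calcium only.  The file format (one delimited row
per group) is nutrient-agnostic, so a table for another nutrient or a
country-specific reference set can be supplied instead.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "LifeStageGroup",
    "DRIEntry",
    "DRITable",
    "GroupAssignmentError",
    "DRITableError",
]

FEMALE = "female"
MALE = "male"
ANY_SEX = "any"

_VALID_SEX = {FEMALE, MALE}


class GroupAssignmentError(ValueError):
    """No life-stage group matches a subject's age/sex/pregnancy status."""


class DRITableError(ValueError):
    """The reference table violates a structural invariant."""


@dataclass(frozen=True)
class LifeStageGroup:
    """One demographic stratum with its own dietary reference values.

    ``sex`` may be ``"any"`` for child groups that pool both sexes.  The age
    interval is half-open: ``age_min_years <= age < age_max_years``.
    """

    label: str
    sex: str
    pregnant: bool
    age_min_years: float
    age_max_years: float

    def __post_init__(self) -> None:
        if not self.age_min_years < self.age_max_years:
            raise DRITableError(
                f"group {self.label!r}: age_min must be < age_max "
                f"({self.age_min_years} vs {self.age_max_years})"
            )
        if self.pregnant and self.sex == MALE:
            raise DRITableError(f"group {self.label!r}: pregnant group cannot be male")

    def contains(self, age_years: float, sex: str, pregnant: bool) -> bool:
        if pregnant != self.pregnant:
            return False
        if self.sex != ANY_SEX and self.sex != sex:
            return False
        return self.age_min_years <= age_years < self.age_max_years


@dataclass(frozen=True)
class DRIEntry:
    """An (EAR, UL) pair in mg/day for one life-stage group."""

    ear_mg: float
    ul_mg: float

    def __post_init__(self) -> None:
        if not (self.ear_mg > 0 and self.ul_mg > self.ear_mg):
            raise DRITableError(
                f"need 0 < EAR < UL, got EAR={self.ear_mg}, UL={self.ul_mg}"
            )


class DRITable:
    """Mapping from life-stage groups to (EAR, UL) reference values.

    Use :meth:`default` for the shipped calcium table, or :meth:`from_csv`
    to load a custom one.  :meth:`assign_group` classifies a subject into
    the unique group covering their age/sex/pregnancy stratum.
    """

    def __init__(self, rows: Iterable[tuple[LifeStageGroup, DRIEntry]]):
        self._rows: list[tuple[LifeStageGroup, DRIEntry]] = list(rows)
        if not self._rows:
            raise DRITableError("empty reference table")
        self._validate_partition()

    def _validate_partition(self) -> None:
        # Within each effective (sex, pregnant) stratum -- where sex="any"
        # rows participate in both sexes -- age intervals must not overlap.
        for sex in (FEMALE, MALE):
            for pregnant in (False, True):
                intervals = sorted(
                    (g.age_min_years, g.age_max_years, g.label)
                    for g, _ in self._rows
                    if g.pregnant == pregnant and g.sex in (sex, ANY_SEX)
                )
                for (a0, a1, l0), (b0, b1, l1) in zip(intervals, intervals[1:]):
                    if b0 < a1:
                        raise DRITableError(
                            f"overlapping age ranges for sex={sex}, "
                            f"pregnant={pregnant}: {l0!r} and {l1!r}"
                        )

    def __iter__(self) -> Iterator[tuple[LifeStageGroup, DRIEntry]]:
        return iter(self._rows)

    def __len__(self) -> int:
        return len(self._rows)

    @property
    def groups(self) -> list[LifeStageGroup]:
        return [g for g, _ in self._rows]

    def entry(self, group: LifeStageGroup) -> DRIEntry:
        for g, e in self._rows:
            if g == group:
                return e
        raise KeyError(group)

    def assign_group(
        self, age_years: float, sex: str, pregnant: bool = False
    ) -> LifeStageGroup:
        """Return the unique group containing (age, sex, pregnant).

        Raises :class:`GroupAssignmentError` when no row matches, e.g. an
        infant younger than 6 months, a pregnant male, or a pregnant woman
        outside the pregnant rows' age span.
        """
        if sex not in _VALID_SEX:
            raise GroupAssignmentError(f"unknown sex {sex!r}")
        if pregnant and sex == MALE:
            raise GroupAssignmentError("no group for a pregnant male subject")
        matches = [g for g, _ in self._rows if g.contains(age_years, sex, pregnant)]
        if not matches:
            raise GroupAssignmentError(
                f"no life-stage group for age={age_years}, sex={sex}, "
                f"pregnant={pregnant}"
            )
        # non-overlap was validated at load, so matches has exactly one entry
        return matches[0]

    def lookup(
        self, age_years: float, sex: str, pregnant: bool = False
    ) -> tuple[LifeStageGroup, DRIEntry]:
        group = self.assign_group(age_years, sex, pregnant)
        return group, self.entry(group)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DRITable":
        rows = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            required = {
                "label", "sex", "pregnant", "age_min_years", "age_max_years",
                "ear_mg", "ul_mg",
            }
            if reader.fieldnames is None or not required <= set(reader.fieldnames):
                missing = required - set(reader.fieldnames or [])
                raise DRITableError(f"{path}: missing columns {sorted(missing)}")
            for lineno, rec in enumerate(reader, start=2):
                try:
                    group = LifeStageGroup(
                        label=rec["label"].strip(),
                        sex=rec["sex"].strip().lower(),
                        pregnant=_parse_bool(rec["pregnant"]),
                        age_min_years=float(rec["age_min_years"]),
                        age_max_years=float(rec["age_max_years"]),
                    )
                    entry = DRIEntry(float(rec["ear_mg"]), float(rec["ul_mg"]))
                except (ValueError, KeyError) as exc:
                    raise DRITableError(f"{path}:{lineno}: {exc}") from exc
                rows.append((group, entry))
        return cls(rows)

    @classmethod
    def default(cls) -> "DRITable":
        """The shipped calcium table (18 life-stage groups, mg/day)."""
        ref = resources.files("calfort.data").joinpath("dri_calcium.csv")
        with resources.as_file(ref) as path:
            return cls.from_csv(path)


def _parse_bool(text: str) -> bool:
    t = text.strip().lower()
    if t in {"true", "1", "yes", "t"}:
        return True
    if t in {"false", "0", "no", "f"}:
        return False
    raise ValueError(f"cannot parse boolean {text!r}")
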