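"""Recall-level dietary data: loading, validation, and per-day aggregation.

The unit of observation is one food item reported by one subject on one
recall day, with its amount (g) and calcium content (mg).  This module
turns those records into per-subject-day totals of calcium and of
*fortifiable flour* -- the grams of flour contained in the foods eaten,
obtained by multiplying each food's amount by its flour fraction from a
food-to-flour map (e.g. bread that is 65% flour contributes 0.65 g of
flour per gram).

Supplements in tablet/pill form are excluded from the flour total (they
may contain starch but would never be fortified) while their calcium still
counts toward intake; powder or liquid supplements count toward both.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .reference_values import FEMALE, MALE

logger = logging.getLogger(__name__)

__all__ = [
    "Subject",
    "RecallRecord",
    "DailyIntake",
    "FlourMap",
    "FlourSummary",
    "DataValidationError",
    "read_subjects",
    "read_recalls",
    "daily_totals",
    "flour_summary",
    "weighted_mean_sd",
]

FLOUR_TYPES = ("wheat", "maize", "rice", "cassava", "other")


class DataValidationError(ValueError):
    """Input data violates the schema or referential integrity."""


@dataclass(frozen=True)
class Subject:
    """One survey participant."""

    subject_id: str
    age_years: float
    sex: str
    pregnant: bool = False
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise DataValidationError(
                f"subject {self.subject_id}: survey weight must be > 0"
            )
        if self.age_years < 0:
            raise DataValidationError(f"subject {self.subject_id}: negative age")


@dataclass(frozen=True)
class RecallRecord:
    """One food item on one subject-day."""

    subject_id: str
    day: int
    food_code: str
    amount_g: float
    calcium_mg: float
    is_tablet_supplement: bool = False

    def __post_init__(self) -> None:
        if self.amount_g < 0 or self.calcium_mg < 0:
            raise DataValidationError(
                f"subject {self.subject_id} day {self.day} food "
                f"{self.food_code}: negative amount or calcium"
            )


@dataclass(frozen=True)
class DailyIntake:
    """Per-subject-day totals (mg calcium, g fortifiable flour)."""

    subject_id: str
    day: int
    calcium_mg: float
    flour_g: float


@dataclass
class FlourSummary:
    """Group-level flour consumption statistics (first recall day)."""

    pct_consuming: float
    mean_flour_g: float
    sd_flour_g: float


class FlourMap:
    """Food-code to flour-content map.

    Each food maps to a list of ``(flour_type, fraction)`` pairs; the
    fortifiable fraction of the food is the sum over its flour types
    (a food with 30% rice flour and 40% wheat flour is 70% flour).
    Unknown food codes are treated as flour-free; the number of distinct
    unmapped codes seen is counted and logged so a patchy map is visible.
    """

    def __init__(self, entries: Mapping[str, Sequence[tuple[str, float]]]):
        self._entries: dict[str, list[tuple[str, float]]] = {}
        for food, pairs in entries.items():
            pairs = [(str(t), float(f)) for t, f in pairs]
            for ftype, frac in pairs:
                if ftype not in FLOUR_TYPES:
                    raise DataValidationError(
                        f"food {food!r}: unknown flour type {ftype!r} "
                        f"(expected one of {FLOUR_TYPES})"
                    )
                if not 0.0 <= frac <= 1.0:
                    raise DataValidationError(
                        f"food {food!r}: fraction {frac} outside [0, 1]"
                    )
            total = sum(f for _, f in pairs)
            if total > 1.0 + 1e-9:
                raise DataValidationError(
                    f"food {food!r}: flour fractions sum to {total:.3f} > 1"
                )
            self._entries[str(food)] = list(pairs)
        self.unmapped_codes: set[str] = set()

    def __contains__(self, food_code: str) -> bool:
        return food_code in self._entries

    def foods(self) -> list[str]:
        return sorted(self._entries)

    def fraction(
        self, food_code: str, flour_types: Iterable[str] | None = None
    ) -> float:
        """Fortifiable flour fraction of one food, optionally restricted to
        a subset of flour types (e.g. wheat-only fortification)."""
        pairs = self._entries.get(food_code)
        if pairs is None:
            if food_code not in self.unmapped_codes:
                self.unmapped_codes.add(food_code)
                logger.debug("food code %r not in flour map; assuming no flour",
                             food_code)
            return 0.0
        if flour_types is None:
            return sum(f for _, f in pairs)
        allowed = set(flour_types)
        return sum(f for t, f in pairs if t in allowed)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FlourMap":
        df = _read_table(path, {"food_code", "flour_type", "fraction"})
        entries: dict[str, list[tuple[str, float]]] = defaultdict(list)
        for rec in df.itertuples(index=False):
            entries[str(rec.food_code)].append(
                (str(rec.flour_type).strip().lower(), float(rec.fraction))
            )
        return cls(entries)

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"food_code": food, "flour_type": t, "fraction": f}
            for food, pairs in sorted(self._entries.items())
            for t, f in pairs
        ]
        pd.DataFrame(rows, columns=["food_code", "flour_type", "fraction"]).to_csv(
            path, index=False
        )


def _read_table(path: str | Path, required: set[str]) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:
        raise DataValidationError(f"cannot read {path}: {exc}") from exc
    missing = required - set(df.columns)
    if missing:
        raise DataValidationError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_subjects(path: str | Path) -> list[Subject]:
    """Load subjects from CSV/TSV with columns
    subject_id, age_years, sex, pregnant, weight (weight optional)."""
    df = _read_table(path, {"subject_id", "age_years", "sex", "pregnant"})
    if "weight" not in df.columns:
        df["weight"] = 1.0
    subjects = []
    errors = []
    for i, rec in enumerate(df.itertuples(index=False), start=2):
        sex = str(rec.sex).strip().lower()
        if sex not in (FEMALE, MALE):
            errors.append(f"line {i}: unknown sex {rec.sex!r}")
            continue
        try:
            subjects.append(
                Subject(
                    subject_id=str(rec.subject_id),
                    age_years=float(rec.age_years),
                    sex=sex,
                    pregnant=_as_bool(rec.pregnant),
                    weight=float(rec.weight),
                )
            )
        except (DataValidationError, ValueError) as exc:
            errors.append(f"line {i}: {exc}")
    if errors:
        raise DataValidationError(
            f"{path}: {len(errors)} invalid subject rows:\n  " + "\n  ".join(errors[:20])
        )
    ids = [s.subject_id for s in subjects]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DataValidationError(f"{path}: duplicate subject ids {dupes[:10]}")
    return subjects


def read_recalls(path: str | Path) -> list[RecallRecord]:
    """Load recall records from CSV/TSV with columns
    subject_id, day, food_code, amount_g, calcium_mg, is_tablet_supplement
    (the supplement flag optional, default false)."""
    df = _read_table(path, {"subject_id", "day", "food_code", "amount_g", "calcium_mg"})
    if "is_tablet_supplement" not in df.columns:
        df["is_tablet_supplement"] = False
    records = []
    errors = []
    for i, rec in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                RecallRecord(
                    subject_id=str(rec.subject_id),
                    day=int(rec.day),
                    food_code=str(rec.food_code),
                    amount_g=float(rec.amount_g),
                    calcium_mg=float(rec.calcium_mg),
                    is_tablet_supplement=_as_bool(rec.is_tablet_supplement),
                )
            )
        except (DataValidationError, ValueError) as exc:
            errors.append(f"line {i}: {exc}")
    if errors:
        raise DataValidationError(
            f"{path}: {len(errors)} invalid recall rows:\n  " + "\n  ".join(errors[:20])
        )
    return records


def _as_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, np.integer, float, np.floating)):
        return bool(int(value))
    t = str(value).strip().lower()
    if t in {"true", "1", "yes", "t"}:
        return True
    if t in {"false", "0", "no", "f"}:
        return False
    raise ValueError(f"cannot parse boolean {value!r}")


def subjects_to_csv(subjects: Sequence[Subject], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "age_years": s.age_years,
                "sex": s.sex,
                "pregnant": s.pregnant,
                "weight": s.weight,
            }
            for s in subjects
        ]
    ).to_csv(path, index=False)


def recalls_to_csv(records: Sequence[RecallRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "day": r.day,
                "food_code": r.food_code,
                "amount_g": r.amount_g,
                "calcium_mg": r.calcium_mg,
                "is_tablet_supplement": r.is_tablet_supplement,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def daily_totals(
    records: Sequence[RecallRecord],
    subjects: Sequence[Subject],
    flour_map: FlourMap,
    flour_types: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Aggregate records into per-subject-day totals.

    Returns a DataFrame with columns ``subject_id, day, calcium_mg,
    flour_g``, one row per observed (subject, day).  Calcium sums over all
    records (supplements included); flour sums ``amount_g * fraction`` over
    non-tablet records only.  ``flour_types`` restricts which flour types
    count as fortifiable.

    Raises :class:`DataValidationError` if any record references an unknown
    subject.
    """
    known = {s.subject_id for s in subjects}
    orphans = sorted({r.subject_id for r in records} - known)
    if orphans:
        raise DataValidationError(
            f"recall records reference {len(orphans)} unknown subject ids: "
            f"{orphans[:10]}"
        )
    totals: dict[tuple[str, int], list[float]] = defaultdict(lambda: [0.0, 0.0])
    for r in records:
        acc = totals[(r.subject_id, r.day)]
        acc[0] += r.calcium_mg
        if not r.is_tablet_supplement:
            acc[1] += r.amount_g * flour_map.fraction(r.food_code, flour_types)
    if flour_map.unmapped_codes:
        logger.info(
            "%d food codes absent from the flour map were treated as flour-free",
            len(flour_map.unmapped_codes),
        )
    rows = [
        {"subject_id": sid, "day": day, "calcium_mg": ca, "flour_g": fl}
        for (sid, day), (ca, fl) in sorted(totals.items())
    ]
    return pd.DataFrame(rows, columns=["subject_id", "day", "calcium_mg", "flour_g"])


def first_day(daily: pd.DataFrame) -> pd.DataFrame:
    """Each subject's first recall day (lowest day index), one row per subject."""
    idx = daily.groupby("subject_id")["day"].idxmin()
    return daily.loc[idx].reset_index(drop=True)


def weighted_mean_sd(values: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    """Survey-weighted mean and population SD."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    w = weights / weights.sum()
    mean = float(np.dot(w, values))
    var = float(np.dot(w, (values - mean) ** 2))
    return mean, float(np.sqrt(var))


def flour_summary(
    daily: pd.DataFrame, subjects: Sequence[Subject]
) -> FlourSummary:
    """Percent of a group consuming any flour and mean/SD flour intake.

    Uses each subject's first recall day only, includes non-consumers
    (zeros) in the mean and SD, and weights by survey weights.
    """
    if not len(subjects):
        raise DataValidationError("flour_summary: empty group")
    wmap = {s.subject_id: s.weight for s in subjects}
    day1 = first_day(daily[daily["subject_id"].isin(wmap)])
    if day1.empty:
        raise DataValidationError("flour_summary: no recall days for this group")
    flour = day1["flour_g"].to_numpy(dtype=float)
    weights = day1["subject_id"].map(wmap).to_numpy(dtype=float)
    pct = 100.0 * float(weights[flour > 0].sum() / weights.sum())
    mean, sd = weighted_mean_sd(flour, weights)
    return FlourSummary(pct_consuming=pct, mean_flour_g=mean, sd_flour_g=sd)
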