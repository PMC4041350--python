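"""Person-level record containers and CSV serialization.

A :class:`PersonRecord` holds the identifiers available from either of the
two sources being linked: a longitudinal population registry (an HDSS) and
a health-facility patient register.  Missing values are represented by
``None`` in memory and by an empty cell in CSV files; an empty string is
never a legal field value.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

#: Fixed CSV column order for person datasets.
PERSON_COLUMNS = [
    "record_id",
    "first_name",
    "surname",
    "other_first_name",
    "sex",
    "birth_day",
    "birth_month",
    "birth_year",
    "village",
    "hh_member_first_name",
    "hh_member_surname",
    "national_id",
    "phone",
]

#: Identifier fields usable as linking variables.
IDENTIFIER_FIELDS = PERSON_COLUMNS[1:]


@dataclass(frozen=True)
class PersonRecord:
    """One individual's identifiers from the registry or the clinic."""

    record_id: str
    first_name: str
    surname: str
    other_first_name: Optional[str] = None
    sex: Optional[str] = None  # "F" or "M"
    birth_day: Optional[int] = None
    birth_month: Optional[int] = None
    birth_year: Optional[int] = None
    village: Optional[str] = None
    hh_member_first_name: Optional[str] = None
    hh_member_surname: Optional[str] = None
    national_id: Optional[str] = None
    phone: Optional[str] = None

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if v == "":
                raise ValueError(
                    f"field {f.name!r} is an empty string; use None for missing"
                )


@dataclass(frozen=True)
class GoldStandard:
    """True-match pairs of (registry record_id, clinic record_id).

    Each clinic record appears at most once: a patient has one registry
    counterpart or none.
    """

    pairs: frozenset

    def __post_init__(self) -> None:
        clinic_ids = [c for _, c in self.pairs]
        if len(clinic_ids) != len(set(clinic_ids)):
            raise ValueError("a clinic record_id appears in more than one gold pair")

    def __len__(self) -> int:
        return len(self.pairs)

    def clinic_ids(self) -> frozenset:
        return frozenset(c for _, c in self.pairs)

    def as_dict(self) -> dict:
        """Map clinic record_id -> registry record_id."""
        return {c: r for r, c in self.pairs}


def records_to_frame(records: Iterable[PersonRecord]) -> pd.DataFrame:
    """Convert records to a DataFrame with the fixed column order.

    Missing values become ``pd.NA``; integer date parts use a nullable
    integer dtype so missingness survives the round trip.
    """
    rows = [{c: getattr(r, c) for c in PERSON_COLUMNS} for r in records]
    df = pd.DataFrame(rows, columns=PERSON_COLUMNS)
    for col in ("birth_day", "birth_month", "birth_year"):
        df[col] = df[col].astype("Int64")
    for col in df.columns:
        if df[col].dtype == object:
            df[col] = df[col].where(df[col].notna(), pd.NA)
    return df


def frame_to_records(df: pd.DataFrame) -> list[PersonRecord]:
    out = []
    for row in df.itertuples(index=False):
        kwargs = {}
        for c in PERSON_COLUMNS:
            v = getattr(row, c)
            if pd.isna(v):
                v = None
            elif c in ("birth_day", "birth_month", "birth_year"):
                v = int(v)
            else:
                v = str(v)
            kwargs[c] = v
        out.append(PersonRecord(**kwargs))
    return out


def write_person_csv(records: Iterable[PersonRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_person_csv(path: str | Path) -> list[PersonRecord]:
    df = pd.read_csv(
        path,
        dtype={c: "string" for c in PERSON_COLUMNS if c not in
               ("birth_day", "birth_month", "birth_year")},
        keep_default_na=True,
    )
    for col in ("birth_day", "birth_month", "birth_year"):
        df[col] = df[col].astype("Int64")
    return frame_to_records(df)


def write_gold_csv(gold: GoldStandard, path: str | Path) -> None:
    df = pd.DataFrame(sorted(gold.pairs), columns=["registry_id", "clinic_id"])
    df.to_csv(path, index=False)


def read_gold_csv(path: str | Path) -> GoldStandard:
    df = pd.read_csv(path, dtype="string")
    pairs = frozenset(zip(df["registry_id"], df["clinic_id"]))
    return GoldStandard(pairs=pairs)
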