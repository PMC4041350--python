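"""Candidate pair generation under three blocking schemes.

Comparing every registry record against every clinic record is quadratic;
blocking restricts comparisons to pairs agreeing on cheap variables.
Three complementary schemes limit the damage a mis-recorded blocking
variable can do: BS1 (same sex and birth year), BS2 (same sex and
village) and BS3 (same initials of first name and surname, ages within
10 years).  A record missing a scheme's blocking variable generates no
pairs under that scheme.
"""

from __future__ import annotations

from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .comparators import normalize
from .engine import ScoredPair
from .records import records_to_frame


class BlockingScheme(str, Enum):
    BS1 = "BS1"  # exact sex and birth year
    BS2 = "BS2"  # exact sex and village
    BS3 = "BS3"  # first letters of first name + surname, |age diff| <= 10

    @classmethod
    def parse(cls, value) -> "BlockingScheme":
        if isinstance(value, cls):
            return value
        return cls(str(value).upper())


DEFAULT_SCHEMES = (BlockingScheme.BS1, BlockingScheme.BS2, BlockingScheme.BS3)

#: Maximum age difference admitted by BS3, in years.
BS3_AGE_WINDOW = 10


def _as_frame(dataset) -> pd.DataFrame:
    if isinstance(dataset, pd.DataFrame):
        return dataset
    return records_to_frame(dataset)


def _norm_col(s: pd.Series) -> pd.Series:
    uniq = s.dropna().unique()
    return s.map({v: normalize(str(v)) for v in uniq})


def block_pairs(registry, clinic, scheme: BlockingScheme,
                reference_year: int = 2010) -> set[tuple]:
    """All (registry_id, clinic_id) pairs satisfying the scheme predicate.

    Age for BS3 is computed as reference_year - birth_year.
    """
    scheme = BlockingScheme.parse(scheme)
    reg = _as_frame(registry)
    cli = _as_frame(clinic)
    if reg.empty or cli.empty:
        return set()

    if scheme is BlockingScheme.BS1:
        r = reg[["record_id", "sex", "birth_year"]].dropna()
        c = cli[["record_id", "sex", "birth_year"]].dropna()
        merged = r.merge(c, on=["sex", "birth_year"],
                         suffixes=("_reg", "_cli"))
    elif scheme is BlockingScheme.BS2:
        r = reg[["record_id", "sex", "village"]].dropna().copy()
        c = cli[["record_id", "sex", "village"]].dropna().copy()
        r["village"] = _norm_col(r["village"])
        c["village"] = _norm_col(c["village"])
        merged = r.merge(c, on=["sex", "village"], suffixes=("_reg", "_cli"))
    else:  # BS3
        r = reg[["record_id", "first_name", "surname", "birth_year"]].dropna().copy()
        c = cli[["record_id", "first_name", "surname", "birth_year"]].dropna().copy()
        for df in (r, c):
            df["fi"] = _norm_col(df["first_name"]).str[:1]
            df["si"] = _norm_col(df["surname"]).str[:1]
        merged = r.merge(c, on=["fi", "si"], suffixes=("_reg", "_cli"))
        if merged.empty:
            return set()
        age_r = reference_year - merged["birth_year_reg"].astype(int)
        age_c = reference_year - merged["birth_year_cli"].astype(int)
        merged = merged[(age_r - age_c).abs() <= BS3_AGE_WINDOW]

    return set(zip(merged["record_id_reg"], merged["record_id_cli"]))


def combine_block_results(per_block_links: Sequence[Iterable[ScoredPair]],
                          resolve_one_to_one: bool = True
                          ) -> set[ScoredPair]:
    """Union the linked pairs of several blocking schemes.

    Duplicate (registry_id, clinic_id) entries collapse to one, keeping
    the maximum score.  With ``resolve_one_to_one`` (the default), a
    clinic record linked to several registry records keeps only the
    highest-scoring pair; ties break on the lexicographically smallest
    registry_id.
    """
    best: dict[tuple, ScoredPair] = {}
    for block in per_block_links:
        for sp in block:
            cur = best.get(sp.pair)
            if cur is None or sp.score > cur.score:
                best[sp.pair] = sp
    if not resolve_one_to_one:
        return set(best.values())

    by_clinic: dict = {}
    for sp in best.values():
        reg_id, cli_id = sp.pair
        cur = by_clinic.get(cli_id)
        if (cur is None or sp.score > cur.score
                or (sp.score == cur.score and reg_id < cur.pair[0])):
            by_clinic[cli_id] = sp
    return set(by_clinic.values())
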