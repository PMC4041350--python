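"""Synthetic registry / clinic dataset generator with known ground truth.

Real evaluations of record linkage between a Health and Demographic
Surveillance System (HDSS) and a clinic register rely on a gold standard of
fingerprint-matched pairs; neither those data nor the identifiers are
public.  This module generates the same *statistical structure* instead: a
registry of unique persons grouped into households (sharing surname and
village), and a clinic dataset in which a configurable fraction of patients
are corrupted copies of registry persons (typos, phonetic spelling
variants, married-surname changes, date-of-birth misreporting that worsens
with age) while the remainder are novel walk-ins drawn from the same name
pools.  Field-level missingness defaults to the completeness percentages
observed in the two sources of the motivating study (e.g. national ID
present for 67.14% of registry records but only 1.55% of clinic records).

Every dataset is a deterministic function of (config, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .records import GoldStandard, PersonRecord

#: Default per-field completeness (probability a value is present), by
#: source.  Fields not listed are always complete.
DEFAULT_MISSINGNESS: dict[str, dict[str, float]] = {
    "registry": {
        "first_name": 1.0,
        "surname": 1.0,
        "other_first_name": 0.3557,
        "sex": 1.0,
        "birth_day": 1.0,
        "birth_month": 1.0,
        "birth_year": 1.0,
        "village": 1.0,
        "hh_member_first_name": 0.9848,
        "hh_member_surname": 0.9848,
        "national_id": 0.6714,
        "phone": 0.3748,
    },
    "clinic": {
        "first_name": 1.0,
        "surname": 1.0,
        "other_first_name": 0.0614,
        "sex": 0.9995,
        "birth_day": 1.0,
        "birth_month": 1.0,
        "birth_year": 1.0,
        "village": 0.8117,
        "hh_member_first_name": 0.7729,
        "hh_member_surname": 0.7660,
        "national_id": 0.0155,
        "phone": 0.2667,
    },
}

#: Corruption-rate modifiers tied to person attributes.  The age slope
#: multiplies corruption rates by (1 + slope * decades over 50); the
#: ethnicity multiplier raises name-corruption rates for persons whose
#: names originate outside the locally dominant orthography, emulating
#: less consistent transcription.
DEFAULT_COVARIATE_EFFECTS: dict[str, float] = {
    "age_slope_per_decade_over_50": 0.5,
    "other_ethnicity_name_multiplier": 1.75,
}

#: Marginal distributions for background covariates attached to registry
#: persons.  Wealth quintiles are assigned directly (no asset model).
COVARIATE_LEVELS = {
    "ethnicity": (["South African", "Other"], [0.85, 0.15]),
    "residence": (["Permanent", "Temporary and other"], [0.92, 0.08]),
    "education": (["None", "Some primary", "Post primary"], [0.16, 0.31, 0.53]),
    "employment": (["Not working", "Working"], [0.85, 0.15]),
    "wealth_quintile": ([1, 2, 3, 4, 5], [0.2, 0.2, 0.2, 0.2, 0.2]),
}

AGE_GROUPS = ["18-34", "35-49", "50-64", "65+"]
#: Adult age structure: (age range, weight).
_AGE_BANDS = [((18, 34), 0.54), ((35, 49), 0.20), ((50, 64), 0.14),
              ((65, 90), 0.12)]

_VILLAGES = [f"Village_{i:02d}" for i in range(1, 26)]

# Phonetically plausible spelling-variant rewrites (applied in either
# direction where both forms occur in practice).
_PHONETIC_VARIANTS = [
    ("PH", "F"), ("F", "PH"), ("CK", "K"), ("C", "K"), ("K", "C"),
    ("SH", "CH"), ("CH", "SH"), ("LL", "L"), ("L", "LL"), ("NN", "N"),
    ("N", "NN"), ("TT", "T"), ("T", "TT"), ("SS", "S"), ("I", "Y"),
    ("Y", "I"), ("EE", "I"), ("OU", "U"), ("U", "OU"), ("MB", "M"),
]

_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


class ConfigurationError(ValueError):
    """Raised when a GeneratorConfig violates its invariants."""


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic study population.

    Probabilities are per-draw; ``missingness`` maps source ("registry" /
    "clinic") to per-field completeness probabilities.  Identical
    (config, seed) pairs produce byte-identical datasets.
    """

    n_registry: int = 5000
    n_clinic: int = 1000
    overlap_fraction: float = 0.6
    mean_household_size: float = 5.0
    typo_rate: float = 0.25
    phonetic_swap_rate: float = 0.30
    surname_change_rate_female: float = 0.20
    dob_error_rate: float = 0.30
    village_change_rate: float = 0.15
    missingness: dict = field(
        default_factory=lambda: {s: dict(f) for s, f in
                                 DEFAULT_MISSINGNESS.items()})
    covariate_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    reference_year: int = 2010
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_registry < 0 or self.n_clinic < 0:
            raise ConfigurationError("record counts must be non-negative")
        for name in ("overlap_fraction", "typo_rate", "phonetic_swap_rate",
                     "surname_change_rate_female", "dob_error_rate",
                     "village_change_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        for source, fields_ in self.missingness.items():
            for fname, p in fields_.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(
                        f"missingness[{source}][{fname}]={p} outside [0, 1]")
        if self.mean_household_size < 1:
            raise ConfigurationError("mean_household_size must be >= 1")
        if self.n_registry < round(self.n_clinic * self.overlap_fraction):
            raise ConfigurationError(
                "overlap demand exceeds registry size: "
                f"{self.n_clinic} x {self.overlap_fraction} > {self.n_registry}")

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        merged_miss = {s: dict(f) for s, f in DEFAULT_MISSINGNESS.items()}
        for s, f in (raw.pop("missingness", None) or {}).items():
            merged_miss.setdefault(s, {}).update(f)
        effects = dict(DEFAULT_COVARIATE_EFFECTS)
        effects.update(raw.pop("covariate_effects", None) or {})
        return cls(missingness=merged_miss, covariate_effects=effects, **raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _load_pool(filename: str) -> list[str]:
    text = (resources.files("hdsslink.data") / filename).read_text()
    return [ln.strip() for ln in text.splitlines()
            if ln.strip() and not ln.startswith("#")]


def load_name_pools(first_names_path=None, surnames_path=None
                    ) -> tuple[list[str], list[str]]:
    """Load first-name and surname pools (bundled lists by default)."""
    if first_names_path is None:
        first = _load_pool("first_names.txt")
    else:
        first = [ln.strip() for ln in open(first_names_path)
                 if ln.strip() and not ln.startswith("#")]
    if surnames_path is None:
        sur = _load_pool("surnames.txt")
    else:
        sur = [ln.strip() for ln in open(surnames_path)
               if ln.strip() and not ln.startswith("#")]
    return first, sur


# ---------------------------------------------------------------------------
# name corruption

def clean_config(**overrides) -> GeneratorConfig:
    """A config with all corruption disabled and every field complete.

    In this limit every true-match clinic record equals its registry
    source field-for-field, so exact linkage must recover the ground
    truth perfectly.
    """
    miss = {src: {f: 1.0 for f in fields}
            for src, fields in DEFAULT_MISSINGNESS.items()}
    base = dict(typo_rate=0.0, phonetic_swap_rate=0.0,
                surname_change_rate_female=0.0, dob_error_rate=0.0,
                village_change_rate=0.0, missingness=miss)
    base.update(overrides)
    return GeneratorConfig(**base)


def corrupt_name(name: str, config: GeneratorConfig,
                 rng: np.random.Generator,
                 rate_multiplier: float = 1.0,
                 typo_operators: Optional[tuple] = None) -> str:
    """Return a possibly corrupted spelling of ``name``.

    With probability ``typo_rate`` one random character edit is applied
    (substitution, insertion, deletion or adjacent transposition); with
    probability ``phonetic_swap_rate`` a phonetically equivalent spelling
    rewrite is applied.  Both rates are scaled by ``rate_multiplier`` and
    capped at 1.  The result is never empty.
    """
    if not name:
        raise ValueError("corrupt_name requires a non-empty name")
    out = name
    p_typo = min(1.0, config.typo_rate * rate_multiplier)
    p_phon = min(1.0, config.phonetic_swap_rate * rate_multiplier)
    if rng.random() < p_typo:
        out = _apply_typo(out, rng, typo_operators)
    if rng.random() < p_phon:
        out = _apply_phonetic_variant(out, rng)
    return out


def _apply_typo(name: str, rng: np.random.Generator,
                operators: Optional[tuple] = None) -> str:
    ops = list(operators) if operators else \
        ["substitute", "insert", "delete", "transpose"]
    if len(name) == 1:
        ops = [o for o in ops if o in ("substitute", "insert")] or ["substitute"]
    op = ops[rng.integers(len(ops))]
    i = int(rng.integers(len(name)))
    if op == "substitute":
        choices = _ALPHABET.replace(name[i].upper(), "")
        ch = choices[rng.integers(len(choices))]
        if not name[i].isupper():
            ch = ch.lower()
        return name[:i] + ch + name[i + 1:]
    if op == "insert":
        ch = _ALPHABET[rng.integers(len(_ALPHABET))].lower()
        return name[:i] + ch + name[i:]
    if op == "delete":
        if len(name) == 1:
            return name
        return name[:i] + name[i + 1:]
    # transpose adjacent, guaranteed to change the string if letters differ
    if i == len(name) - 1:
        i -= 1
    if name[i] == name[i + 1]:
        return _apply_typo(name, rng, operators)
    return name[:i] + name[i + 1] + name[i] + name[i + 2:]


def _apply_phonetic_variant(name: str, rng: np.random.Generator) -> str:
    upper = name.upper()
    applicable = [(a, b) for a, b in _PHONETIC_VARIANTS if a in upper]
    if not applicable:
        return name
    a, b = applicable[rng.integers(len(applicable))]
    pos = upper.find(a)
    repl = b.capitalize() if name[pos].isupper() else b.lower()
    return name[:pos] + repl + name[pos + len(a):]


# ---------------------------------------------------------------------------
# registry generation

def _draw_category(rng, levels, probs):
    return levels[int(rng.choice(len(levels), p=probs))]


def person_covariates(record_id: str, birth_year: Optional[int],
                      config: GeneratorConfig) -> dict:
    """Background covariates for one registry person.

    Drawn from fixed marginals with an RNG keyed on (seed, record_id), so
    the same person always receives the same covariates regardless of
    which generator stage asks.
    """
    key = int("".join(ch for ch in record_id if ch.isdigit()) or "0")
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 911, key])
    cov = {name: _draw_category(rng, levels, probs)
           for name, (levels, probs) in COVARIATE_LEVELS.items()}
    age = None if birth_year is None else config.reference_year - birth_year
    if age is None:
        group = None
    elif age < 35:
        group = "18-34"
    elif age < 50:
        group = "35-49"
    elif age < 65:
        group = "50-64"
    else:
        group = "65+"
    cov["age"] = age
    cov["age_group"] = group
    return cov


def _corruption_multiplier(age: int, covariates: dict,
                           config: GeneratorConfig) -> float:
    eff = config.covariate_effects
    mult = 1.0
    slope = eff.get("age_slope_per_decade_over_50", 0.0)
    if age > 50:
        mult *= 1.0 + slope * (age - 50) / 10.0
    if covariates.get("ethnicity") == "Other":
        mult *= eff.get("other_ethnicity_name_multiplier", 1.0)
    return mult


def _draw_age(rng: np.random.Generator) -> int:
    weights = np.array([w for _, w in _AGE_BANDS])
    lo, hi = _AGE_BANDS[int(rng.choice(len(_AGE_BANDS), p=weights / weights.sum()))][0]
    return int(rng.integers(lo, hi + 1))


def _new_national_id(rng: np.random.Generator, clinic_only: bool = False) -> str:
    # 13-digit identifier; clinic-only walk-ins draw from a disjoint range
    # so spurious deterministic ID matches cannot occur by construction.
    lead = "9" if clinic_only else str(rng.integers(1, 9))
    return lead + "".join(str(rng.integers(10)) for _ in range(12))


def _new_phone(rng: np.random.Generator) -> str:
    return "0" + "".join(str(rng.integers(10)) for _ in range(9))


def _mask(value, present: bool):
    return value if present else None


def generate_registry(config: GeneratorConfig) -> list[PersonRecord]:
    """Generate the registry (HDSS) dataset.

    Persons are grouped into households sharing surname and village; the
    household-member fields cite the oldest *other* member.  Field
    completeness follows the registry column of ``config.missingness``.
    """
    config.validate()
    n = config.n_registry
    if n == 0:
        return []
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 101])
    first_pool, sur_pool = load_name_pools()
    miss = config.missingness["registry"]

    # households: sizes Poisson(mean), floored at 2 so every member has a
    # co-resident to cite
    sizes = []
    total = 0
    while total < n:
        size = max(2, int(rng.poisson(config.mean_household_size)))
        size = min(size, n - total) if n - total >= 2 else n - total
        sizes.append(max(1, size))
        total += sizes[-1]

    people = []  # (record_id, first, surname, sex, age, day, month, year,
    #              village, household index)
    idx = 0
    for hh_index, size in enumerate(sizes):
        surname = sur_pool[rng.integers(len(sur_pool))]
        village = _VILLAGES[rng.integers(len(_VILLAGES))]
        for _ in range(size):
            record_id = f"R{idx:06d}"
            first = first_pool[rng.integers(len(first_pool))]
            sex = "F" if rng.random() < 0.55 else "M"
            age = _draw_age(rng)
            year = config.reference_year - age
            day = int(rng.integers(1, 29))
            month = int(rng.integers(1, 13))
            people.append((record_id, first, surname, sex, age, day, month,
                           year, village, hh_index))
            idx += 1

    # oldest other member per household
    by_hh: dict[int, list] = {}
    for p in people:
        by_hh.setdefault(p[9], []).append(p)
    oldest_other = {}
    for members in by_hh.values():
        ranked = sorted(members, key=lambda p: (-p[4], p[0]))
        for p in members:
            other = ranked[0] if ranked[0][0] != p[0] else (
                ranked[1] if len(ranked) > 1 else None)
            oldest_other[p[0]] = other

    records = []
    for (record_id, first, surname, sex, age, day, month, year, village,
         hh_index) in people:
        other = oldest_other[record_id]
        rec = PersonRecord(
            record_id=record_id,
            first_name=first,
            surname=surname,
            other_first_name=_mask(
                first_pool[rng.integers(len(first_pool))],
                rng.random() < miss.get("other_first_name", 1.0)),
            sex=sex,  # never missing in the registry
            birth_day=_mask(day, rng.random() < miss.get("birth_day", 1.0)),
            birth_month=_mask(month, rng.random() < miss.get("birth_month", 1.0)),
            birth_year=year,  # never missing in the registry
            village=_mask(village, rng.random() < miss.get("village", 1.0)),
            hh_member_first_name=_mask(
                other[1] if other else None,
                rng.random() < miss.get("hh_member_first_name", 1.0)),
            hh_member_surname=_mask(
                other[2] if other else None,
                rng.random() < miss.get("hh_member_surname", 1.0)),
            national_id=_mask(_new_national_id(rng),
                              rng.random() < miss.get("national_id", 1.0)),
            phone=_mask(_new_phone(rng),
                        rng.random() < miss.get("phone", 1.0)),
        )
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# clinic derivation

def derive_clinic_records(registry: list[PersonRecord],
                          config: GeneratorConfig
                          ) -> tuple[list[PersonRecord], GoldStandard]:
    """Derive the clinic dataset and its ground truth from the registry.

    ``overlap_fraction`` of the ``n_clinic`` records are corrupted copies
    of distinct registry persons (recorded in the GoldStandard); the rest
    are novel walk-in patients drawn from the same name pools.  Clinic
    field completeness follows the clinic column of the missingness
    config.
    """
    config.validate()
    n_true = int(round(config.n_clinic * config.overlap_fraction))
    if n_true > 0 and not registry:
        raise ConfigurationError("registry empty but overlap_fraction > 0")
    if n_true > len(registry):
        raise ConfigurationError(
            f"overlap demand {n_true} exceeds registry size {len(registry)}")
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 202])
    first_pool, sur_pool = load_name_pools()
    miss = config.missingness["clinic"]

    chosen = rng.choice(len(registry), size=n_true, replace=False) if n_true else []
    clinic: list[PersonRecord] = []
    pairs = []
    counter = 0

    def next_id():
        nonlocal counter
        rid = f"C{counter:06d}"
        counter += 1
        return rid

    for reg_idx in chosen:
        src = registry[int(reg_idx)]
        cov = person_covariates(src.record_id, src.birth_year, config)
        age = cov["age"] if cov["age"] is not None else 30
        mult = _corruption_multiplier(age, cov, config)

        first = corrupt_name(src.first_name, config, rng, mult)
        surname = src.surname
        if src.sex == "F" and rng.random() < config.surname_change_rate_female:
            # married name differs from the registry (maiden) surname
            alternatives = [su for su in sur_pool if su != src.surname]
            surname = alternatives[rng.integers(len(alternatives))]
        else:
            surname = corrupt_name(surname, config, rng, mult)

        day, month, year = src.birth_day, src.birth_month, src.birth_year
        slope = config.covariate_effects.get("age_slope_per_decade_over_50", 0.0)
        dob_mult = 1.0 + slope * max(0.0, (age - 50) / 10.0)
        if rng.random() < min(1.0, config.dob_error_rate * dob_mult):
            part = ("day", "month", "year")[rng.integers(3)]
            if part == "day" and day is not None:
                day = int(1 + (day - 1 + int(rng.integers(1, 28))) % 28)
            elif part == "month" and month is not None:
                month = int(1 + (month - 1 + int(rng.integers(1, 12))) % 12)
            elif year is not None:
                year = int(year + rng.choice([-5, -4, -3, -2, -1, 1, 2, 3, 4, 5]))

        village = src.village
        if village is not None and rng.random() < config.village_change_rate:
            # moved, or reported the place of a different residence
            others = [v for v in _VILLAGES if v != village]
            village = others[rng.integers(len(others))]

        hh_first = src.hh_member_first_name
        if hh_first is not None:
            hh_first = corrupt_name(hh_first, config, rng, mult)
        hh_sur = src.hh_member_surname
        if hh_sur is not None:
            hh_sur = corrupt_name(hh_sur, config, rng, mult)

        cid = next_id()
        rec = PersonRecord(
            record_id=cid,
            first_name=first,
            surname=surname,
            other_first_name=_mask(
                src.other_first_name,
                src.other_first_name is not None
                and rng.random() < miss.get("other_first_name", 1.0)),
            sex=_mask(src.sex, rng.random() < miss.get("sex", 1.0)),
            birth_day=_mask(day, day is not None
                            and rng.random() < miss.get("birth_day", 1.0)),
            birth_month=_mask(month, month is not None
                              and rng.random() < miss.get("birth_month", 1.0)),
            birth_year=_mask(year, year is not None
                             and rng.random() < miss.get("birth_year", 1.0)),
            village=_mask(village, village is not None
                          and rng.random() < miss.get("village", 1.0)),
            hh_member_first_name=_mask(
                hh_first, hh_first is not None
                and rng.random() < miss.get("hh_member_first_name", 1.0)),
            hh_member_surname=_mask(
                hh_sur, hh_sur is not None
                and rng.random() < miss.get("hh_member_surname", 1.0)),
            national_id=_mask(src.national_id, src.national_id is not None
                              and rng.random() < miss.get("national_id", 1.0)),
            phone=_mask(src.phone, src.phone is not None
                        and rng.random() < miss.get("phone", 1.0)),
        )
        clinic.append(rec)
        pairs.append((src.record_id, cid))

    for _ in range(config.n_clinic - n_true):
        cid = next_id()
        age = _draw_age(rng)
        rec = PersonRecord(
            record_id=cid,
            first_name=first_pool[rng.integers(len(first_pool))],
            surname=sur_pool[rng.integers(len(sur_pool))],
            other_first_name=_mask(
                first_pool[rng.integers(len(first_pool))],
                rng.random() < miss.get("other_first_name", 1.0)),
            sex=_mask("F" if rng.random() < 0.6 else "M",
                      rng.random() < miss.get("sex", 1.0)),
            birth_day=_mask(int(rng.integers(1, 29)),
                            rng.random() < miss.get("birth_day", 1.0)),
            birth_month=_mask(int(rng.integers(1, 13)),
                              rng.random() < miss.get("birth_month", 1.0)),
            birth_year=_mask(config.reference_year - age,
                             rng.random() < miss.get("birth_year", 1.0)),
            village=_mask(_VILLAGES[rng.integers(len(_VILLAGES))],
                          rng.random() < miss.get("village", 1.0)),
            hh_member_first_name=_mask(
                first_pool[rng.integers(len(first_pool))],
                rng.random() < miss.get("hh_member_first_name", 1.0)),
            hh_member_surname=_mask(
                sur_pool[rng.integers(len(sur_pool))],
                rng.random() < miss.get("hh_member_surname", 1.0)),
            national_id=_mask(_new_national_id(rng, clinic_only=True),
                              rng.random() < miss.get("national_id", 1.0)),
            phone=_mask(_new_phone(rng),
                        rng.random() < miss.get("phone", 1.0)),
        )
        clinic.append(rec)

    # shuffle so true-match records are not a prefix of the file
    order = rng.permutation(len(clinic))
    clinic = [clinic[int(i)] for i in order]
    return clinic, GoldStandard(pairs=frozenset(pairs))


def generate_datasets(config: GeneratorConfig
                      ) -> tuple[list[PersonRecord], list[PersonRecord],
                                 GoldStandard]:
    """Convenience wrapper: registry, clinic and ground truth in one call."""
    registry = generate_registry(config)
    clinic, gold = derive_clinic_records(registry, config)
    return registry, clinic, gold


def covariate_table(registry: list[PersonRecord], gold: GoldStandard,
                    config: GeneratorConfig,
                    linked_pairs: Optional[set] = None) -> pd.DataFrame:
    """Per gold-standard individual: covariates plus matched indicators.

    ``matched_strict`` requires the linkage to have recovered the true
    pair; ``matched_any`` only that the clinic record was linked to some
    registry record.
    """
    by_id = {r.record_id: r for r in registry}
    linked_pairs = set() if linked_pairs is None else set(linked_pairs)
    linked_clinic = {c for _, c in linked_pairs}
    rows = []
    for reg_id, clin_id in sorted(gold.pairs):
        rec = by_id[reg_id]
        cov = person_covariates(reg_id, rec.birth_year, config)
        rows.append({
            "registry_id": reg_id,
            "clinic_id": clin_id,
            "sex": rec.sex,
            "age_group": cov["age_group"],
            "ethnicity": cov["ethnicity"],
            "residence": cov["residence"],
            "education": cov["education"],
            "employment": cov["employment"],
            "wealth_quintile": cov["wealth_quintile"],
            "matched_strict": int((reg_id, clin_id) in linked_pairs),
            "matched_any": int(clin_id in linked_clinic),
        })
    return pd.DataFrame(rows)
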