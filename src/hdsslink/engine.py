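"""Fellegi-Sunter core: comparison vectors, EM estimation, weight scoring,
threshold selection and the deterministic pre-linkage stage.

For each candidate pair and each linking field i the comparison outcome is
agree / disagree / missing.  Under the Fellegi-Sunter model the field
carries an agreement probability m_i among true matches and u_i among
non-matches; a pair's matching score is the sum over non-missing fields of
log2(m_i/u_i) on agreement and log2((1-m_i)/(1-u_i)) on disagreement
(missing fields contribute zero weight).  m_i, u_i and the mixture
proportion of true matches are estimated from the candidate pairs
themselves with an EM algorithm for a two-class latent mixture assuming
conditional independence of fields given match status.  The estimated
match proportion then fixes a rank-based acceptance threshold: with M =
round(p_hat * n_pairs) expected matches, the threshold is the M-th largest
score and pairs scoring at or above it are accepted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .comparators import (AgreementRule, EXACT, Outcome, agree,
                          agree_normalized, normalize)
from .records import IDENTIFIER_FIELDS, PersonRecord, records_to_frame

#: Encoding of outcomes in comparison matrices.
AGREE, DISAGREE, MISSING = np.int8(1), np.int8(0), np.int8(-1)

_OUTCOME_CODE = {Outcome.AGREE: AGREE, Outcome.DISAGREE: DISAGREE,
                 Outcome.MISSING: MISSING}
_CODE_OUTCOME = {int(AGREE): Outcome.AGREE, int(DISAGREE): Outcome.DISAGREE,
                 int(MISSING): Outcome.MISSING}

#: Fields compared with a string rule; all other fields compare exactly.
NAME_FIELDS = ("first_name", "surname", "other_first_name",
               "hh_member_first_name", "hh_member_surname")


class FieldConfigurationError(ValueError):
    """Unknown linking field or rule/field mismatch."""


@dataclass(frozen=True)
class ComparisonVector:
    """Field-wise agreement outcomes for one candidate record pair."""

    pair: tuple
    outcomes: dict

    def codes(self, fields: Sequence[str]) -> np.ndarray:
        return np.array([_OUTCOME_CODE[self.outcomes[f]] for f in fields],
                        dtype=np.int8)


@dataclass(frozen=True)
class ScoredPair:
    """A candidate pair with its total matching weight (in bits)."""

    pair: tuple
    score: float
    classification: Optional[str] = None  # match | nonmatch | review


@dataclass
class EMSettings:
    init_m: float = 0.9
    init_u: float = 0.1
    init_p: float = 0.01
    tol: float = 1e-6
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class MatchParameters:
    """Per-field m/u probabilities and the estimated match proportion."""

    fields: tuple
    m: np.ndarray
    u: np.ndarray
    p_hat: float
    converged: bool = True
    n_iter: int = 0
    loglik: list = dc_field(default_factory=list)
    flags: list = dc_field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "fields": list(self.fields),
            "m": {f: float(v) for f, v in zip(self.fields, self.m)},
            "u": {f: float(v) for f, v in zip(self.fields, self.u)},
            "p_hat": float(self.p_hat),
            "converged": self.converged,
            "n_iter": self.n_iter,
            "flags": list(self.flags),
        }


def default_rules(fields: Sequence[str],
                  name_rule: AgreementRule) -> dict:
    """One rule per field: ``name_rule`` on name fields, exact elsewhere."""
    rules = {}
    for f in fields:
        if f not in IDENTIFIER_FIELDS:
            raise FieldConfigurationError(f"unknown linking field {f!r}")
        rules[f] = name_rule if f in NAME_FIELDS else EXACT
    return rules


def compare_pair(rec_a: PersonRecord, rec_b: PersonRecord,
                 fields: Sequence[str], rules: dict) -> ComparisonVector:
    """Compare one record pair field-by-field.

    Date parts are three separate exact-match fields; missingness on
    either side propagates as a missing outcome.
    """
    outcomes = {}
    for f in fields:
        if f not in IDENTIFIER_FIELDS:
            raise FieldConfigurationError(f"unknown linking field {f!r}")
        rule = rules.get(f, EXACT)
        va, vb = getattr(rec_a, f), getattr(rec_b, f)
        va = None if va is None else str(va)
        vb = None if vb is None else str(vb)
        outcomes[f] = agree(va, vb, rule)
    return ComparisonVector(pair=(rec_a.record_id, rec_b.record_id),
                            outcomes=outcomes)


def _norm_series(s: pd.Series) -> pd.Series:
    uniq = s.dropna().unique()
    mapping = {v: normalize(str(v)) for v in uniq}
    return s.map(mapping)


def _compare_arrays(a: pd.Series, b: pd.Series,
                    rule: AgreementRule) -> np.ndarray:
    """Vectorized three-state comparison of two aligned value series."""
    a = a.reset_index(drop=True)
    b = b.reset_index(drop=True)
    out = np.full(len(a), MISSING, dtype=np.int8)
    present = a.notna().to_numpy() & b.notna().to_numpy()
    if not present.any():
        return out
    an = _norm_series(a[present].astype(str))
    bn = _norm_series(b[present].astype(str))
    if rule.kind.value == "exact":
        res = (an.to_numpy() == bn.to_numpy())
    else:
        # evaluate the rule once per distinct value pair (cached globally)
        key = pd.Series(list(zip(an, bn)))
        codes, uniques = pd.factorize(key)
        verdicts = np.array(
            [agree_normalized(x, y, rule) for x, y in uniques])
        res = verdicts[codes]
    out[np.flatnonzero(present)] = np.where(res, AGREE, DISAGREE)
    return out


def compare_many(registry, clinic, pairs: Sequence[tuple],
                 fields: Sequence[str], rules: dict) -> np.ndarray:
    """Comparison matrix (n_pairs x n_fields, int8) for candidate pairs.

    ``registry`` / ``clinic`` may be record lists or DataFrames in the
    standard column layout.
    """
    reg = registry if isinstance(registry, pd.DataFrame) else records_to_frame(registry)
    cli = clinic if isinstance(clinic, pd.DataFrame) else records_to_frame(clinic)
    reg = reg.set_index("record_id", drop=False)
    cli = cli.set_index("record_id", drop=False)
    for f in fields:
        if f not in IDENTIFIER_FIELDS:
            raise FieldConfigurationError(f"unknown linking field {f!r}")
    if not pairs:
        return np.empty((0, len(fields)), dtype=np.int8)
    rid = [p[0] for p in pairs]
    cid = [p[1] for p in pairs]
    reg_rows = reg.loc[rid]
    cli_rows = cli.loc[cid]
    cols = []
    for f in fields:
        cols.append(_compare_arrays(reg_rows[f], cli_rows[f],
                                    rules.get(f, EXACT)))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# EM estimation

def _mixture_loglik(patterns, counts, m, u, p) -> float:
    log_m = _pattern_loglik(patterns, m)
    log_u = _pattern_loglik(patterns, u)
    mix = np.logaddexp(np.log(p) + log_m, np.log1p(-p) + log_u)
    return float(np.dot(counts, mix))


def _pattern_loglik(patterns: np.ndarray, prob: np.ndarray) -> np.ndarray:
    """Log-likelihood of each pattern row under per-field agreement
    probabilities, skipping missing outcomes."""
    agree_t = np.log(prob)[None, :]
    disagree_t = np.log1p(-prob)[None, :]
    terms = np.where(patterns == AGREE, agree_t,
                     np.where(patterns == DISAGREE, disagree_t, 0.0))
    return terms.sum(axis=1)


def em_fit_matrix(matrix: np.ndarray, fields: Sequence[str],
                  settings: Optional[EMSettings] = None) -> MatchParameters:
    """Fit the two-class mixture to a comparison matrix.

    The E-step computes each pair's posterior probability of being a true
    match; the M-step re-estimates m_i, u_i (over non-missing outcomes
    only) and the mixture proportion.  Parameters are clamped to
    [1e-6, 1-1e-6].  The observed-data log-likelihood is recorded per
    iteration and is non-decreasing.
    """
    settings = settings or EMSettings()
    if matrix.size == 0:
        raise ValueError("em_fit requires at least one comparison vector")
    matrix = np.asarray(matrix, dtype=np.int8)
    k = matrix.shape[1]
    patterns, counts = np.unique(matrix, axis=0, return_counts=True)
    flags: list[str] = []
    if len(patterns) < 2:
        flags.append("non_identifiable")
        m = np.full(k, settings.init_m)
        u = np.full(k, settings.init_u)
        return MatchParameters(tuple(fields), m, u, settings.init_p,
                               converged=False, n_iter=0, flags=flags)

    lo, hi = 1e-6, 1 - 1e-6
    m = np.full(k, float(settings.init_m))
    u = np.full(k, float(settings.init_u))
    p = float(settings.init_p)
    counts_f = counts.astype(float)
    n = counts_f.sum()
    logliks: list[float] = []
    converged = False
    it = 0
    for it in range(1, settings.max_iter + 1):
        log_m = _pattern_loglik(patterns, m)
        log_u = _pattern_loglik(patterns, u)
        log_num = np.log(p) + log_m
        log_den = np.logaddexp(log_num, np.log1p(-p) + log_u)
        logliks.append(float(np.dot(counts_f, log_den)))
        resp = np.exp(log_num - log_den)  # P(match | pattern)

        w_match = resp * counts_f
        w_non = (1.0 - resp) * counts_f
        agree_mask = (patterns == AGREE)
        known_mask = (patterns != MISSING)
        m_new = ((w_match[:, None] * agree_mask).sum(axis=0)
                 / np.maximum((w_match[:, None] * known_mask).sum(axis=0), 1e-300))
        u_new = ((w_non[:, None] * agree_mask).sum(axis=0)
                 / np.maximum((w_non[:, None] * known_mask).sum(axis=0), 1e-300))
        p_new = float(w_match.sum() / n)
        m_new = np.clip(m_new, lo, hi)
        u_new = np.clip(u_new, lo, hi)
        p_new = min(max(p_new, lo), hi)

        delta = max(np.max(np.abs(m_new - m)), np.max(np.abs(u_new - u)),
                    abs(p_new - p))
        m, u, p = m_new, u_new, p_new
        if delta < settings.tol:
            converged = True
            break
    if not converged:
        flags.append("max_iter_reached")

    # relabel so the match class has the higher mean agreement probability
    if m.mean() < u.mean():
        m, u = u, m
        p = 1.0 - p
        flags.append("classes_relabelled")
    for f, mi, ui in zip(fields, m, u):
        if mi <= ui:
            flags.append(f"m_not_above_u:{f}")

    return MatchParameters(tuple(fields), m, u, p, converged=converged,
                           n_iter=it, loglik=logliks, flags=flags)


def em_fit(vectors: Iterable[ComparisonVector],
           settings: Optional[EMSettings] = None,
           fields: Optional[Sequence[str]] = None) -> MatchParameters:
    """Fit match parameters from ComparisonVector objects."""
    vectors = list(vectors)
    if not vectors:
        raise ValueError("em_fit requires at least one comparison vector")
    if fields is None:
        fields = tuple(vectors[0].outcomes.keys())
    matrix = np.stack([v.codes(fields) for v in vectors])
    return em_fit_matrix(matrix, fields, settings)


# ---------------------------------------------------------------------------
# scoring and threshold

def field_weight(m_i: float, u_i: float, outcome: Outcome) -> float:
    """Per-field weight in bits: log2(m/u) on agreement,
    log2((1-m)/(1-u)) on disagreement, 0 on missing."""
    if not (0.0 < m_i < 1.0 and 0.0 < u_i < 1.0):
        raise ValueError("m and u must lie strictly inside (0, 1)")
    if outcome is Outcome.AGREE:
        return math.log2(m_i / u_i)
    if outcome is Outcome.DISAGREE:
        return math.log2((1.0 - m_i) / (1.0 - u_i))
    return 0.0


def score_matrix(matrix: np.ndarray, params: MatchParameters) -> np.ndarray:
    """Total matching weight for each row of a comparison matrix."""
    matrix = np.asarray(matrix, dtype=np.int8)
    if matrix.shape[1] != len(params.fields):
        raise FieldConfigurationError(
            "comparison matrix and parameters disagree on field count")
    agree_w = np.log2(params.m / params.u)[None, :]
    disagree_w = np.log2((1.0 - params.m) / (1.0 - params.u))[None, :]
    terms = np.where(matrix == AGREE, agree_w,
                     np.where(matrix == DISAGREE, disagree_w, 0.0))
    return terms.sum(axis=1)


def score_pairs(vectors: Iterable[ComparisonVector],
                params: MatchParameters) -> list[ScoredPair]:
    vectors = list(vectors)
    for v in vectors:
        if set(v.outcomes) != set(params.fields):
            raise FieldConfigurationError(
                f"vector fields {sorted(v.outcomes)} do not match "
                f"parameter fields {sorted(params.fields)}")
    if not vectors:
        return []
    matrix = np.stack([v.codes(params.fields) for v in vectors])
    scores = score_matrix(matrix, params)
    return [ScoredPair(pair=v.pair, score=float(s))
            for v, s in zip(vectors, scores)]


def select_threshold(scores: Sequence[float], p_hat: float,
                     n_pairs: int) -> float:
    """Rank-based acceptance threshold.

    With M = round(p_hat * n_pairs) expected true matches, the threshold
    is the M-th largest score; pairs scoring >= threshold are accepted.
    M = 0 yields +inf (nothing auto-accepted).
    """
    scores = np.asarray(list(scores), dtype=float)
    if scores.size == 0:
        raise ValueError("select_threshold requires at least one score")
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError("p_hat must lie in [0, 1]")
    m_expected = int(round(p_hat * n_pairs))
    if m_expected <= 0:
        return math.inf
    m_expected = min(m_expected, scores.size)
    return float(np.sort(scores)[::-1][m_expected - 1])


# ---------------------------------------------------------------------------
# deterministic stage

@dataclass(frozen=True)
class DeterministicLinks:
    """Output of the deterministic stage: links plus flagged ID collisions."""

    links: frozenset
    collisions: tuple


def normalize_phone(phone: str) -> Optional[str]:
    """Strip non-digits and a leading country code (27 / 0027 / +27)."""
    digits = "".join(ch for ch in str(phone) if ch.isdigit())
    if digits.startswith("0027"):
        digits = "0" + digits[4:]
    elif digits.startswith("27") and len(digits) == 11:
        digits = "0" + digits[2:]
    return digits or None


def normalize_id(national_id: str) -> Optional[str]:
    out = "".join(str(national_id).split())
    return out or None


def _unique_value_map(values: dict) -> tuple[dict, list]:
    """Map value -> record_id for values occurring exactly once; values
    shared by several records are returned as collisions."""
    seen: dict = {}
    for rec_id, v in values.items():
        seen.setdefault(v, []).append(rec_id)
    unique = {v: ids[0] for v, ids in seen.items() if len(ids) == 1}
    collisions = [(v, tuple(sorted(ids))) for v, ids in seen.items()
                  if len(ids) > 1]
    return unique, collisions


def deterministic_link(registry: Sequence[PersonRecord],
                       clinic: Sequence[PersonRecord]) -> DeterministicLinks:
    """Link records sharing a national ID, or a telephone number together
    with the first name.

    Values appearing on multiple records of one side are ID collisions:
    they are flagged and produce no link.  The result is one-to-one.
    """
    collisions: list = []

    reg_ids = {r.record_id: normalize_id(r.national_id)
               for r in registry if r.national_id is not None}
    cli_ids = {r.record_id: normalize_id(r.national_id)
               for r in clinic if r.national_id is not None}
    reg_map, col_r = _unique_value_map({k: v for k, v in reg_ids.items() if v})
    cli_map, col_c = _unique_value_map({k: v for k, v in cli_ids.items() if v})
    collisions.extend(("national_id",) + c for c in col_r + col_c)

    links: set[tuple] = set()
    linked_reg: set = set()
    linked_cli: set = set()
    for value, cli_rec in cli_map.items():
        if value in reg_map:
            links.add((reg_map[value], cli_rec))
            linked_reg.add(reg_map[value])
            linked_cli.add(cli_rec)

    def phone_key(rec: PersonRecord):
        if rec.phone is None or rec.first_name is None:
            return None
        ph = normalize_phone(rec.phone)
        if ph is None:
            return None
        return (ph, normalize(rec.first_name))

    reg_ph = {r.record_id: phone_key(r) for r in registry
              if phone_key(r) is not None and r.record_id not in linked_reg}
    cli_ph = {r.record_id: phone_key(r) for r in clinic
              if phone_key(r) is not None and r.record_id not in linked_cli}
    reg_pmap, col_pr = _unique_value_map(reg_ph)
    cli_pmap, col_pc = _unique_value_map(cli_ph)
    collisions.extend(("phone_first_name",) + c for c in col_pr + col_pc)
    for value, cli_rec in cli_pmap.items():
        if value in reg_pmap:
            links.add((reg_pmap[value], cli_rec))

    return DeterministicLinks(links=frozenset(links),
                              collisions=tuple(collisions))
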