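"""String comparison primitives and per-field agreement rules.

Linking names across a population registry and a clinic register must
tolerate typographical errors and spelling variation, so besides exact
equality the package offers the Jaro-Winkler similarity and two phonetic
encoders (classic American Soundex and Double Metaphone), plus a combined
rule that agrees when any of the three does.  All comparisons case-fold,
strip accents and trim whitespace first.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from typing import Optional

from ._metaphone import double_metaphone as _double_metaphone


class Outcome(str, Enum):
    """Three-state field comparison outcome; missing propagates."""

    AGREE = "agree"
    DISAGREE = "disagree"
    MISSING = "missing"


@lru_cache(maxsize=1 << 17)
def normalize(s: str) -> str:
    """Case-fold, strip accents and trim surrounding whitespace."""
    s = unicodedata.normalize("NFKD", s)
    s = "".join(ch for ch in s if not unicodedata.combining(ch))
    return s.strip().upper()


def jaro(a: str, b: str) -> float:
    """Jaro similarity of two non-empty strings (no prefix boost)."""
    if a == b:
        return 1.0
    la, lb = len(a), len(b)
    window = max(la, lb) // 2 - 1
    if window < 0:
        window = 0
    a_flags = [False] * la
    b_flags = [False] * lb
    matches = 0
    for i, ca in enumerate(a):
        lo = max(0, i - window)
        hi = min(lb, i + window + 1)
        for j in range(lo, hi):
            if not b_flags[j] and b[j] == ca:
                a_flags[i] = b_flags[j] = True
                matches += 1
                break
    if matches == 0:
        return 0.0
    # transpositions: matched characters out of order, counted in halves
    b_matched = [b[j] for j in range(lb) if b_flags[j]]
    transpositions = sum(
        1 for ca, cb in zip((a[i] for i in range(la) if a_flags[i]), b_matched)
        if ca != cb
    ) // 2
    m = matches
    return (m / la + m / lb + (m - transpositions) / m) / 3.0


def jaro_winkler(a: str, b: str, prefix_scale: float = 0.1,
                 max_prefix: int = 4) -> float:
    """Jaro-Winkler similarity: Jaro plus a boost for a shared prefix.

    The boost adds ``prefix_scale`` per shared leading character (at most
    ``max_prefix`` of them) times the remaining distance to 1.  Inputs are
    normalized before comparison; empty inputs are rejected because the
    caller, not the comparator, owns the missing-data policy.
    """
    a = normalize(a)
    b = normalize(b)
    if not a or not b:
        raise ValueError("jaro_winkler requires non-empty strings")
    j = jaro(a, b)
    prefix = 0
    for ca, cb in zip(a, b):
        if ca != cb or prefix >= max_prefix:
            break
        prefix += 1
    return j + prefix * prefix_scale * (1.0 - j)


@lru_cache(maxsize=1 << 19)
def _jw_cached(a: str, b: str) -> float:
    """Jaro-Winkler on already-normalized strings (symmetric cache key)."""
    if b < a:
        a, b = b, a
    j = jaro(a, b)
    prefix = 0
    for ca, cb in zip(a, b):
        if ca != cb or prefix >= 4:
            break
        prefix += 1
    return j + prefix * 0.1 * (1.0 - j)


_SOUNDEX_CODES = {}
for letters, digit in (("BFPV", "1"), ("CGJKQSXZ", "2"), ("DT", "3"),
                       ("L", "4"), ("MN", "5"), ("R", "6")):
    for ch in letters:
        _SOUNDEX_CODES[ch] = digit


@lru_cache(maxsize=1 << 17)
def soundex(s: str) -> str:
    """Classic American Soundex: initial letter + 3 digits, zero-padded.

    H and W are transparent (a consonant on each side of them counts as
    adjacent); vowels separate repeated codes.
    """
    s = normalize(s)
    letters = [ch for ch in s if ch.isalpha()]
    if not letters:
        raise ValueError("soundex requires at least one alphabetic character")
    first = letters[0]
    code = [first]
    prev = _SOUNDEX_CODES.get(first, "")
    for ch in letters[1:]:
        if ch in "HW":
            continue
        digit = _SOUNDEX_CODES.get(ch, "")
        if digit and digit != prev:
            code.append(digit)
            if len(code) == 4:
                break
        prev = digit
    return "".join(code).ljust(4, "0")


@lru_cache(maxsize=65536)
def double_metaphone(s: str) -> tuple[str, str]:
    """Double Metaphone (primary, alternate) codes, capped at 4 characters."""
    s = normalize(s)
    if not any(ch.isalpha() for ch in s):
        raise ValueError(
            "double_metaphone requires at least one alphabetic character")
    return _double_metaphone(s)


class RuleKind(str, Enum):
    EXACT = "exact"
    JW_THRESHOLD = "jw_threshold"
    DOUBLE_METAPHONE = "double_metaphone"
    SOUNDEX = "soundex"
    COMBINED = "combined"


@dataclass(frozen=True)
class AgreementRule:
    """A per-field agreement rule.

    ``combined`` agrees when the Jaro-Winkler score reaches ``jw_cutoff``
    OR the Double Metaphone codes agree OR the Soundex codes agree.
    """

    kind: RuleKind
    jw_cutoff: Optional[float] = None

    def __post_init__(self) -> None:
        needs_cutoff = self.kind in (RuleKind.JW_THRESHOLD, RuleKind.COMBINED)
        if needs_cutoff and self.jw_cutoff is None:
            raise ValueError(f"rule {self.kind.value} requires jw_cutoff")
        if not needs_cutoff and self.jw_cutoff is not None:
            raise ValueError(f"rule {self.kind.value} takes no jw_cutoff")
        if self.jw_cutoff is not None and not 0.0 <= self.jw_cutoff <= 1.0:
            raise ValueError("jw_cutoff must lie in [0, 1]")

    @classmethod
    def parse(cls, spec: str) -> "AgreementRule":
        """Parse the rule vocabulary: exact | jw:<cutoff> | dm | soundex |
        combined:<cutoff>."""
        spec = spec.strip().lower()
        if spec == "exact":
            return cls(RuleKind.EXACT)
        if spec == "dm":
            return cls(RuleKind.DOUBLE_METAPHONE)
        if spec == "soundex":
            return cls(RuleKind.SOUNDEX)
        if spec.startswith("jw:"):
            return cls(RuleKind.JW_THRESHOLD, jw_cutoff=float(spec[3:]))
        if spec.startswith("combined:"):
            return cls(RuleKind.COMBINED, jw_cutoff=float(spec[9:]))
        raise ValueError(f"unknown agreement rule {spec!r}")

    def __str__(self) -> str:
        if self.kind is RuleKind.JW_THRESHOLD:
            return f"jw:{self.jw_cutoff:g}"
        if self.kind is RuleKind.COMBINED:
            return f"combined:{self.jw_cutoff:g}"
        return {RuleKind.EXACT: "exact", RuleKind.DOUBLE_METAPHONE: "dm",
                RuleKind.SOUNDEX: "soundex"}[self.kind]


EXACT = AgreementRule(RuleKind.EXACT)


def _dm_agree(a: str, b: str) -> bool:
    pa, aa = double_metaphone(a)
    pb, ab = double_metaphone(b)
    return pa == pb or pa == ab or pb == aa


@lru_cache(maxsize=1 << 19)
def agree_normalized(na: str, nb: str, rule: AgreementRule) -> bool:
    """Rule verdict on already-normalized, non-empty values."""
    if rule.kind is RuleKind.EXACT:
        return na == nb
    if rule.kind is RuleKind.JW_THRESHOLD:
        return _jw_cached(na, nb) >= rule.jw_cutoff
    if rule.kind is RuleKind.DOUBLE_METAPHONE:
        return _dm_agree(na, nb)
    if rule.kind is RuleKind.SOUNDEX:
        return soundex(na) == soundex(nb)
    if rule.kind is RuleKind.COMBINED:
        return (na == nb or soundex(na) == soundex(nb) or _dm_agree(na, nb)
                or _jw_cached(na, nb) >= rule.jw_cutoff)
    raise ValueError(f"unhandled rule kind {rule.kind}")  # pragma: no cover


def agree(a: Optional[str], b: Optional[str], rule: AgreementRule) -> Outcome:
    """Compare two field values under a rule; missing on either side
    propagates as :attr:`Outcome.MISSING`."""
    if a is None or b is None:
        return Outcome.MISSING
    na, nb = normalize(str(a)), normalize(str(b))
    if not na or not nb:
        return Outcome.MISSING
    return Outcome.AGREE if agree_normalized(na, nb, rule) else Outcome.DISAGREE
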