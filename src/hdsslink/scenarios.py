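"""Linkage scenarios: identifier sets, string rules, the hybrid
deterministic-then-probabilistic flow, and simulated clerical review.

Twenty built-in scenarios form a grid.  S1-S6 link on routinely collected
identifiers (first name, surname, day/month/year of birth, village) under
six name-comparison rules (exact, JW >= 0.7, JW >= 0.9, Double Metaphone,
Soundex, and the combination "JW >= 0.9 or DM or Soundex").  S7-S12 add
another household member's first name; S13-S15 add the household member's
surname as well (JW >= 0.9 / DM / Soundex only).  S16 prepends a
deterministic stage (national ID, or telephone + first name) to the best
probabilistic scenario (S12); S17-S20 add clerical review of 5/10/15/20%
of the scored pairs nearest the acceptance threshold, adjudicated by two
simulated reviewers with a third breaking disagreements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .blocking import (BlockingScheme, DEFAULT_SCHEMES, block_pairs,
                       combine_block_results)
from .comparators import AgreementRule
from .engine import (EMSettings, MatchParameters, ScoredPair, compare_many,
                     default_rules, deterministic_link, em_fit_matrix,
                     score_matrix, select_threshold)
from .records import GoldStandard, PersonRecord, records_to_frame

ROUTINE_FIELDS = ("first_name", "surname", "birth_day", "birth_month",
                  "birth_year", "village")

_RULE_COLUMNS = ("exact", "jw:0.7", "jw:0.9", "dm", "soundex", "combined:0.9")


class ScenarioConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ScenarioSpec:
    """One linkage scenario: identifier set, name rule, stages."""

    id: str
    field_set: tuple
    name_rule: AgreementRule
    deterministic_stage: bool = False
    clerical_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.clerical_fraction <= 1.0:
            raise ScenarioConfigurationError(
                "clerical_fraction must lie in [0, 1]")


def builtin_scenarios() -> list[ScenarioSpec]:
    """The twenty built-in scenarios S1-S20."""
    specs: list[ScenarioSpec] = []
    for i, rule in enumerate(_RULE_COLUMNS, start=1):
        specs.append(ScenarioSpec(
            id=f"S{i}", field_set=ROUTINE_FIELDS,
            name_rule=AgreementRule.parse(rule)))
    hh_first = ROUTINE_FIELDS + ("hh_member_first_name",)
    for i, rule in enumerate(_RULE_COLUMNS, start=7):
        specs.append(ScenarioSpec(
            id=f"S{i}", field_set=hh_first,
            name_rule=AgreementRule.parse(rule)))
    hh_both = hh_first + ("hh_member_surname",)
    for i, rule in zip((13, 14, 15), ("jw:0.9", "dm", "soundex")):
        specs.append(ScenarioSpec(
            id=f"S{i}", field_set=hh_both,
            name_rule=AgreementRule.parse(rule)))
    # S16: hybrid — deterministic stage, then the best probabilistic
    # scenario's settings (S12)
    specs.append(ScenarioSpec(
        id="S16", field_set=hh_first,
        name_rule=AgreementRule.parse("combined:0.9"),
        deterministic_stage=True))
    for i, frac in zip((17, 18, 19, 20), (0.05, 0.10, 0.15, 0.20)):
        specs.append(ScenarioSpec(
            id=f"S{i}", field_set=hh_first,
            name_rule=AgreementRule.parse("combined:0.9"),
            deterministic_stage=True, clerical_fraction=frac))
    return specs


def get_scenario(scenario_id: str) -> ScenarioSpec:
    for spec in builtin_scenarios():
        if spec.id == scenario_id.upper():
            return spec
    raise ScenarioConfigurationError(f"unknown scenario {scenario_id!r}")


@dataclass
class LinkageResult:
    """Full output of one scenario run."""

    links: set
    scored: list
    threshold: float
    provenance: dict  # pair -> deterministic | probabilistic | clerical
    params: dict = dc_field(default_factory=dict)  # scheme -> MatchParameters
    collisions: tuple = ()
    review_decisions: dict = dc_field(default_factory=dict)

    def links_by_provenance(self, kind: str) -> set:
        return {p for p, k in self.provenance.items() if k == kind}


def clerical_queue(scored: Sequence[ScoredPair], threshold: float,
                   fraction: float) -> list[ScoredPair]:
    """Pairs nearest the threshold selected for human review.

    Half the requested volume comes from each side of the threshold by
    rank (rounded up per side); if one side runs out the other side
    fills in.  The queue is ordered by |score - threshold|.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ScenarioConfigurationError("fraction must lie in [0, 1]")
    scored = list(scored)
    n = len(scored)
    if fraction == 0.0 or n == 0:
        return []
    k_side = math.ceil(fraction * n / 2.0)
    if math.isinf(threshold):
        # nothing auto-accepted: review the top-scoring pairs
        ordered = sorted(scored, key=lambda sp: (-sp.score, sp.pair))
        return ordered[:min(n, 2 * k_side)]
    above = sorted((sp for sp in scored if sp.score >= threshold),
                   key=lambda sp: (sp.score - threshold, sp.pair))
    below = sorted((sp for sp in scored if sp.score < threshold),
                   key=lambda sp: (threshold - sp.score, sp.pair))
    take_above = above[:k_side]
    take_below = below[:k_side]
    target = min(n, 2 * k_side)
    if len(take_above) + len(take_below) < target:
        if len(take_above) < k_side:
            take_below = below[:target - len(take_above)]
        else:
            take_above = above[:target - len(take_below)]
    queue = take_above + take_below
    queue.sort(key=lambda sp: (abs(sp.score - threshold), sp.pair))
    return queue


def simulate_review(queue: Sequence[ScoredPair], truth: GoldStandard,
                    reviewer_error: float, seed: int) -> dict:
    """Simulate two independent reviewers plus an adjudicator.

    Each reviewer reports the true status flipped with probability
    ``reviewer_error``; on disagreement a third reviewer with the same
    error model decides.  Returns pair -> bool (match decision).
    """
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 733])
    gold_pairs = truth.pairs
    decisions: dict[tuple, bool] = {}
    for sp in queue:
        true_status = sp.pair in gold_pairs
        r1 = true_status ^ (rng.random() < reviewer_error)
        r2 = true_status ^ (rng.random() < reviewer_error)
        if r1 == r2:
            decisions[sp.pair] = bool(r1)
        else:
            decisions[sp.pair] = bool(
                true_status ^ (rng.random() < reviewer_error))
    return decisions


def run_scenario(spec: ScenarioSpec,
                 registry: Sequence[PersonRecord],
                 clinic: Sequence[PersonRecord],
                 truth: Optional[GoldStandard] = None,
                 seed: int = 0,
                 reference_year: int = 2010,
                 schemes: Sequence[BlockingScheme] = DEFAULT_SCHEMES,
                 em_settings: Optional[EMSettings] = None,
                 reviewer_error: float = 0.0) -> LinkageResult:
    """Execute one scenario end to end.

    The optional deterministic stage links on national ID or telephone +
    first name and removes linked records from the probabilistic stage.
    Then, per blocking scheme: candidate pairs -> comparison vectors ->
    EM -> scores -> rank threshold -> accepted pairs.  Block outputs are
    unioned, deduplicated to one registry record per clinic record, and
    optionally passed through simulated clerical review.
    """
    if spec.clerical_fraction > 0 and truth is None:
        raise ScenarioConfigurationError(
            f"scenario {spec.id} needs ground truth for clerical review")

    reg_df = records_to_frame(registry)
    cli_df = records_to_frame(clinic)
    provenance: dict[tuple, str] = {}
    collisions: tuple = ()

    det_links: frozenset = frozenset()
    if spec.deterministic_stage:
        det = deterministic_link(registry, clinic)
        det_links = det.links
        collisions = det.collisions
        linked_reg = {r for r, _ in det_links}
        linked_cli = {c for _, c in det_links}
        reg_df = reg_df[~reg_df["record_id"].isin(linked_reg)]
        cli_df = cli_df[~cli_df["record_id"].isin(linked_cli)]
        for pair in det_links:
            provenance[pair] = "deterministic"

    rules = default_rules(spec.field_set, spec.name_rule)
    per_block_accepted: list[list[ScoredPair]] = []
    all_scored: dict[tuple, float] = {}
    params_by_scheme: dict[str, MatchParameters] = {}
    thresholds: list[float] = []

    for scheme in schemes:
        scheme = BlockingScheme.parse(scheme)
        pairs = sorted(block_pairs(reg_df, cli_df, scheme,
                                   reference_year=reference_year))
        if not pairs:
            continue
        matrix = compare_many(reg_df, cli_df, pairs, spec.field_set, rules)
        params = em_fit_matrix(matrix, spec.field_set, em_settings)
        params_by_scheme[scheme.value] = params
        if "non_identifiable" in params.flags:
            continue
        # a credible match class agrees at least as often as chance on
        # every identifier; strictly m < u on some field means the
        # "match" class is an artifact of correlated chance agreement
        # (no true matches in the block) — accept nothing from it
        if bool((params.m < params.u).any()):
            params.flags.append("degenerate_block_skipped")
            continue
        scores = score_matrix(matrix, params)
        threshold = select_threshold(scores, params.p_hat, len(pairs))
        thresholds.append(threshold)
        accepted = [ScoredPair(pair=p, score=float(s), classification="match")
                    for p, s in zip(pairs, scores) if s >= threshold]
        per_block_accepted.append(accepted)
        for p, s in zip(pairs, scores):
            if p not in all_scored or s > all_scored[p]:
                all_scored[p] = float(s)

    auto_links = combine_block_results(per_block_accepted)
    finite = [t for t in thresholds if not math.isinf(t)]
    threshold_eff = min(finite) if finite else math.inf

    scored_all = [ScoredPair(pair=p, score=s)
                  for p, s in sorted(all_scored.items())]

    review_decisions: dict = {}
    if spec.clerical_fraction > 0:
        queue = clerical_queue(scored_all, threshold_eff,
                               spec.clerical_fraction)
        review_decisions = simulate_review(queue, truth, reviewer_error, seed)
        queued = set(review_decisions)
        # automatic classification is suspended for queued pairs
        kept_auto = [sp for sp in auto_links if sp.pair not in queued]
        clerical_accept = [ScoredPair(pair=p, score=all_scored[p],
                                      classification="match")
                           for p, dec in review_decisions.items() if dec]
        by_clinic: dict = {}
        for sp in clerical_accept:  # clerical decisions take precedence
            cur = by_clinic.get(sp.pair[1])
            if (cur is None or sp.score > cur[0].score
                    or (sp.score == cur[0].score and sp.pair[0] < cur[0].pair[0])):
                by_clinic[sp.pair[1]] = (sp, "clerical")
        for sp in kept_auto:
            if sp.pair[1] not in by_clinic:
                by_clinic[sp.pair[1]] = (sp, "probabilistic")
        final_pairs = {}
        for sp, kind in by_clinic.values():
            final_pairs[sp.pair] = kind
    else:
        final_pairs = {sp.pair: "probabilistic" for sp in auto_links}

    links = set(det_links)
    for pair, kind in final_pairs.items():
        if pair[1] in {c for _, c in det_links}:
            continue  # clinic record already linked deterministically
        links.add(pair)
        provenance[pair] = kind

    scored_out = [ScoredPair(pair=sp.pair, score=sp.score,
                             classification=("review" if sp.pair in review_decisions
                                             else ("match" if sp.pair in links
                                                   else "nonmatch")))
                  for sp in scored_all]

    return LinkageResult(links=links, scored=scored_out,
                         threshold=threshold_eff, provenance=provenance,
                         params=params_by_scheme, collisions=collisions,
                         review_decisions=review_decisions)


def links_to_frame(result: LinkageResult) -> pd.DataFrame:
    """Links as a DataFrame (registry_id, clinic_id, score, provenance)."""
    scores = {sp.pair: sp.score for sp in result.scored}
    rows = [{"registry_id": r, "clinic_id": c,
             "score": scores.get((r, c), float("nan")),
             "provenance": result.provenance.get((r, c), "")}
            for r, c in sorted(result.links)]
    return pd.DataFrame(rows,
                        columns=["registry_id", "clinic_id", "score",
                                 "provenance"])
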