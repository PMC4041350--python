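"""Fellegi-Sunter engine: comparison vectors, EM parameter recovery,
weight closed forms, rank-threshold selection and deterministic linkage."""

import math

import numpy as np
import pytest

from hdsslink.comparators import AgreementRule, Outcome
from hdsslink.engine import (AGREE, DISAGREE, MISSING, ComparisonVector,
                             EMSettings, FieldConfigurationError, ScoredPair,
                             compare_pair, default_rules, deterministic_link,
                             em_fit, em_fit_matrix, field_weight,
                             normalize_phone, score_matrix, score_pairs,
                             select_threshold)
from hdsslink.records import PersonRecord


def simulate_vectors(rng, n, m, u, p):
    """Generate comparison matrices from known mixture parameters."""
    k = len(m)
    is_match = rng.random(n) < p
    probs = np.where(is_match[:, None], np.asarray(m)[None, :],
                     np.asarray(u)[None, :])
    return (rng.random((n, k)) < probs).astype(np.int8), is_match


FIELDS4 = ("f1", "f2", "f3", "f4")


class TestComparePair:
    REC_A = PersonRecord(record_id="R1", first_name="Martha",
                         surname="Baloyi", sex="F", birth_day=3,
                         birth_month=7, birth_year=1980,
                         village="Village_01")
    FIELDS = ("first_name", "surname", "birth_day", "birth_month",
              "birth_year", "village")

    def test_identical_records_agree_everywhere(self):
        rec_b = PersonRecord(**{**self.REC_A.__dict__, "record_id": "C1"})
        rules = default_rules(self.FIELDS, AgreementRule.parse("exact"))
        cv = compare_pair(self.REC_A, rec_b, self.FIELDS, rules)
        assert all(o is Outcome.AGREE for o in cv.outcomes.values())

    def test_missing_field_propagates(self):
        rec_b = PersonRecord(**{**self.REC_A.__dict__, "record_id": "C1",
                                "village": None})
        rules = default_rules(self.FIELDS, AgreementRule.parse("exact"))
        cv = compare_pair(self.REC_A, rec_b, self.FIELDS, rules)
        assert cv.outcomes["village"] is Outcome.MISSING

    def test_combined_rule_on_transposed_name(self):
        rec_b = PersonRecord(**{**self.REC_A.__dict__, "record_id": "C1",
                                "first_name": "Marhta"})
        rules = default_rules(self.FIELDS, AgreementRule.parse("combined:0.9"))
        cv = compare_pair(self.REC_A, rec_b, self.FIELDS, rules)
        assert cv.outcomes["first_name"] is Outcome.AGREE

    def test_unknown_field_rejected(self):
        with pytest.raises(FieldConfigurationError):
            default_rules(("not_a_field",), AgreementRule.parse("exact"))


class TestEMFit:
    def test_parameter_recovery_from_known_truth(self):
        """EM recovers (m, u, p) from 20,000 simulated vectors."""
        rng = np.random.default_rng(2024)
        matrix, _ = simulate_vectors(rng, 20_000, [0.92] * 4, [0.08] * 4, 0.05)
        params = em_fit_matrix(matrix, FIELDS4)
        assert params.converged
        assert np.all(np.abs(params.m - 0.92) <= 0.02)
        assert np.all(np.abs(params.u - 0.08) <= 0.02)
        assert abs(params.p_hat - 0.05) <= 0.01

    def test_loglik_nondecreasing(self):
        rng = np.random.default_rng(7)
        matrix, _ = simulate_vectors(rng, 5_000, [0.9] * 4, [0.1] * 4, 0.1)
        params = em_fit_matrix(matrix, FIELDS4)
        ll = np.array(params.loglik)
        assert np.all(np.diff(ll) >= -1e-8)

    def test_all_identical_vectors_flagged_non_identifiable(self):
        matrix = np.ones((100, 3), dtype=np.int8)
        params = em_fit_matrix(matrix, ("a", "b", "c"))
        assert "non_identifiable" in params.flags

    def test_label_swap_resolved_by_relabelling(self):
        """Starting from inverted initial values still ends with the match
        class having the higher agreement probabilities."""
        rng = np.random.default_rng(11)
        matrix, _ = simulate_vectors(rng, 10_000, [0.9] * 4, [0.1] * 4, 0.2)
        settings = EMSettings(init_m=0.1, init_u=0.9, init_p=0.99)
        params = em_fit_matrix(matrix, FIELDS4, settings)
        assert params.m.mean() > params.u.mean()
        assert abs(params.p_hat - 0.2) <= 0.02

    def test_missing_outcomes_excluded_from_updates(self):
        rng = np.random.default_rng(3)
        matrix, _ = simulate_vectors(rng, 20_000, [0.92] * 4, [0.08] * 4, 0.05)
        # blank out 30% of field 0 at random: estimates stay calibrated
        mask = rng.random(20_000) < 0.3
        matrix[mask, 0] = MISSING
        params = em_fit_matrix(matrix, FIELDS4)
        assert abs(params.m[0] - 0.92) <= 0.03
        assert abs(params.u[0] - 0.08) <= 0.03

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            em_fit([])

    def test_em_fit_accepts_vectors(self):
        vectors = [ComparisonVector(("R1", "C1"),
                                    {"a": Outcome.AGREE, "b": Outcome.AGREE}),
                   ComparisonVector(("R2", "C2"),
                                    {"a": Outcome.DISAGREE,
                                     "b": Outcome.DISAGREE})] * 50
        params = em_fit(vectors)
        assert set(params.fields) == {"a", "b"}


class TestWeights:
    def test_closed_forms(self):
        assert field_weight(0.9, 0.1, Outcome.AGREE) == pytest.approx(
            math.log2(9), abs=1e-4)  # +3.1699
        assert field_weight(0.9, 0.1, Outcome.DISAGREE) == pytest.approx(
            -math.log2(9), abs=1e-4)
        assert field_weight(0.5, 0.5, Outcome.AGREE) == 0.0
        assert field_weight(0.5, 0.5, Outcome.DISAGREE) == 0.0
        assert field_weight(0.9, 0.1, Outcome.MISSING) == 0.0

    def test_boundary_probabilities_rejected(self):
        with pytest.raises(ValueError):
            field_weight(1.0, 0.1, Outcome.AGREE)
        with pytest.raises(ValueError):
            field_weight(0.9, 0.0, Outcome.AGREE)

    def test_sign_follows_m_vs_u(self):
        assert field_weight(0.8, 0.2, Outcome.AGREE) > 0
        assert field_weight(0.8, 0.2, Outcome.DISAGREE) < 0


def _params(m, u, p=0.1, fields=FIELDS4):
    from hdsslink.engine import MatchParameters
    k = len(fields)
    return MatchParameters(tuple(fields), np.full(k, m), np.full(k, u), p)


class TestScoring:
    def test_all_agree_score_is_additive(self):
        matrix = np.full((1, 4), AGREE, dtype=np.int8)
        score = score_matrix(matrix, _params(0.9, 0.1))[0]
        assert score == pytest.approx(4 * math.log2(9), abs=1e-4)  # 12.6797

    def test_all_missing_scores_zero(self):
        matrix = np.full((1, 4), MISSING, dtype=np.int8)
        assert score_matrix(matrix, _params(0.9, 0.1))[0] == 0.0

    def test_mixed_outcomes_equal_hand_sum(self):
        fields = ("a", "b", "c")
        matrix = np.array([[AGREE, DISAGREE, MISSING]], dtype=np.int8)
        params = _params(0.8, 0.2, fields=fields)
        expected = math.log2(0.8 / 0.2) + math.log2(0.2 / 0.8) + 0.0
        assert score_matrix(matrix, params)[0] == pytest.approx(expected)

    def test_score_pairs_validates_fields(self):
        v = ComparisonVector(("R1", "C1"), {"x": Outcome.AGREE})
        with pytest.raises(FieldConfigurationError):
            score_pairs([v], _params(0.9, 0.1))

    def test_score_pairs_returns_scored(self):
        v = ComparisonVector(("R1", "C1"),
                             {f: Outcome.AGREE for f in FIELDS4})
        out = score_pairs([v], _params(0.9, 0.1))
        assert out[0].pair == ("R1", "C1")
        assert out[0].score == pytest.approx(4 * math.log2(9), abs=1e-4)


class TestSelectThreshold:
    def test_rank_rule(self):
        assert select_threshold([10, 5, 1], p_hat=1 / 3, n_pairs=3) == 10

    def test_m_equals_n_gives_min(self):
        assert select_threshold([10, 5, 1], p_hat=1.0, n_pairs=3) == 1

    def test_m_zero_gives_infinity(self):
        assert select_threshold([10, 5, 1], p_hat=0.0, n_pairs=3) == math.inf

    def test_accepted_set_equals_top_m_oracle(self):
        """Threshold classification equals a brute-force top-M cut on a
        simulated two-component score mixture."""
        rng = np.random.default_rng(99)
        n, p = 1000, 0.2
        is_match = rng.random(n) < p
        scores = np.where(is_match, rng.normal(12, 2, n), rng.normal(-8, 3, n))
        m_expected = int(round(p * n))
        thr = select_threshold(scores, p, n)
        accepted = scores >= thr
        oracle_cut = np.sort(scores)[::-1][m_expected - 1]
        oracle = scores >= oracle_cut
        assert np.array_equal(accepted, oracle)
        # sensitivity / PPV of the accepted set match the oracle's exactly
        assert (accepted & is_match).sum() == (oracle & is_match).sum()
        assert accepted.sum() == oracle.sum()


class TestDeterministicLink:
    def rec(self, rid, **kw):
        base = dict(record_id=rid, first_name="Anna", surname="Baloyi")
        base.update(kw)
        return PersonRecord(**base)

    def test_equal_national_id_links(self):
        out = deterministic_link([self.rec("R1", national_id="8001015009087")],
                                 [self.rec("C1", national_id="8001015009087")])
        assert out.links == {("R1", "C1")}

    def test_missing_phone_never_matches(self):
        out = deterministic_link([self.rec("R1", phone=None)],
                                 [self.rec("C1", phone=None)])
        assert out.links == set()

    def test_phone_plus_first_name_links(self):
        out = deterministic_link([self.rec("R1", phone="0731234567")],
                                 [self.rec("C1", phone="073 123 4567")])
        assert out.links == {("R1", "C1")}

    def test_phone_same_but_name_differs_no_link(self):
        out = deterministic_link(
            [self.rec("R1", phone="0731234567")],
            [self.rec("C1", phone="0731234567", first_name="Grace")])
        assert out.links == set()

    def test_id_collision_flagged_not_linked(self):
        reg = [self.rec("R1", national_id="9001010000000"),
               self.rec("R2", national_id="9001010000000")]
        cli = [self.rec("C1", national_id="9001010000000")]
        out = deterministic_link(reg, cli)
        assert out.links == set()
        assert any(kind == "national_id" for kind, *_ in out.collisions)

    def test_phone_normalization_strips_country_code(self):
        assert normalize_phone("+27 73 123 4567") == "0731234567"
        assert normalize_phone("0027731234567") == "0731234567"
        assert normalize_phone("073-123-4567") == "0731234567"
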