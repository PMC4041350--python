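"""Synthetic registry/clinic generator: determinism, household structure,
missingness calibration, corruption behaviour and ground-truth consistency."""

import numpy as np
import pytest

from hdsslink import (GeneratorConfig, clean_config, corrupt_name,
                      derive_clinic_records, generate_datasets,
                      generate_registry)
from hdsslink.records import (PERSON_COLUMNS, PersonRecord, frame_to_records,
                              read_gold_csv, read_person_csv,
                              records_to_frame, write_gold_csv,
                              write_person_csv)
from hdsslink.synthetic import ConfigurationError


class TestConfigValidation:
    def test_probability_bounds(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(typo_rate=1.5)
        with pytest.raises(ConfigurationError):
            GeneratorConfig(overlap_fraction=-0.1)

    def test_overlap_demand_vs_registry_size(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(n_registry=100, n_clinic=500, overlap_fraction=0.9)

    def test_negative_counts(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(n_registry=-1)


class TestGenerateRegistry:
    def test_empty_registry(self):
        assert generate_registry(GeneratorConfig(n_registry=0, n_clinic=0)) == []

    def test_exact_count_and_unique_ids(self):
        cfg = GeneratorConfig(n_registry=500, n_clinic=100, seed=3)
        recs = generate_registry(cfg)
        assert len(recs) == 500
        assert len({r.record_id for r in recs}) == 500

    def test_determinism(self):
        cfg = GeneratorConfig(n_registry=300, n_clinic=100, seed=42)
        assert generate_registry(cfg) == generate_registry(cfg)

    def test_sex_and_birth_year_never_missing(self):
        cfg = GeneratorConfig(n_registry=400, n_clinic=100, seed=1)
        for r in generate_registry(cfg):
            assert r.sex in ("F", "M")
            assert r.birth_year is not None

    def test_national_id_completeness_calibration(self):
        """Registry ID completeness tracks the configured 67.14%."""
        cfg = GeneratorConfig(n_registry=1000, n_clinic=100, seed=7)
        recs = generate_registry(cfg)
        frac = 100 * sum(r.national_id is not None for r in recs) / len(recs)
        assert frac == pytest.approx(67.14, abs=3.0)

    def test_households_share_surname_and_village(self):
        cfg = GeneratorConfig(n_registry=400, n_clinic=100, seed=2)
        recs = generate_registry(cfg)
        by_key = {}
        for r in recs:
            by_key.setdefault((r.surname, r.village), []).append(r)
        # hh_member fields reference a real co-resident: same surname+village
        names_by_key = {k: {m.first_name for m in v} for k, v in by_key.items()}
        cited = 0
        for r in recs:
            if r.hh_member_first_name is None:
                continue
            cited += 1
            assert r.hh_member_first_name in names_by_key[(r.surname, r.village)]
            assert r.hh_member_surname in (None, r.surname)
        assert cited > 0


class TestDeriveClinic:
    def test_gold_size_forced_by_config(self):
        cfg = GeneratorConfig(n_registry=2000, n_clinic=500,
                              overlap_fraction=0.6, seed=3)
        registry = generate_registry(cfg)
        clinic, gold = derive_clinic_records(registry, cfg)
        assert len(clinic) == 500
        assert len(gold) == 300
        clinic_ids = {r.record_id for r in clinic}
        registry_ids = {r.record_id for r in registry}
        for reg_id, clin_id in gold.pairs:
            assert reg_id in registry_ids and clin_id in clinic_ids

    def test_identity_corruption_limit(self):
        """With corruption off and everything complete, each true-match
        clinic record equals its registry source field-for-field."""
        cfg = clean_config(n_registry=300, n_clinic=100, seed=9)
        registry = generate_registry(cfg)
        clinic, gold = derive_clinic_records(registry, cfg)
        reg_by_id = {r.record_id: r for r in registry}
        cli_by_id = {r.record_id: r for r in clinic}
        compare_fields = [c for c in PERSON_COLUMNS if c != "record_id"]
        for reg_id, clin_id in gold.pairs:
            src, dst = reg_by_id[reg_id], cli_by_id[clin_id]
            for f in compare_fields:
                assert getattr(src, f) == getattr(dst, f), f

    def test_clinic_national_id_completeness(self):
        cfg = GeneratorConfig(n_registry=5000, n_clinic=2000, seed=4)
        registry, clinic, gold = generate_datasets(cfg)
        frac = 100 * sum(r.national_id is not None for r in clinic) / len(clinic)
        assert frac == pytest.approx(1.55, abs=1.5)

    def test_clinic_village_completeness(self):
        cfg = GeneratorConfig(n_registry=5000, n_clinic=2000, seed=4)
        _, clinic, _ = generate_datasets(cfg)
        frac = 100 * sum(r.village is not None for r in clinic) / len(clinic)
        assert frac == pytest.approx(81.17, abs=3.0)

    def test_clinic_only_count_and_determinism(self):
        cfg = GeneratorConfig(n_registry=1000, n_clinic=400,
                              overlap_fraction=0.7, seed=6)
        registry = generate_registry(cfg)
        clinic1, gold1 = derive_clinic_records(registry, cfg)
        clinic2, gold2 = derive_clinic_records(registry, cfg)
        assert clinic1 == clinic2 and gold1 == gold2
        n_true = round(400 * 0.7)
        assert len([r for r in clinic1
                    if r.record_id not in gold1.clinic_ids()]) == 400 - n_true

    def test_overlap_exceeding_registry_rejected(self):
        cfg = GeneratorConfig(n_registry=10, n_clinic=10, overlap_fraction=1.0)
        with pytest.raises(ConfigurationError):
            derive_clinic_records(generate_registry(cfg)[:5], cfg)


class TestCorruptName:
    def test_zero_rates_identity(self):
        cfg = GeneratorConfig(typo_rate=0.0, phonetic_swap_rate=0.0)
        rng = np.random.default_rng(0)
        assert corrupt_name("Martha", cfg, rng) == "Martha"

    def test_empty_name_rejected(self):
        cfg = GeneratorConfig()
        with pytest.raises(ValueError):
            corrupt_name("", cfg, np.random.default_rng(0))

    def test_single_substitution_gives_edit_distance_one(self):
        cfg = GeneratorConfig(typo_rate=1.0, phonetic_swap_rate=0.0)
        rng = np.random.default_rng(1)
        for _ in range(50):
            out = corrupt_name("Martha", cfg, rng,
                               typo_operators=("substitute",))
            assert len(out) == len("Martha")
            assert sum(a != b for a, b in zip(out, "Martha")) == 1

    def test_corrupted_fraction_matches_binomial_rate(self):
        """Empirical corruption frequency tracks the configured typo rate."""
        cfg = GeneratorConfig(typo_rate=0.2, phonetic_swap_rate=0.0)
        rng = np.random.default_rng(123)
        n = 10_000
        changed = sum(corrupt_name("Tintswalo", cfg, rng) != "Tintswalo"
                      for _ in range(n))
        assert 100 * changed / n == pytest.approx(20.0, abs=2.0)

    def test_never_empty(self):
        cfg = GeneratorConfig(typo_rate=1.0, phonetic_swap_rate=1.0)
        rng = np.random.default_rng(5)
        for _ in range(200):
            assert corrupt_name("A", cfg, rng) != ""


class TestDatasetInvariants:
    def test_full_determinism(self):
        cfg = GeneratorConfig(n_registry=600, n_clinic=200, seed=17)
        assert generate_datasets(cfg) == generate_datasets(cfg)

    def test_no_empty_string_fields(self, default_data):
        registry, clinic, _ = default_data
        for rec in registry + clinic:
            for col in PERSON_COLUMNS:
                assert getattr(rec, col) != ""

    def test_each_clinic_record_at_most_one_gold_pair(self, default_data):
        _, _, gold = default_data
        clinic_ids = [c for _, c in gold.pairs]
        assert len(clinic_ids) == len(set(clinic_ids))


class TestCsvRoundTrip:
    def test_person_and_gold_round_trip(self, tmp_path, default_data):
        registry, clinic, gold = default_data
        p = tmp_path / "reg.csv"
        write_person_csv(registry, p)
        assert read_person_csv(p) == registry
        g = tmp_path / "gold.csv"
        write_gold_csv(gold, g)
        assert read_gold_csv(g) == gold

    def test_frame_round_trip_preserves_missing(self):
        rec = PersonRecord(record_id="R1", first_name="A", surname="B",
                           sex="F", birth_year=1980)
        df = records_to_frame([rec])
        assert df["village"].isna().all()
        assert frame_to_records(df) == [rec]

    def test_empty_string_field_rejected(self):
        with pytest.raises(ValueError):
            PersonRecord(record_id="R1", first_name="", surname="B")
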