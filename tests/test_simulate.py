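"""Synthetic-cohort generator: consistency, determinism, recovery."""

import dataclasses

import numpy as np
import pytest

from octostrat.io import records_to_frame
from octostrat.outcomes import compute_effects, within_group_effect_size
from octostrat.simulate import (
    DiscretizedTruncatedNormal,
    SyntheticConfig,
    TruncatedNormal,
    generate_baseline,
    generate_followup,
    load_synthetic_config,
)
from octostrat.stratify import stratify_cohorts


class TestDistributions:
    def test_truncated_normal_respects_bounds(self):
        d = TruncatedNormal(26.0, 3.0, 15.0, 30.0)
        x = d.sample(np.random.default_rng(0), 500)
        assert x.min() >= 15.0 and x.max() < 30.0

    def test_truncated_moments_match_empirical(self):
        d = TruncatedNormal(5.6, 2.0, 0.0, 10.0)
        x = d.sample(np.random.default_rng(1), 200_000)
        assert x.mean() == pytest.approx(d.population_mean, abs=0.02)
        assert x.std(ddof=1) == pytest.approx(d.population_sd, abs=0.02)

    def test_infeasible_region_rejected(self):
        with pytest.raises(ValueError, match="infeasible|empty"):
            TruncatedNormal(0.0, 0.1, 50.0, 60.0)
        with pytest.raises(ValueError, match="empty"):
            TruncatedNormal(5.0, 1.0, 4.0, 3.0)

    def test_discretized_scores_are_integers_in_support(self):
        d = DiscretizedTruncatedNormal(8.5, 2.3, 0, 11)
        x = d.sample(np.random.default_rng(2), 1000)
        assert np.all(x == np.round(x))
        assert x.min() >= 0 and x.max() <= 11
        assert d.population_sd > 0


class TestBaselineGeneration:
    def test_default_sizes_match_study_conditions(self):
        cfg = SyntheticConfig.default()
        sizes = {c.cohort_id: c.n for c in cfg.cohorts}
        assert sizes == {"AMS_OA": 553, "STABILO": 159, "NEXA": 100, "CBT": 222,
                         "VIDEX": 177}
        assert sum(sizes.values()) == 1211
        n_ex = sum(round(c.n * c.exercise_fraction) for c in cfg.cohorts)
        assert n_ex == 584

    def test_stratifier_recovers_generated_labels_exactly(self, small_synthetic):
        _, records, truth = small_synthetic
        labels, _ = stratify_cohorts(records)
        assert (labels.sort_index() == truth.sort_index()).all()

    def test_same_seed_reproduces_identical_tables(self):
        cfg = SyntheticConfig.default(size_multiplier=0.2)
        a, _ = generate_baseline(cfg, seed=7)
        b, _ = generate_baseline(cfg, seed=7)
        assert records_to_frame(a).equals(records_to_frame(b))
        c, _ = generate_baseline(cfg, seed=8)
        assert not records_to_frame(a).equals(records_to_frame(c))

    def test_pooled_mixture_near_published_proportions(self):
        cfg = SyntheticConfig.default(size_multiplier=4.0)
        records, _ = generate_baseline(cfg, seed=3)
        labels, table = stratify_cohorts(records)
        n = table.grand_total
        for lab, target in (("low", 34.8), ("high", 17.6), ("obesity", 47.6)):
            got = table.pooled_proportions[lab]
            se = 100 * np.sqrt(target / 100 * (1 - target / 100) / n)
            assert abs(got - target) <= 3 * se

    def test_structural_missingness_by_cohort(self, small_synthetic):
        _, records, _ = small_synthetic
        by_cohort = {}
        for r in records:
            d = by_cohort.setdefault(r.cohort_id, {"surg": 0, "com": 0, "n": 0})
            d["n"] += 1
            d["surg"] += r.knee_surgery is not None
            d["com"] += r.comorbidity_count is not None
        assert by_cohort["NEXA"]["surg"] == by_cohort["NEXA"]["n"]
        assert by_cohort["AMS_OA"]["surg"] == 0
        assert by_cohort["AMS_OA"]["com"] == by_cohort["AMS_OA"]["n"]
        assert by_cohort["CBT"]["com"] == 0


class TestFollowupGeneration:
    def test_non_arm_records_get_no_followup(self, small_synthetic):
        _, records, _ = small_synthetic
        for r in records:
            if not r.exercise_arm:
                assert not r.has_followup

    def test_followup_scores_stay_on_scale(self, small_synthetic):
        _, records, _ = small_synthetic
        for r in records:
            if r.pain_fu_raw is not None:
                assert 0 <= r.pain_fu_raw <= r.pain_scale.upper
            if r.womac_pf_fu is not None:
                assert 0 <= r.womac_pf_fu <= 100
            if r.strength_fu is not None:
                assert r.strength_fu >= 0

    def test_zero_delta_zero_noise_gives_zero_effect_size(self):
        cfg = SyntheticConfig.default(size_multiplier=0.3)
        zero = {k: 0.0 for k in cfg.effects.delta}
        cfg = dataclasses.replace(
            cfg, effects=dataclasses.replace(cfg.effects, delta=zero, noise_ratio=0.0)
        )
        records, _ = generate_baseline(cfg, seed=5)
        records = generate_followup(records, cfg, seed=6)
        arm = [r for r in records if r.exercise_arm]
        b = [r.womac_pf_baseline for r in arm]
        f = [r.womac_pf_fu for r in arm]
        assert within_group_effect_size(b, f, "function") == pytest.approx(0.0, abs=1e-9)

    def test_moderate_n_effect_size_recovery(self):
        """delta = 0.8 at n=1000 with small noise is recovered within
        Monte-Carlo error."""
        cfg = SyntheticConfig.default(size_multiplier=0.3)
        delta = {k: 0.8 for k in cfg.effects.delta}
        cfg = dataclasses.replace(
            cfg,
            cohorts=tuple(
                dataclasses.replace(c, n=500, exercise_fraction=1.0)
                for c in cfg.cohorts[:2]
            ),
            effects=dataclasses.replace(cfg.effects, delta=delta, noise_ratio=0.1),
        )
        records, truth = generate_baseline(cfg, seed=9)
        records = generate_followup(records, cfg, seed=10)
        arm = [r for r in records if truth[r.patient_id] == "low"]
        b = [r.pain_baseline_raw for r in arm]
        f = [r.pain_fu_raw for r in arm]
        es = within_group_effect_size(b, f, "pain")
        se = np.sqrt((1 + 0.8**2 / 2) / len(b))
        assert abs(es - 0.8) <= 3 * se

    def test_missing_delta_is_an_error(self):
        cfg = SyntheticConfig.default(size_multiplier=0.1)
        incomplete = dict(cfg.effects.delta)
        incomplete.pop(("low", "pain"))
        cfg = dataclasses.replace(
            cfg, effects=dataclasses.replace(cfg.effects, delta=incomplete)
        )
        records, _ = generate_baseline(cfg, seed=11)
        with pytest.raises(KeyError, match="pain"):
            generate_followup(records, cfg, seed=12)


class TestConfigSerialization:
    def test_yaml_round_trip(self, tmp_path):
        from octostrat.simulate import dump_synthetic_config

        cfg = SyntheticConfig.default()
        path = tmp_path / "gen.yaml"
        dump_synthetic_config(cfg, str(path))
        back = load_synthetic_config(str(path))
        assert back.to_dict() == cfg.to_dict()

    def test_shipped_default_config_matches_code_defaults(self):
        from octostrat.config import DEFAULT_CONFIG_PATH, RuleConstants, load_rules

        cfg = load_synthetic_config(str(DEFAULT_CONFIG_PATH))
        assert cfg.to_dict() == SyntheticConfig.default().to_dict()
        assert load_rules(DEFAULT_CONFIG_PATH) == RuleConstants()
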