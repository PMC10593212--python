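"""TRI-B engine: elementary indices, assignment rules, oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_instance
from oracle import naive_optimistic, naive_pessimistic, naive_sigma
from vawrisk.electre import (CriterionSpec, LimitProfiles, ModelConfig,
                             assign_optimistic, assign_pessimistic, classify_all,
                             credibility, credibility_pair, default_config,
                             global_concordance, load_config, outranks,
                             partial_concordance, partial_discordance,
                             save_config)
from vawrisk.exceptions import ConfigError
from vawrisk.io import PerformanceTable

SPEC = CriterionSpec(code="C", weight=1.0, q=0.1, p=0.2, v=1.0)
STUDY_WEIGHTS = (0.5, 1.0, 0.3, 1.0)


class TestPartialConcordance:
    @pytest.mark.parametrize("gx, gb, expected", [
        (0.5, 0.5, 1.0),    # no gap: full support
        (0.2, 0.5, 0.0),    # gap beyond preference threshold
        (0.35, 0.5, 0.5),   # interpolation: (0.2 - 0.15) / (0.2 - 0.1)
        (0.4, 0.5, 1.0),    # gap exactly q: continuity with the q-branch
    ])
    def test_piecewise_values(self, gx, gb, expected):
        assert partial_concordance(gx, gb, SPEC) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_q_equals_p_is_step(self):
        spec = CriterionSpec(code="C", weight=1.0, q=0.2, p=0.2, v=1.0)
        assert partial_concordance(0.31, 0.5, spec) == 1.0
        assert partial_concordance(0.30, 0.5, spec) == 0.0


class TestPartialDiscordance:
    @pytest.mark.parametrize("gx, gb, expected", [
        (0.4, 0.5, 0.0),    # below preference threshold: no opposition
        (0.0, 1.0, 1.0),    # veto reached
        (0.0, 0.6, 0.5),    # interpolation: (0.6 - 0.2) / (1.0 - 0.2)
    ])
    def test_piecewise_values(self, gx, gb, expected):
        assert partial_discordance(gx, gb, SPEC) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_p_equals_v_is_step(self):
        spec = CriterionSpec(code="C", weight=1.0, q=0.1, p=0.5, v=0.5)
        assert partial_discordance(0.0, 0.49, spec) == 0.0
        assert partial_discordance(0.0, 0.5, spec) == 1.0


class TestGlobalConcordance:
    def test_all_ones_gives_one(self):
        assert global_concordance([1, 1, 1, 1], STUDY_WEIGHTS) == pytest.approx(1.0)

    def test_all_zeros_gives_zero(self):
        assert global_concordance([0, 0, 0, 0], STUDY_WEIGHTS) == 0.0

    def test_weighted_mean_with_study_weights(self):
        # three concordant criteria out of four: (0.5 + 1.0 + 0.3) / 2.8
        assert global_concordance([1, 1, 1, 0], STUDY_WEIGHTS) == pytest.approx(
            1.8 / 2.8, abs=1e-12)

    def test_empty_criteria_rejected(self):
        with pytest.raises(ValueError):
            global_concordance([], [])


class TestCredibility:
    def test_no_strong_discordance_returns_concordance(self):
        assert credibility(0.7, [0.7, 0.2, 0.0]) == pytest.approx(0.7)

    def test_single_strong_discordance_discounts(self):
        # 0.5 * (1 - 0.9) / (1 - 0.5)
        assert credibility(0.5, [0.9, 0.0, 0.0]) == pytest.approx(0.1, abs=1e-12)

    def test_veto_annihilates(self):
        assert credibility(0.5, [1.0, 0.0]) == 0.0

    @settings(max_examples=200, deadline=None)
    @given(st.floats(0, 1), st.lists(st.floats(0, 1), min_size=1, max_size=6))
    def test_bounded_by_concordance(self, C, Ds):
        sigma = credibility(C, Ds)
        assert 0.0 <= sigma <= C + 1e-15


class TestOutranks:
    @pytest.mark.parametrize("sigma, lam, expected", [
        (0.65, 0.60, True),
        (0.55, 0.60, False),
        (0.60, 0.60, True),  # inclusive cut
    ])
    def test_cut(self, sigma, lam, expected):
        assert outranks(sigma, lam) is expected

    def test_lambda_outside_half_one_rejected(self):
        with pytest.raises(ConfigError):
            outranks(0.7, 0.4)


class TestAssignmentStudyConfig:
    """Hand-walked cases under the published profiles/thresholds, lambda=0.60."""

    def test_dominating_alternative_gets_top_class(self, study_config):
        b5 = study_config.profiles.vector(5, study_config.codes)
        x = b5 + 0.01
        assert assign_pessimistic(x, study_config) == 6
        assert assign_optimistic(x, study_config) == 6

    def test_fully_vetoed_alternative_gets_bottom_class(self, study_config):
        b1 = study_config.profiles.vector(1, study_config.codes)
        x = b1 - 1.0  # worse than b_1 by the veto threshold on every criterion
        assert assign_pessimistic(x, study_config) == 1
        assert assign_optimistic(x, study_config) == 1

    def test_alternative_at_b3_lands_in_class_five(self, study_config):
        # x = b_3 fails against b_5 (C = 1.5/2.8 < 0.60) but matches b_4
        # within the indifference thresholds, hence sigma = 1 there.
        x = study_config.profiles.vector(3, study_config.codes)
        b5 = study_config.profiles.vector(5, study_config.codes)
        sigma_b5 = credibility_pair(x, b5, study_config.criteria)
        assert sigma_b5 == pytest.approx(1.5 / 2.8, abs=1e-12)
        assert assign_pessimistic(x, study_config) == 5

    def test_profile_on_itself_outranks(self, study_config):
        for h in range(1, 6):
            b = study_config.profiles.vector(h, study_config.codes)
            assert credibility_pair(b, b, study_config.criteria) == 1.0


class TestOracleEquivalence:
    def test_sigma_and_classes_match_naive_transcription(self, rng):
        """Engine output equals a straight-line reimplementation of the
        concordance/discordance/credibility/assignment chain on 100 random
        instances (4 criteria, 5 profiles)."""
        for _ in range(100):
            config, profiles = random_instance(rng)
            qs = [c.q for c in config.criteria]
            ps = [c.p for c in config.criteria]
            vs = [c.v for c in config.criteria]
            ws = [c.weight for c in config.criteria]
            for _ in range(5):
                x = rng.uniform(0, 1, size=4)
                for h in range(1, 6):
                    b = profiles[h - 1]
                    assert credibility_pair(x, b, config.criteria) == pytest.approx(
                        naive_sigma(list(x), list(b), qs, ps, vs, ws), abs=1e-12)
                lam = config.lambda_cut
                assert assign_pessimistic(x, config) == naive_pessimistic(
                    list(x), [list(b) for b in profiles], qs, ps, vs, ws, lam)
                assert assign_optimistic(x, config) == naive_optimistic(
                    list(x), [list(b) for b in profiles], qs, ps, vs, ws, lam)

    def test_matches_oracle_for_varying_profile_counts(self, rng):
        for n_profiles in (1, 2, 5):
            for _ in range(30):
                config, profiles = random_instance(rng, n_profiles=n_profiles)
                qs = [c.q for c in config.criteria]
                ps = [c.p for c in config.criteria]
                vs = [c.v for c in config.criteria]
                ws = [c.weight for c in config.criteria]
                x = rng.uniform(0, 1, size=4)
                assert assign_pessimistic(x, config) == naive_pessimistic(
                    list(x), [list(b) for b in profiles], qs, ps, vs, ws,
                    config.lambda_cut)


class TestEngineProperties:
    def test_dominance_gives_full_credibility(self, rng):
        """x >= b componentwise implies sigma(x, b) = 1 and outranking at
        any lambda <= 1."""
        for _ in range(200):
            config, profiles = random_instance(rng)
            h = int(rng.integers(1, 6))
            b = profiles[h - 1]
            x = b + rng.uniform(0, 0.5, size=4)
            assert credibility_pair(x, b, config.criteria) == 1.0

    def test_pessimistic_class_monotone_in_performance(self, rng):
        """Improving one criterion value never lowers the pessimistic class."""
        for _ in range(1000):
            config, _ = random_instance(rng, n_profiles=int(rng.choice([1, 2, 5])))
            x = rng.uniform(0, 1, size=4)
            j = int(rng.integers(0, 4))
            y = x.copy()
            y[j] += rng.uniform(0, 0.5)
            assert assign_pessimistic(y, config) >= assign_pessimistic(x, config)

    def test_pessimistic_never_exceeds_optimistic(self, rng):
        for _ in range(500):
            config, _ = random_instance(rng)
            x = rng.uniform(0, 1, size=4)
            assert assign_pessimistic(x, config) <= assign_optimistic(x, config)

    def test_minimize_direction_equivalent_to_sign_flip(self, study_config, rng):
        """A minimize criterion behaves exactly like a maximize criterion on
        negated evaluations and mirrored profiles."""
        from dataclasses import replace

        orig = study_config.profiles.boundaries
        # minimize C4: raw boundaries descend (b_1 = worst = largest Gini)
        config_min = replace(
            study_config,
            criteria=tuple(replace(c, direction="minimize") if c.code == "C4"
                           else c for c in study_config.criteria),
            profiles=LimitProfiles(
                boundaries={k: (tuple(reversed(v)) if k == "C4" else v)
                            for k, v in orig.items()},
                directions={"C4": "minimize"}))
        # all-maximize equivalent: C4 evaluations negated everywhere
        config_max = replace(
            study_config,
            profiles=LimitProfiles(
                boundaries={k: (tuple(-b for b in reversed(v)) if k == "C4"
                                else v)
                            for k, v in orig.items()}))
        for _ in range(50):
            x = rng.uniform(0, 1, size=4)
            x_neg = x.copy()
            x_neg[3] = -x[3]
            assert assign_pessimistic(x, config_min) == \
                assign_pessimistic(x_neg, config_max)
            assert assign_optimistic(x, config_min) == \
                assign_optimistic(x_neg, config_max)


class TestClassifyAll:
    def _table(self, rng, n=12):
        values = rng.uniform(0, 1, size=(n, 4))
        return PerformanceTable(
            alternatives=tuple(f"A{i}" for i in range(n)),
            criteria=("C1", "C2", "C3", "C4"), values=values)

    def test_one_result_per_alternative(self, study_config, rng):
        table = self._table(rng)
        results = classify_all(table, study_config)
        assert [r.id for r in results] == list(table.alternatives)

    def test_deterministic(self, study_config, rng):
        table = self._table(rng)
        assert classify_all(table, study_config) == classify_all(table, study_config)

    def test_criteria_mismatch_rejected(self, study_config, rng):
        table = PerformanceTable(alternatives=("A",), criteria=("C1", "C2"),
                                 values=rng.uniform(0, 1, size=(1, 2)))
        with pytest.raises(ConfigError, match="mismatch"):
            classify_all(table, study_config)


class TestConfigValidation:
    def test_threshold_order_enforced(self):
        with pytest.raises(ConfigError):
            CriterionSpec(code="C", weight=1.0, q=0.3, p=0.2, v=1.0)

    def test_profile_order_enforced(self):
        with pytest.raises(ConfigError):
            LimitProfiles(boundaries={"C1": (0.5, 0.3)})

    def test_lambda_range_enforced(self, study_config):
        with pytest.raises(ConfigError):
            study_config.with_lambda(0.4)

    def test_yaml_round_trip(self, study_config, tmp_path):
        path = tmp_path / "config.yaml"
        save_config(study_config, path)
        loaded = load_config(path)
        assert loaded == study_config

    def test_default_config_matches_study_tables(self, study_config):
        assert study_config.lambda_cut == 0.60
        assert study_config.n_profiles == 5
        weights = [c.weight for c in study_config.criteria]
        assert weights == [0.5, 1.0, 0.3, 1.0]
        assert sum(weights) == pytest.approx(2.8)
        assert study_config.profiles.boundaries["C3"] == (0.01, 0.03, 0.04, 0.08, 0.50)
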