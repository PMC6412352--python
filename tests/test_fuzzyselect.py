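import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import importance_bf
from steerwake.fuzzyselect import (
    N_RULES,
    RULE_ANTECEDENTS,
    FuzzyParams,
    default_params,
    importance_degree,
    importance_degrees,
    load_params,
    membership,
    save_params,
    select_features,
)
from steerwake.simdata import generate_feature_bench


def _random_params(rng):
    c = np.sort(rng.random((4, 3)), axis=1)
    s = 0.05 + 0.95 * rng.random((4, 3))
    alpha = rng.choice([0.0, 0.5, 1.0], size=N_RULES)
    return FuzzyParams(c=c, s=s, alpha=alpha)


class TestMembership:
    def test_peak_at_center(self):
        assert membership(0.5, 0.5, 0.2) == 1.0

    def test_one_sigma_value(self):
        assert membership(0.7, 0.5, 0.2) == pytest.approx(math.exp(-0.5))

    def test_three_sigma_value(self):
        assert membership(1.1, 0.5, 0.2) == pytest.approx(math.exp(-4.5))

    def test_rejects_nonpositive_width(self):
        with pytest.raises(ValueError):
            membership(0.5, 0.5, 0.0)


class TestDefaultParams:
    def test_rule_base_has_81_distinct_rules(self):
        assert RULE_ANTECEDENTS.shape == (81, 4)
        assert len({tuple(r) for r in RULE_ANTECEDENTS}) == 81

    def test_majority_heuristic_consequents(self):
        p = default_params()
        rules = {tuple(r): i for i, r in enumerate(map(tuple, RULE_ANTECEDENTS))}
        assert p.alpha[rules[(2, 2, 2, 2)]] == 1.0  # H,H,H,H
        assert p.alpha[rules[(0, 0, 1, 2)]] == 0.5  # L,L,M,H: only 2 lows
        assert p.alpha[rules[(0, 0, 0, 1)]] == 0.0  # L,L,L,M

    def test_centers_at_unit_domain_anchor_points(self):
        p = default_params()
        assert np.allclose(p.c, np.tile([0.0, 0.5, 1.0], (4, 1)))
        assert np.all(p.s == 0.2125)


class TestParamValidation:
    def test_rejects_nonpositive_widths(self):
        p = default_params()
        with pytest.raises(ValueError):
            FuzzyParams(c=p.c, s=np.zeros((4, 3)), alpha=p.alpha)

    def test_rejects_unordered_centers(self):
        p = default_params()
        c = p.c.copy()
        c[1] = [1.0, 0.5, 0.0]
        with pytest.raises(ValueError):
            FuzzyParams(c=c, s=p.s, alpha=p.alpha)

    def test_rejects_off_grid_consequents(self):
        p = default_params()
        alpha = p.alpha.copy()
        alpha[0] = 0.3
        with pytest.raises(ValueError):
            FuzzyParams(c=p.c, s=p.s, alpha=alpha)


class TestImportanceDegree:
    def test_constant_consequents_give_constant_output(self):
        p = default_params()
        for const in (0.0, 0.5, 1.0):
            params = FuzzyParams(c=p.c, s=p.s, alpha=np.full(N_RULES, const))
            for h in ([0, 0, 0, 0], [1, 1, 1, 1], [0.3, 0.7, 0.1, 0.9]):
                assert importance_degree(h, params) == pytest.approx(const)

    def test_all_high_input_matches_oracle_and_exceeds_half(self):
        p = default_params()
        got = importance_degree([1, 1, 1, 1], p)
        ref = importance_bf([1, 1, 1, 1], p.c.tolist(), p.s.tolist(), p.alpha.tolist())
        assert got == pytest.approx(ref, abs=1e-12)
        assert got > 0.5

    def test_vectorized_evaluation_equals_naive_81_rule_loop(self):
        rng = np.random.default_rng(17)
        for _ in range(60):
            params = _random_params(rng)
            h = rng.random(4)
            got = importance_degree(h, params)
            ref = importance_bf(
                h.tolist(), params.c.tolist(), params.s.tolist(), params.alpha.tolist()
            )
            assert got == pytest.approx(ref, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_output_always_within_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        params = _random_params(rng)
        h = -0.5 + 2.0 * rng.random(4)  # deliberately out of domain; clipped
        val = importance_degree(h, params)
        assert 0.0 <= val <= 1.0

    def test_continuity_on_input_grid(self):
        # no jump larger than epsilon for a small input perturbation
        p = default_params()
        grid = np.linspace(0, 1, 21)
        delta = 1e-4
        for g in grid:
            h = np.array([g, 0.5, 0.5, 0.5])
            a = importance_degree(h, p)
            b = importance_degree(h + [delta, 0, 0, 0], p)
            assert abs(a - b) < 1e-2

    def test_raising_a_consequent_never_lowers_output(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            params = _random_params(rng)
            h = rng.random(4)
            base = importance_degree(h, params)
            l = int(rng.integers(0, N_RULES))
            alpha = params.alpha.copy()
            if alpha[l] == 1.0:
                continue
            alpha[l] = 1.0
            raised = FuzzyParams(c=params.c, s=params.s, alpha=alpha)
            assert importance_degree(h, raised) >= base - 1e-15


class TestSelection:
    def test_all_one_consequents_select_everything(self, bench):
        X, y, _ = bench
        p = default_params()
        all_one = FuzzyParams(c=p.c, s=p.s, alpha=np.ones(N_RULES))
        assert select_features(X, y, all_one).n_selected == 36

    def test_all_zero_consequents_select_nothing(self, bench):
        X, y, _ = bench
        p = default_params()
        all_zero = FuzzyParams(c=p.c, s=p.s, alpha=np.zeros(N_RULES))
        assert select_features(X, y, all_zero).n_selected == 0

    def test_selection_mask_matches_threshold_rule(self, bench):
        X, y, _ = bench
        res = select_features(X, y, default_params())
        assert np.array_equal(res.selected, res.importance > res.threshold)

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_informative_features_are_selected(self, seed):
        X, y, informative = generate_feature_bench(
            2000, 36, 5, effect_size=2.0, seed=seed
        )
        res = select_features(X, y, default_params())
        assert set(informative.tolist()) <= set(res.selected_indices.tolist())


class TestSerialization:
    def test_yaml_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        params = _random_params(rng)
        save_params(params, tmp_path / "p.yaml")
        back = load_params(tmp_path / "p.yaml")
        assert np.allclose(back.c, params.c)
        assert np.allclose(back.s, params.s)
        assert np.array_equal(back.alpha, params.alpha)
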