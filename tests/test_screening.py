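from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metamarker.screening import (
    adjust_benjamini_hochberg,
    adjust_benjamini_yekutieli,
    mann_whitney,
    screen_metabolites,
)
from metamarker.synthetic import SyntheticConfig, generate
from metamarker.io_prep import preprocess


def enumerate_mw_p(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all label assignments."""
    pooled = sorted(x) + sorted(y)
    n = len(x)
    ranks = {v: r + 1 for r, v in enumerate(sorted(pooled))}

    def u_of(subset):
        rank_sum = sum(ranks[v] for v in subset)
        return rank_sum - n * (n + 1) / 2

    observed = u_of(x)
    m = len(y)
    mean_u = n * m / 2
    us = [u_of(c) for c in combinations(pooled, n)]
    dev = abs(observed - mean_u)
    extreme = sum(abs(u - mean_u) >= dev - 1e-12 for u in us)
    return extreme / len(us)


class TestMannWhitney:
    def test_exact_branch_matches_enumeration(self):
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        u, p = mann_whitney(x, y)
        assert u == 0.0
        assert p == pytest.approx(0.1)
        assert p == pytest.approx(enumerate_mw_p(x, y))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_branch_matches_enumeration_random(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.permutation(np.arange(10.0))[:4]
        y = rng.uniform(0, 12, size=5).round(3)
        _, p = mann_whitney(x, y)
        assert p == pytest.approx(enumerate_mw_p(list(x), list(y)))

    def test_identical_samples_give_p_one(self):
        x = [1.0, 2.0, 3.0]
        _, p = mann_whitney(x, x)
        assert p == pytest.approx(1.0, abs=1e-9)

    @given(
        st.lists(st.integers(0, 1000), min_size=2, max_size=7, unique=True),
        st.lists(st.integers(1001, 2000), min_size=2, max_size=7, unique=True),
    )
    @settings(max_examples=30, deadline=None)
    def test_swap_symmetry(self, x, y):
        x = [float(v) for v in x]
        y = [float(v) + 0.5 for v in y]
        u_xy, p_xy = mann_whitney(x, y)
        u_yx, p_yx = mann_whitney(y, x)
        assert p_xy == pytest.approx(p_yx)
        assert u_yx == pytest.approx(len(x) * len(y) - u_xy)

    def test_exact_close_to_asymptotic_at_n8(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            x = rng.permutation(np.arange(100.0))[:8]
            y = rng.permutation(np.arange(100.0, 200.0))[:8] - rng.uniform(40, 60)
            _, p_exact = mann_whitney(x, y, exact_max_n=8)
            _, p_asym = mann_whitney(x, y, exact_max_n=0)
            assert abs(p_exact - p_asym) <= 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


def by_oracle(p):
    """Independent Benjamini-Yekutieli step-up computed from the definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    c_m = sum(1.0 / i for i in range(1, m + 1))
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, c_m * m * p[i] / (rank_idx + 1))
        adj[i] = running
    return np.minimum(adj, 1.0)


class TestFDRAdjustment:
    def test_bh_step_up_by_hand(self):
        adj = adjust_benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_is_identity_and_all_ones_stay_one(self):
        assert adjust_benjamini_hochberg([0.05])[0] == pytest.approx(0.05)
        assert adjust_benjamini_yekutieli([0.05])[0] == pytest.approx(0.05)
        np.testing.assert_array_equal(adjust_benjamini_hochberg([1.0] * 4), [1.0] * 4)

    @pytest.mark.parametrize("seed", [0, 3, 7])
    def test_by_matches_independent_step_up(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, size=15)
        np.testing.assert_allclose(adjust_benjamini_yekutieli(p), by_oracle(p))

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_by_dominates_bh_dominates_raw(self, p):
        bh = adjust_benjamini_hochberg(p)
        by = adjust_benjamini_yekutieli(p)
        assert np.all(by >= bh - 1e-12)
        assert np.all(bh >= np.asarray(p) - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(bh[order]) >= -1e-12)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_benjamini_hochberg([0.5, 1.2])


class TestScreen:
    def _matrix(self, seed, shift=0.0, m=20):
        cfg = SyntheticConfig(
            n_metabolites=m,
            block_sizes=[],
            primary_markers={0: shift} if shift else {},
            missing_rate=0.0,
            seed=seed,
        )
        raw, _ = generate(cfg)
        return preprocess(raw)

    def test_planted_three_sd_shift_is_flagged(self):
        flagged = 0
        for seed in range(10):
            table = screen_metabolites(self._matrix(seed, shift=3.0))
            row = table.set_index("metabolite").loc["M01"]
            flagged += bool(row["significant"])
            assert row["direction"] == 1
        assert flagged >= 9  # >=95% of seeds in the large-sample limit

    def test_null_screen_flag_fraction_near_zero(self):
        total = sum(
            screen_metabolites(self._matrix(100 + seed))["significant"].sum()
            for seed in range(10)
        )
        assert total / (10 * 20) <= 0.01

    def test_single_metabolite_reduces_to_mann_whitney(self):
        m = self._matrix(3, m=1)
        table = screen_metabolites(m, correction="bh")
        u, p = mann_whitney(m.values[m.case_mask, 0], m.values[m.control_mask, 0])
        assert table.loc[0, "u"] == pytest.approx(u)
        assert table.loc[0, "p"] == pytest.approx(p)
        assert table.loc[0, "p_adj"] == pytest.approx(p)

    def test_small_group_rejected(self, tiny_matrix):
        from metamarker.io_prep import PreprocessConfig, impute_and_filter

        m = impute_and_filter(tiny_matrix, PreprocessConfig(missing_fraction_max=0.5))
        m.group[:] = "control"
        m.group[0] = "case"
        with pytest.raises(ValueError, match="at least 2"):
            screen_metabolites(m)
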