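"""Rating normalisation, group assignment and rank-based inference."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gazephase.compare import (GroupComparison, assign_groups, bh_fdr,
                               normalize_ratings, rank_biserial,
                               rank_biserial_from_u, wilcoxon_rank_sum)
from gazephase.exceptions import ConfigurationError, DataError


def ratings_frame(rows):
    return pd.DataFrame(rows, columns=["participant_id", "artwork_id",
                                       "rating"])


class TestNormalizeRatings:
    def test_min_max_mapping(self):
        df = ratings_frame([("p1", "a", 1), ("p1", "b", 10)])
        out = normalize_ratings(df)
        assert list(out["normalized"]) == [0.0, 1.0]
        assert not out["constant_scale"].any()

    def test_constant_scale_fallback(self):
        df = ratings_frame([("p1", "a", 4), ("p1", "b", 4), ("p1", "c", 4)])
        out = normalize_ratings(df)
        assert (out["normalized"] == 0.5).all()
        assert out["constant_scale"].all()

    def test_affine_invariance(self):
        """Two participants whose scales are affine transforms of each
        other get identical normalised values."""
        base = [2, 5, 8]
        shifted = [x + 2 for x in base]           # affine: +2
        rows = [("p1", f"a{i}", r) for i, r in enumerate(base)]
        rows += [("p2", f"a{i}", r) for i, r in enumerate(shifted)]
        out = normalize_ratings(ratings_frame(rows))
        v1 = out[out["participant_id"] == "p1"]["normalized"].to_numpy()
        v2 = out[out["participant_id"] == "p2"]["normalized"].to_numpy()
        np.testing.assert_allclose(v1, v2)

    def test_out_of_range_rating_rejected(self):
        with pytest.raises(DataError):
            normalize_ratings(ratings_frame([("p1", "a", 11)]))


class TestAssignGroups:
    def test_split_matches_full_sort(self):
        """12 artworks with distinct means: the 6/6 split equals an
        independent full sort of artwork means."""
        rng = np.random.default_rng(0)
        rows = []
        for p in range(5):
            for a in range(12):
                rows.append((f"p{p}", f"art{a:02d}",
                             int(rng.integers(1, 11))))
        df = normalize_ratings(ratings_frame(rows))
        ga = assign_groups(df)
        means = df.groupby("artwork_id")["normalized"].mean()
        expected_high = set(means.sort_values(ascending=False).index[:6])
        assert set(ga.high) == expected_high

    def test_noise_free_generator_groups_recovered(self):
        from gazephase.simulate import GenerativeConfig, simulate_study

        cfg = GenerativeConfig(n_participants=5, n_artworks=6, n_high=3,
                               sampling_rate_hz=30.0, K_true=3,
                               rating_noise_sd=0.0, seed=5)
        data, gt = simulate_study(cfg)
        ga = assign_groups(normalize_ratings(data.ratings))
        assert ga.group == gt.group

    def test_boundary_tie_deterministic(self):
        rows = [("p1", "a", 2), ("p1", "b", 2), ("p1", "c", 8),
                ("p1", "d", 8)]
        df = normalize_ratings(ratings_frame(rows))
        ga1 = assign_groups(df)
        ga2 = assign_groups(df)
        assert ga1.group == ga2.group
        assert ga1.high == ["c", "d"]

    def test_odd_artwork_count_rejected(self):
        rows = [("p1", f"a{i}", i + 1) for i in range(5)]
        with pytest.raises(ConfigurationError):
            assign_groups(normalize_ratings(ratings_frame(rows)))


class TestWilcoxon:
    def test_complete_separation_6v6_reproduces_reported_triple(self):
        """Complete separation of 6 artworks vs 6: exact two-sided
        p = 2/924, z = 18/sqrt(39), r = z/sqrt(12)."""
        a = np.array([7, 8, 9, 10, 11, 12], dtype=float)
        b = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        res = wilcoxon_rank_sum(a, b)
        assert res.exact
        assert res.U == 36.0
        assert res.p == pytest.approx(2 / 924, rel=1e-12)
        assert res.z == pytest.approx(18 / np.sqrt(39), abs=1e-12)
        r = rank_biserial(res.z, 12)
        assert r == pytest.approx(18 / np.sqrt(39) / np.sqrt(12), abs=1e-12)
        assert round(res.z, 2) == 2.88
        assert round(r, 2) == 0.83

    def test_swap_symmetry(self):
        rng = np.random.default_rng(1)
        a = rng.normal(1, 1, 8)
        b = rng.normal(0, 1, 7)
        r1 = wilcoxon_rank_sum(a, b)
        r2 = wilcoxon_rank_sum(b, a)
        assert r1.p == pytest.approx(r2.p, rel=1e-12)
        assert r1.z == pytest.approx(-r2.z, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_p_matches_permutation_enumeration(self, seed):
        """Exact p equals brute-force enumeration over all group
        assignments for small untied samples."""
        rng = np.random.default_rng(seed)
        n_a, n_b = int(rng.integers(3, 6)), int(rng.integers(3, 6))
        pool = rng.permutation(100)[: n_a + n_b].astype(float)
        a, b = pool[:n_a], pool[n_a:]
        res = wilcoxon_rank_sum(a, b)
        assert res.exact
        # enumeration oracle: U statistic over all C(n, n_a) assignments
        u_obs = sum(1 for x in a for y in b if x > y)
        us = []
        for idx in combinations(range(n_a + n_b), n_a):
            ga = pool[list(idx)]
            gb = np.delete(pool, list(idx))
            us.append(sum(1 for x in ga for y in gb if x > y))
        us = np.array(us)
        mu = n_a * n_b / 2
        p_exact = np.mean(np.abs(us - mu) >= np.abs(u_obs - mu) - 1e-9)
        assert res.p == pytest.approx(p_exact, rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(DataError):
            wilcoxon_rank_sum([], [1.0])

    def test_ties_fall_back_to_corrected_normal(self):
        a = [1.0, 2.0, 2.0, 3.0]
        b = [2.0, 4.0, 5.0, 6.0]
        res = wilcoxon_rank_sum(a, b)
        assert not res.exact
        assert 0 < res.p <= 1


class TestRankBiserial:
    def test_reference_values(self):
        assert rank_biserial(0.0, 12) == 0.0
        assert rank_biserial(np.sqrt(12), 12) == pytest.approx(1.0)
        assert rank_biserial(100.0, 12) == 1.0   # clipped

    def test_u_based_alternative(self):
        # complete separation: U = n_a * n_b
        assert rank_biserial_from_u(36, 6, 6) == pytest.approx(1.0)
        assert rank_biserial_from_u(18, 6, 6) == pytest.approx(0.0)


def naive_bh(p):
    """Quadratic-scan step-up oracle."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, i in enumerate(order, start=1):
        candidates = [m * p[j] / (list(order).index(j) + 1)
                      for j in order[rank_pos - 1:]]
        q[i] = min(1.0, min(candidates))
    return q


class TestBH:
    def test_hand_computed_step_up(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(bh_fdr(p), [0.04, 0.04, 0.04, 0.04])

    def test_degenerate_cases(self):
        assert bh_fdr(np.array([0.37]))[0] == pytest.approx(0.37)
        np.testing.assert_allclose(bh_fdr(np.ones(5)), np.ones(5))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_naive_quadratic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-6, 1.0, size=int(rng.integers(1, 40)))
        np.testing.assert_allclose(bh_fdr(p), naive_bh(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            bh_fdr(np.array([0.0, 0.5]))
        with pytest.raises(DataError):
            bh_fdr(np.array([1.2]))

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    def test_q_at_least_p_over_max_rank_and_monotone(self, p):
        p = np.array(p)
        q = bh_fdr(p)
        assert np.all(q <= 1.0 + 1e-12)
        assert np.all(q >= p / len(p) - 1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)


def tidy_metrics(rows):
    return pd.DataFrame(rows, columns=["participant", "artwork", "bin",
                                       "t_start", "t_end", "metric",
                                       "value"])


class TestGroupComparison:
    def _toy_table(self, delta=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        arts = [f"a{i}" for i in range(4)]
        for p in range(6):
            for ai, a in enumerate(arts):
                for b in range(2):
                    base = rng.normal(0.5, 0.1)
                    if ai < 2:
                        base += delta
                    rows.append((f"p{p}", a, b, 3.0 * b, 3.0 * (b + 1),
                                 "Hnorm", base))
        return tidy_metrics(rows)

    def _groups(self):
        from gazephase.compare import GroupAssignment

        return GroupAssignment(group={"a0": "high", "a1": "high",
                                      "a2": "low", "a3": "low"})

    def test_single_cell_family_q_equals_p(self):
        table = self._toy_table(seed=1)
        table = table[table["bin"] == 0]
        res = GroupComparison(table, self._groups()).fit()
        tab = res.table[res.table["testable"]]
        assert len(tab) == 1
        assert tab["q"].iloc[0] == pytest.approx(tab["p"].iloc[0])

    def test_sign_convention_high_larger_positive(self):
        res = GroupComparison(self._toy_table(delta=1.0, seed=2),
                              self._groups()).fit()
        tab = res.table[res.table["testable"]]
        assert (tab["z"] > 0).all()
        assert (tab["r"] > 0).all()

    def test_untestable_cell_flagged_not_dropped(self):
        table = self._toy_table(seed=3)
        # remove all low-group rows in bin 1 -> untestable cell remains
        drop = (table["bin"] == 1) & table["artwork"].isin(["a2", "a3"])
        res = GroupComparison(table[~drop], self._groups()).fit()
        row = res.table[(res.table["bin"] == 1)]
        assert len(row) == 1
        assert not row["testable"].iloc[0]

    def test_plot_returns_axes(self):
        import matplotlib
        matplotlib.use("Agg")
        res = GroupComparison(self._toy_table(delta=0.5, seed=5),
                              self._groups()).fit()
        ax = res.plot()
        assert ax.get_ylabel() == "-log10 p"

    def test_observation_units(self):
        table = self._toy_table(delta=0.5, seed=4)
        for unit, n_high in [("episode", 12), ("artwork", 2),
                             ("participant", 6)]:
            res = GroupComparison(table, self._groups(), unit=unit).fit()
            assert res.table["n_high"].max() == n_high
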