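"""CV statistics, the within-day permutation null, the Mantel test, modularity
clustering and social differentiation, each against an independent oracle."""

import numpy as np
import pandas as pd
import pytest

from probassoc import (HWIMatrix, association_cv, beta_binomial_fit,
                       daily_associations, hwi_matrix, make_fixture,
                       mantel_test, modularity, newman_clusters,
                       permute_within_days, social_differentiation)


def square(ids, entries):
    n = len(ids)
    w = np.zeros((n, n))
    for (i, j), v in entries.items():
        w[i, j] = w[j, i] = v
    return HWIMatrix(individuals=list(ids), values=w, counts={})


class TestAssociationCV:
    def test_constant_positive_values(self):
        m = square("abc", {(0, 1): 0.4, (0, 2): 0.4, (1, 2): 0.4})
        assert association_cv(m) == pytest.approx(0.0, abs=1e-12)

    def test_two_value_closed_form(self):
        m = square("abc", {(0, 1): 0.2, (0, 2): 0.6, (1, 2): 0.4})
        vals = np.array([0.2, 0.6, 0.4])
        assert association_cv(m) == pytest.approx(vals.std() / vals.mean())

    def test_zeros_inflate_cv(self):
        m = square("abcd", {(0, 1): 0.5, (2, 3): 0.5})
        assert association_cv(m) > association_cv(m, nonzero_only=True)

    def test_zero_mean_rejected(self):
        m = square("abc", {})
        with pytest.raises(ValueError, match="mean"):
            association_cv(m)


class TestPermutationNull:
    def test_degree_conservation_asserted(self, sim_small):
        df, _ = sim_small
        assoc = daily_associations(df, "probabilistic", threshold=10)
        res = permute_within_days(assoc, n_permutations=20, n_trials=50,
                                  seed=4, check_degrees=True)
        assert res.flip_success_rate > 0

    def test_add_one_p_value_bounds(self, sim_small):
        df, _ = sim_small
        assoc = daily_associations(df, "probabilistic", threshold=10)
        res = permute_within_days(assoc, n_permutations=99, n_trials=50,
                                  seed=0)
        assert 1 / 100 <= res.p_all <= 1.0
        assert res.n_permutations == 99

    def test_invariant_statistic_gives_p_one(self):
        # a single dyad ever associated: no 2x2 checkerboard exists, the
        # permuted statistic always equals the observed one
        df = pd.DataFrame({
            "individual": ["A", "B", "C", "D"],
            "event": ["e1", "e1", "e2", "e3"],
            "ordinal": [1, 1, 1, 1],
            "date": ["2020-06-01"] * 4,
        })
        assoc = daily_associations(df, "same_frame")
        res = permute_within_days(assoc, n_permutations=50, n_trials=20,
                                  seed=0)
        assert res.p_all == 1.0
        assert res.flip_success_rate == 0.0

    def test_planted_preferences_detected(self, sim_small):
        df, _ = sim_small  # strong within-unit cohesion
        assoc = daily_associations(df, "probabilistic", threshold=10)
        res = permute_within_days(assoc, n_permutations=100, n_trials=200,
                                  seed=1)
        assert res.p_all <= 0.05


class TestMantel:
    def test_perfect_block_structure(self):
        m = square("abcd", {(0, 1): 1.0, (2, 3): 1.0})
        res = mantel_test(m, {"a": "g1", "b": "g1", "c": "g2", "d": "g2"},
                          n_permutations=99, seed=0)
        assert res.matrix_correlation == pytest.approx(1.0)

    def test_hand_computed_correlation(self):
        entries = {(0, 1): 0.9, (0, 2): 0.1, (1, 2): 0.2,
                   (0, 3): 0.0, (1, 3): 0.1, (2, 3): 0.8,
                   (0, 4): 0.05, (1, 4): 0.0, (2, 4): 0.7, (3, 4): 0.9,
                   (0, 5): 0.8, (1, 5): 0.85, (2, 5): 0.0, (3, 5): 0.1,
                   (4, 5): 0.05}
        m = square("abcdef", entries)
        groups = {"a": "x", "b": "x", "f": "x", "c": "y", "d": "y", "e": "y"}
        iu, ju = np.triu_indices(6, k=1)
        ids = list("abcdef")
        same = np.array([groups[ids[i]] == groups[ids[j]]
                         for i, j in zip(iu, ju)], dtype=float)
        expected = np.corrcoef(m.values[iu, ju], same)[0, 1]
        res = mantel_test(m, groups, n_permutations=99, seed=0)
        assert res.matrix_correlation == pytest.approx(expected)
        # with 6 individuals only 720 labelings exist and 10% of them
        # reproduce the same 3+3 partition, so P cannot drop below ~0.1
        assert res.p_value <= 0.15

    def test_structureless_matrix_not_significant(self):
        rng = np.random.default_rng(7)
        n = 12
        w = rng.uniform(0, 1, (n, n))
        w = np.triu(w, 1)
        w = w + w.T
        ids = [f"i{k}" for k in range(n)]
        m = HWIMatrix(individuals=ids, values=w, counts={})
        groups = {i: f"g{k % 3}" for k, i in enumerate(ids)}
        res = mantel_test(m, groups, n_permutations=200, seed=1)
        assert abs(res.matrix_correlation) < 0.4
        assert res.p_value > 0.05

    def test_relabeling_invariance(self):
        m = square("abcd", {(0, 1): 0.9, (2, 3): 0.8, (0, 2): 0.1})
        g1 = {"a": "x", "b": "x", "c": "y", "d": "y"}
        g2 = {"a": "blue", "b": "blue", "c": "red", "d": "red"}
        r1 = mantel_test(m, g1, n_permutations=50, seed=3)
        r2 = mantel_test(m, g2, n_permutations=50, seed=3)
        assert r1.matrix_correlation == pytest.approx(r2.matrix_correlation)

    def test_simultaneous_permutation_invariance(self):
        ids = list("abcde")
        rng = np.random.default_rng(0)
        w = rng.uniform(0, 1, (5, 5))
        w = np.triu(w, 1); w = w + w.T
        m = HWIMatrix(individuals=ids, values=w, counts={})
        groups = {"a": "x", "b": "x", "c": "y", "d": "y", "e": "y"}
        perm = [3, 1, 4, 0, 2]
        ids_p = [ids[k] for k in perm]
        m_p = HWIMatrix(individuals=ids_p, values=w[np.ix_(perm, perm)],
                        counts={})
        r1 = mantel_test(m, groups, n_permutations=10, seed=0)
        r2 = mantel_test(m_p, groups, n_permutations=10, seed=0)
        assert r1.matrix_correlation == pytest.approx(r2.matrix_correlation)

    def test_degenerate_membership_rejected(self):
        m = square("abcd", {(0, 1): 0.5, (2, 3): 0.2})
        with pytest.raises(ValueError, match="groups"):
            mantel_test(m, {k: "same" for k in "abcd"})


class TestNewmanClustering:
    def test_two_triangles(self):
        fx = make_fixture("two-triangles")
        part = newman_clusters(fx.data)
        assert part.q == pytest.approx(fx.expected["q"], abs=1e-12)
        assert part.n_clusters == fx.expected["n_clusters"]
        groups = {}
        for ind, lab in part.assignment.items():
            groups.setdefault(lab, set()).add(ind)
        assert sorted(map(frozenset, groups.values())) == sorted(
            map(frozenset, fx.expected["partition"]))

    def test_complete_graph_indivisible(self):
        n = 8
        w = np.ones((n, n)) - np.eye(n)
        m = HWIMatrix(individuals=[f"i{k}" for k in range(n)], values=w,
                      counts={})
        part = newman_clusters(m)
        assert part.n_clusters == 1

    def test_all_zero_weights(self):
        m = square("abcd", {})
        part = newman_clusters(m)
        assert part.n_clusters == 1 and part.q == 0.0

    def test_q_matches_direct_recomputation(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = int(rng.integers(6, 25))
            w = rng.uniform(0, 1, (n, n)) * (rng.random((n, n)) < 0.3)
            w = np.triu(w, 1); w = w + w.T
            m = HWIMatrix(individuals=[f"i{k}" for k in range(n)],
                          values=w, counts={})
            part = newman_clusters(m)
            labels = part.labels(m.individuals)
            assert part.q == pytest.approx(modularity(w, labels), abs=1e-10)

    def test_planted_modules_recovered(self):
        rng = np.random.default_rng(1)
        n, k = 24, 4
        lab = np.repeat(np.arange(k), n // k)
        w = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                base = 0.8 if lab[i] == lab[j] else 0.01
                w[i, j] = w[j, i] = min(base * rng.uniform(0.8, 1.2), 1.0)
        m = HWIMatrix(individuals=[f"i{kk}" for kk in range(n)], values=w,
                      counts={})
        part = newman_clusters(m)
        assert part.n_clusters == k
        # partition must be identical to the planted one up to relabeling
        found = part.labels(m.individuals)
        mapping = {}
        for planted, got in zip(lab, found):
            mapping.setdefault(planted, got)
            assert mapping[planted] == got

    def test_empty_rejected(self):
        m = HWIMatrix(individuals=[], values=np.zeros((0, 0)), counts={})
        with pytest.raises(ValueError, match="empty"):
            newman_clusters(m)


class TestSocialDifferentiation:
    def test_homogeneous_limit(self):
        rng = np.random.default_rng(2)
        d = np.full(300, 50)
        x = rng.binomial(50, 0.3, size=300)
        res = beta_binomial_fit(x, d)
        assert res.s < 0.2

    def test_identical_proportions_near_zero(self):
        d = np.full(200, 40)
        x = np.full(200, 12)  # all dyads exactly 0.3
        res = beta_binomial_fit(x, d)
        assert res.s == pytest.approx(0.0, abs=0.05)

    def test_balanced_bimodal_latent_cv_one(self):
        # half the dyads always associated, half never: the latent
        # distribution has mean 1/2 and sd 1/2, so its CV is exactly 1
        d = np.full(100, 20)
        x = np.r_[np.full(50, 20), np.zeros(50)]
        res = beta_binomial_fit(x, d)
        assert res.s == pytest.approx(1.0, abs=0.05)

    def test_skewed_bimodal_exceeds_one(self):
        # 1 in 4 dyads always associated: latent CV = sqrt(3) > 1
        d = np.full(100, 20)
        x = np.r_[np.full(25, 20), np.zeros(75)]
        res = beta_binomial_fit(x, d)
        assert res.s > 1.0

    def test_beta_latent_recovery(self):
        rng = np.random.default_rng(0)
        p = rng.beta(0.5, 4.5, size=500)
        x = rng.binomial(20, p)
        res = beta_binomial_fit(x, np.full(500, 20))
        true_cv = np.sqrt(4.5 / (0.5 * (0.5 + 4.5 + 1)))
        assert res.s == pytest.approx(true_cv, rel=0.2)

    def test_loglik_dominates_grid_starts(self):
        rng = np.random.default_rng(4)
        p = rng.beta(1.2, 3.0, size=200)
        x = rng.binomial(15, p)
        d = np.full(200, 15)
        res = beta_binomial_fit(x, d)
        from probassoc.metrics import _bb_loglik
        grid = np.linspace(-2.0, 2.5, 4)
        for la in grid:
            for lb in grid:
                assert res.loglik >= _bb_loglik(np.array([la, lb]), x, d) - 1e-9

    def test_all_unsampled_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            beta_binomial_fit(np.zeros(5), np.zeros(5))

    def test_from_association_data(self, sim_small):
        df, _ = sim_small
        assoc = daily_associations(df, "probabilistic", threshold=10)
        res = social_differentiation(assoc)
        assert res.s > 0.2  # planted units: clearly non-homogeneous
        assert not res.boundary
        assert np.isfinite(res.loglik)
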