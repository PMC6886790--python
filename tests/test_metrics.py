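import itertools

import numpy as np
import pytest
from scipy.stats import kstest

import seasonet as sn
from seasonet.metrics import METRIC_FUNCTIONS, _random_incidence
from seasonet.synthetic import network_with_marginals


def brute_force_nodf(A: np.ndarray) -> float:
    """Independent pairwise-definition oracle: explicit loop over all pairs."""
    A = (np.asarray(A) > 0).astype(int)
    m, n = A.shape
    terms = []
    for axis_matrix in (A, A.T):
        rows = [set(np.flatnonzero(r)) for r in axis_matrix]
        fills = [len(r) for r in rows]
        for i, j in itertools.combinations(range(len(rows)), 2):
            if fills[i] > fills[j] and fills[j] > 0:
                terms.append(100.0 * len(rows[i] & rows[j]) / fills[j])
            elif fills[j] > fills[i] and fills[i] > 0:
                terms.append(100.0 * len(rows[i] & rows[j]) / fills[i])
            else:
                terms.append(0.0)
    return float(np.mean(terms))


class TestConnectance:
    @pytest.mark.parametrize(
        "n_pl,n_po,L,expected",
        [(93, 111, 434, 0.084), (66, 92, 318, 0.105), (51, 56, 127, 0.089)],
    )
    def test_published_values(self, n_pl, n_po, L, expected):
        net = network_with_marginals(n_pl, n_po, L, seed=0)
        assert round(sn.bipartite_connectance(net), 3) == expected

    def test_half_filled_two_by_two(self):
        net = network_with_marginals(2, 2, 2, seed=0)
        assert sn.bipartite_connectance(net) == 1.0

    def test_doubled_is_twice_standard(self, community):
        cfg, records, _ = community
        net = sn.build_network(records, cal=cfg.calendar)
        assert sn.bipartite_connectance(net) == pytest.approx(
            2 * sn.bipartite_connectance(net, doubled=False)
        )

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            sn.bipartite_connectance(sn.build_network([]))


class TestDegreeSummary:
    def test_side_means_are_L_over_N(self, community):
        cfg, records, _ = community
        net = sn.build_network(records, cal=cfg.calendar)
        s = sn.degree_summary(net)
        assert s.mean_plant_degree == pytest.approx(net.n_links / net.n_plants)
        assert s.mean_pollinator_degree == pytest.approx(net.n_links / net.n_pollinators)
        assert sum(s.plant_degree.values()) == sum(s.pollinator_degree.values()) == net.n_links

    def test_single_link_network(self):
        import datetime as dt

        net = sn.build_network([sn.VisitRecord(dt.date(2008, 11, 3), "P", "B")])
        s = sn.degree_summary(net, sn.interaction_frequency(net))
        assert s.plant_degree == {"P": 1}
        assert s.pollinator_degree == {"B": 1}
        assert s.plant_weighted == {"P": 1.0}

    def test_weighted_degree_sums_frequencies(self, community):
        cfg, records, _ = community
        net = sn.build_network(records, cal=cfg.calendar)
        freqs = sn.interaction_frequency(net)
        s = sn.degree_summary(net, freqs)
        some_bee = next(iter(net.pollinators))
        expected = sum(f for (p, b), f in freqs.F.items() if b == some_bee)
        assert s.pollinator_weighted[some_bee] == pytest.approx(expected)


class TestNodf:
    def test_perfectly_nested_triangle(self):
        assert sn.nodf([[1, 1, 1], [1, 1, 0], [1, 0, 0]]) == 100.0

    def test_identity_has_no_overlap(self):
        assert sn.nodf(np.eye(3)) == 0.0

    def test_pinned_small_matrix(self):
        A = [[1, 1, 0], [1, 0, 1], [0, 1, 0]]
        assert sn.nodf(A) == pytest.approx(brute_force_nodf(np.array(A)))

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(12345)
        for _ in range(50):
            shape = (rng.integers(4, 7), rng.integers(4, 7))
            A = (rng.random(shape) < rng.uniform(0.2, 0.8)).astype(int)
            assert sn.nodf(A) == pytest.approx(brute_force_nodf(A), abs=1e-10)

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ValueError):
            sn.nodf([[1, 0, 1]])


class TestNestednessSignificance:
    def test_perfectly_nested_vs_null(self):
        # a large triangular matrix: no seeded null draw reaches NODF = 100
        A = np.tril(np.ones((6, 6), dtype=int))
        from seasonet.metrics import nestedness_significance

        net = _matrix_network(A)
        result = nestedness_significance(net, n_rand=999, seed=7)
        assert result.nodf == 100.0
        assert result.p_value == pytest.approx(1 / 1000)

    def test_precondition_on_ensemble_size(self):
        net = _matrix_network(np.tril(np.ones((4, 4), dtype=int)))
        from seasonet.metrics import nestedness_significance

        with pytest.raises(ValueError):
            nestedness_significance(net, n_rand=0)

    def test_p_uniform_when_observed_is_null_draw(self):
        """Empirical p is ~uniform when the observed network is itself a null draw."""
        from seasonet.metrics import nodf

        rng = np.random.default_rng(99)
        m, n, L = 8, 8, 20
        pvals = []
        for _ in range(200):
            obs = nodf(_random_incidence(rng, m, n, L, None))
            null = np.array([nodf(_random_incidence(rng, m, n, L, None)) for _ in range(199)])
            pvals.append((1 + int(np.sum(null >= obs))) / 200)
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_marginal_null_model_runs(self, community):
        cfg, records, _ = community
        net = sn.build_network(records, "dry", cal=cfg.calendar)
        from seasonet.metrics import nestedness_significance

        res = nestedness_significance(net, n_rand=99, null_model="marginal", seed=3)
        assert 0 < res.p_value <= 1
        assert 0 <= res.nodf <= 100


def _matrix_network(A: np.ndarray) -> sn.BipartiteNetwork:
    visits = {
        (f"P{i}", f"B{j}"): 1 for i in range(A.shape[0]) for j in range(A.shape[1]) if A[i, j]
    }
    return sn.BipartiteNetwork(visits=visits, active_days={p: 1 for p, _ in visits})


class TestDegreeModelFits:
    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            sn.fit_degree_models([1, 2, 3, 2, 1])

    def test_degenerate_distribution_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            sn.fit_degree_models([3] * 20)

    def test_aic_identity_and_unique_rank(self):
        rng = np.random.default_rng(0)
        degrees = rng.geometric(0.3, size=200)
        fits = sn.fit_degree_models(degrees)
        assert [f.rank for f in fits] == [1, 2, 3]
        for f in fits:
            assert f.aic == pytest.approx(2 * f.n_params - 2 * f.log_likelihood)
            assert np.isfinite(f.log_likelihood)

    def test_ranking_invariant_to_permutation(self):
        rng = np.random.default_rng(5)
        degrees = rng.geometric(0.3, size=300)
        a = [f.model for f in sn.fit_degree_models(degrees)]
        b = [f.model for f in sn.fit_degree_models(rng.permutation(degrees))]
        assert a == b


class TestSeasonalMetricTest:
    def test_identical_seasonal_visit_totals_give_p_one(self):
        import datetime as dt

        # same multiset of visits in each season: the n_visits difference is
        # zero under every permutation, so the one-tailed p is 1
        records = []
        for day, season_month in ((3, 11), (3, 6)):
            records += [
                sn.VisitRecord(dt.date(2008 if season_month == 11 else 2009, season_month, day), p, b)
                for p, b in [("P1", "B1"), ("P2", "B2"), ("P1", "B2")]
            ]
        out = sn.seasonal_metric_test(records, metric="n_visits", n_perm=99, seed=0)
        assert out["observed_diff"] == 0
        assert out["p_value"] == 1.0

    def test_detects_built_in_seasonal_size_asymmetry(self):
        """The generator's rainy-dominated community yields significant size differences."""
        cfg = sn.CommunityConfig()
        for seed in range(10):
            records, _ = sn.generate_community(cfg, seed=seed)
            out = sn.seasonal_metric_test(
                records, cal=cfg.calendar, metric="network_size", n_perm=299, seed=seed
            )
            assert out["p_value"] <= 0.05

    def test_zero_permutations_rejected(self, community):
        cfg, records, _ = community
        with pytest.raises(ValueError):
            sn.seasonal_metric_test(records, cal=cfg.calendar, n_perm=0)

    def test_unknown_metric_rejected(self, community):
        cfg, records, _ = community
        with pytest.raises(ValueError, match="unknown metric"):
            sn.seasonal_metric_test(records, cal=cfg.calendar, metric="modularity")

    def test_metric_registry_covers_reported_measures(self, community):
        cfg, records, _ = community
        net = sn.build_network(records, cal=cfg.calendar)
        for name in ("network_size", "connectance", "mean_plant_degree", "nodf"):
            assert np.isfinite(METRIC_FUNCTIONS[name](net))
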