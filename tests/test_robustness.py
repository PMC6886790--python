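import datetime as dt

import numpy as np
import pytest
from scipy.stats import binomtest

import seasonet as sn
from seasonet.robustness import RemovalScenario, auc_significantly_different


def star_network() -> sn.BipartiteNetwork:
    visits = {(f"P{i}", "B1"): 1 for i in range(1, 5)}
    return sn.BipartiteNetwork(visits=visits, active_days={p: 1 for p, _ in visits})


def complete_network(s: int, t: int | None = None) -> sn.BipartiteNetwork:
    t = s if t is None else t
    visits = {(f"P{i}", f"B{j}"): 1 for i in range(s) for j in range(t)}
    return sn.BipartiteNetwork(visits=visits, active_days={p: 1 for p, _ in visits})


class TestRemovalSequence:
    def test_tie_block_permuted_across_iterations(self):
        visits = {("P1", "A"): 1, ("P2", "A"): 1, ("P3", "A"): 1, ("P1", "B"): 1, ("P1", "C"): 1}
        net = sn.BipartiteNetwork(visits=visits, active_days={p: 1 for p, _ in visits})
        scenario = RemovalScenario(side="pollinators", order="decreasing")
        rng = np.random.default_rng(0)
        firsts, orders = set(), set()
        for _ in range(100):
            seq = sn.removal_sequence(net, scenario, rng)
            firsts.add(seq[0])
            orders.add(tuple(seq[1:]))
        assert firsts == {"A"}  # degree 3 always first
        assert orders == {("B", "C"), ("C", "B")}  # both tie orders observed

    def test_distinct_keys_are_deterministic(self):
        # pollinator degrees A=1, C=2, B=3: strictly distinct
        visits = {
            ("P1", "A"): 1,
            ("P1", "B"): 1, ("P2", "B"): 1, ("P3", "B"): 1,
            ("P2", "C"): 1, ("P3", "C"): 1,
        }
        net = sn.BipartiteNetwork(visits=visits, active_days={p: 1 for p, _ in visits})
        scenario = RemovalScenario(side="pollinators", order="increasing")
        rng = np.random.default_rng(0)
        seqs = {tuple(sn.removal_sequence(net, scenario, rng)) for _ in range(20)}
        assert seqs == {("A", "C", "B")}

    def test_random_order_reproducible_under_seed(self):
        net = complete_network(4)
        scenario = RemovalScenario(side="plants", order="random")
        a = sn.removal_sequence(net, scenario, np.random.default_rng(42))
        b = sn.removal_sequence(net, scenario, np.random.default_rng(42))
        assert a == b


class TestExtinctionCascade:
    def test_star_curve_and_auc(self):
        net = star_network()
        x, y = sn.extinction_cascade(net, ["B1"])
        assert x.tolist() == [0.0, 1.0] and y.tolist() == [1.0, 0.0]
        assert np.trapezoid(y, x) == pytest.approx(0.5)

    def test_complete_two_by_two(self):
        net = complete_network(2)
        x, y = sn.extinction_cascade(net, ["B0", "B1"])
        assert y.tolist() == [1.0, 1.0, 0.0]
        assert np.trapezoid(y, x) == pytest.approx(0.75)

    def test_flow_fraction_after_hub_removal(self):
        # total visitation 10; pollinator Bhub carries 4
        visits = {("P1", "Bhub"): 4, ("P1", "B2"): 3, ("P2", "B3"): 3}
        net = sn.BipartiteNetwork(visits=visits, active_days={"P1": 1, "P2": 1})
        freqs = sn.interaction_frequency(net)
        x, y = sn.extinction_cascade(net, ["Bhub", "B2", "B3"], mode="flow", freqs=freqs)
        assert y[0] == 1.0
        assert y[1] == pytest.approx(0.6)
        assert y[-1] == pytest.approx(0.0)

    def test_non_permutation_rejected(self):
        net = complete_network(2)
        with pytest.raises(ValueError, match="permutation"):
            sn.extinction_cascade(net, ["B0"])

    def test_curves_non_increasing_from_one(self, community):
        cfg, records, _ = community
        net = sn.build_network(records, "dry", cal=cfg.calendar)
        rng = np.random.default_rng(3)
        seq = sn.removal_sequence(net, RemovalScenario(side="plants", order="random"), rng)
        x, y = sn.extinction_cascade(net, seq)
        assert y[0] == 1.0
        assert np.all(np.diff(y) <= 1e-12)


class TestRobustnessExperiment:
    def test_no_ties_gives_zero_width_ci(self):
        # plant degrees 1, 2, 3: tie-free targeted removal is fully deterministic
        visits = {("P1", "A"): 1, ("P2", "A"): 1, ("P2", "B"): 1, ("P3", "A"): 1, ("P3", "B"): 1, ("P3", "C"): 1}
        net = sn.BipartiteNetwork(visits=visits, active_days={p: 1 for p, _ in visits})
        curve = sn.robustness_experiment(
            net, RemovalScenario(side="plants", order="decreasing", iterations=50, seed=0)
        )
        assert np.allclose(curve.ci_low, curve.ci_high)
        assert curve.auc_ci[0] == pytest.approx(curve.auc_ci[1])

    @pytest.mark.parametrize("s", range(2, 11))
    def test_complete_network_closed_form(self, s):
        net = complete_network(s)
        curve = sn.robustness_experiment(
            net, RemovalScenario(side="pollinators", order="decreasing", iterations=5, seed=0)
        )
        assert curve.auc == pytest.approx(1 - 1 / (2 * s))

    def test_flow_curves_bracketed(self, community):
        cfg, records, _ = community
        net = sn.build_network(records, "rainy", cal=cfg.calendar)
        freqs = sn.interaction_frequency(net)
        curve = sn.robustness_experiment(
            net,
            RemovalScenario(side="pollinators", order="random", mode="flow", iterations=10, seed=1),
            freqs=freqs,
        )
        assert curve.mean[0] == pytest.approx(1.0)
        assert curve.mean[-1] == pytest.approx(0.0)
        assert 0.0 <= curve.auc <= 1.0

    def test_auc_matches_rectangle_sum_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            n_pl, n_po = rng.integers(4, 9), rng.integers(4, 9)
            links = {(f"P{i}", f"B{j}") for i in range(n_pl) for j in range(n_po) if rng.random() < 0.5}
            links |= {(f"P{i}", f"B{i % n_po}") for i in range(n_pl)}
            links |= {(f"P{j % n_pl}", f"B{j}") for j in range(n_po)}
            visits = {l: 1 for l in links}
            net = sn.BipartiteNetwork(visits=visits, active_days={p: 1 for p, _ in visits})
            seq = sn.removal_sequence(
                net, RemovalScenario(side="pollinators", order="random"), rng
            )
            x, y = sn.extinction_cascade(net, seq)
            S = len(seq)
            rect = float(np.sum(y[1:]) / S)  # right-endpoint rectangle sum
            # trapezoid exceeds the right-endpoint sum by exactly (y0-yS)/(2S)
            assert np.trapezoid(y, x) == pytest.approx(rect, abs=1 / (2 * S) + 1e-12)

    def test_targeted_removal_is_more_damaging_in_expectation(self):
        """Decreasing-degree removal yields lower AUC than increasing on most
        heavy-tailed networks (sign test over 20 synthetic communities)."""
        wins = 0
        for seed in range(20):
            records, _ = sn.generate_community(sn.CommunityConfig(), seed=400 + seed)
            net = sn.build_network(records, "dry")
            dec = sn.robustness_experiment(
                net, RemovalScenario(side="pollinators", order="decreasing", iterations=10, seed=seed)
            )
            inc = sn.robustness_experiment(
                net, RemovalScenario(side="pollinators", order="increasing", iterations=10, seed=seed)
            )
            wins += dec.auc < inc.auc
        assert binomtest(wins, 20, 0.5, alternative="greater").pvalue < 0.05

    def test_pollinator_removal_drains_flow_faster_than_plant_removal(self):
        """Weighted robustness: the community loses visitation flow faster under
        removal of pollinators (the guild holding the aseasonal hubs)."""
        for seed in range(10):
            records, _ = sn.generate_community(sn.CommunityConfig(), seed=500 + seed)
            net = sn.build_network(records)
            freqs = sn.interaction_frequency(net)
            po = sn.robustness_experiment(
                net,
                RemovalScenario(side="pollinators", order="decreasing", weighted=True, mode="flow", iterations=10, seed=seed),
                freqs=freqs,
            )
            pl = sn.robustness_experiment(
                net,
                RemovalScenario(side="plants", order="decreasing", weighted=True, mode="flow", iterations=10, seed=seed),
                freqs=freqs,
            )
            assert po.auc < pl.auc

    def test_ci_overlap_flag(self):
        net = complete_network(5)
        a = sn.robustness_experiment(net, RemovalScenario(side="plants", order="random", iterations=20, seed=0))
        assert not auc_significantly_different(a, a)

    def test_dynamic_reranking_option_runs(self, community):
        cfg, records, _ = community
        net = sn.build_network(records, "dry", cal=cfg.calendar)
        curve = sn.robustness_experiment(
            net,
            RemovalScenario(side="pollinators", order="decreasing", iterations=3, seed=0, recompute_degrees=True),
        )
        assert curve.mean[0] == 1.0 and 0 <= curve.auc <= 1
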