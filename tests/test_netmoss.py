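import numpy as np
import pandas as pd
import pytest

from conftest import random_network
from gutnet.data_io import ValidationError
from gutnet.modules import ModulePartition, detect_modules
from gutnet.netmoss import (ChainConfig, benjamini_hochberg,
                            differential_module_distance, nmss, nmss_scores,
                            nmss_significance, run_longitudinal,
                            run_per_timepoint)
from gutnet.network import sparcc
from gutnet.synthetic import SimulationConfig, simulate_counts


def _partition(net, mapping):
    return ModulePartition({t: mapping[t] for t in net.taxon_ids})


class TestDifferentialModuleDistance:
    def test_identical_partitions_have_zero_self_distance(self):
        rng = np.random.default_rng(0)
        net = random_network(rng, 12)
        labels = {t: ("M1" if i < 6 else "M2")
                  for i, t in enumerate(net.taxon_ids)}
        part = _partition(net, labels)
        dist = differential_module_distance(net, part, net, part)
        assert dist.distance.loc["M1", "M1"] == 0.0
        assert dist.distance.loc["M2", "M2"] == 0.0
        assert ("M1", "M1") in dist.stable_pairs

    def test_split_module_jaccard_half(self):
        rng = np.random.default_rng(1)
        net = random_network(rng, 8)
        ids = net.taxon_ids
        part_a = _partition(net, {t: "M1" for t in ids})
        part_b = _partition(net, {t: ("L" if i < 4 else "R")
                                  for i, t in enumerate(ids)})
        dist = differential_module_distance(net, part_a, net, part_b)
        assert dist.distance.loc["M1", "L"] == pytest.approx(0.5)
        assert dist.distance.loc["M1", "R"] == pytest.approx(0.5)

    def test_disjoint_partitions_distance_one(self):
        rng = np.random.default_rng(2)
        net_a = random_network(rng, 6)
        net_b = random_network(rng, 6)
        net_b.taxon_ids = [f"other{i}" for i in range(6)]
        part_a = _partition(net_a, {t: "M1" for t in net_a.taxon_ids})
        part_b = _partition(net_b, {t: "M1" for t in net_b.taxon_ids})
        dist = differential_module_distance(net_a, part_a, net_b, part_b)
        assert (dist.distance.to_numpy() == 1.0).all()

    def test_empty_partition_rejected(self):
        rng = np.random.default_rng(3)
        net = random_network(rng, 5)
        part = _partition(net, {t: "M1" for t in net.taxon_ids})
        with pytest.raises(ValidationError):
            differential_module_distance(net, ModulePartition({}), net, part)


class TestNmss:
    def test_self_transition_scores_zero_everywhere(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            net = random_network(rng, 15)
            part = detect_modules(net, min_module_size=3)
            dist = differential_module_distance(net, part, net, part)
            scores = nmss_scores(dist)
            assert (scores["raw"] == 0).all()
            assert (scores["nmss"] == 0).all()

    def test_node_absent_from_one_network_reported_missing(self):
        rng = np.random.default_rng(5)
        net = random_network(rng, 6)
        part = _partition(net, {t: "M1" for t in net.taxon_ids})
        dist = differential_module_distance(net, part, net, part)
        with pytest.raises(ValidationError, match="absent"):
            nmss(dist, "nonexistent")

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(6)
        net_a = random_network(rng, 12)
        net_b = random_network(rng, 12)
        net_b.taxon_ids = list(net_a.taxon_ids)
        part_a = detect_modules(net_a, min_module_size=3)
        part_b = detect_modules(net_b, min_module_size=3)
        dist = differential_module_distance(net_a, part_a, net_b, part_b)
        base = nmss_scores(dist)["raw"]
        # permute node order everywhere; scores must follow the labels
        perm = rng.permutation(12)
        from gutnet.network import CorrelationNetwork
        net_a2 = CorrelationNetwork([net_a.taxon_ids[i] for i in perm],
                                    net_a.adjacency[np.ix_(perm, perm)])
        net_b2 = CorrelationNetwork([net_b.taxon_ids[i] for i in perm],
                                    net_b.adjacency[np.ix_(perm, perm)])
        part_a2 = ModulePartition({t: part_a.assignment[t]
                                   for t in net_a2.taxon_ids})
        part_b2 = ModulePartition({t: part_b.assignment[t]
                                   for t in net_b2.taxon_ids})
        dist2 = differential_module_distance(net_a2, part_a2, net_b2, part_b2)
        permuted = nmss_scores(dist2)["raw"]
        for t in net_a.taxon_ids:
            assert permuted[t] == pytest.approx(base[t])

    def test_planted_rewired_driver_ranks_top(self):
        hits = 0
        for s in range(10):
            cfg = SimulationConfig(
                n_taxa=40, n_samples_per_group_per_timepoint=90,
                n_timepoints=1, module_sizes=[15, 15],
                basis_correlation_within_module=0.7, driver_taxa=[0],
                driver_log2_effect=2.0, driver_rewire=True, seed=600 + s)
            table, meta, _ = simulate_counts(cfg)
            m = meta.frame
            ta = table.select_samples(
                list(m.loc[m.group == "control", "sample_id"]))
            tb = table.select_samples(
                list(m.loc[m.group == "stress", "sample_id"]))
            kw = dict(n_inner_iterations=5, n_exclusion_rounds=3)
            net_a = sparcc(ta, seed=s, **kw)
            net_b = sparcc(tb, seed=s + 1, **kw)
            dist = differential_module_distance(
                net_a, detect_modules(net_a), net_b, detect_modules(net_b))
            ranks = nmss_scores(dist)["nmss"].rank(ascending=False)
            hits += ranks["g000"] <= 2   # top 5% of 40 taxa
        assert hits >= 8


class TestBenjaminiHochberg:
    def test_hand_example(self):
        q = benjamini_hochberg(np.array([0.01, 0.02, 0.03]))
        np.testing.assert_allclose(q, [0.03, 0.03, 0.03])

    def test_matches_brute_force_definition(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = rng.uniform(size=12)
            q = benjamini_hochberg(p)
            m = len(p)
            order = np.argsort(p)
            # brute force: q_(i) = min_{j >= i} p_(j) * m / j
            brute = np.empty(m)
            prev = np.inf
            for rank in range(m, 0, -1):
                prev = min(prev, p[order[rank - 1]] * m / rank)
                brute[order[rank - 1]] = min(prev, 1.0)
            np.testing.assert_allclose(q, brute, atol=1e-12)


class TestSignificance:
    def _arms(self, seed, **kw):
        cfg = SimulationConfig(n_taxa=25, n_samples_per_group_per_timepoint=40,
                               n_timepoints=1, module_sizes=[10, 8],
                               basis_correlation_within_module=0.7,
                               seed=seed, **kw)
        table, meta, _ = simulate_counts(cfg)
        m = meta.frame
        return (table.select_samples(list(m.loc[m.group == "control",
                                               "sample_id"])),
                table.select_samples(list(m.loc[m.group == "stress",
                                               "sample_id"])))

    def test_p_values_never_zero_and_q_monotone_in_rank(self):
        ta, tb = self._arms(seed=20)
        res = nmss_significance(ta, tb, n_permutations=100, seed=0)
        assert (res["p_value"] > 0).all()
        assert (res["p_value"] <= 1).all()
        ranked = res.sort_values("p_value")
        assert ranked["q_value"].is_monotonic_increasing

    def test_deterministic_given_seed(self):
        ta, tb = self._arms(seed=21)
        r1 = nmss_significance(ta, tb, n_permutations=100, seed=5)
        r2 = nmss_significance(ta, tb, n_permutations=100, seed=5)
        pd.testing.assert_frame_equal(r1, r2)

    def test_rewired_drivers_significant(self):
        ta, tb = self._arms(seed=22, driver_taxa=[0, 1, 2],
                            driver_log2_effect=2.0, driver_rewire=True)
        res = nmss_significance(ta, tb, n_permutations=200, seed=0)
        assert (res.loc[["g000", "g001", "g002"], "q_value"] < 0.05).all()

    def test_direction_follows_abundance_shift(self):
        ta, tb = self._arms(seed=23, driver_taxa=[0], driver_log2_effect=2.0,
                            driver_rewire=True)
        res = nmss_significance(ta, tb, n_permutations=100, seed=0)
        # drivers are up-shifted in the stress arm (B)
        assert res.loc["g000", "direction"] == "enriched_in_B"


class TestModes:
    def _study(self, seed, **kw):
        cfg = SimulationConfig(n_taxa=25, n_samples_per_group_per_timepoint=15,
                               n_timepoints=3, module_sizes=[10, 8],
                               basis_correlation_within_module=0.7,
                               seed=seed, **kw)
        return simulate_counts(cfg)

    def test_per_timepoint_returns_one_result_per_timepoint(self):
        table, meta, _ = self._study(seed=30)
        res = run_per_timepoint(table, meta, n_permutations=100, seed=0)
        assert set(res) == {"t1", "t2", "t3"}
        for t, frame in res.items():
            assert (frame["timepoint"] == t).all()

    def test_single_timepoint_reduces_to_plain_run(self):
        cfg = SimulationConfig(n_taxa=25, n_samples_per_group_per_timepoint=15,
                               n_timepoints=1, module_sizes=[10, 8], seed=31)
        table, meta, _ = simulate_counts(cfg)
        res = run_per_timepoint(table, meta, n_permutations=100, seed=0)
        assert list(res) == ["t1"]
        m = meta.frame
        ta = table.select_samples(list(m.loc[m.group == "control",
                                             "sample_id"]))
        tb = table.select_samples(list(m.loc[m.group == "stress",
                                             "sample_id"]))
        direct = nmss_significance(ta, tb, n_permutations=100, seed=0)
        np.testing.assert_allclose(res["t1"]["raw"], direct["raw"])
        np.testing.assert_allclose(res["t1"]["p_value"], direct["p_value"])

    def test_longitudinal_needs_two_timepoints(self):
        cfg = SimulationConfig(n_taxa=25, n_samples_per_group_per_timepoint=15,
                               n_timepoints=1, module_sizes=[10], seed=32)
        table, meta, _ = simulate_counts(cfg)
        with pytest.raises(ValidationError, match="2 timepoints"):
            run_longitudinal(table, meta, n_permutations=100, seed=0)

    def test_longitudinal_deterministic(self):
        table, meta, _ = self._study(seed=33)
        r1 = run_longitudinal(table, meta, n_permutations=100, seed=2)
        r2 = run_longitudinal(table, meta, n_permutations=100, seed=2)
        pd.testing.assert_frame_equal(r1, r2)
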