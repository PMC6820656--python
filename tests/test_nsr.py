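import itertools
import math

import numpy as np
import pytest

from netvuln import (
    GeneSetCollection,
    RegulatoryNetwork,
    compare_nsr_groups,
    compute_nsr,
    count_nprg,
    generate_network,
    nsr_significance,
    nsr_table,
    select_biomarkers,
)
from netvuln.nsr import _sample_degree_preserving
from netvuln.errors import ParameterError

from conftest import random_bipartite
import pandas as pd


def brute_nsr_map(network):
    in_deg = {}
    for _, g in network.edges:
        in_deg[g] = in_deg.get(g, 0) + 1
    out = {m: 0 for m in network.mirnas}
    for m, g in network.edges:
        if in_deg[g] == 1:
            out[m] += 1
    return out


def enumerate_null_graphs(network):
    """Independent exhaustive enumeration of simple bipartite graphs with
    the observed degree sequences (uniform null), via raw product
    iteration with deduplication."""
    mirnas = list(network.mirnas)
    mrnas = list(network.mrnas)
    d_mi = {m: len([1 for a, _ in network.edges if a == m]) for m in mirnas}
    d_mr = {g: len([1 for _, b in network.edges if b == g]) for g in mrnas}
    choices = [itertools.combinations(mrnas, d_mi[m]) for m in mirnas]
    graphs = []
    for combo in itertools.product(*[list(c) for c in choices]):
        counts = {g: 0 for g in mrnas}
        for targets in combo:
            for g in targets:
                counts[g] += 1
        if counts == d_mr:
            graphs.append(frozenset(
                (m, g) for m, targets in zip(mirnas, combo) for g in targets
            ))
    return graphs


class TestComputeNSR:
    def test_toy_single_lines(self, toy_network):
        assert compute_nsr(toy_network) == {"m1": 1, "m2": 1}

    def test_all_shared_targets_zero(self):
        net = RegulatoryNetwork(
            [("m1", "a"), ("m2", "a"), ("m1", "b"), ("m2", "b")]
        )
        assert compute_nsr(net) == {"m1": 0, "m2": 0}

    def test_brute_force_oracle_on_random_networks(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            net = random_bipartite(
                rng,
                n_mirna=int(rng.integers(2, 7)),
                n_mrna=int(rng.integers(2, 13)),
                n_edges=int(rng.integers(1, 20)),
            )
            assert compute_nsr(net) == brute_nsr_map(net)

    def test_total_nsr_counts_each_single_mrna_once(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            net = random_bipartite(rng, 6, 10, 18)
            in_deg = net.in_degree()
            n_singles = sum(1 for g in net.mrnas if in_deg[g] == 1)
            assert sum(compute_nsr(net).values()) == n_singles


class TestNullModel:
    def test_rewiring_preserves_every_degree(self):
        net, _ = generate_network(n_mirna=15, n_mrna=40, mean_targets=6,
                                  n_planted=2, planted_excess_singles=5, seed=0)
        mi, gi = net.to_index_arrays()
        rng = np.random.default_rng(0)
        for _ in range(20):
            g = _sample_degree_preserving(mi, gi, len(net.mrnas), rng)
            np.testing.assert_array_equal(
                np.bincount(g, minlength=len(net.mrnas)),
                np.bincount(gi, minlength=len(net.mrnas)),
            )
            # simple graph: no duplicate edges
            keys = mi * len(net.mrnas) + g
            assert len(np.unique(keys)) == len(keys)

    def test_exact_enumeration_small_network(self):
        # m1->{a,b}, m2->{b,c}, m3->{c}: 5 degree-preserving simple graphs,
        # miRNA m1 holds the unique single-line mRNA 'a' in 2 of them.
        net = RegulatoryNetwork(
            [("m1", "a"), ("m1", "b"), ("m2", "b"), ("m2", "c"), ("m3", "c")]
        )
        graphs = enumerate_null_graphs(net)
        assert len(graphs) == 5
        p = nsr_significance(net, method="rewire")
        # independent oracle probability that nsr(m1) >= observed (=1)
        obs = compute_nsr(net)
        count = 0
        for g in graphs:
            sub = RegulatoryNetwork(sorted(g))
            if compute_nsr(sub).get("m1", 0) >= obs["m1"]:
                count += 1
        assert p["m1"] == pytest.approx(count / len(graphs))
        assert p["m1"] == pytest.approx(0.4)
        # zero NSR miRNAs can never exceed their observed value
        assert p["m2"] == pytest.approx(1.0)
        assert p["m3"] == pytest.approx(1.0)

    def test_planted_biomarker_significant(self):
        net, truth = generate_network(n_mirna=50, n_mrna=150, mean_targets=10,
                                      n_planted=1, planted_excess_singles=10,
                                      seed=5)
        p = nsr_significance(net, method="rewire", n_perm=1000, seed=1)
        m = truth.planted_biomarkers[0]
        assert p[m] < 0.01

    def test_smoothed_p_never_zero_or_above_one(self):
        net, _ = generate_network(n_mirna=10, n_mrna=30, mean_targets=4,
                                  n_planted=1, planted_excess_singles=4, seed=2)
        p = nsr_significance(net, n_perm=200, seed=3)
        assert all(1.0 / 201 <= v <= 1.0 for v in p.values())

    def test_low_n_perm_rejected(self):
        net, _ = generate_network(seed=0)
        with pytest.raises(ParameterError):
            nsr_significance(net, n_perm=50)

    def test_rank_variant_runs_and_orders_sensibly(self):
        net, truth = generate_network(n_mirna=30, n_mrna=100, mean_targets=8,
                                      n_planted=1, planted_excess_singles=10,
                                      seed=7)
        p = nsr_significance(net, method="rank")
        m = truth.planted_biomarkers[0]
        assert 0 <= p[m] <= 1
        assert p[m] <= min(p.values()) + 1e-12  # planted miRNA most significant


class TestCompareGroups:
    def test_complete_separation_4v4(self):
        p = compare_nsr_groups([10, 11, 12, 13], [1, 2, 3, 4])
        assert p == pytest.approx(1 / 70)

    def test_no_separation_p_large(self):
        p = compare_nsr_groups([5, 5, 5], [5, 5, 5])
        assert p > 0.5

    def test_matches_exhaustive_rank_enumeration(self):
        a = [9.0, 4.0, 7.0]
        b = [1.0, 3.0, 8.0, 2.0]
        # enumerate all C(7,3) assignments of the pooled ranks
        pooled = sorted(a + b)
        u_obs = sum(1 for x in a for y in b if x > y)
        count = 0
        total = 0
        for combo in itertools.combinations(range(7), 3):
            xs = [pooled[i] for i in combo]
            ys = [pooled[i] for i in range(7) if i not in combo]
            u = sum(1 for x in xs for y in ys if x > y)
            total += 1
            count += u >= u_obs
        assert compare_nsr_groups(a, b) == pytest.approx(count / total, abs=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ParameterError):
            compare_nsr_groups([], [1, 2])


class TestNPRGAndSelection:
    def test_disjoint_resistance_list_all_zero(self, toy_network):
        nprg = count_nprg(toy_network, ["zzz"])
        assert nprg == {"m1": 0, "m2": 0}

    def test_toy_overlap(self, toy_network):
        assert count_nprg(toy_network, ["b"]) == {"m1": 1, "m2": 1}

    def test_accepts_gene_set_collection(self, toy_network):
        sets = GeneSetCollection({"r": ("d", ("a", "c"))})
        assert count_nprg(toy_network, sets) == {"m1": 1, "m2": 1}

    def test_selection_boundary_strict(self):
        df = pd.DataFrame(
            {"nsr": [5, 6], "p_nsr": [0.01, 0.005], "nprg": [2, 0]},
            index=pd.Index(["mA", "mB"], name="mirna"),
        )
        out = select_biomarkers(df, nsr_alpha=0.01)
        # mA fails on p (0.01 not < 0.01), mB fails on nprg
        assert not out["selected"].any()

    def test_selection_monotone_in_resistance_list(self, toy_network):
        p = {"m1": 0.001, "m2": 0.5}
        base = pd.DataFrame({
            "nsr": [1, 1],
            "p_nsr": [p["m1"], p["m2"]],
            "nprg": list(count_nprg(toy_network, ["a"]).values()),
        }, index=pd.Index(["m1", "m2"], name="mirna"))
        bigger = base.copy()
        bigger["nprg"] = list(count_nprg(toy_network, ["a", "b"]).values())
        sel_base = set(select_biomarkers(base).index[select_biomarkers(base)["selected"]])
        sel_big = set(select_biomarkers(bigger).index[select_biomarkers(bigger)["selected"]])
        assert sel_base <= sel_big

    def test_output_sorted_by_nsr_then_id(self):
        df = pd.DataFrame(
            {"nsr": [3, 7, 3], "p_nsr": [0.5, 0.5, 0.5], "nprg": [0, 0, 0]},
            index=pd.Index(["mC", "mA", "mB"], name="mirna"),
        )
        out = select_biomarkers(df)
        assert list(out.index) == ["mA", "mB", "mC"]

    def test_full_table_recovers_planted(self):
        net, truth = generate_network(seed=9)
        table = nsr_table(net, truth.resistance_genes, n_perm=500, seed=1)
        selected = set(table.index[table["selected"]])
        assert set(truth.planted_biomarkers) <= selected
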