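"""DAG mechanics, triple patterns, CPTs, sampling, fitting, d-separation."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mitebn import (
    BayesNet,
    CPT,
    CycleError,
    DAG,
    classify_triples,
    d_separated,
    fit_cpds,
    joint_probability,
    joint_table,
    make_truth_net,
    random_net,
    sample,
)


class TestDAG:
    def test_cycle_rejected_on_mutation(self):
        dag = DAG(nodes="ABC", edges=[("A", "B"), ("B", "C")])
        with pytest.raises(CycleError):
            dag.add_edge("C", "A")

    def test_self_loop_and_duplicate_rejected(self):
        dag = DAG(nodes="AB", edges=[("A", "B")])
        with pytest.raises(ValueError):
            dag.add_edge("A", "A")
        with pytest.raises(ValueError):
            dag.add_edge("A", "B")

    def test_reverse_edge_rolls_back_on_cycle(self):
        dag = DAG(nodes="ABC", edges=[("A", "B"), ("A", "C"), ("C", "B")])
        with pytest.raises(CycleError):
            dag.reverse_edge("A", "B")  # B->A plus A->C->B is a cycle
        assert dag.has_edge("A", "B")


class TestClassifyTriples:
    @pytest.mark.parametrize(
        "edges, expected",
        [
            ([("X", "Y"), ("Y", "Z")], ("X", "Y", "Z", "chain")),
            ([("Y", "X"), ("Y", "Z")], ("X", "Y", "Z", "fork")),
            ([("X", "Y"), ("Z", "Y")], ("X", "Y", "Z", "collider")),
        ],
    )
    def test_canonical_patterns(self, edges, expected):
        dag = DAG(nodes="XYZ", edges=edges)
        (t,) = classify_triples(dag)
        assert (t.x, t.y, t.z, t.kind) == expected

    def test_empty_dag(self):
        assert classify_triples(DAG(nodes="XYZ")) == []

    def test_matches_exhaustive_enumeration_on_random_dags(self):
        for seed in range(20):
            net = random_net(6, seed=seed, edge_prob=0.4)
            dag = net.dag
            found = {(t.x, t.y, t.z, t.kind) for t in classify_triples(dag)}
            edge_set = set(dag.edges)
            expected = set()
            for trio in itertools.combinations(dag.nodes, 3):
                es = [
                    (u, v)
                    for u, v in itertools.permutations(trio, 2)
                    if (u, v) in edge_set
                ]
                if len(es) != 2:
                    continue
                (u1, v1), (u2, v2) = es
                if v1 == v2:
                    x, z = sorted((u1, u2))
                    expected.add((x, v1, z, "collider"))
                elif u1 == u2:
                    x, z = sorted((v1, v2))
                    expected.add((x, u1, z, "fork"))
                else:
                    chain = (u1, v1, v2) if v1 == u2 else (u2, v2, v1)
                    expected.add((*chain, "chain"))
            assert found == expected


class TestJointAndSampling:
    def test_single_node_joint(self):
        net = BayesNet(DAG(nodes=["A"]), {"A": CPT("A", (), np.array([0.3]))})
        assert joint_probability(net, {"A": 1}) == pytest.approx(0.3)
        assert joint_probability(net, {"A": 0}) == pytest.approx(0.7)

    @pytest.mark.parametrize("name", ["chain3", "collider3", "strong5", "paper11"])
    def test_joint_sums_to_one_for_fixtures(self, name):
        net = make_truth_net(name)
        k = len(net.nodes)
        total = sum(
            joint_probability(net, dict(zip(net.nodes, bits)))
            for bits in itertools.product((0, 1), repeat=k)
        ) if k <= 5 else joint_table(net)[1].sum()
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_joint_matches_enumerated_table(self):
        net = random_net(5, seed=3)
        nodes, table = joint_table(net)
        for bits in itertools.product((0, 1), repeat=5):
            assert table[bits] == pytest.approx(
                joint_probability(net, dict(zip(nodes, bits))), abs=1e-14
            )

    def test_degenerate_net_samples_all_ones(self):
        net = BayesNet(
            DAG(nodes="AB", edges=[("A", "B")]),
            {"A": CPT("A", (), [1.0]), "B": CPT("B", ("A",), [1.0, 1.0])},
        )
        assert sample(net, 50, seed=0).to_numpy().all()

    def test_fixed_seed_reproducible(self):
        net = make_truth_net("strong5")
        a = sample(net, 500, seed=42)
        b = sample(net, 500, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_sampled_marginals_within_3se(self):
        net = make_truth_net("strong5")
        n = 50_000
        data = sample(net, n, seed=7)
        nodes, table = joint_table(net)
        for i, node in enumerate(nodes):
            truth = table.sum(axis=tuple(j for j in range(len(nodes)) if j != i))[1]
            est = data[node].mean()
            se = np.sqrt(truth * (1 - truth) / n)
            assert abs(est - truth) < 3 * se + 1e-9


class TestFitCpds:
    def test_parentless_mle(self):
        data = pd.DataFrame({"A": [1] * 7 + [0] * 3})
        net = fit_cpds(DAG(nodes=["A"]), data, alpha=0.0)
        assert net.cpts["A"].p1[0] == pytest.approx(0.7)

    def test_laplace_prior_on_unobserved_configuration(self):
        data = pd.DataFrame({"A": [0, 0, 0, 0], "B": [0, 1, 0, 1]})
        net = fit_cpds(DAG(nodes="AB", edges=[("A", "B")]), data, alpha=1.0)
        # configuration A=1 never observed -> symmetric prior
        assert net.cpts["B"].p1[1] == pytest.approx(0.5)

    def test_mle_flags_unobserved_configuration(self):
        data = pd.DataFrame({"A": [0, 0], "B": [0, 1]})
        net = fit_cpds(DAG(nodes="AB", edges=[("A", "B")]), data, alpha=0.0)
        assert np.isnan(net.cpts["B"].p1[1])
        with pytest.raises(ValueError, match="undefined"):
            net.cpts["B"].prob(1, (1,))

    def test_parameter_recovery_improves_with_n(self):
        truth = make_truth_net("strong5")

        def max_err(n, seed):
            fitted = fit_cpds(truth.dag, sample(truth, n, seed=seed), alpha=1.0)
            return max(
                np.nanmax(np.abs(fitted.cpts[v].p1 - truth.cpts[v].p1)) for v in truth.nodes
            )

        small = [max_err(500, s) for s in range(5)]
        large = [max_err(50_000, s) for s in range(5)]
        assert max(large) < 0.02
        assert np.mean(small) > np.mean(large)


class TestSerialization:
    def test_json_roundtrip(self, tmp_path):
        net = make_truth_net("paper11")
        path = tmp_path / "net.json"
        net.save(path)
        back = BayesNet.load(path)
        assert back.dag == net.dag
        for node in net.nodes:
            np.testing.assert_allclose(back.cpts[node].p1, net.cpts[node].p1)

    def test_inconsistent_cpt_rejected(self):
        with pytest.raises(ValueError):
            BayesNet(
                DAG(nodes="AB", edges=[("A", "B")]),
                {"A": CPT("A", (), [0.5]), "B": CPT("B", (), [0.5])},
            )


class TestDSeparation:
    def test_chain_blocked_by_middle(self):
        dag = DAG(nodes="XYZ", edges=[("X", "Y"), ("Y", "Z")])
        assert d_separated(dag, "X", "Z", {"Y"})
        assert not d_separated(dag, "X", "Z")

    def test_collider_opens_under_conditioning(self):
        dag = DAG(nodes="XYZ", edges=[("X", "Y"), ("Z", "Y")])
        assert d_separated(dag, "X", "Z")
        assert not d_separated(dag, "X", "Z", {"Y"})

    def test_collider_descendant_opens_path(self):
        dag = DAG(nodes="XYZW", edges=[("X", "Y"), ("Z", "Y"), ("Y", "W")])
        assert not d_separated(dag, "X", "Z", {"W"})

    def test_matches_networkx_on_random_dags(self):
        for seed in range(25):
            net = random_net(7, seed=seed, edge_prob=0.3)
            g = net.dag.to_networkx()
            nodes = net.nodes
            rng = np.random.default_rng(seed)
            for _ in range(30):
                x, z = rng.choice(len(nodes), size=2, replace=False)
                rest = [i for i in range(len(nodes)) if i not in (x, z)]
                size = int(rng.integers(0, len(rest) + 1))
                cond = {nodes[i] for i in rng.choice(rest, size=size, replace=False)}
                assert d_separated(net.dag, nodes[x], nodes[z], cond) == nx.is_d_separator(
                    g, {nodes[x]}, {nodes[z]}, cond
                )

    def test_dsep_implies_conditional_independence(self):
        for seed in range(3):
            net = random_net(6, seed=seed, edge_prob=0.35)
            nodes, table = joint_table(net)
            for xi, zi in itertools.combinations(range(len(nodes)), 2):
                rest = [i for i in range(len(nodes)) if i not in (xi, zi)]
                for r in range(len(rest) + 1):
                    for cond in itertools.combinations(rest, r):
                        if not d_separated(
                            net.dag, nodes[xi], nodes[zi], {nodes[i] for i in cond}
                        ):
                            continue
                        dev = _max_ci_deviation(table, len(nodes), xi, zi, cond)
                        assert dev < 1e-12


def _max_ci_deviation(table, k, xi, zi, cond):
    """max over assignments of |P(x,z,y)P(y) - P(x,y)P(z,y)|."""
    others = tuple(i for i in range(k) if i not in (xi, zi) and i not in cond)
    pxzy = table.sum(axis=others) if others else table
    # axes of pxzy correspond to sorted([xi, zi, *cond])
    kept = sorted((xi, zi, *cond))
    ax_x, ax_z = kept.index(xi), kept.index(zi)
    py = pxzy.sum(axis=(ax_x, ax_z))
    pxy = pxzy.sum(axis=ax_z)
    pzy = pxzy.sum(axis=ax_x)
    dev = 0.0
    for bits in itertools.product((0, 1), repeat=len(kept)):
        y = tuple(b for i, b in zip(kept, bits) if i in cond)
        xy = tuple(b for i, b in zip(kept, bits) if i != zi)
        zy = tuple(b for i, b in zip(kept, bits) if i != xi)
        dev = max(dev, abs(pxzy[bits] * py[y] - pxy[xy] * pzy[zy]))
    return dev
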