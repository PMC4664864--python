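from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from metmod.similarity import cosine_similarity
from metmod.synthetic import (
    AbundanceSpec,
    MotifSpec,
    NetworkSpec,
    generate_abundance,
    generate_network,
    generate_pathway_graph,
    generate_pathways,
)


class TestGenerateNetwork:
    @pytest.mark.parametrize(
        "motif,size,n_edges,max_degree",
        [
            ("path", 3, 2, 2),
            ("star", 37, 36, 36),
            ("clique", 5, 10, 4),
            ("ring", 11, 11, 2),
        ],
    )
    def test_motif_closed_forms(self, motif, size, n_edges, max_degree):
        net, truth = generate_network(NetworkSpec(modules=(MotifSpec(motif, size),), seed=3))
        assert net.n_nodes == size and net.n_edges == n_edges
        assert max(d for _, d in net.simple_graph().degree()) == max_degree
        assert truth.n_modules == 1

    def test_bridged_cliques_edge_count(self):
        spec = NetworkSpec(
            modules=(MotifSpec("clique", 5), MotifSpec("clique", 6)),
            bridges=((0, 1, 1),),
            seed=11,
        )
        net, truth = generate_network(spec)
        assert net.n_edges == 10 + 15 + 1
        assert truth.n_modules == 2

    def test_er_block_connected(self):
        for seed in range(5):
            spec = NetworkSpec(modules=(MotifSpec("er_block", 12, 0.15),), seed=seed)
            net, _ = generate_network(spec)
            assert nx.is_connected(net.simple_graph())

    def test_motifs_are_connected_induced_subgraphs(self):
        spec = NetworkSpec(
            modules=(MotifSpec("path", 4), MotifSpec("star", 6), MotifSpec("ring", 5)),
            bridges=((0, 1, 2), (1, 2, 1)),
            seed=5,
        )
        net, truth = generate_network(spec)
        for members in truth.modules().values():
            assert nx.is_connected(net.simple_graph().subgraph(members))

    def test_multi_edge_pairs_added(self):
        spec = NetworkSpec(
            modules=(MotifSpec("clique", 4),),
            multi_edge_pairs=((0, 2),),
            seed=0,
        )
        net, _ = generate_network(spec)
        mult = net.multiplicities()
        assert sum(1 for c in mult.values() if c > 1) == 2

    def test_reproducible_and_seed_sensitive(self):
        spec = NetworkSpec(modules=(MotifSpec("er_block", 10, 0.4),), seed=42)
        a, _ = generate_network(spec)
        b, _ = generate_network(spec)
        assert sorted(a.graph.edges()) == sorted(b.graph.edges())
        c, _ = generate_network(NetworkSpec(modules=spec.modules, seed=43))
        assert sorted(a.graph.edges()) != sorted(c.graph.edges())

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="motif"):
            MotifSpec("blob", 3)
        with pytest.raises(ValueError, match="nonexistent"):
            NetworkSpec(modules=(MotifSpec("path", 3),), bridges=((0, 5, 1),))


class TestGeneratePathways:
    def test_exact_overlap(self):
        net, truth = generate_network(NetworkSpec(modules=(MotifSpec("clique", 8), MotifSpec("ring", 10)), seed=1))
        (pw,) = generate_pathways(truth, [(0, 8, 7, "P")], seed=2)
        module = truth.modules()[0]
        assert len(pw.members & module) == 7 and pw.size == 8

    def test_zero_overlap_disjoint(self):
        net, truth = generate_network(NetworkSpec(modules=(MotifSpec("clique", 8), MotifSpec("ring", 10)), seed=1))
        (pw,) = generate_pathways(truth, [(0, 20, 0, "P")], seed=2)
        assert not (pw.members & truth.modules()[0])
        assert pw.size == 20  # topped up with fresh identifiers

    def test_glycine_like_overlap_gives_printed_similarity(self):
        net, truth = generate_network(NetworkSpec(modules=(MotifSpec("star", 37), MotifSpec("ring", 40)), seed=1))
        (pw,) = generate_pathways(truth, [(0, 32, 22, "GST")], seed=2)
        assert cosine_similarity(truth.modules()[0], pw.members) == 63.94

    def test_excess_overlap_rejected(self):
        net, truth = generate_network(NetworkSpec(modules=(MotifSpec("path", 3),), seed=1))
        with pytest.raises(ValueError, match="overlap"):
            generate_pathways(truth, [(0, 5, 4, "P")], seed=0)


class TestGeneratePathwayGraph:
    @pytest.mark.parametrize(
        "size,topology,check",
        [
            (4, "path", lambda g: sorted(d for _, d in g.degree()) == [1, 1, 2, 2]),
            (8, "star", lambda g: max(d for _, d in g.degree()) == 7),
            (11, "ring", lambda g: all(d == 2 for _, d in g.degree()) and g.number_of_edges() == 11),
            (9, "er", nx.is_connected),
        ],
    )
    def test_topologies(self, size, topology, check):
        pg = generate_pathway_graph(size, topology, seed=4)
        assert pg.size == size and check(pg.graph)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            generate_pathway_graph(1, "path")


class TestGenerateAbundance:
    def test_null_fold_recovered(self):
        spec = AbundanceSpec(folds={"m": 1.0}, n_per_group=500, cv=0.1, seed=9)
        t = generate_abundance(spec)
        a = t.data.loc["m", t.samples_of("sham")].mean()
        b = t.data.loc["m", t.samples_of("ischemia")].mean()
        assert b / a == pytest.approx(1.0, abs=0.02)

    def test_valine_like_fold_recovered(self):
        spec = AbundanceSpec(folds={"valine": 1.64}, n_per_group=50, cv=0.1, seed=7)
        t = generate_abundance(spec)
        a = t.data.loc["valine", t.samples_of("sham")].mean()
        b = t.data.loc["valine", t.samples_of("ischemia")].mean()
        assert 1.5 <= b / a <= 1.8

    def test_seed_changes_table(self):
        s1 = generate_abundance(AbundanceSpec(folds={"m": 1.5}, seed=1))
        s2 = generate_abundance(AbundanceSpec(folds={"m": 1.5}, seed=2))
        assert not s1.data.equals(s2.data)
        s1b = generate_abundance(AbundanceSpec(folds={"m": 1.5}, seed=1))
        assert s1.data.equals(s1b.data)

    def test_mean_fold_unbiased_over_replicates(self):
        # statistical fidelity: mean estimated fold within 2% of the target
        target = 1.64
        est = []
        for seed in range(1000):
            t = generate_abundance(
                AbundanceSpec(folds={"m": target}, n_per_group=10, cv=0.2, seed=seed)
            )
            a = t.data.loc["m", t.samples_of("sham")].mean()
            b = t.data.loc["m", t.samples_of("ischemia")].mean()
            est.append(b / a)
        assert np.mean(est) == pytest.approx(target, rel=0.02)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            AbundanceSpec(folds={"m": -1.0})
        with pytest.raises(ValueError):
            AbundanceSpec(folds={"m": 1.0}, n_per_group=1)
        with pytest.raises(ValueError):
            AbundanceSpec(folds={"m": 1.0}, cv=0.0)
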