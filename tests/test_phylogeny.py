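"""Alignment, concatenation, distance models, NJ and bootstrap."""

import math
import random

import dendropy
import numpy as np
import pytest

import symcore as sc
from conftest import mutate, random_seq


def aln(taxa_rows, **kw):
    return sc.MultipleAlignment(
        taxa=[t for t, _ in taxa_rows], rows=[r for _, r in taxa_rows], **kw
    )


class TestAlignGene:
    def test_identical_sequences_gapless(self):
        a = sc.align_gene({"x": "ATGGCA" * 10, "y": "ATGGCA" * 10})
        assert a.rows[0] == a.rows[1]
        assert "-" not in a.rows[0]

    def test_single_gap_case(self):
        a = sc.align_gene({"x": "ACGT", "y": "AGT"})
        assert a.row("x") == "ACGT"
        assert a.row("y") == "A-GT"

    def test_simulated_orthologs_gapless(self):
        rng = random.Random(0)
        base = random_seq(rng, 240)
        seqs = {f"t{i}": mutate(base, 0.05, rng) for i in range(5)}
        a = sc.align_gene(seqs)
        assert a.length == 240
        assert all("-" not in r for r in a.rows)

    def test_empty_sequence_rejected(self):
        with pytest.raises(sc.ParameterError):
            sc.align_gene({"x": "ACGT", "y": ""})


class TestConcatenate:
    def test_singleton_identity(self):
        a = aln([("x", "ACGT"), ("y", "ACGA")], name="g1")
        sm = sc.concatenate([a])
        assert sm.alignment.rows == a.rows
        assert sm.partitions == {"g1": (0, 4)}

    def test_length_additivity_and_partitions(self):
        a = aln([("x", "A" * 100), ("y", "C" * 100)], name="g1")
        b = aln([("x", "G" * 250), ("y", "T" * 250)], name="g2")
        sm = sc.concatenate([a, b])
        assert sm.alignment.length == 350
        assert sm.partitions == {"g1": (0, 100), "g2": (100, 350)}

    def test_drop_incomplete_policy(self):
        a = aln([("x", "AAAA"), ("y", "CCCC"), ("z", "GGGG")])
        b = aln([("x", "TT"), ("y", "AA")])
        sm = sc.concatenate([a, b], taxon_policy="drop-incomplete")
        assert set(sm.alignment.taxa) == {"x", "y"}

    def test_pad_gaps_policy(self):
        a = aln([("x", "AAAA"), ("y", "CCCC"), ("z", "GGGG")])
        b = aln([("x", "TT"), ("y", "AA")])
        sm = sc.concatenate([a, b], taxon_policy="pad-gaps")
        assert sm.alignment.row("z") == "GGGG--"

    def test_no_shared_taxa_is_error(self):
        a = aln([("x", "AAAA"), ("y", "CCCC")])
        b = aln([("w", "TT"), ("v", "AA")])
        with pytest.raises(sc.ParameterError):
            sc.concatenate([a, b], taxon_policy="drop-incomplete")


class TestDistances:
    def test_identical_rows_zero(self):
        d = sc.distance_matrix(aln([("x", "ACGTACGT"), ("y", "ACGTACGT")]), "jc")
        assert d.values[0, 1] == 0.0

    def test_jc_closed_form(self):
        rows = aln([("x", "A" * 70 + "C" * 30), ("y", "A" * 70 + "G" * 30)])
        d = sc.distance_matrix(rows, "jc")
        assert d.values[0, 1] == pytest.approx(-0.75 * math.log(1 - 0.4), abs=1e-4)
        assert d.values[0, 1] == pytest.approx(0.3831, abs=1e-4)

    def test_jc_saturation_capped(self):
        rows = aln([("x", "A" * 25 + "C" * 75), ("y", "G" * 25 + "T" * 75)])
        d = sc.distance_matrix(rows, "jc", saturation_cap=5.0)
        assert d.saturated[0, 1]
        assert d.values[0, 1] == 5.0

    def test_k2p_matches_manual_formula(self):
        # 10 transitions (A<->G) and 5 transversions (A<->C) over 100 sites
        x = "A" * 100
        y = "G" * 10 + "C" * 5 + "A" * 85
        d = sc.distance_matrix(aln([("x", x), ("y", y)]), "k2p")
        P, Q = 0.10, 0.05
        want = -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
        assert d.values[0, 1] == pytest.approx(want, abs=1e-9)

    def test_pairwise_deletion(self):
        rows = aln([("x", "ACGT--GT"), ("y", "ACGAAC-T"), ("z", "ACGTACGT")])
        d = sc.distance_matrix(rows, "p")
        # x-y compare only the 5 columns where both are ungapped: 1 mismatch
        assert d.values[0, 1] == pytest.approx(1 / 5)

    def test_zero_comparable_columns_error(self):
        rows = aln([("x", "AC--"), ("y", "--GT")])
        with pytest.raises(sc.ParameterError):
            sc.distance_matrix(rows, "p")

    def test_permutation_equivariance(self):
        rng = random.Random(1)
        base = random_seq(rng, 150)
        seqs = [("a", mutate(base, 0.1, rng)), ("b", mutate(base, 0.2, rng)),
                ("c", mutate(base, 0.3, rng))]
        d1 = sc.distance_matrix(aln(seqs), "jc")
        d2 = sc.distance_matrix(aln(seqs[::-1]), "jc")
        for i, ti in enumerate(d1.taxa):
            for j, tj in enumerate(d1.taxa):
                assert d1.values[i, j] == pytest.approx(d2.get(ti, tj))

    def test_concat_p_distance_is_weighted_average(self):
        rng = random.Random(2)
        genes = []
        for k, L in enumerate((90, 210)):
            base = random_seq(rng, L)
            genes.append(
                aln([("x", base), ("y", mutate(base, 0.1 * (k + 1), rng))],
                    name=f"g{k}")
            )
        per_gene = [sc.distance_matrix(g, "p").values[0, 1] for g in genes]
        sm = sc.concatenate(genes)
        combined = sc.distance_matrix(sm, "p").values[0, 1]
        want = (90 * per_gene[0] + 210 * per_gene[1]) / 300
        assert combined == pytest.approx(want, abs=1e-12)


def tree_from_newick(newick, taxa):
    return sc.PhyloTree(
        tree=dendropy.Tree.get(data=newick, schema="newick"), taxa=list(taxa)
    )


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        dm = sc.DistanceMatrix(taxa=["a", "b", "c"], values=D,
                               saturated=np.zeros((3, 3), bool))
        t = sc.nj_tree(dm)
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in t.tree.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx((5 + 9 - 10) / 2)
        assert lengths["b"] == pytest.approx((5 + 10 - 9) / 2)
        assert lengths["c"] == pytest.approx((9 + 10 - 5) / 2)

    def test_additive_four_taxon_recovery(self):
        # tree ((A:1,B:2):4,(C:2,D:3)) -> additive distances
        D = np.array(
            [[0, 3, 7, 8], [3, 0, 8, 9], [7, 8, 0, 5], [8, 9, 5, 0]], dtype=float
        )
        dm = sc.DistanceMatrix(taxa=list("ABCD"), values=D,
                               saturated=np.zeros((4, 4), bool))
        t = sc.nj_tree(dm)
        want = tree_from_newick("((A:1,B:2):4,(C:2,D:3));", "ABCD")
        assert sc.robinson_foulds(t, want) == 0
        # branch lengths exact: total tree length 1+2+4+2+3
        total = sum(e.length for e in t.tree.preorder_edge_iter() if e.length)
        assert total == pytest.approx(12.0)

    def test_agrees_with_dendropy_on_random_matrices(self):
        rng = np.random.default_rng(3)
        for n in (5, 6, 8):
            # random tree-like data: perturbed ultrametric
            coords = rng.random((n, 4))
            D = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    D[i, j] = D[j, i] = np.abs(coords[i] - coords[j]).sum() + 0.05
            taxa = [f"t{i}" for i in range(n)]
            dm = sc.DistanceMatrix(taxa=taxa, values=D,
                                   saturated=np.zeros((n, n), bool))
            mine = sc.nj_tree(dm)
            # dendropy's NJ as the independent implementation
            csv = "," + ",".join(taxa) + "\n" + "\n".join(
                taxa[i] + "," + ",".join(str(D[i, j]) for j in range(n))
                for i in range(n)
            )
            import io as _io

            pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
                src=_io.StringIO(csv), delimiter=","
            )
            ref = pdm.nj_tree()
            ref_pt = sc.PhyloTree(tree=ref, taxa=taxa)
            assert sc.robinson_foulds(mine, ref_pt) == 0

    def test_simulated_low_divergence_topology(self):
        rep = sc.simulate_ancestor(40, seed=13)
        newick = "(((A:0.02,B:0.02):0.02,(C:0.02,D:0.02):0.02):0.02,E:0.04);"
        scen = sc.EvolutionScenario(tree=newick, loss_prob=0, gain_rate=0,
                                    omega=0.5, seed=13)
        genomes, _ = sc.evolve_clade(rep, scen)
        alns = [
            sc.MultipleAlignment(
                taxa=list(genomes),
                rows=[genomes[g][k].seq for g in genomes],
                name=f"g{k}",
            )
            for k in range(len(rep.genes))
        ]
        sm = sc.concatenate(alns)
        t = sc.nj_tree(sc.distance_matrix(sm, "jc"))
        want = tree_from_newick(newick, list(genomes))
        assert sc.robinson_foulds(t, want) == 0

    def test_outgroup_rooting(self):
        D = np.array(
            [[0, 3, 7, 8], [3, 0, 8, 9], [7, 8, 0, 5], [8, 9, 5, 0]], dtype=float
        )
        dm = sc.DistanceMatrix(taxa=list("ABCD"), values=D,
                               saturated=np.zeros((4, 4), bool))
        t = sc.nj_tree(dm, outgroup="D")
        root_children = t.tree.seed_node.child_nodes()
        sides = [
            {lf.taxon.label for lf in c.leaf_iter()} for c in root_children
        ]
        assert {"D"} in sides

    def test_unknown_outgroup_rejected(self):
        dm = sc.DistanceMatrix(
            taxa=["a", "b", "c"], values=np.ones((3, 3)) - np.eye(3),
            saturated=np.zeros((3, 3), bool),
        )
        with pytest.raises(sc.ParameterError):
            sc.nj_tree(dm, outgroup="zz")


class TestBootstrap:
    def _signal_supermatrix(self):
        rng = random.Random(4)
        base = random_seq(rng, 400)
        a = mutate(base, 0.02, rng)
        b = mutate(a, 0.02, rng)
        c = mutate(base, 0.25, rng)
        d = mutate(c, 0.02, rng)
        rows = aln([("a", a), ("b", b), ("c", c), ("d", d)])
        return sc.Supermatrix(alignment=rows, partitions={"g": (0, 400)})

    def test_strong_signal_full_support(self):
        t = sc.bootstrap_support(self._signal_supermatrix(), n_reps=30, seed=1)
        assert t.supports
        assert all(v == 100.0 for v in t.supports.values())

    def test_single_replicate_support_binary(self):
        t = sc.bootstrap_support(self._signal_supermatrix(), n_reps=1, seed=2)
        assert set(t.supports.values()) <= {0.0, 100.0}

    def test_deterministic_given_seed(self):
        sm = self._signal_supermatrix()
        t1 = sc.bootstrap_support(sm, n_reps=10, seed=3)
        t2 = sc.bootstrap_support(sm, n_reps=10, seed=3)
        assert t1.newick() == t2.newick()
        assert t1.supports == t2.supports
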