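"""RBH orthology, core-genome intersection and loss accounting."""

import random

import pytest

import symcore as sc
from conftest import random_seq


def rec(locus, genome, seq):
    return sc.GeneRecord(locus_id=locus, genome_id=genome, seq=seq)


def hitmap(qg, sg, mapping):
    hits = {
        q: sc.SimilarityHit(
            query_locus=q, subject_locus=s, identity=0.9, query_coverage=1.0,
            subject_coverage=1.0, score=100,
        )
        for q, s in mapping.items()
    }
    return sc.BestHitMap(query_genome=qg, subject_genome=sg, hits=hits)


class TestReciprocalBestHits:
    def test_genome_vs_itself(self):
        rng = random.Random(0)
        genes = [rec(f"g{i}", "GA", random_seq(rng, 250)) for i in range(15)]
        hits = sc.best_hits(genes, genes)
        table = sc.reciprocal_best_hits(hits, hits)
        assert sorted(table.pairs) == [(g.locus_id, g.locus_id) for g in sorted(genes, key=lambda r: r.locus_id)]

    def test_asymmetric_best_excluded(self):
        ab = hitmap("GA", "GB", {"x": "y"})
        ba = hitmap("GB", "GA", {"y": "z"})
        table = sc.reciprocal_best_hits(ab, ba)
        assert table.pairs == []

    def test_mismatched_genomes_rejected(self):
        with pytest.raises(sc.ParameterError):
            sc.reciprocal_best_hits(hitmap("GA", "GB", {}), hitmap("GA", "GB", {}))

    def test_symmetry(self):
        ab = hitmap("GA", "GB", {"a1": "b1", "a2": "b2", "a3": "b9"})
        ba = hitmap("GB", "GA", {"b1": "a1", "b2": "a2", "b9": "a4"})
        t1 = sc.reciprocal_best_hits(ab, ba)
        t2 = sc.reciprocal_best_hits(ba, ab)
        assert sorted(t1.pairs) == sorted((b, a) for a, b in t2.pairs)
        # one-to-one
        assert len({a for a, _ in t1.pairs}) == len(t1.pairs)
        assert len({b for _, b in t1.pairs}) == len(t1.pairs)

    def test_simulated_pair_count_matches_truth(self, pair_clade):
        _, _, genomes, truth = pair_clade
        table = sc.rbh_between(genomes["A"], genomes["B"], sc.DEFAULT_PARAMS)
        expected = len(truth.core_of(["A", "B"]))
        assert abs(len(table) - expected) <= 0.02 * expected


class TestGenusCore:
    def test_identical_members(self):
        rng = random.Random(1)
        ref = [rec(f"g{i}", "R", random_seq(rng, 250)) for i in range(10)]
        twin = [rec(g.locus_id, "M", g.seq) for g in ref]
        table = sc.rbh_between(ref, twin, sc.DEFAULT_PARAMS)
        core = sc.genus_core(ref, ["R", "M"], [table])
        assert core.loci == {g.locus_id for g in ref}

    def test_single_absence_excluded(self):
        rng = random.Random(2)
        ref = [rec(f"g{i}", "R", random_seq(rng, 250)) for i in range(10)]
        member = [rec(g.locus_id, "M", g.seq) for g in ref if g.locus_id != "g3"]
        table = sc.rbh_between(ref, member, sc.DEFAULT_PARAMS)
        core = sc.genus_core(ref, ["R", "M"], [table])
        assert "g3" not in core.loci
        assert core.loci == {g.locus_id for g in ref} - {"g3"}

    def test_missing_table_is_error(self):
        ref = [rec("g0", "R", "ACGT" * 40)]
        with pytest.raises(sc.ParameterError):
            sc.genus_core(ref, ["R", "M"], [])

    def test_core_monotone_in_members(self, quad_clade):
        _, _, genomes, _ = quad_clade
        t_a2 = sc.rbh_between(genomes["A1"], genomes["A2"], sc.DEFAULT_PARAMS)
        t_b1 = sc.rbh_between(genomes["A1"], genomes["B1"], sc.DEFAULT_PARAMS)
        small = sc.genus_core(genomes["A1"], ["A1", "A2"], [t_a2])
        large = sc.genus_core(genomes["A1"], ["A1", "A2", "B1"], [t_a2, t_b1])
        assert large.loci <= small.loci

    def test_recovers_truth_clade_core(self, quad_clade):
        _, _, genomes, truth = quad_clade
        t = sc.rbh_between(genomes["A1"], genomes["A2"], sc.DEFAULT_PARAMS)
        core = sc.genus_core(genomes["A1"], ["A1", "A2"], [t], clade="gA")
        expected = truth.clade_core("gA")
        # recovered core may also contain stem-branch gains shared by members
        assert len(expected & core.loci) >= 0.98 * len(expected)
        assert abs(len(core) - len(expected)) <= max(3, 0.05 * len(expected))


class TestLcaCore:
    def test_degenerate_bridge(self):
        rng = random.Random(3)
        ref = [rec(f"g{i}", "R", random_seq(rng, 250)) for i in range(8)]
        core_a = sc.CoreGenome(clade="A", reference="R", loci={"g0", "g1", "g2"}, members=["R"])
        core_b = sc.CoreGenome(clade="B", reference="R", loci={"g1", "g2", "g3"}, members=["R"])
        bridge = sc.OrthologTable(a_id="R", b_id="R", pairs=[(g.locus_id, g.locus_id) for g in ref])
        lca = sc.lca_core(core_a, core_b, bridge)
        assert lca.loci == {"g1", "g2"}
        assert lca.reference == "R"

    def test_disjoint_content_empty(self):
        core_a = sc.CoreGenome(clade="A", reference="RA", loci={"a1"}, members=["RA"])
        core_b = sc.CoreGenome(clade="B", reference="RB", loci={"b1"}, members=["RB"])
        bridge = sc.OrthologTable(a_id="RA", b_id="RB", pairs=[])
        assert sc.lca_core(core_a, core_b, bridge).loci == set()

    def test_wrong_bridge_rejected(self):
        core_a = sc.CoreGenome(clade="A", reference="RA", loci=set(), members=[])
        core_b = sc.CoreGenome(clade="B", reference="RB", loci=set(), members=[])
        bridge = sc.OrthologTable(a_id="RX", b_id="RB", pairs=[])
        with pytest.raises(sc.ParameterError):
            sc.lca_core(core_a, core_b, bridge)

    def test_lca_law(self, quad_clade):
        _, _, genomes, truth = quad_clade
        params = sc.DEFAULT_PARAMS
        t_a = sc.rbh_between(genomes["A1"], genomes["A2"], params)
        t_b = sc.rbh_between(genomes["B1"], genomes["B2"], params)
        core_a = sc.genus_core(genomes["A1"], ["A1", "A2"], [t_a], clade="gA")
        core_b = sc.genus_core(genomes["B1"], ["B1", "B2"], [t_b], clade="gB")
        bridge = sc.rbh_between(genomes["A1"], genomes["B1"], params)
        lca = sc.lca_core(core_a, core_b, bridge)
        assert lca.loci <= core_a.loci
        assert len(lca) <= min(len(core_a), len(core_b))
        expected = truth.clade_core("anc")
        assert abs(len(lca) - len(expected)) <= max(3, 0.03 * len(expected))


class TestLossAccounting:
    def _core_and_table(self, n=20, retained=15):
        loci = {f"g{i}" for i in range(n)}
        core = sc.CoreGenome(clade="LCA", reference="R", loci=loci, members=["R"])
        pairs = [(f"g{i}", f"t{i}") for i in range(retained)]
        table = sc.OrthologTable(a_id="R", b_id="T", pairs=pairs)
        return core, table

    def test_partition_invariant(self):
        core, table = self._core_and_table()
        ledger = sc.loss_accounting(core, table, "T", {"g0": "motility"})
        assert ledger.retained | ledger.lost == core.loci
        assert not (ledger.retained & ledger.lost)
        assert ledger.n_retained + ledger.n_lost == ledger.lca_size
        assert sum(ledger.lost_by_category.values()) == ledger.n_lost

    def test_self_target_loses_nothing(self):
        core, _ = self._core_and_table()
        table = sc.OrthologTable(a_id="R", b_id="R", pairs=[(l, l) for l in core.loci])
        ledger = sc.loss_accounting(core, table, "R")
        assert ledger.lost == set()

    def test_uncategorized_counts_as_hypothetical(self):
        core, table = self._core_and_table(n=10, retained=7)
        ledger = sc.loss_accounting(core, table, "T", {})
        assert ledger.lost_by_category == {"hypothetical": 3}

    def test_exact_on_zero_divergence_target(self, quad_clade):
        _, _, genomes, truth = quad_clade
        params = sc.DEFAULT_PARAMS
        t_a = sc.rbh_between(genomes["A1"], genomes["A2"], params)
        t_b = sc.rbh_between(genomes["B1"], genomes["B2"], params)
        core_a = sc.genus_core(genomes["A1"], ["A1", "A2"], [t_a], clade="gA")
        core_b = sc.genus_core(genomes["B1"], ["B1", "B2"], [t_b], clade="gB")
        bridge = sc.rbh_between(genomes["A1"], genomes["B1"], params)
        lca = sc.lca_core(core_a, core_b, bridge)
        table = sc.rbh_between(genomes["A1"], genomes["T"], params)
        ledger = sc.loss_accounting(lca, table, "T")
        truly_absent = {
            l for l in truth.ancestral_loci if l not in truth.inventories["T"]
        }
        assert ledger.lost == truly_absent & lca.loci
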