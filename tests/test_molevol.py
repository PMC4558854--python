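"""Codon alignment and NG86 dN/dS, checked against exhaustive pathway
enumeration built directly on Biopython's translator."""

import numpy as np
import pytest

import symcore as sc
from symcore import genetics
from symcore.molevol import _tables
from oracles import ng86_pair_oracle, ng86_sites_oracle


def rec(locus, genome, seq):
    return sc.GeneRecord(locus_id=locus, genome_id=genome, seq=seq)


def ca_from_codons(codons_a, codons_b):
    return sc.CodonAlignment(
        a_locus="a", b_locus="b",
        codons_a=np.array([genetics.CODON_INDEX[c] for c in codons_a]),
        codons_b=np.array([genetics.CODON_INDEX[c] for c in codons_b]),
        dropped=0,
    )


class TestCodonAlign:
    def test_identical_sequences(self):
        seq = "ATG" + "GCTGAAACT" * 33
        ca = sc.codon_align(rec("a", "A", seq), rec("b", "B", seq))
        assert ca.n_codons == 100
        assert ca.dropped == 0

    def test_in_frame_insertion_dropped(self):
        a = "ATG" + "GCTGAA" * 20
        b = "ATG" + "GCTGAA" * 10 + "CCTCCTCCT" + "GCTGAA" * 10
        ca = sc.codon_align(rec("a", "A", a), rec("b", "B", b))
        assert ca.dropped == 3
        assert ca.n_codons == 41
        est = sc.ng86_estimate(ca)
        assert est.Sd == 0.0 and est.Nd == 0.0  # flanks are identical

    def test_terminal_stop_trimmed(self):
        seq = "ATG" + "GCTGAAACT" * 12 + "TAA"
        ca = sc.codon_align(rec("a", "A", seq), rec("b", "B", seq))
        assert ca.n_codons == 37

    def test_internal_stop_rejected(self):
        seq = "ATG" + "GCT" * 20 + "TAA" + "GCT" * 20
        with pytest.raises(sc.CodonAlignmentError):
            sc.codon_align(rec("a", "A", seq), rec("b", "B", seq))

    def test_too_few_columns_filtered(self):
        a = "ATG" + "GCTGAA" * 5
        with pytest.raises(sc.AlignmentFilterError):
            sc.codon_align(rec("a", "A", a), rec("b", "B", a), min_codons=30)

    def test_dissimilar_pair_fails_filter(self):
        a = "ATG" + "GCA" * 40
        b = "ATG" + "TTT" * 8
        with pytest.raises(sc.AlignmentFilterError):
            sc.codon_align(rec("a", "A", a), rec("b", "B", b))


class TestNG86:
    def test_identical_zero(self):
        codons = ["ATG"] + ["GAA"] * 99
        est = sc.ng86_estimate(ca_from_codons(codons, codons))
        assert est.Sd == est.Nd == 0.0
        assert est.dS == est.dN == 0.0
        assert not est.saturated

    def test_single_synonymous_difference(self):
        base = ["ATG"] + ["GAA"] * 99
        other = list(base)
        other[50] = "TTC"
        base[50] = "TTT"  # Phe -> Phe, third-position transition
        est = sc.ng86_estimate(ca_from_codons(base, other))
        assert est.Sd == 1.0
        assert est.Nd == 0.0

    def test_pathway_averaging_against_oracle(self):
        base = ["ATG"] + ["GAA"] * 99
        other = list(base)
        base[10], other[10] = "TTT", "GTA"  # two-difference codon
        est = sc.ng86_estimate(ca_from_codons(base, other))
        sd, nd = ng86_pair_oracle("TTT", "GTA")
        assert est.Sd == pytest.approx(sd)
        assert est.Nd == pytest.approx(nd)

    def test_full_pairwise_table_matches_oracle(self):
        """Every sense-codon pair's (Sd, Nd) equals exhaustive enumeration."""
        _, pair_sd, pair_nd = _tables()
        for c1 in genetics.SENSE_CODONS:
            i1 = genetics.CODON_INDEX[c1]
            for c2 in genetics.SENSE_CODONS:
                i2 = genetics.CODON_INDEX[c2]
                sd, nd = ng86_pair_oracle(c1, c2)
                assert pair_sd[i1, i2] == pytest.approx(sd), (c1, c2)
                assert pair_nd[i1, i2] == pytest.approx(nd), (c1, c2)

    def test_site_fractions_match_oracle(self):
        syn, _, _ = _tables()
        for codon in genetics.SENSE_CODONS:
            assert syn[genetics.CODON_INDEX[codon]] == pytest.approx(
                ng86_sites_oracle(codon)
            ), codon

    def test_site_conservation(self):
        rng = np.random.default_rng(0)
        sense = np.array([genetics.CODON_INDEX[c] for c in genetics.SENSE_CODONS])
        for _ in range(5):
            L = int(rng.integers(40, 120))
            ca = sc.CodonAlignment(
                a_locus="a", b_locus="b",
                codons_a=sense[rng.integers(0, len(sense), L)],
                codons_b=sense[rng.integers(0, len(sense), L)],
                dropped=0,
            )
            est = sc.ng86_estimate(ca)
            assert est.S_sites + est.N_sites == pytest.approx(3 * L)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        sense = np.array([genetics.CODON_INDEX[c] for c in genetics.SENSE_CODONS])
        a = sense[rng.integers(0, len(sense), 60)]
        b = sense[rng.integers(0, len(sense), 60)]
        ab = sc.ng86_estimate(
            sc.CodonAlignment(a_locus="a", b_locus="b", codons_a=a, codons_b=b, dropped=0)
        )
        ba = sc.ng86_estimate(
            sc.CodonAlignment(a_locus="b", b_locus="a", codons_a=b, codons_b=a, dropped=0)
        )
        assert ab.Sd == pytest.approx(ba.Sd)
        assert ab.S_sites == pytest.approx(ba.S_sites)
        assert ab.pN == pytest.approx(ba.pN)

    def test_jc_correction_and_saturation_flag(self):
        # pS beyond the JC domain -> saturated, dS undefined
        base = ["GAA"] * 50
        other = ["GAG"] * 50  # every codon one synonymous transition
        est = sc.ng86_estimate(ca_from_codons(base, other))
        assert est.saturated
        assert est.dS is None


class TestGenomeWide:
    def test_identical_pairs_zero(self):
        genes = [
            rec(f"g{i}", "A", "ATG" + "GCTGAAACT" * 20) for i in range(5)
        ]
        partners = [rec(g.locus_id, "B", g.seq) for g in genes]
        table = sc.OrthologTable(
            a_id="A", b_id="B", pairs=[(g.locus_id, g.locus_id) for g in genes]
        )
        df, summary = sc.genome_wide_dnds(table, genes, partners)
        assert summary["mean_dS_unsaturated"] == 0.0
        assert summary["fraction_saturated"] == 0.0
        assert len(df) == 5

    def test_all_filtered_warns_not_crashes(self):
        a = [rec("g", "A", "ATG" + "GCA" * 5)]
        b = [rec("g", "B", "ATG" + "GCA" * 5)]
        table = sc.OrthologTable(a_id="A", b_id="B", pairs=[("g", "g")])
        with pytest.warns(UserWarning):
            df, summary = sc.genome_wide_dnds(table, a, b)
        assert df.empty
        assert summary["n_skipped"] == 1

    def test_mean_dS_monotone_in_divergence(self):
        rep = sc.simulate_ancestor(40, seed=17)
        means = []
        for t in (0.1, 0.3, 0.8):
            scen = sc.EvolutionScenario(
                tree=f"(A:{t / 2},B:{t / 2});", loss_prob=0, gain_rate=0,
                omega=0.3, seed=17,
            )
            genomes, _ = sc.evolve_clade(rep, scen)
            table = sc.OrthologTable(
                a_id="A", b_id="B",
                pairs=[(g.locus_id, g.locus_id) for g in genomes["A"]],
            )
            _, summary = sc.genome_wide_dnds(table, genomes["A"], genomes["B"])
            means.append(summary["mean_dS_unsaturated"])
        assert means[0] < means[1] < means[2]

    def test_plot_returns_axes(self):
        import matplotlib

        matplotlib.use("Agg")
        genes = [rec("g", "A", "ATG" + "GCTGAAACT" * 20)]
        partners = [rec("g", "B", genes[0].seq)]
        table = sc.OrthologTable(a_id="A", b_id="B", pairs=[("g", "g")])
        df, _ = sc.genome_wide_dnds(table, genes, partners)
        ax = sc.plot_dnds(df)
        assert ax is not None
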