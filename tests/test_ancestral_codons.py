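import numpy as np
import pytest

import convflight as cf
from convflight.ancestral_codons import (
    FLIGHTLESS,
    NON_SUSTAINED,
    SUSTAINED,
    UNCLASSIFIED,
    ReconstructionError,
)
from oracles import enumeration_posterior


def labels_for(species):
    return cf.SpeciesGroupTable(
        {s: ("flight_degenerate" if s.startswith("deg") else "flying") for s in species}
    )


@pytest.fixture(scope="module")
def four_taxon_tree(tmp_path_factory):
    p = tmp_path_factory.mktemp("trees") / "four.nwk"
    p.write_text("((deg01:0.1,fly01:0.15):0.05,(deg02:0.2,fly02:0.1):0.08);\n")
    return cf.read_tree(p)


class TestCodonReconstruction:
    def test_invariant_codon_is_recovered_with_high_pp(self, four_taxon_tree):
        aln = cf.LabeledAlignment(
            "g", {sp: "AGT" for sp in ["deg01", "fly01", "deg02", "fly02"]},
            labels_for(["deg01", "fly01", "deg02", "fly02"]),
        )
        rec = cf.reconstruct_codon(aln, 1, four_taxon_tree, cf.jc69())
        codon, pp = rec.root_call()
        assert codon == "AGT" and pp > 0.9

    def test_two_leaf_symmetric_split_gives_half_pp(self, tree_factory):
        phy = tree_factory("(deg01:0.2,fly01:0.2);")
        aln = cf.LabeledAlignment(
            "g", {"deg01": "AGT", "fly01": "GGT"}, labels_for(["deg01", "fly01"])
        )
        rec = cf.reconstruct_codon(aln, 1, phy, cf.jc69())
        codon, pp = rec.root_call()
        # first position A/G exactly equivocal; PP is that 1/2 multiplied by
        # the (high but not perfect) certainty of the two invariant positions
        assert codon in ("AGT", "GGT")
        row = rec.codon_posteriors[list(rec.node_indices).index(rec.tree_index.root_index)]
        assert row[rec.codons.index("AGT")] == pytest.approx(row[rec.codons.index("GGT")], rel=1e-9)
        assert 0.4 < pp <= 0.5

    def test_codon_posterior_is_product_of_position_posteriors(self, four_taxon_tree):
        seqs = {"deg01": "GGTAC", "fly01": "AGTAC", "deg02": "GCTAC", "fly02": "AGAAC"}
        aln = cf.LabeledAlignment("g", seqs, labels_for(list(seqs)))
        model = cf.hky85(2.0, np.array([0.3, 0.2, 0.2, 0.3]), gamma_shape=0.7, n_categories=4)
        rec = cf.reconstruct_codon(aln, 2, four_taxon_tree, model)
        post = rec.codon_posteriors[list(rec.node_indices).index(rec.tree_index.root_index)]
        # oracle: per-position enumeration posteriors, multiplied and renormalised
        pos_posts = []
        for col in (2, 3, 4):
            leaf_states = {sp: seqs[sp][col - 1] for sp in seqs}
            pos_posts.append(enumeration_posterior(four_taxon_tree, model, leaf_states, None))
        expect = np.einsum("i,j,k->ijk", *pos_posts).ravel()
        expect /= expect.sum()
        assert post == pytest.approx(expect, abs=1e-10)

    def test_pp_is_one_only_when_every_position_is_certain(self, four_taxon_tree):
        aln = cf.LabeledAlignment(
            "g", {sp: "AGT" for sp in ["deg01", "fly01", "deg02", "fly02"]},
            labels_for(["deg01", "fly01", "deg02", "fly02"]),
        )
        rec = cf.reconstruct_codon(aln, 1, four_taxon_tree, cf.jc69())
        for i, node in enumerate(rec.node_indices):
            _, pp = rec.best_codon(int(node))
            assert pp <= 1.0 + 1e-12

    def test_all_missing_column_is_an_error(self, four_taxon_tree):
        aln = cf.LabeledAlignment(
            "g",
            {sp: "ANT" for sp in ["deg01", "fly01", "deg02", "fly02"]},
            labels_for(["deg01", "fly01", "deg02", "fly02"]),
        )
        with pytest.raises(ReconstructionError, match="column 2"):
            cf.reconstruct_codon(aln, 1, four_taxon_tree, cf.jc69())

    def test_out_of_range_codon_rejected(self, four_taxon_tree):
        aln = cf.LabeledAlignment(
            "g", {sp: "AGTC" for sp in ["deg01", "fly01", "deg02", "fly02"]},
            labels_for(["deg01", "fly01", "deg02", "fly02"]),
        )
        with pytest.raises(IndexError):
            cf.reconstruct_codon(aln, 3, four_taxon_tree, cf.jc69())


class TestPhenotypeMap:
    @pytest.mark.parametrize(
        "atgl, acot7, expected",
        [
            ("AGT", "GCG", SUSTAINED),        # Ser + Ala
            ("GGT", "GCG", NON_SUSTAINED),    # Gly + Ala
            ("GGG", "GTG", FLIGHTLESS),       # Gly + Val
            ("AGT", "GTG", UNCLASSIFIED),     # Ser + Val: no class
            ("TTT", "GCG", UNCLASSIFIED),     # Phe + Ala: no class
        ],
    )
    def test_fixed_map(self, atgl, acot7, expected):
        call = cf.genotype_to_phenotype(atgl, acot7)
        assert call.phenotype_class == expected

    def test_map_is_total_over_residue_classes(self):
        # every combination of (Ser|Gly|other) x (Ala|Val|other) is classified
        reps = {"S": "AGT", "G": "GGT", "other": "TTT"}
        reps2 = {"A": "GCG", "V": "GTG", "other": "TGG"}
        for c1 in reps.values():
            for c2 in reps2.values():
                call = cf.genotype_to_phenotype(c1, c2)
                assert call.phenotype_class in (
                    SUSTAINED, NON_SUSTAINED, FLIGHTLESS, UNCLASSIFIED
                )

    def test_stop_codon_warns_and_is_unclassified(self):
        with pytest.warns(UserWarning, match="stop codon"):
            call = cf.genotype_to_phenotype("TAA", "GCG")
        assert call.phenotype_class == UNCLASSIFIED

    def test_non_codon_rejected(self):
        with pytest.raises(ValueError):
            cf.genotype_to_phenotype("AG", "GCG")
        with pytest.raises(ValueError):
            cf.genotype_to_phenotype("AGN", "GCG")


@pytest.fixture(scope="module")
def planted_codon_setup(tmp_path_factory):
    """Foreground tips carry GGT at the ATGL codon and GTG at the ACOT7
    codon while the background carries AGT / GCG, on short branches."""
    p = tmp_path_factory.mktemp("rb") / "t.nwk"
    p.write_text(
        "(((deg01:0.01,(fly01:0.01,fly02:0.01):0.01):0.01,"
        "((fly03:0.01,fly04:0.01):0.01,(deg02:0.01,fly05:0.01):0.01):0.01):0.01,"
        "fly06:0.02);\n"
    )
    phy = cf.read_tree(p)
    species = ["deg01", "fly01", "fly02", "fly03", "fly04", "deg02", "fly05", "fly06"]
    atgl = {"deg01": "GGT", "deg02": "GGT"}
    acot7 = {"deg01": "GTG", "deg02": "GTG"}
    seqs = {
        sp: atgl.get(sp, "AGT") + acot7.get(sp, "GCG") + "ACGT" for sp in species
    }
    aln = cf.LabeledAlignment("focal", seqs, labels_for(species))
    return phy, aln


class TestRobustness:
    def test_identical_trees_give_identical_calls(self, planted_codon_setup):
        phy, aln = planted_codon_setup
        model = cf.jc69()
        df = cf.robustness_report(aln, 1, 4, [phy, phy, phy], model)
        assert len(df) == 3
        assert df["atgl_codon"].nunique() == 1 and df["acot7_codon"].nunique() == 1

    def test_background_codon_wins_the_root_across_nni_variants(self, planted_codon_setup):
        phy, aln = planted_codon_setup
        variants = cf.make_topology_variants(
            phy, [frozenset({"fly01", "fly02"}), frozenset({"deg02", "fly05"})], k=5, seed=1
        )
        model = cf.jc69()
        df = cf.robustness_report(aln, 1, 4, variants, model)
        assert len(df) == 5
        assert set(df["atgl_codon"]) == {"AGT"}
        assert set(df["acot7_codon"]) == {"GCG"}
        assert set(df["phenotype_class"]) == {SUSTAINED}

    def test_mismatched_leaf_set_skipped_with_warning(self, planted_codon_setup, tmp_path, caplog):
        phy, aln = planted_codon_setup
        bad = tmp_path / "bad.nwk"
        bad.write_text("((deg01:0.1,fly01:0.1):0.1,wrong:0.1);\n")
        bad_phy = cf.read_tree(bad)
        with caplog.at_level("WARNING"):
            df = cf.robustness_report(aln, 1, 4, [phy, bad_phy], cf.jc69())
        assert len(df) == 1
        assert any("skipped" in r.message for r in caplog.records)
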