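"""Disease-variant mapping, recurrence and reversion."""

import numpy as np
import pandas as pd
import pytest

from mtconserv.ancestral import leaf_states_from_column
from mtconserv.io import CodonAlignment, DiseaseVariant, Phylogeny
from mtconserv.reference import GeneMap, translate_codon
from mtconserv.variants import (
    CladeRegistry,
    detect_reversion,
    disease_residue_of,
    map_variant,
    recurrence_report,
    summarize,
)

# Overlapping-gene coordinate fixture: heavy strand of 90 positions with
#   geneA  1-30 (+)  M K G S F P V H L W
#   geneB 29-58 (+)  G Y D S R T Q P Y L   (frame-shifted overlap at 29-30)
#   geneC 61-90 (-)  M F H P A D C K E L   (light strand)
GENE_A = ["ATG", "AAA", "GGC", "TCC", "TTT", "CCA", "GTG", "CAT", "CTA",
          "TGG"]
GENE_B = ["GGC", "TAC", "GAT", "TCA", "CGA", "ACT", "CAG", "CCG", "TAC",
          "CTT"]
GENE_C = ["ATG", "TTT", "CAC", "CCA", "GCT", "GAC", "TGT", "AAA", "GAA",
          "CTA"]


@pytest.fixture
def overlap_setup(tmp_path):
    gmap_path = tmp_path / "genes.tsv"
    gmap_path.write_text(
        "gene\tstart\tend\tstrand\n"
        "geneA\t1\t30\t+\n"
        "geneB\t29\t58\t+\n"
        "geneC\t61\t90\t-\n"
    )
    gmap = GeneMap.from_tsv(gmap_path)
    ref = GENE_A + GENE_B + GENE_C
    other = list(ref)
    other[3] = "CCC"  # S4P variation in geneA among non-reference taxa
    taxa = ["H", "X1", "X2", "X3"]
    mat = np.array([ref, other, other, ref], dtype="<U3")
    prov = (
        [("geneA", i + 1) for i in range(10)]
        + [("geneB", i + 1) for i in range(10)]
        + [("geneC", i + 1) for i in range(10)]
    )
    aln = CodonAlignment(gene="multi", taxa=taxa, codons=mat,
                         provenance=prov)
    return gmap, aln


class TestMapVariant:
    def test_overlap_missense_and_samesense_differ_by_frame(
        self, overlap_setup
    ):
        gmap, aln = overlap_setup
        # heavy position 30 is codon 10/offset 2 of geneA (TGG->TGA,
        # tryptophan in the mito code: samesense) and codon 1/offset 1
        # of geneB (GGC->GAC: missense)
        v = DiseaseVariant.from_notation("m.30G>A", "reported")
        targets = {t.gene: t for t in map_variant(v, aln, "H", gmap)}
        assert targets["geneA"].kind == "samesense"
        assert targets["geneB"].kind == "missense"
        assert targets["geneB"].mut_aa == "D"

    def test_overlap_nonsense_in_one_frame(self, overlap_setup):
        gmap, aln = overlap_setup
        v = DiseaseVariant.from_notation("m.29G>A", "reported")
        targets = {t.gene: t for t in map_variant(v, aln, "H", gmap)}
        assert targets["geneA"].kind == "nonsense"
        assert targets["geneB"].kind == "missense"
        assert targets["geneB"].mut_aa == "S"

    def test_light_strand_gene_complements_alt(self, overlap_setup):
        gmap, aln = overlap_setup
        # heavy m.86A>G hits geneC codon 2 offset 1: TTT -> TCT (F->S)
        v = DiseaseVariant.from_notation("m.86A>G", "reported")
        (t,) = map_variant(v, aln, "H", gmap)
        assert (t.gene, t.codon) == ("geneC", 2)
        assert t.ref_codon == "TTT" and t.mut_codon == "TCT"
        assert t.kind == "missense" and t.mut_aa == "S"

    def test_intergenic_position_unmapped(self, overlap_setup):
        gmap, aln = overlap_setup
        v = DiseaseVariant.from_notation("m.59T>C", "reported")
        assert map_variant(v, aln, "H", gmap) == []

    def test_annotation_beats_frame_unless_strict(self, overlap_setup):
        gmap, aln = overlap_setup
        v = DiseaseVariant.from_notation(
            "m.30G>A", "reported", protein_change="G1E"
        )
        targets = map_variant(v, aln, "H", gmap)
        target = next(t for t in targets if t.kind == "missense")
        assert disease_residue_of(v, target) == "E"  # annotated wins
        assert disease_residue_of(v, target, strict_coordinates=True) == "D"


class TestCladeRegistry:
    def test_nesting_violation_rejected(self):
        with pytest.raises(ValueError):
            CladeRegistry(
                nonhuman_primates={"a", "b"},
                catarrhines={"a"},
                hominids={"a", "c"},  # c outside catarrhines
                extinct_homo=set(),
                human="h",
            )

    def test_nested_from_tree_is_properly_nested(self):
        tree = Phylogeny.from_newick(
            "((((H:1,N:1):1,(G:1,P:1):1):1,(M:1,B:1):1):1,(L:1,T:1):1);"
        )
        reg = CladeRegistry.nested_from_tree(tree, human="H")
        assert reg.extinct_homo <= reg.hominids
        assert reg.hominids <= reg.catarrhines
        assert reg.catarrhines <= reg.nonhuman_primates
        assert "H" not in reg.nonhuman_primates

    def test_species_deduplication(self):
        reg = CladeRegistry(
            nonhuman_primates={"a1", "a2", "b"},
            catarrhines=set(),
            hominids=set(),
            extinct_homo=set(),
            human="h",
            species_of={"a1": "spA", "a2": "spA", "b": "spB"},
        )
        assert reg.species("a1") == reg.species("a2") == "spA"


class TestReversion:
    def test_planted_reversion_detected(self):
        # ancestral hominid S, human lineage S->A; disease residue S
        tree = Phylogeny.from_newick(
            "(((H:1,N:1):1,(G:1,P:1):1):1,(O1:1,O2:1):1);"
        )
        aln = CodonAlignment(
            gene="g",
            taxa=["H", "N", "G", "P", "O1", "O2"],
            codons=np.array([["GCA"], ["GCA"], ["TCA"], ["TCA"],
                             ["TCA"], ["TCA"]], dtype="<U3"),
        )
        tree.bind(aln)
        aa_col = np.array([translate_codon(c) for c in aln.codons[:, 0]])
        human = tree.leaf_index("H")
        assert detect_reversion(tree, aa_col, human, "S")

    def test_invariant_column_is_not_reversion(self):
        tree = Phylogeny.from_newick("((H:1,N:1):1,(G:1,P:1):1);")
        aln = CodonAlignment(
            gene="g",
            taxa=["H", "N", "G", "P"],
            codons=np.array([["GCA"]] * 4, dtype="<U3"),
        )
        tree.bind(aln)
        aa_col = np.array(["A", "A", "A", "A"])
        assert not detect_reversion(tree, aa_col, tree.leaf_index("H"), "A")
        assert not detect_reversion(tree, aa_col, tree.leaf_index("H"), "S")


@pytest.fixture(scope="module")
def synthetic_run(tmp_path_factory):
    from mtconserv.pipeline import RunConfig, run_mapvariants, run_simulate
    from mtconserv.simulate import SimulationConfig

    tmp = tmp_path_factory.mktemp("recurrence")
    run_simulate(
        SimulationConfig(n_taxa=25, n_codons=150, seed=17),
        f"{tmp}/bundle", n_confirmed=8, n_reported=25,
    )
    cfg = RunConfig(
        alignment=f"{tmp}/bundle/alignment.fasta",
        tree=f"{tmp}/bundle/tree.nwk",
        gene_map=f"{tmp}/bundle/gene_map.tsv",
        gene_offsets=f"{tmp}/bundle/gene_offsets.tsv",
        variants=f"{tmp}/bundle/variants.tsv",
        outdir=f"{tmp}/out",
        reference_taxon="REF",
    )
    return cfg, run_mapvariants(cfg)


class TestRecurrenceReports:

    def test_clade_flags_are_nested(self, synthetic_run):
        _, res = synthetic_run
        for r in res["reports"]:
            assert (not r.present_in_extinct_homo) or r.present_in_hominids
            assert (not r.present_in_hominids) or r.present_in_catarrhines
            assert (
                not r.present_in_catarrhines
            ) or r.present_in_nonhuman_primates

    def test_origins_zero_iff_no_species_carries_residue(
        self, synthetic_run
    ):
        _, res = synthetic_run
        for r in res["reports"]:
            if r.disease_residue is None:
                continue
            assert (r.n_independent_origins == 0) == (
                r.n_species_with_residue == 0
            )

    def test_origin_counts_stable_under_pruning_to_carriers(
        self, synthetic_run
    ):
        # for single-origin residues a tree pruned to the carriers plus
        # the reference must keep the count at one
        import dendropy

        from mtconserv.ancestral import count_independent_origins
        from mtconserv.io import read_codon_alignment

        cfg, res = synthetic_run
        aln = read_codon_alignment(cfg.alignment)
        aa = aln.aa_matrix()
        reports = [
            r for r in res["reports"]
            if r.n_independent_origins == 1
            and r.primary_target and r.primary_target.column is not None
        ]
        assert reports, "expected at least one single-origin variant"
        for r in reports[:5]:
            col = aa[:, r.primary_target.column]
            carriers = {
                aln.taxa[i]
                for i in range(aln.n_taxa)
                if col[i] == r.disease_residue
            }
            keep = carriers | {"REF"}
            src = dendropy.Tree.get(path=cfg.tree, schema="newick",
                                    preserve_underscores=True)
            pruned = src.extract_tree_with_taxa_labels(keep)
            ptree = Phylogeny(pruned)
            ptree.bind(aln)
            ls = leaf_states_from_column(ptree, col)
            assert count_independent_origins(
                ptree, ls, r.disease_residue
            ) == 1

    def test_empty_variant_list_gives_empty_tables(self, synthetic_run):
        site = pd.DataFrame({"column": [0, 1], "ind1": [1, 2]})
        tables = summarize([], site)
        assert tables["per_mutation"].empty
        assert tables["positions"].empty
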