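"""Conservation indices and SLAC-style selection scoring."""

import numpy as np
import pytest
from scipy import stats as sps

from conftest import make_alignment
from mtconserv.conservation import (
    codon_site_fractions,
    enumerate_indel_events,
    extended_binomial_p,
    included_columns,
    ind1,
    ind2,
    pathway_counts,
    site_conservation_table,
    size_distance_correlation,
    slac_site,
    GeneSummary,
)
from mtconserv.io import Phylogeny


class TestPathwayCounts:
    def test_identity_and_single_steps(self):
        assert pathway_counts("TCC", "TCC") == (0.0, 0.0)
        assert pathway_counts("TCC", "CCC") == (0.0, 1.0)  # S->P missense
        assert pathway_counts("TCA", "TCG") == (1.0, 0.0)  # S->S silent

    def test_two_step_average(self):
        # TCA(S)->TGG(W): via TGA (W in the mito code!) or TCG (S);
        # both orderings give one synonymous + one non-synonymous step
        assert pathway_counts("TCA", "TGG") == (1.0, 1.0)

    def test_stop_blocked_ordering_excluded(self):
        # AGC(S)->ACA(T): the ordering via AGA (a mito stop) is blocked,
        # leaving only AGC->ACC(T)->ACA, one non-syn + one syn step
        assert pathway_counts("AGC", "ACA") == (1.0, 1.0)

    def test_counts_sum_to_hamming_distance(self):
        rng = np.random.default_rng(5)
        sense = [c for c in
                 ("".join(p) for p in __import__("itertools").product(
                     "ACGT", repeat=3))
                 ]
        from mtconserv.reference import translate_codon
        sense = [c for c in sense if translate_codon(c) != "*"]
        for _ in range(50):
            c1, c2 = rng.choice(sense, 2, replace=False)
            d = sum(a != b for a, b in zip(c1, c2))
            s, n = pathway_counts(c1, c2)
            assert s + n == pytest.approx(d)


class TestSiteFractions:
    def test_fourfold_degenerate_third_position(self):
        # CTx leucine block: all 3 third-position changes synonymous and
        # first position T->C (TTA/TTG) also leucine
        syn, nonsyn = codon_site_fractions("CTC")
        assert syn + nonsyn == pytest.approx(3.0)
        assert syn > 0.9

    def test_methionine_has_some_synonymous_exchange(self):
        # ATA<->ATG are both Met in the mito code
        syn, _ = codon_site_fractions("ATG")
        assert syn > 0.0


class TestExtendedBinomial:
    @pytest.mark.parametrize("n,k,p", [(10, 3, 0.5), (7, 0, 0.3),
                                       (12, 12, 0.8), (5, 2, 0.66)])
    def test_matches_integer_binomial_tails(self, n, k, p):
        upper = sps.binom.sf(k - 1, n, p)
        lower = sps.binom.cdf(k, n, p)
        expected = min(1.0, 2 * min(upper, lower))
        assert extended_binomial_p(k, n, p) == pytest.approx(
            expected, rel=1e-9
        )

    def test_degenerate_inputs_give_one(self):
        assert extended_binomial_p(0, 0, 0.5) == 1.0


class TestIndices:
    def test_ind1_counts_distinct_defined_residues(self):
        assert ind1(np.array(list("SSSPP"))) == 2
        assert ind1(np.array(["S", "X", "-", "S"])) == 1
        assert ind1(np.array(["X", "-"])) is None

    def test_ind1_matches_set_cardinality_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            col = rng.choice(list("ARNDCX-"), size=20)
            expected = len(set(col) - {"X", "-"})
            assert ind1(col) == (expected or None)

    def test_ind2_zero_on_invariant_residue_column(self, bound_pair):
        tree, aln = bound_pair
        aa_col = np.array(["S", "S", "S", "S"])
        assert ind2(tree, aa_col) == 0

    def test_ind2_counts_missense_events(self, bound_pair):
        tree, aln = bound_pair
        # S,S,P,P on ((A,B),(C,D)) is one missense event
        assert ind2(tree, np.array(list("SSPP"))) == 1


class TestSlac:
    def test_invariant_column_not_flagged(self, bound_pair):
        tree, _ = bound_pair
        col = np.array(["TCC"] * 4, dtype="<U3")
        res = slac_site(tree, col)
        assert res.dn == 0.0 and res.ds == 0.0
        assert not res.negatively_selected

    def test_two_taxon_synonymous_change_closed_form(self):
        # TCC vs TCT: one synonymous step; TCC has 3 synonymous of 9
        # non-stop neighbours, so ES=1 site, EN=2 sites; dS=1, dN=0;
        # two-tailed extended binomial at k=0, n=1, p=2/3 gives 2/3
        tree = Phylogeny.from_newick("(A:0.5,B:0.5);")
        aln = make_alignment(["A", "B"], ["TCC", "TCT"])
        tree.bind(aln)
        res = slac_site(tree, aln.codons[:, 0])
        assert res.expected_syn_sites == pytest.approx(1.0)
        assert res.ds == pytest.approx(1.0)
        assert res.dn == 0.0
        assert res.p_value == pytest.approx(2.0 / 3.0)
        assert res.observed_syn == pytest.approx(1.0)

    def test_two_taxon_missense_change(self):
        tree = Phylogeny.from_newick("(A:0.5,B:0.5);")
        aln = make_alignment(["A", "B"], ["TCC", "CCC"])
        tree.bind(aln)
        res = slac_site(tree, aln.codons[:, 0])
        assert res.dn > 0 and res.ds == 0.0
        assert not res.negatively_selected


class TestInclusionRule:
    def test_reference_gap_and_stop_columns_dropped(self, four_taxon):
        aln = make_alignment(
            ["A", "B", "C", "D"],
            ["ATGTCCTAG", "ATG---TAG", "ATGTCATAG", "ATGTCGTAG"],
        )
        # reference row A: ATG TCC TAG -> keep 0,1, drop stop column 2
        cols = included_columns(aln, "A")
        assert cols == [0, 1]
        aln2 = make_alignment(
            ["A", "B", "C", "D"],
            ["ATG---TAG", "ATGAAATAG", "ATGTCATAG", "ATGTCGTAG"],
        )
        assert included_columns(aln2, "A") == [0]

    def test_without_reference_all_columns_kept(self, four_taxon):
        aln = make_alignment(
            ["A", "B", "C", "D"],
            ["ATGTCC", "ATGTCC", "ATGTCA", "ATGTCG"],
        )
        assert included_columns(aln, None) == [0, 1]


class TestIndels:
    def test_gapless_gene_has_no_events(self, bound_pair):
        tree, aln = bound_pair
        assert enumerate_indel_events(aln, tree) == []

    def test_single_clade_gap_block_is_one_deletion(self, four_taxon):
        aln = make_alignment(
            ["A", "B", "C", "D"],
            ["ATG---", "ATG---", "ATGTCA", "ATGTCG"],
        )
        four_taxon.bind(aln)
        events = enumerate_indel_events(aln, four_taxon)
        assert len(events) == 1
        assert events[0].kind == "deletion"
        assert (events[0].start_column, events[0].end_column) == (1, 1)

    def test_independent_gaps_counted_separately(self, four_taxon):
        aln = make_alignment(
            ["A", "B", "C", "D"],
            ["ATG---", "ATGTCA", "ATG---", "ATGTCG"],
        )
        four_taxon.bind(aln)
        events = enumerate_indel_events(aln, four_taxon)
        assert len(events) == 2
        assert {e.kind for e in events} == {"deletion"}


class TestCorrelation:
    def test_three_point_closed_form(self):
        s = [
            GeneSummary("g1", 300, 0.1, 0.9, 0),
            GeneSummary("g2", 600, 0.3, 0.8, 0),
            GeneSummary("g3", 900, 0.2, 0.7, 0),
        ]
        out = size_distance_correlation(s)
        x = np.array([300, 600, 900], dtype=float)
        y = np.array([0.1, 0.3, 0.2])
        r = np.corrcoef(x, y)[0, 1]
        assert out["size_vs_distance"]["r2"] == pytest.approx(r * r)
        assert out["size_vs_fraction_negative"]["r2"] == pytest.approx(1.0)

    def test_constant_distances_give_zero(self):
        s = [GeneSummary(f"g{i}", 300 * i, 0.5, 0.5, 0) for i in (1, 2, 3)]
        out = size_distance_correlation(s)
        assert out["size_vs_distance"]["r2"] == 0.0


def test_site_table_invariants_on_small_synthetic(bound_pair):
    tree, aln = bound_pair
    df = site_conservation_table(aln, tree, reference_taxon="A")
    assert ((df["ind1"] == 1) == (df["ind2"] == 0)).all()
    assert (df["ind2"] >= df["ind1"] - 1).all()
    flagged = df[df["negatively_selected"]]
    assert (flagged["dn"] < flagged["ds"]).all()
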