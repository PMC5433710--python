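"""Radical physicochemical change detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mtconserv.physchem import (
    RadicalChangeModel,
    magnitude_category,
    neutral_category_probs,
    property_zscores,
    site_radical_summary,
)
from mtconserv.reference import AMINO_ACIDS, PropertyTable

TABLE = PropertyTable.packaged()
AA = st.sampled_from(list(AMINO_ACIDS))
PROP = st.integers(min_value=0, max_value=30)


class TestMagnitudeCategory:
    def test_identity_gives_zero_sentinel(self):
        for p in range(31):
            assert magnitude_category("A", "A", p, TABLE) == 0

    @settings(derandomize=True, max_examples=200)
    @given(a=AA, b=AA, p=PROP)
    def test_symmetry(self, a, b, p):
        assert magnitude_category(a, b, p, TABLE) == magnitude_category(
            b, a, p, TABLE
        )

    @settings(derandomize=True, max_examples=200)
    @given(a=AA, b=AA, p=PROP)
    def test_matches_direct_bin_arithmetic(self, a, b, p):
        if a == b:
            return
        mag = abs(TABLE.value(p, b) - TABLE.value(p, a))
        width = TABLE.max_change[p] / 8.0
        expected = min(8, max(1, int(np.ceil(mag / width))))
        assert magnitude_category(a, b, p, TABLE) == expected

    def test_extreme_pair_reaches_top_category(self):
        # the pair attaining a property's full range is category 8
        p = 0
        vals = TABLE.values[p]
        a = AMINO_ACIDS[int(vals.argmin())]
        b = AMINO_ACIDS[int(vals.argmax())]
        assert magnitude_category(a, b, p, TABLE) == 8

    def test_unknown_residue_rejected(self):
        with pytest.raises(KeyError):
            magnitude_category("A", "B", 0, TABLE)


class TestZScores:
    def test_inventory_matching_expectation_gives_zero_z(self):
        # feed exactly one copy of every permitted missense change under
        # uniform usage: observed proportions equal the neutral model
        from mtconserv.reference import GeneticCode, translate_codon

        code = GeneticCode.vertebrate_mito()
        inventory = []
        for codon in code.sense_codons:
            aa = translate_codon(codon)
            for i in range(3):
                for b in "ACGT":
                    if b == codon[i]:
                        continue
                    nb = codon[:i] + b + codon[i + 1 :]
                    nb_aa = translate_codon(nb, code)
                    if nb_aa not in ("*", aa):
                        inventory.append((aa, nb_aa))
        zs = property_zscores(inventory, TABLE)
        finite = zs.z[np.isfinite(zs.z)]
        assert np.abs(finite).max() < 1e-9

    def test_empty_inventory_rejected(self):
        with pytest.raises(ValueError):
            property_zscores([], TABLE)

    def test_degenerate_cells_are_nan_and_excluded(self):
        zs = property_zscores([("A", "G")] * 10, TABLE)
        assert np.isnan(zs.z).any()
        assert not zs.significant()[np.isnan(zs.z)].any()


class TestRadicalSummary:
    def test_invariant_column_scores_zero(self):
        model = RadicalChangeModel(TABLE, category_only=True)
        assert site_radical_summary([], model) == (0, 0)

    def test_category_only_mode_flags_extreme_changes(self):
        model = RadicalChangeModel(TABLE, category_only=True)
        # D->I crosses most hydrophobicity-like scales widely
        n, mx = site_radical_summary([("D", "I")], model)
        assert n == 1
        assert mx >= 1

    def test_conservative_change_not_radical(self):
        model = RadicalChangeModel(TABLE, category_only=True)
        props = model.radical_properties("I", "L")
        assert len(props) <= 2  # near-identical residues

    def test_radical_count_bounded_by_substitution_count(self):
        model = RadicalChangeModel(TABLE, category_only=True)
        subs = [("D", "I"), ("I", "L"), ("K", "E")]
        n, _ = site_radical_summary(subs, model)
        assert n <= len(subs)

    def test_z_mode_is_subset_of_category_mode(self):
        rng = np.random.default_rng(6)
        aas = list(AMINO_ACIDS)
        inventory = [
            (rng.choice(aas), rng.choice(aas)) for _ in range(300)
        ]
        inventory = [(a, b) for a, b in inventory if a != b]
        zmodel = RadicalChangeModel.from_inventory(inventory, TABLE)
        cmodel = RadicalChangeModel(TABLE, category_only=True)
        for a, b in inventory[:50]:
            assert zmodel.radical_properties(a, b) <= cmodel.radical_properties(a, b)
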