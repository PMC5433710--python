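"""Radical physicochemical amino-acid change detection.

Every amino-acid replacement is scored against 31 property scales: the
absolute property change is binned into 8 equal-width magnitude
categories spanning the property's maximum attainable pairwise change,
and replacements falling in categories 6-8 are candidate radical
changes.  At dataset level, a (property, category) cell is significant
when its observed count exceeds the neutral expectation — all
single-nucleotide missense changes permitted by the mitochondrial code,
weighted by observed codon usage — with a z-score above 3.09
(p < 0.001).  The default radical call requires both the category and
the z-score criterion; a category-only mode serves small datasets where
the z statistics are unstable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reference import STOP, GeneticCode, PropertyTable, translate_codon

RADICAL_CATEGORIES = (6, 7, 8)
Z_THRESHOLD = 3.09


def magnitude_category(
    from_aa: str, to_aa: str, prop: int | str, table: PropertyTable
) -> int:
    """Magnitude category 1..8 of a replacement; 0 for identity."""
    if from_aa == to_aa:
        return 0
    mag = table.change(prop, from_aa, to_aa)
    if isinstance(prop, str):
        prop = table.properties.index(prop)
    mx = table.max_change[prop]
    if mx == 0:
        return 1
    cat = int(np.ceil(8.0 * mag / mx))
    return min(max(cat, 1), 8)


def neutral_category_probs(
    table: PropertyTable,
    code: GeneticCode | None = None,
    codon_usage: dict[str, float] | None = None,
) -> np.ndarray:
    """(n_properties, 8) neutral probabilities of magnitude categories.

    Expectations come from every single-nucleotide missense change the
    code permits, weighted by codon usage (uniform when none given).
    """
    code = code or GeneticCode.vertebrate_mito()
    probs = np.zeros((len(table), 8))
    total = 0.0
    for codon in code.sense_codons:
        w = 1.0 if codon_usage is None else codon_usage.get(codon, 0.0)
        if w == 0.0:
            continue
        aa = translate_codon(codon, code)
        for i in range(3):
            for b in "ACGT":
                if b == codon[i]:
                    continue
                nb = codon[:i] + b + codon[i + 1 :]
                nb_aa = translate_codon(nb, code)
                if nb_aa in (STOP, aa):
                    continue
                total += w
                for p in range(len(table)):
                    cat = magnitude_category(aa, nb_aa, p, table)
                    probs[p, cat - 1] += w
    if total == 0:
        raise ValueError("no permitted missense changes under the usage")
    return probs / total


def codon_usage_of(codons: np.ndarray, code: GeneticCode | None = None
                   ) -> dict[str, float]:
    code = code or GeneticCode.vertebrate_mito()
    sense = set(code.sense_codons)
    vals, counts = np.unique(codons, return_counts=True)
    usage = {c: float(n) for c, n in zip(vals, counts) if c in sense}
    tot = sum(usage.values())
    return {c: n / tot for c, n in usage.items()} if tot else {}


@dataclass
class PropertyZScores:
    """Dataset-level z statistics per (property, magnitude category)."""

    z: np.ndarray  # (n_properties, 8); NaN where expectation degenerate
    observed: np.ndarray
    expected: np.ndarray

    def significant(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.z > Z_THRESHOLD


def property_zscores(
    substitutions: list[tuple[str, str]],
    table: PropertyTable,
    code: GeneticCode | None = None,
    codon_usage: dict[str, float] | None = None,
) -> PropertyZScores:
    """z = (observed - expected)/sd under a binomial neutral model, per
    property and magnitude category, over a genome-wide inventory of
    branch amino-acid substitutions."""
    if not substitutions:
        raise ValueError("empty substitution inventory")
    probs = neutral_category_probs(table, code, codon_usage)
    n = len(substitutions)
    obs = np.zeros((len(table), 8))
    for from_aa, to_aa in substitutions:
        for p in range(len(table)):
            cat = magnitude_category(from_aa, to_aa, p, table)
            if cat:
                obs[p, cat - 1] += 1
    exp = n * probs
    sd = np.sqrt(n * probs * (1.0 - probs))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (obs - exp) / sd, np.nan)
    return PropertyZScores(z=z, observed=obs, expected=exp)


@dataclass
class RadicalChangeModel:
    """Decides which properties change radically for a replacement."""

    table: PropertyTable
    zscores: PropertyZScores | None = None
    category_only: bool = False
    _sig: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.zscores is not None:
            self._sig = self.zscores.significant()

    @classmethod
    def from_inventory(
        cls,
        substitutions: list[tuple[str, str]],
        table: PropertyTable | None = None,
        codon_usage: dict[str, float] | None = None,
        category_only: bool = False,
    ) -> "RadicalChangeModel":
        table = table or PropertyTable.packaged()
        zs = None
        if not category_only and substitutions:
            zs = property_zscores(substitutions, table,
                                  codon_usage=codon_usage)
        return cls(table=table, zscores=zs, category_only=category_only)

    def radical_properties(self, from_aa: str, to_aa: str) -> set[str]:
        out = set()
        if from_aa == to_aa:
            return out
        for p, name in enumerate(self.table.properties):
            cat = magnitude_category(from_aa, to_aa, p, self.table)
            if cat not in RADICAL_CATEGORIES:
                continue
            if self.category_only or self._sig is None:
                out.add(name)
            elif self._sig[p, cat - 1]:
                out.add(name)
        return out


def site_radical_summary(
    substitutions: list[tuple[str, str]],
    model: RadicalChangeModel,
) -> tuple[int, int]:
    """(number of radical substitutions, max properties affected) for
    one column's branch substitution list."""
    n_radical = 0
    max_props = 0
    for from_aa, to_aa in substitutions:
        props = model.radical_properties(from_aa, to_aa)
        if props:
            n_radical += 1
            max_props = max(max_props, len(props))
    return n_radical, max_props
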