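"""Mapping disease-associated mtDNA variants onto aligned codon columns.

A parsed ``m.NNNNR>A`` variant maps, through the gene coordinate map,
to one aligned codon column per overlapping protein gene (the ATP8/ATP6
and ND4L/ND4 overlaps make two-gene hits routine).  Per target the
reference and mutant codons are derived strand-aware from the
designated reference row, classifying the variant as missense,
samesense or nonsense *per gene*.  Recurrence statistics then ask how
often the disease-associated residue arose independently across the
phylogeny, how many species carry it, whether it occurs in nested clade
tiers (non-human primates > catarrhines > hominids > extinct Homo), and
whether the human lineage reverted away from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ancestral
from .conservation import human_codon_numbers
from .io import CodonAlignment, DiseaseVariant, Phylogeny
from .reference import (
    STOP,
    UNKNOWN,
    GeneMap,
    complement,
    map_mtdna_position,
    translate_codon,
)


@dataclass
class MappedTarget:
    gene: str
    codon: int  # reference codon number within the gene
    column: int | None  # aligned column; None when not alignable
    ref_codon: str | None = None
    mut_codon: str | None = None
    ref_aa: str | None = None
    mut_aa: str | None = None
    kind: str = "unmapped"  # missense | samesense | nonsense | unmapped


def map_variant(
    variant: DiseaseVariant,
    alignment: CodonAlignment,
    reference_taxon: str,
    gmap: GeneMap | None = None,
) -> list[MappedTarget]:
    """Map a variant to its aligned column(s), one per overlapped gene.

    Positions outside protein genes yield an empty list.  The mutant
    codon is built strand-aware: for light-strand genes the substituted
    base is complemented before insertion into the coding-strand codon.
    """
    gmap = gmap or GeneMap.rcrs()
    hits = map_mtdna_position(variant.position, gmap)
    codmap = human_codon_numbers(alignment, reference_taxon)
    by_gene_codon = {v: k for k, v in codmap.items()}
    ref_row = alignment.codons[alignment.row(reference_taxon)]
    out = []
    for gene, codon_num, offset in hits:
        column = by_gene_codon.get((gene, codon_num))
        if column is None:
            out.append(MappedTarget(gene, codon_num, None))
            continue
        ref_codon = str(ref_row[column])
        strand = gmap[gene].strand
        alt = variant.alt if strand == "+" else complement(variant.alt)
        mut_codon = (
            ref_codon[:offset] + alt + ref_codon[offset + 1 :]
        )
        ref_aa = translate_codon(ref_codon)
        mut_aa = translate_codon(mut_codon)
        if UNKNOWN in (ref_aa, mut_aa):
            kind = "unmapped"
        elif mut_aa == ref_aa:
            kind = "samesense"
        elif mut_aa == STOP:
            kind = "nonsense"
        else:
            kind = "missense"
        out.append(
            MappedTarget(gene, codon_num, column, ref_codon, mut_codon,
                         ref_aa, mut_aa, kind)
        )
    return out


@dataclass
class CladeRegistry:
    """Named taxon sets for the nested presence tiers.

    ``species_of`` collapses multiple sequences of one species to a
    single presence vote; by default each taxon label is its own
    species.
    """

    nonhuman_primates: set[str]
    catarrhines: set[str]
    hominids: set[str]
    extinct_homo: set[str]
    human: str = ""
    species_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.extinct_homo <= self.hominids:
            raise ValueError("extinct Homo must be within hominids")
        if not self.hominids <= self.catarrhines:
            raise ValueError("hominids must be within catarrhines")
        if not self.catarrhines <= self.nonhuman_primates | {self.human}:
            raise ValueError("catarrhines must be within primates + human")

    def species(self, taxon: str) -> str:
        return self.species_of.get(taxon, taxon)

    @classmethod
    def from_tsv(cls, path, human: str) -> "CladeRegistry":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        sets = {k: set() for k in
                ("nonhuman_primates", "catarrhines", "hominids",
                 "extinct_homo")}
        species_of = {}
        for r in df.itertuples():
            clades = {c.strip() for c in r.clades.split(";") if c.strip()}
            for k in sets:
                if k in clades:
                    sets[k].add(r.taxon)
            sp = getattr(r, "species", "") or r.taxon
            species_of[r.taxon] = sp
        return cls(human=human, species_of=species_of, **sets)

    @classmethod
    def nested_from_tree(
        cls, tree: Phylogeny, human: str
    ) -> "CladeRegistry":
        """Synthetic nesting: clade tiers are successively larger
        ancestral clades around the designated human leaf."""
        leaf = tree.leaf_index(human)
        path = tree.path_to_root(leaf)

        def leaves_at(depth: int) -> set[str]:
            node = path[min(depth, len(path) - 1)]
            stack, out = [node], set()
            while stack:
                v = stack.pop()
                if tree.is_leaf(v):
                    out.add(tree.leaf_label[v])
                else:
                    stack.extend(tree.children[v])
            return out - {human}

        all_leaves = {tree.leaf_label[v] for v in tree.leaves} - {human}
        return cls(
            nonhuman_primates=all_leaves,
            catarrhines=leaves_at(4),
            hominids=leaves_at(2),
            extinct_homo=leaves_at(1),
            human=human,
        )


@dataclass
class RecurrenceReport:
    variant: DiseaseVariant
    targets: list[MappedTarget]
    disease_residue: str | None
    present_in_nonhuman_primates: bool = False
    present_in_catarrhines: bool = False
    present_in_hominids: bool = False
    present_in_extinct_homo: bool = False
    n_independent_origins: int = 0
    n_species_with_residue: int = 0
    is_reversion: bool = False
    ind1: int | None = None
    ind2: int | None = None
    ind3: float | None = None
    negatively_selected: bool | None = None
    reason: str | None = None

    @property
    def primary_target(self) -> MappedTarget | None:
        for t in self.targets:
            if t.kind == "missense":
                return t
        return self.targets[0] if self.targets else None


def disease_residue_of(
    variant: DiseaseVariant, target: MappedTarget | None,
    strict_coordinates: bool = False,
) -> str | None:
    """The amino acid the variant would place at the target position.

    The protein-change annotation wins when present; the frame-derived
    residue wins only in strict-coordinates mode (conflicts logged by
    the caller through the report's ``reason``).
    """
    annotated = None
    if variant.protein_change and len(variant.protein_change) >= 3:
        annotated = variant.protein_change[-1].upper()
    derived = target.mut_aa if target else None
    if strict_coordinates and derived is not None:
        return derived
    return annotated or derived


def detect_reversion(
    tree: Phylogeny,
    aa_column: np.ndarray,
    human_taxon_node: int,
    disease_residue: str,
) -> bool:
    """True when an ancestor on the human path carried the disease
    residue and a later branch on that path substituted away from it."""
    ls = ancestral.leaf_states_from_column(tree, aa_column)
    if not ls:
        return False
    states = ancestral.reconstruct(tree, ls)
    path = list(reversed(tree.path_to_root(human_taxon_node)))  # root->leaf
    seen = False
    for node in path:
        s = states[node]
        if s is None:
            continue
        if s == disease_residue:
            seen = True
        elif seen:
            return True
    return False


def recurrence_report(
    variant: DiseaseVariant,
    alignment: CodonAlignment,
    tree: Phylogeny,
    clades: CladeRegistry,
    reference_taxon: str,
    gmap: GeneMap | None = None,
    site_table: pd.DataFrame | None = None,
    aa_matrix: np.ndarray | None = None,
) -> RecurrenceReport:
    """Full recurrence/cladistic report for one variant."""
    targets = map_variant(variant, alignment, reference_taxon, gmap)
    report = RecurrenceReport(variant=variant, targets=targets,
                              disease_residue=None)
    if not targets or all(t.column is None for t in targets):
        report.reason = "position outside protein-coding genes"
        return report
    target = report.primary_target
    residue = disease_residue_of(variant, target)
    report.disease_residue = residue
    if residue is None:
        report.reason = "disease residue undeterminable"
        return report
    if target.mut_aa is not None and residue != target.mut_aa:
        report.reason = (
            f"annotated residue {residue} differs from frame-derived "
            f"{target.mut_aa}"
        )
    if aa_matrix is None:
        aa_matrix = alignment.aa_matrix()
    col = target.column
    aa_col = aa_matrix[:, col]
    human_row = alignment.row(reference_taxon)

    carriers = {
        alignment.taxa[i]
        for i in range(alignment.n_taxa)
        if aa_col[i] == residue and i != human_row
    }
    report.present_in_nonhuman_primates = bool(
        carriers & clades.nonhuman_primates
    )
    report.present_in_catarrhines = bool(carriers & clades.catarrhines)
    report.present_in_hominids = bool(carriers & clades.hominids)
    report.present_in_extinct_homo = bool(carriers & clades.extinct_homo)
    report.n_species_with_residue = len(
        {clades.species(t) for t in carriers}
    )
    ls = ancestral.leaf_states_from_column(tree, aa_col)
    report.n_independent_origins = ancestral.count_independent_origins(
        tree, ls, residue
    )
    report.is_reversion = detect_reversion(
        tree, aa_col, tree.leaf_index(reference_taxon), residue
    )
    if site_table is not None:
        row = site_table[site_table["column"] == col]
        if len(row):
            r = row.iloc[0]
            report.ind1 = None if pd.isna(r["ind1"]) else int(r["ind1"])
            report.ind2 = None if pd.isna(r["ind2"]) else int(r["ind2"])
            report.ind3 = (
                float(r["ind3"]) if "ind3" in row.columns else None
            )
            report.negatively_selected = bool(r["negatively_selected"])
    return report


def summarize(
    reports: list[RecurrenceReport],
    site_table: pd.DataFrame,
    radical_by_column: dict[int, int] | None = None,
) -> dict[str, pd.DataFrame]:
    """Gene x status summary tables.

    ``positions`` counts deduplicated aligned codon positions per gene
    and status; per-mutation tallies are emitted alongside since both
    denominators are informative.  The invariant/variable split uses
    Ind1 = 1; the "never radical" list needs per-column radical counts.
    """
    ind1_by_col = dict(zip(site_table["column"], site_table["ind1"]))
    rows = []
    for rep in reports:
        t = rep.primary_target
        if t is None or t.column is None or rep.disease_residue is None:
            continue
        rows.append(
            {
                "gene": t.gene,
                "status": rep.variant.status,
                "column": t.column,
                "ind1": ind1_by_col.get(t.column),
                "in_primates": rep.present_in_nonhuman_primates,
                "in_catarrhines": rep.present_in_catarrhines,
                "in_hominids": rep.present_in_hominids,
                "in_extinct_homo": rep.present_in_extinct_homo,
                "origins": rep.n_independent_origins,
                "species": rep.n_species_with_residue,
                "notation": rep.variant.notation,
            }
        )
    df = pd.DataFrame(rows)
    out: dict[str, pd.DataFrame] = {"per_mutation": df}
    if df.empty:
        out["positions"] = pd.DataFrame()
        out["invariant_positions"] = pd.DataFrame()
        out["never_radical_positions"] = pd.DataFrame()
        out["recurrence_stats"] = pd.DataFrame()
        return out

    # deduplicate to aligned positions (a position may host several
    # mutations; any mutation's clade presence marks the position)
    pos = (
        df.groupby(["status", "gene", "column"])
        .agg(
            ind1=("ind1", "first"),
            in_primates=("in_primates", "any"),
            in_catarrhines=("in_catarrhines", "any"),
            in_hominids=("in_hominids", "any"),
            in_extinct_homo=("in_extinct_homo", "any"),
        )
        .reset_index()
    )
    pos["invariant"] = pos["ind1"] == 1
    table2 = (
        pos.groupby(["status", "gene"])
        .agg(
            total=("column", "count"),
            invariant=("invariant", "sum"),
            variable=("invariant", lambda s: int((~s).sum())),
            in_primates=("in_primates", "sum"),
            in_catarrhines=("in_catarrhines", "sum"),
            in_hominids=("in_hominids", "sum"),
            in_extinct_homo=("in_extinct_homo", "sum"),
        )
        .reset_index()
    )
    out["positions"] = table2

    inv = df[df["ind1"] == 1]
    out["invariant_positions"] = inv[
        ["status", "gene", "notation", "column"]
    ].drop_duplicates()

    if radical_by_column is not None:
        never = df[
            (df["ind1"] > 1)
            & df["column"].map(lambda c: radical_by_column.get(c, 0) == 0)
        ]
        out["never_radical_positions"] = never[
            ["status", "gene", "notation", "column"]
        ].drop_duplicates()
    else:
        out["never_radical_positions"] = pd.DataFrame()

    stats_rows = []
    for status, grp in df.groupby("status"):
        for col in ("origins", "species"):
            v = grp.drop_duplicates("column")[col].astype(float)
            stats_rows.append(
                {
                    "status": status,
                    "quantity": col,
                    "mean": v.mean(),
                    "min": v.min(),
                    "max": v.max(),
                    "sd": v.std(ddof=1) if len(v) > 1 else 0.0,
                }
            )
    out["recurrence_stats"] = pd.DataFrame(stats_rows)
    return out
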