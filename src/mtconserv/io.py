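"""Readers and writers for codon alignments, trees and variant tables.

FASTA alignments are read through Biopython, newick trees through
dendropy; the tree is converted to a flat array representation
(postorder node indexing) that the per-column algorithms consume.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from Bio import SeqIO

from .reference import GeneticCode, translate_codon

log = logging.getLogger(__name__)

GAP_CODON = "---"


class FormatError(ValueError):
    pass


class BindingError(ValueError):
    pass


@dataclass
class CodonAlignment:
    """Aligned codon matrix (taxa x columns of 3-letter cells).

    ``provenance`` carries, per column, the originating gene and the
    gene-local codon index (1-based, pre-gap numbering is not tracked;
    the index is the column's ordinal within its gene block).
    """

    gene: str
    taxa: list[str]
    codons: np.ndarray  # (n_taxa, n_cols), dtype '<U3'
    provenance: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.codons.ndim != 2:
            raise FormatError("codon matrix must be 2-D")
        if len(self.taxa) != self.codons.shape[0]:
            raise FormatError("taxon count does not match matrix rows")
        if not self.provenance:
            self.provenance = [
                (self.gene, i + 1) for i in range(self.codons.shape[1])
            ]

    @property
    def n_taxa(self) -> int:
        return self.codons.shape[0]

    @property
    def n_columns(self) -> int:
        return self.codons.shape[1]

    def row(self, taxon: str) -> int:
        try:
            return self.taxa.index(taxon)
        except ValueError:
            raise KeyError(f"taxon {taxon!r} not in alignment") from None

    def column(self, j: int) -> np.ndarray:
        return self.codons[:, j]

    def aa_matrix(self, code: GeneticCode | None = None) -> np.ndarray:
        """Translate every cell; N/gap-containing cells become 'X'."""
        cache: dict[str, str] = {}
        out = np.empty(self.codons.shape, dtype="<U1")
        flat = self.codons.ravel()
        res = np.empty(flat.shape, dtype="<U1")
        for i, c in enumerate(flat):
            aa = cache.get(c)
            if aa is None:
                aa = translate_codon(c, code)
                cache[c] = aa
            res[i] = aa
        out = res.reshape(self.codons.shape)
        return out

    def subalignment(self, columns: list[int]) -> "CodonAlignment":
        return CodonAlignment(
            gene=self.gene,
            taxa=list(self.taxa),
            codons=self.codons[:, columns],
            provenance=[self.provenance[j] for j in columns],
        )

    def nucleotides(self) -> np.ndarray:
        """Per-taxon nucleotide strings (n_taxa,) as a '<U' array."""
        return np.array(["".join(row) for row in self.codons])

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for label, row in zip(self.taxa, self.codons):
                fh.write(f">{label}\n{''.join(row)}\n")


def read_codon_alignment(
    path: str | Path, frame_offset: int = 0, gene: str = "concat"
) -> CodonAlignment:
    """Read an aligned FASTA into a codon matrix.

    ``frame_offset`` leading columns are dropped before splitting into
    codons; a trailing remainder of 1-2 nucleotide columns is dropped
    with a warning.  Cells containing 1-2 gap characters are normalized
    to the fully gapped cell ``---`` (with a logged warning), so every
    cell is either gapless or ``---``.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no sequences in {path}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) > 1:
        raise FormatError(f"unequal sequence lengths in {path}: {lengths}")
    (length,) = lengths
    usable = length - frame_offset
    rem = usable % 3
    if rem:
        log.warning("dropping %d trailing nucleotide column(s)", rem)
    n_cols = usable // 3
    taxa = [r.description or r.id for r in records]
    mat = np.empty((len(records), n_cols), dtype="<U3")
    n_partial = 0
    for i, r in enumerate(records):
        s = str(r.seq).upper()[frame_offset : frame_offset + 3 * n_cols]
        for j in range(n_cols):
            cell = s[3 * j : 3 * j + 3]
            if "-" in cell and cell != GAP_CODON:
                n_partial += 1
                cell = GAP_CODON
            mat[i, j] = cell
    if n_partial:
        log.warning("normalized %d partially gapped codon cell(s)", n_partial)
    return CodonAlignment(gene=gene, taxa=taxa, codons=mat)


VARIANT_RE = re.compile(r"^m\.(\d+)([ACGTacgt])>([ACGTacgt])$")


def parse_variant(notation: str) -> tuple[int, str, str]:
    """Parse MITOMAP-style ``m.8528T>C`` into (position, ref, alt)."""
    m = VARIANT_RE.match(notation.strip())
    if not m:
        raise ValueError(f"cannot parse variant notation {notation!r}")
    return int(m.group(1)), m.group(2).upper(), m.group(3).upper()


@dataclass
class DiseaseVariant:
    notation: str
    position: int
    ref: str
    alt: str
    status: str  # 'confirmed' | 'reported'
    protein_change: str | None = None
    phenotype: str = ""
    score: float | None = None

    @classmethod
    def from_notation(cls, notation: str, status: str, **kw) -> "DiseaseVariant":
        pos, ref, alt = parse_variant(notation)
        status = status.strip().lower()
        if status not in ("confirmed", "reported"):
            raise ValueError(f"unknown variant status {status!r}")
        return cls(notation, pos, ref, alt, status, **kw)


def read_variants(path: str | Path) -> list[DiseaseVariant]:
    """Read a variant TSV with header
    ``notation  status  protein_change  phenotype  [score]``."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"notation", "status"}
    if not need <= set(df.columns):
        raise FormatError(f"variant table needs columns {sorted(need)}")
    out = []
    for r in df.itertuples():
        pc = getattr(r, "protein_change", None)
        if pc is not None and (pd.isna(pc) or pc == ""):
            pc = None
        ph = getattr(r, "phenotype", "") or ""
        if isinstance(ph, float):
            ph = ""
        sc = getattr(r, "score", None)
        score = None if sc is None or pd.isna(sc) else float(sc)
        out.append(
            DiseaseVariant.from_notation(
                r.notation, r.status, protein_change=pc, phenotype=ph,
                score=score,
            )
        )
    return out


class Phylogeny:
    """Rooted tree with branch lengths in a flat array form.

    Nodes are indexed in postorder (root last); ``parent[root] == -1``.
    Leaf labels are bound to alignment rows with :meth:`bind`.  Internal
    node labels / support values from the newick source are retained in
    ``node_labels`` but never used in computation.
    """

    def __init__(self, tree: dendropy.Tree):
        tree.is_rooted = True
        self._dendropy = tree
        nodes = list(tree.postorder_node_iter())
        self.n_nodes = len(nodes)
        index = {id(nd): i for i, nd in enumerate(nodes)}
        self.parent = np.full(self.n_nodes, -1, dtype=int)
        self.length = np.zeros(self.n_nodes)
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        self.leaf_label: dict[int, str] = {}
        self.node_labels: dict[int, str] = {}
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
            self.length[i] = nd.edge.length or 0.0
            if nd.is_leaf():
                self.leaf_label[i] = nd.taxon.label if nd.taxon else (nd.label or "")
            elif nd.label:
                self.node_labels[i] = nd.label
        self.root = self.n_nodes - 1
        self.leaves = sorted(self.leaf_label)
        self.leaf_rows: dict[int, int] | None = None

    @classmethod
    def from_newick(cls, source: str | Path) -> "Phylogeny":
        p = Path(source)
        if p.exists():
            tree = dendropy.Tree.get(path=str(p), schema="newick",
                                     preserve_underscores=True)
        else:
            tree = dendropy.Tree.get(data=str(source), schema="newick",
                                     preserve_underscores=True)
        return cls(tree)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def total_length(self) -> float:
        return float(self.length[: self.root].sum())

    def postorder(self) -> range:
        return range(self.n_nodes)

    def preorder(self) -> range:
        return range(self.n_nodes - 1, -1, -1)

    def is_leaf(self, i: int) -> bool:
        return not self.children[i]

    def path_to_root(self, i: int) -> list[int]:
        out = [i]
        while self.parent[i] != -1:
            i = self.parent[i]
            out.append(i)
        return out

    def leaf_index(self, label: str) -> int:
        for i, lab in self.leaf_label.items():
            if lab == label:
                return i
        raise KeyError(label)

    def bind(self, alignment: CodonAlignment,
             rename: dict[str, str] | None = None) -> "Phylogeny":
        """Bind leaves to alignment rows (exact-string matching).

        ``rename`` maps tree leaf labels to alignment taxon labels.
        Raises :class:`BindingError` naming any unmatched leaves.
        """
        rename = rename or {}
        rows = {}
        missing = []
        for i, label in self.leaf_label.items():
            name = rename.get(label, label)
            try:
                rows[i] = alignment.row(name)
            except KeyError:
                missing.append(label)
        if missing:
            raise BindingError(
                f"tree leaves absent from alignment: {sorted(missing)}"
            )
        self.leaf_rows = rows
        return self

    def write_newick(self, path: str | Path) -> None:
        self._dendropy.write(path=str(path), schema="newick",
                             suppress_rooting=True)


def read_tree(path: str | Path) -> Phylogeny:
    return Phylogeny.from_newick(path)


def read_rename_map(path: str | Path) -> dict[str, str]:
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        a, b = line.split("\t")[:2]
        out[a] = b
    return out
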