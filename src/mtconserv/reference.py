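"""Packaged reference data for the human mitochondrial genome.

Three resources live here:

* the vertebrate mitochondrial genetic code (NCBI translation table 2),
* the rCRS (NC_012920) coordinate map of the 13 protein-coding genes,
* a table of 31 physicochemical amino-acid property scales used for
  radical-change scoring.

Coordinates follow the rCRS convention: positions are 1-based and
inclusive, ``m.NNNN`` notation refers to the heavy-strand sequence.
mt-ND6 is encoded on the light strand; its codons are numbered from the
gene's highest rCRS coordinate (the 5' end of its mRNA), and callers that
need the coding-strand base must complement the heavy-strand base.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

RCRS_LENGTH = 16_569

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
STOP = "*"
#: sentinel returned for codons containing N or gap characters
UNKNOWN = "X"

_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")


def _build_code() -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[2]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = STOP
    return code


@dataclass(frozen=True)
class GeneticCode:
    """Vertebrate mitochondrial codon -> one-letter amino acid map."""

    table: dict[str, str]

    @classmethod
    def vertebrate_mito(cls) -> "GeneticCode":
        return cls(table=_build_code())

    @property
    def sense_codons(self) -> list[str]:
        return sorted(c for c, aa in self.table.items() if aa != STOP)

    @property
    def stop_codons(self) -> list[str]:
        return sorted(c for c, aa in self.table.items() if aa == STOP)

    def __len__(self) -> int:
        return len(self.table)


def translate_codon(codon: str, code: GeneticCode | None = None) -> str:
    """Translate a codon; ``X`` for codons containing N or gaps.

    Raises ``ValueError`` for strings that are not exactly 3 characters
    over ``{A,C,G,T,N,-}``.
    """
    if code is None:
        code = _DEFAULT_CODE
    if len(codon) != 3:
        raise ValueError(f"codon must have length 3, got {codon!r}")
    codon = codon.upper()
    if any(b not in "ACGTN-" for b in codon):
        raise ValueError(f"invalid codon characters in {codon!r}")
    if "N" in codon or "-" in codon:
        return UNKNOWN
    return code.table[codon]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


@dataclass(frozen=True)
class Gene:
    name: str
    start: int  # rCRS, 1-based inclusive
    end: int
    strand: str  # '+' or '-'

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def n_codons(self) -> int:
        # incomplete terminal codons (completed by polyadenylation in vivo)
        # are excluded from the codon count
        return self.length // 3

    def codon_positions(self, codon_number: int) -> tuple[int, int, int]:
        """rCRS positions of the three bases of codon ``codon_number``.

        Returned in reading order (codon position 1, 2, 3); decreasing
        for light-strand genes.
        """
        if not 1 <= codon_number <= self.n_codons:
            raise ValueError(
                f"{self.name} has {self.n_codons} codons; got {codon_number}"
            )
        off = 3 * (codon_number - 1)
        if self.strand == "+":
            p = self.start + off
            return (p, p + 1, p + 2)
        p = self.end - off
        return (p, p - 1, p - 2)


class GeneMap:
    """The 13 protein-coding genes of the human mitochondrial genome."""

    def __init__(self, genes: list[Gene]):
        self.genes = {g.name: g for g in genes}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneMap":
        df = pd.read_csv(path, sep="\t")
        genes = [
            Gene(r.gene, int(r.start), int(r.end), r.strand)
            for r in df.itertuples()
        ]
        return cls(genes)

    @classmethod
    def rcrs(cls) -> "GeneMap":
        with importlib.resources.as_file(
            importlib.resources.files("mtconserv.data") / "gene_map.tsv"
        ) as p:
            return cls.from_tsv(p)

    def __getitem__(self, name: str) -> Gene:
        return self.genes[name]

    def __iter__(self):
        return iter(self.genes.values())

    def __len__(self) -> int:
        return len(self.genes)


def map_mtdna_position(
    pos: int, gmap: GeneMap | None = None
) -> list[tuple[str, int, int]]:
    """Map an rCRS position to ``(gene, codon_number, offset_in_codon)``.

    One entry per overlapping protein gene; codon numbers are 1-based in
    each gene's own frame, ``offset_in_codon`` in 0..2 counts along the
    reading direction (reverse along rCRS for light-strand genes).
    Positions falling in no protein gene, or in a gene's incomplete
    terminal codon, yield no entry.
    """
    if gmap is None:
        gmap = _DEFAULT_GENE_MAP
    if not 1 <= pos <= RCRS_LENGTH:
        raise ValueError(f"position {pos} outside rCRS 1..{RCRS_LENGTH}")
    hits = []
    for g in gmap:
        if not g.start <= pos <= g.end:
            continue
        off = pos - g.start if g.strand == "+" else g.end - pos
        codon = off // 3 + 1
        if codon > g.n_codons:  # incomplete terminal codon
            continue
        hits.append((g.name, codon, off % 3))
    return hits


class PropertyTable:
    """31 physicochemical amino-acid property scales.

    Compiled from published AAindex scales; per property the maximum
    attainable pairwise change magnitude anchors the 8 equal-width
    magnitude categories used in radical-change scoring.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [aa for aa in AMINO_ACIDS if aa not in df.columns]
        if missing:
            raise ValueError(f"property table lacks amino acids {missing}")
        self.df = df
        self.values = df[list(AMINO_ACIDS)].to_numpy(dtype=float)
        self.properties = list(df["property"])
        self._aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
        self.max_change = np.ptp(self.values, axis=1)  # per property

    @classmethod
    def packaged(cls) -> "PropertyTable":
        with importlib.resources.as_file(
            importlib.resources.files("mtconserv.data")
            / "physchem_properties31.tsv"
        ) as p:
            return cls(pd.read_csv(p, sep="\t"))

    def value(self, prop: int | str, aa: str) -> float:
        if isinstance(prop, str):
            prop = self.properties.index(prop)
        return float(self.values[prop, self._aa_index[aa]])

    def change(self, prop: int | str, from_aa: str, to_aa: str) -> float:
        return abs(self.value(prop, to_aa) - self.value(prop, from_aa))

    def __len__(self) -> int:
        return len(self.properties)


_DEFAULT_CODE = GeneticCode.vertebrate_mito()
_DEFAULT_GENE_MAP = GeneMap.rcrs()
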