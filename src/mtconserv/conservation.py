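"""Per-column conservation indices and SLAC-style selection scoring.

Three indices describe each aligned codon column:

* **Ind1** — number of distinct amino acids among defined cells;
* **Ind2** — number of missense substitution events, counted as
  parsimony state changes on the translated column (so an invariant
  residue column scores 0 regardless of synonymous codon turnover);
* **Ind3** — standardized empirical-Bayes evolutionary rate (see
  :mod:`mtconserv.rates`).

The SLAC-style test reconstructs ancestral codons, counts observed
synonymous/non-synonymous events, derives expected synonymous site
fractions from the ancestral codons weighted by branch length, and
assesses dN != dS with a two-tailed extended binomial (continuous
counts handled through the regularized incomplete beta function).
A codon column is called negatively selected when dN < dS with
p <= 0.1 (a strict alpha = 0.05 flag is reported alongside).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import special, stats

from . import ancestral
from .io import CodonAlignment, Phylogeny
from .reference import STOP, UNKNOWN, GeneticCode, translate_codon

_CODE = GeneticCode.vertebrate_mito()
_BASES = "ACGT"


# ---------------------------------------------------------------------------
# codon-level counting machinery


@lru_cache(maxsize=None)
def pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) event counts for one codon change.

    Averages over every minimal mutational pathway between the codons
    that avoids stop codons; if all orderings pass through a stop, all
    orderings count.  A single-step change contributes exactly one
    event.
    """
    if c1 == c2:
        return (0.0, 0.0)
    diff = [i for i in range(3) if c1[i] != c2[i]]
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        steps = []
        blocked = False
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            if translate_codon(nxt) == STOP and nxt != c2:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        paths.append((blocked, steps))
    viable = [steps for blocked, steps in paths if not blocked]
    if not viable:
        viable = [steps for _, steps in paths]
    syn = nonsyn = 0.0
    for steps in viable:
        for a, b in steps:
            if translate_codon(a) == translate_codon(b):
                syn += 1
            else:
                nonsyn += 1
    n = len(viable)
    return (syn / n, nonsyn / n)


@lru_cache(maxsize=None)
def codon_site_fractions(codon: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) site counts of a codon (sum = 3).

    Fractions over the single-nucleotide neighbours, excluding changes
    into stop codons.
    """
    aa = translate_codon(codon)
    if aa in (STOP, UNKNOWN):
        return (0.0, 0.0)
    syn = tot = 0
    for i in range(3):
        for b in _BASES:
            if b == codon[i]:
                continue
            nb = codon[:i] + b + codon[i + 1 :]
            nb_aa = translate_codon(nb)
            if nb_aa == STOP:
                continue
            tot += 1
            if nb_aa == aa:
                syn += 1
    if tot == 0:
        return (0.0, 3.0)
    return (3.0 * syn / tot, 3.0 - 3.0 * syn / tot)


def extended_binomial_p(k: float, n: float, p: float) -> float:
    """Two-tailed extended binomial p-value for ``k`` successes of ``n``.

    Continuous counts are supported through the regularized incomplete
    beta function, which coincides with the binomial tail at integers.
    """
    if n <= 0 or not 0 < p < 1:
        return 1.0
    k = min(max(k, 0.0), n)
    upper = special.betainc(k, n - k + 1.0, p) if k > 0 else 1.0
    lower = 1.0 - special.betainc(k + 1.0, n - k, p) if k < n else 1.0
    return float(min(1.0, 2.0 * min(upper, lower)))


# ---------------------------------------------------------------------------
# per-column indices


def ind1(aa_column: np.ndarray) -> int | None:
    """Number of distinct amino acids among defined cells; None when
    every cell is undefined."""
    defined = {a for a in aa_column if a not in (UNKNOWN, "-", "")}
    return len(defined) if defined else None


def column_substitution_pairs(
    tree: Phylogeny, codon_column: np.ndarray
) -> list[tuple[int, str, str]]:
    """Per-branch codon substitutions under the deterministic MPR."""
    ls = ancestral.leaf_states_from_column(tree, codon_column)
    return ancestral.branch_substitutions(tree, ls)


def aa_substitutions(
    tree: Phylogeny, aa_column: np.ndarray
) -> list[tuple[int, str, str]] | None:
    """Per-branch amino-acid substitutions (missense events) under the
    deterministic MPR on the translated column; None when no leaf is
    informative."""
    ls = ancestral.leaf_states_from_column(tree, aa_column)
    if not ls:
        return None
    return ancestral.branch_substitutions(tree, ls)


def ind2(tree: Phylogeny, aa_column: np.ndarray) -> int | None:
    """Missense substitution events in one column.

    Counted as parsimony state changes on the translated (residue)
    column, so an invariant residue column always scores 0 even when
    its codons vary synonymously across distant codon families.
    """
    subs = aa_substitutions(tree, aa_column)
    return None if subs is None else len(subs)


@dataclass
class SlacResult:
    dn: float
    ds: float
    p_value: float
    negatively_selected: bool
    negatively_selected_strict: bool
    observed_syn: float
    observed_nonsyn: float
    expected_syn_sites: float
    expected_nonsyn_sites: float


def slac_site(
    tree: Phylogeny,
    codon_column: np.ndarray,
    alpha: float = 0.1,
    strict_alpha: float = 0.05,
) -> SlacResult | None:
    """SLAC-style per-column selection scoring; None when the column has
    no informative leaf."""
    ls = ancestral.leaf_states_from_column(tree, codon_column)
    if not ls:
        return None
    states = ancestral.reconstruct(tree, ls)
    obs_syn = obs_nonsyn = 0.0
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p == -1 or states[v] is None or states[v] == states[p]:
            continue
        s, n = pathway_counts(states[p], states[v])
        obs_syn += s
        obs_nonsyn += n
    wsum = es = 0.0
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p == -1 or states[p] is None:
            continue
        t = max(tree.length[v], 0.0)
        sf, _ = codon_site_fractions(states[p])
        es += t * sf
        wsum += t
    if wsum == 0:  # star-like degenerate branch lengths: equal weights
        for v in range(tree.n_nodes):
            p = tree.parent[v]
            if p == -1 or states[p] is None:
                continue
            es += codon_site_fractions(states[p])[0]
            wsum += 1.0
    es_sites = es / wsum if wsum else 0.0
    en_sites = 3.0 - es_sites
    ds = obs_syn / es_sites if es_sites > 0 else 0.0
    dn = obs_nonsyn / en_sites if en_sites > 0 else 0.0
    total = obs_syn + obs_nonsyn
    p_val = extended_binomial_p(obs_nonsyn, total, en_sites / 3.0)
    neg = dn < ds
    return SlacResult(
        dn=dn,
        ds=ds,
        p_value=p_val,
        negatively_selected=neg and p_val <= alpha,
        negatively_selected_strict=neg and p_val <= strict_alpha,
        observed_syn=obs_syn,
        observed_nonsyn=obs_nonsyn,
        expected_syn_sites=es_sites,
        expected_nonsyn_sites=en_sites,
    )


# ---------------------------------------------------------------------------
# column inclusion and the site table


def included_columns(
    alignment: CodonAlignment,
    reference_taxon: str | None,
    drop_reference_gaps: bool = True,
    drop_terminal_stops: bool = True,
) -> list[int]:
    """Columns analyzed: terminal stop codons of each gene block and
    columns undefined in the reference row are dropped (configurable)."""
    n = alignment.n_columns
    keep = np.ones(n, dtype=bool)
    if reference_taxon is not None:
        row = alignment.codons[alignment.row(reference_taxon)]
        aa = np.array([translate_codon(c) for c in row])
        if drop_reference_gaps:
            keep &= aa != UNKNOWN
        if drop_terminal_stops:
            # reference stop columns are not analyzed codon positions
            keep &= aa != STOP
    return [int(j) for j in np.flatnonzero(keep)]


def human_codon_numbers(
    alignment: CodonAlignment, reference_taxon: str
) -> dict[int, tuple[str, int]]:
    """Column -> (gene, codon number in the reference sequence).

    Codons are numbered along non-gap reference cells within each gene
    block, which realizes the "codon position in humans" anchoring.
    """
    row = alignment.codons[alignment.row(reference_taxon)]
    out: dict[int, tuple[str, int]] = {}
    counters: dict[str, int] = {}
    for j, cell in enumerate(row):
        gene = alignment.provenance[j][0]
        if "-" in cell:
            continue
        counters[gene] = counters.get(gene, 0) + 1
        out[j] = (gene, counters[gene])
    return out


def site_conservation_table(
    alignment: CodonAlignment,
    tree: Phylogeny,
    reference_taxon: str | None = None,
    columns: list[int] | None = None,
    alpha: float = 0.1,
) -> pd.DataFrame:
    """Ind1, Ind2 and SLAC summaries for every included column."""
    if columns is None:
        columns = included_columns(alignment, reference_taxon)
    aa = alignment.aa_matrix()
    rows = []
    for j in columns:
        codon_col = alignment.codons[:, j]
        aa_col = aa[:, j]
        defined = sum(1 for a in aa_col if a not in (UNKNOWN, "-", ""))
        res = slac_site(tree, codon_col, alpha=alpha)
        rows.append(
            {
                "column": j,
                "gene": alignment.provenance[j][0],
                "n_informative": defined,
                "ind1": ind1(aa_col),
                "ind2": ind2(tree, aa_col),
                "nonsyn_pathway": res.observed_nonsyn if res else np.nan,
                "dn": res.dn if res else np.nan,
                "ds": res.ds if res else np.nan,
                "p_value": res.p_value if res else np.nan,
                "negatively_selected": bool(res.negatively_selected)
                if res
                else False,
                "negatively_selected_strict": bool(
                    res.negatively_selected_strict
                )
                if res
                else False,
            }
        )
    df = pd.DataFrame(rows)
    if reference_taxon is not None and len(df):
        codmap = human_codon_numbers(alignment, reference_taxon)
        df["human_codon"] = [
            codmap.get(j, (None, None))[1] for j in df["column"]
        ]
    return df


# ---------------------------------------------------------------------------
# indels


@dataclass
class IndelEvent:
    gene: str
    start_column: int
    end_column: int  # inclusive
    branch: int
    kind: str  # 'insertion' | 'deletion'


def enumerate_indel_events(
    alignment: CodonAlignment, tree: Phylogeny
) -> list[IndelEvent]:
    """Independent insertion/deletion events of codon gap blocks.

    Maximal per-taxon runs of fully gapped columns define candidate
    blocks; each distinct (start, end) block becomes a binary
    presence/absence character whose parsimony changes on the tree are
    the events.  A branch on which the gap appears is a deletion, one on
    which it disappears an insertion.
    """
    gaps = alignment.codons == "---"
    blocks: set[tuple[int, int, str]] = set()
    genes = [g for g, _ in alignment.provenance]
    for i in range(alignment.n_taxa):
        j = 0
        while j < alignment.n_columns:
            if gaps[i, j]:
                start = j
                while (
                    j + 1 < alignment.n_columns
                    and gaps[i, j + 1]
                    and genes[j + 1] == genes[start]
                ):
                    j += 1
                blocks.add((start, j, genes[start]))
            j += 1
    events: list[IndelEvent] = []
    for start, end, gene in sorted(blocks):
        present = gaps[:, start : end + 1].all(axis=1)
        ls = {
            node: ("G" if present[row] else "N")
            for node, row in tree.leaf_rows.items()
        }
        # alphabet order makes root ties prefer the residues-present
        # state, so an ambiguous block is scored as derived (deletion)
        states = ancestral.reconstruct(tree, ls, alphabet=["N", "G"])
        for v in range(tree.n_nodes):
            p = tree.parent[v]
            if p == -1 or states[v] == states[p]:
                continue
            kind = "deletion" if states[v] == "G" else "insertion"
            events.append(IndelEvent(gene, start, end, v, kind))
    return events


# ---------------------------------------------------------------------------
# gene summaries


@dataclass
class GeneSummary:
    gene: str
    length_bp: int
    mean_distance: float
    fraction_negative: float
    n_indel_events: int


def size_distance_correlation(
    summaries: list[GeneSummary],
) -> dict[str, dict[str, float]]:
    """Pearson r^2 and two-sided p for gene size vs mean distance and
    gene size vs fraction of negatively selected codons."""
    size = np.array([s.length_bp for s in summaries], dtype=float)
    out = {}
    for name, y in (
        ("size_vs_distance", [s.mean_distance for s in summaries]),
        ("size_vs_fraction_negative", [s.fraction_negative for s in summaries]),
    ):
        y = np.asarray(y, dtype=float)
        if np.allclose(y, y[0]) or np.allclose(size, size[0]):
            out[name] = {"r2": 0.0, "p": 1.0}
            continue
        r, p = stats.pearsonr(size, y)
        out[name] = {"r2": float(r * r), "p": float(p)}
    return out
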