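"""Parsimony reconstruction of codon and amino-acid columns.

Minimum change counts use unit-cost Sankoff dynamic programming, which
equals the Fitch minimum on bifurcating trees and stays exact on
polytomies.  A deterministic top-down traceback (prefer the parental
state whenever it is optimal for the child — DELTRAN-like) turns the DP
into a single most-parsimonious reconstruction (MPR), the substrate for
substitution listings.  Independent-origin counts minimize, over *all*
MPRs, the number of branches gaining the residue; presence of the
residue at the root counts as one origin.

Missing leaf states (gaps, untranslatable codons) follow the classic
convention: they are compatible with every state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Phylogeny

INF = np.inf

#: characters that denote a missing observation at a leaf
MISSING = {"X", "-", "?", ""}


def leaf_states_from_column(
    tree: Phylogeny, column: np.ndarray
) -> dict[int, str]:
    """Map leaf node ids to their (defined) states for one column.

    The tree must be bound to the alignment the column comes from.
    Cells in :data:`MISSING` (or fully gapped codon cells) are omitted.
    """
    if tree.leaf_rows is None:
        raise ValueError("tree is not bound to an alignment")
    out = {}
    for node, row in tree.leaf_rows.items():
        s = str(column[row])
        if s in MISSING:
            continue
        # for codon cells the nucleotide ambiguity/gap characters make
        # the whole cell missing; single letters are residue states
        # (where N is asparagine, not an ambiguity)
        if len(s) == 3 and ("-" in s or "N" in s):
            continue
        out[node] = s
    return out


def _alphabet(leaf_states: dict[int, str],
              alphabet: list[str] | None) -> list[str]:
    if alphabet is None:
        alphabet = sorted(set(leaf_states.values()))
    return alphabet


def sankoff_costs(
    tree: Phylogeny,
    leaf_states: dict[int, str],
    alphabet: list[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Per-node minimal subtree change counts, one column per state."""
    alphabet = _alphabet(leaf_states, alphabet)
    a_index = {s: i for i, s in enumerate(alphabet)}
    n_states = len(alphabet)
    cost = np.zeros((tree.n_nodes, n_states))
    for v in tree.postorder():
        if tree.is_leaf(v):
            s = leaf_states.get(v)
            if s is not None:
                cost[v, :] = INF
                cost[v, a_index[s]] = 0.0
        else:
            acc = np.zeros(n_states)
            for c in tree.children[v]:
                cc = cost[c]
                acc += np.minimum(cc, cc.min() + 1.0)
            cost[v] = acc
    return cost, alphabet


def fitch_min_changes(
    tree: Phylogeny,
    leaf_states: dict[int, str],
    alphabet: list[str] | None = None,
) -> int | None:
    """Parsimony minimum number of state changes; None if no leaf is
    informative."""
    if not leaf_states:
        return None
    cost, _ = sankoff_costs(tree, leaf_states, alphabet)
    return int(cost[tree.root].min())


def reconstruct(
    tree: Phylogeny,
    leaf_states: dict[int, str],
    alphabet: list[str] | None = None,
) -> list[str | None]:
    """One deterministic MPR: per-node state assignment.

    Root takes the lexicographically smallest optimal state; every child
    keeps its parent's state whenever that is optimal for the child's
    subtree, otherwise the smallest optimal alternative.  Returns None
    for every node when no leaf is informative.
    """
    if not leaf_states:
        return [None] * tree.n_nodes
    cost, alphabet = sankoff_costs(tree, leaf_states, alphabet)
    state = [None] * tree.n_nodes
    state[tree.root] = alphabet[int(np.argmin(cost[tree.root]))]
    a_index = {s: i for i, s in enumerate(alphabet)}
    for v in tree.preorder():
        if v == tree.root:
            continue
        p_state = state[tree.parent[v]]
        cv = cost[v]
        mc = cv.min()
        # keeping the parent state is optimal iff its subtree cost does
        # not exceed the best alternative plus one change
        if cv[a_index[p_state]] <= mc + 1.0:
            state[v] = p_state
        else:
            state[v] = alphabet[int(np.argmin(cv))]
    return state


def branch_substitutions(
    tree: Phylogeny,
    leaf_states: dict[int, str],
    alphabet: list[str] | None = None,
) -> list[tuple[int, str, str]]:
    """Per-branch (child_node, from_state, to_state) under the
    deterministic MPR; list length equals the parsimony minimum."""
    state = reconstruct(tree, leaf_states, alphabet)
    subs = []
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p == -1 or state[v] is None:
            continue
        if state[v] != state[p]:
            subs.append((v, state[p], state[v]))
    return subs


def count_independent_origins(
    tree: Phylogeny,
    leaf_states: dict[int, str],
    residue: str,
    alphabet: list[str] | None = None,
) -> int:
    """Minimum, over all MPRs, of independent gains of ``residue``.

    A gain is a branch whose parent state is not the residue and whose
    child state is; the residue being ancestral at the root counts as
    one origin, so the count is 0 exactly when no leaf carries the
    residue.
    """
    if len(residue) == 1 and residue not in "ARNDCQEGHILKMFPSTWYV*":
        raise ValueError(f"invalid residue symbol {residue!r}")
    if not leaf_states:
        return 0
    alphabet = _alphabet(leaf_states, alphabet)
    if residue not in alphabet:
        return 0
    r = alphabet.index(residue)
    cost, _ = sankoff_costs(tree, leaf_states, alphabet)
    n_states = len(alphabet)
    orig = np.zeros((tree.n_nodes, n_states))
    for v in tree.postorder():
        if tree.is_leaf(v):
            continue
        acc = np.zeros(n_states)
        for c in tree.children[v]:
            cc, oc = cost[c], orig[c]
            mc = cc.min()
            at_min = cc == mc
            omin_all = oc[at_min].min()
            nonr = at_min.copy()
            nonr[r] = False
            omin_nonr = oc[nonr].min() if nonr.any() else INF
            omin_r = oc[r] if at_min[r] else INF
            # optimal continuation cost for parent state s is
            # min(cc[s], mc+1); gather min origins among optimal choices
            val = np.empty(n_states)
            # changing into some optimal t: t==r adds an origin unless s==r
            change = min(omin_nonr, omin_r + 1.0)
            val[:] = change
            val[r] = omin_all
            keep_ok = cc <= mc + 1.0  # keeping s is among optimal choices
            val[keep_ok] = np.minimum(val[keep_ok], oc[keep_ok])
            exact = cc == mc  # keeping s is the *only* optimal choice
            val[exact] = oc[exact]
            acc += val
        orig[v] = acc
    root_cost = cost[tree.root]
    best = root_cost.min()
    cand = np.where(root_cost == best)[0]
    totals = orig[tree.root, cand] + (cand == r)
    return int(totals.min())


@dataclass
class AncestralColumn:
    """Reconstruction summary of one aligned column."""

    column: int
    states: list[str | None]
    min_changes: int | None
    substitutions: list[tuple[int, str, str]]

    @classmethod
    def from_column(
        cls, tree: Phylogeny, column: np.ndarray, column_id: int,
        alphabet: list[str] | None = None,
    ) -> "AncestralColumn":
        ls = leaf_states_from_column(tree, column)
        return cls(
            column=column_id,
            states=reconstruct(tree, ls, alphabet),
            min_changes=fitch_min_changes(tree, ls, alphabet),
            substitutions=branch_substitutions(tree, ls, alphabet),
        )
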