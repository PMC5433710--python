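"""Independent brute-force oracles used across the test suite.

These enumerate every possible labeling of internal (and missing-leaf)
nodes, so they are exact by construction and share no code with the
dynamic programs they check.
"""

from __future__ import annotations

import itertools

import numpy as np

from mtconserv.io import Phylogeny


def random_binary_newick(rng: np.random.Generator, n_leaves: int) -> str:
    """Random binary topology over T0..T{n-1} with unit branch lengths."""
    nodes = [f"T{i}:1" for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[i], nodes[j]
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(f"({a},{b}):1")
    return nodes[0] + ";"


def enumerate_labelings(tree: Phylogeny, leaf_states: dict[int, str],
                        alphabet: list[str]):
    """Yield full node-state assignments (list indexed by node id)."""
    free = [v for v in range(tree.n_nodes)
            if not tree.is_leaf(v) or v not in leaf_states]
    fixed = {v: s for v, s in leaf_states.items()}
    for combo in itertools.product(alphabet, repeat=len(free)):
        assign = [None] * tree.n_nodes
        for v, s in fixed.items():
            assign[v] = s
        for v, s in zip(free, combo):
            assign[v] = s
        yield assign


def changes_of(tree: Phylogeny, assign: list[str]) -> int:
    return sum(
        1
        for v in range(tree.n_nodes)
        if tree.parent[v] != -1 and assign[v] != assign[tree.parent[v]]
    )


def origins_of(tree: Phylogeny, assign: list[str], residue: str) -> int:
    n = sum(
        1
        for v in range(tree.n_nodes)
        if tree.parent[v] != -1
        and assign[v] == residue
        and assign[tree.parent[v]] != residue
    )
    return n + (1 if assign[tree.root] == residue else 0)


def min_changes_bruteforce(tree: Phylogeny, leaf_states: dict[int, str],
                           alphabet: list[str]) -> int:
    return min(
        changes_of(tree, a)
        for a in enumerate_labelings(tree, leaf_states, alphabet)
    )


def min_origins_bruteforce(tree: Phylogeny, leaf_states: dict[int, str],
                           alphabet: list[str], residue: str) -> int:
    """Min origins among labelings achieving the parsimony minimum."""
    best_changes = None
    best_orig = None
    for a in enumerate_labelings(tree, leaf_states, alphabet):
        ch = changes_of(tree, a)
        if best_changes is None or ch < best_changes:
            best_changes = ch
            best_orig = origins_of(tree, a, residue)
        elif ch == best_changes:
            best_orig = min(best_orig, origins_of(tree, a, residue))
    return best_orig
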