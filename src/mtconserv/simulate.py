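"""Synthetic codon alignments, trees and variant tables with ground truth.

The generator emulates the statistical structure the analysis assumes
for primate mitochondrial protein genes: strong purifying selection (a
two-class omega mixture dominated by conserved sites), gamma-distributed
site rate multipliers with an invariant fraction, a high
transition/transversion ratio, clade-consistent gap blocks, and
"disease variants" planted either in the most conserved sites
(confirmed-like) or uniformly (reported-like).

Codon evolution is GY94-style: single-nucleotide codon exchanges with
transition bias ``kappa``, target-codon equilibrium frequency, and a
non-synonymous multiplier ``omega``; substitutions into stop codons are
rejected.  Branch lengths are neutral nucleotide substitutions per
site: the generator rate is normalized so that at ``omega = 1`` and
rate multiplier 1 one unit of branch length yields one expected
nucleotide substitution per site.  The full event log is retained so
that replaying events reproduces every leaf sequence exactly.
"""

from __future__ import annotations

import json
import random as pyrandom
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .io import CodonAlignment, Phylogeny
from .reference import GeneticCode, translate_codon

_CODE = GeneticCode.vertebrate_mito()
_SENSE = _CODE.sense_codons
_SENSE_INDEX = {c: i for i, c in enumerate(_SENSE)}
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

REFERENCE_TAXON = "REF"


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic generator.

    Defaults emulate a primate-mitogenome-like regime: most sites under
    strong purifying selection, mtDNA-typical transition bias, moderate
    rate heterogeneity with an invariant fraction, and sparse
    clade-consistent gap blocks.
    """

    n_taxa: int = 60
    n_codons: int = 600
    tree_newick: str | None = None
    tree_length: float = 8.0  # summed neutral substitutions/site
    birth_rate: float = 1.0
    death_rate: float = 0.3
    gamma_shape: float = 0.7
    p_invariant: float = 0.15
    fraction_conserved: float = 0.85
    omega_conserved: float = 0.05
    omega_variable: float = 0.6
    kappa: float = 8.0
    gap_block_rate: float = 0.015  # expected blocks per taxon
    gap_block_mean_len: int = 3
    seed: int = 0

    def validate(self):
        for name in ("p_invariant", "fraction_conserved"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.omega_conserved < 0 or self.omega_variable < 0:
            raise ValueError("omega values must be non-negative")


@dataclass
class SimulationTruth:
    """Ground truth: per-site rate/omega, the event log, planted gaps."""

    site_rate: np.ndarray
    site_omega: np.ndarray
    root_sequence: list[str]
    # per branch (child node id): list of (site, from_codon, to_codon, syn)
    events: dict[int, list[tuple[int, str, str, bool]]]
    gap_blocks: list[tuple[int, int, int]] = field(default_factory=list)
    planted: pd.DataFrame | None = None

    def n_events(self) -> int:
        return sum(len(v) for v in self.events.values())

    def nonsyn_events_per_site(self, n_sites: int) -> np.ndarray:
        out = np.zeros(n_sites)
        for evs in self.events.values():
            for site, _, _, syn in evs:
                if not syn:
                    out[site] += 1
        return out


class _CodonProcess:
    """Precomputed single-nucleotide neighbour structure of the code."""

    def __init__(self, kappa: float):
        n = len(_SENSE)
        self.targets: list[np.ndarray] = []
        self.weights: list[np.ndarray] = []
        self.syn: list[np.ndarray] = []
        pi = 1.0 / n  # uniform codon frequencies
        for codon in _SENSE:
            aa = translate_codon(codon)
            tg, wt, sy = [], [], []
            for i in range(3):
                for b in "ACGT":
                    if b == codon[i]:
                        continue
                    nb = codon[:i] + b + codon[i + 1 :]
                    if nb not in _SENSE_INDEX:  # stop codons rejected
                        continue
                    tg.append(_SENSE_INDEX[nb])
                    wt.append(pi * (kappa if (codon[i], b) in _TRANSITIONS
                                    else 1.0))
                    sy.append(translate_codon(nb) == aa)
            self.targets.append(np.array(tg))
            self.weights.append(np.array(wt))
            self.syn.append(np.array(sy, dtype=bool))
        # neutral total codon rate under uniform codon frequencies;
        # scaling by 3/Z makes one unit of branch length one expected
        # neutral nucleotide substitution per site
        z = sum(pi * w.sum() for w in self.weights)
        self.scale = 3.0 / z


def _birth_death_tree(cfg: SimulationConfig, seed: int) -> dendropy.Tree:
    from dendropy.simulate import treesim

    tree = treesim.birth_death_tree(
        birth_rate=cfg.birth_rate,
        death_rate=cfg.death_rate,
        num_extant_tips=cfg.n_taxa,
        rng=pyrandom.Random(seed),
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = REFERENCE_TAXON if i == 0 else f"T{i:03d}"
    total = sum(e.length or 0.0 for e in tree.preorder_edge_iter())
    if total <= 0:
        raise ValueError("degenerate simulated tree")
    f = cfg.tree_length / total
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length *= f
    return tree


def simulate_alignment(
    cfg: SimulationConfig,
) -> tuple[CodonAlignment, Phylogeny, SimulationTruth]:
    """Evolve a codon alignment along a (simulated or given) tree."""
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    s_tree, s_sites, s_events, s_gaps = ss.spawn(4)
    rng_sites = np.random.default_rng(s_sites)
    rng_events = np.random.default_rng(s_events)
    rng_gaps = np.random.default_rng(s_gaps)

    if cfg.tree_newick is not None:
        tree = Phylogeny.from_newick(cfg.tree_newick)
    else:
        seed_int = int(s_tree.generate_state(1)[0] % (2**31))
        tree = Phylogeny(_birth_death_tree(cfg, seed_int))

    n_sites = cfg.n_codons
    rate = np.where(
        rng_sites.random(n_sites) < cfg.p_invariant,
        0.0,
        rng_sites.gamma(cfg.gamma_shape, 1.0 / cfg.gamma_shape, n_sites),
    )
    omega = np.where(
        rng_sites.random(n_sites) < cfg.fraction_conserved,
        cfg.omega_conserved,
        cfg.omega_variable,
    )

    proc = _CodonProcess(cfg.kappa)
    root_seq = rng_sites.integers(0, len(_SENSE), n_sites)
    seqs: dict[int, np.ndarray] = {tree.root: root_seq}
    events: dict[int, list[tuple[int, str, str, bool]]] = {}
    site_scale = rate * proc.scale
    for v in tree.preorder():
        if v == tree.root:
            continue
        parent_seq = seqs[tree.parent[v]]
        seq = parent_seq.copy()
        t_branch = max(tree.length[v], 0.0)
        evs: list[tuple[int, str, str, bool]] = []
        if t_branch > 0:
            for site in np.flatnonzero(site_scale > 0):
                sc = site_scale[site]
                t = 0.0
                state = seq[site]
                while True:
                    w = proc.weights[state].copy()
                    ns = ~proc.syn[state]
                    w[ns] *= omega[site]
                    total = w.sum() * sc
                    if total <= 0:
                        break
                    t += rng_events.exponential(1.0 / total)
                    if t >= t_branch:
                        break
                    nxt = proc.targets[state][
                        rng_events.choice(len(w), p=w / w.sum())
                    ]
                    evs.append(
                        (int(site), _SENSE[state], _SENSE[nxt],
                         bool(translate_codon(_SENSE[state])
                              == translate_codon(_SENSE[nxt])))
                    )
                    state = int(nxt)
                seq[site] = state
        seqs[v] = seq
        events[v] = evs

    taxa_nodes = sorted(tree.leaf_label)
    taxa = [tree.leaf_label[v] for v in taxa_nodes]
    mat = np.empty((len(taxa), n_sites), dtype="<U3")
    for row, v in enumerate(taxa_nodes):
        for j in range(n_sites):
            mat[row, j] = _SENSE[seqs[v][j]]

    # clade-consistent gap blocks (whole-codon deletions)
    gap_blocks: list[tuple[int, int, int]] = []
    internals = [v for v in range(tree.n_nodes)
                 if not tree.is_leaf(v) and v != tree.root]
    n_blocks = rng_gaps.poisson(cfg.gap_block_rate * cfg.n_taxa)
    ref_node = next(v for v in taxa_nodes
                    if tree.leaf_label[v] == REFERENCE_TAXON)
    for _ in range(n_blocks):
        carrier = int(rng_gaps.choice(
            internals if internals else taxa_nodes))
        length = 1 + rng_gaps.geometric(1.0 / cfg.gap_block_mean_len)
        start = int(rng_gaps.integers(0, max(1, n_sites - length)))
        below = _leaves_below(tree, carrier)
        if ref_node in below:  # keep the reference row gap-free
            continue
        rows = [taxa_nodes.index(v) for v in below]
        mat[rows, start : start + length] = "---"
        gap_blocks.append((carrier, start, start + length - 1))

    aln = CodonAlignment(gene="SYN1", taxa=taxa, codons=mat)
    tree.bind(aln)
    truth = SimulationTruth(
        site_rate=rate,
        site_omega=omega,
        root_sequence=[_SENSE[i] for i in root_seq],
        events=events,
        gap_blocks=gap_blocks,
    )
    return aln, tree, truth


def _leaves_below(tree: Phylogeny, node: int) -> list[int]:
    stack, out = [node], []
    while stack:
        v = stack.pop()
        if tree.is_leaf(v):
            out.append(v)
        else:
            stack.extend(tree.children[v])
    return out


def replay_events(
    tree: Phylogeny, truth: SimulationTruth
) -> dict[int, list[str]]:
    """Recompute every node's sequence from the root and the event log."""
    seqs = {tree.root: list(truth.root_sequence)}
    for v in tree.preorder():
        if v == tree.root:
            continue
        seq = list(seqs[tree.parent[v]])
        for site, frm, to, _ in truth.events.get(v, []):
            if seq[site] != frm:
                raise ValueError(
                    f"event log inconsistent at node {v} site {site}"
                )
            seq[site] = to
        seqs[v] = seq
    return seqs


def plant_variants(
    aln: CodonAlignment,
    tree: Phylogeny,
    truth: SimulationTruth,
    n_conserved: int = 28,
    n_variable: int = 192,
    seed: int = 0,
) -> pd.DataFrame:
    """Fabricate a disease-variant table with known conservation class.

    Confirmed-like variants sit in the lowest-rate decile of sites,
    reported-like variants are uniform over sites; coordinates follow
    the synthetic single-gene map (gene ``SYN1`` starting at position 1
    on the + strand).  Returns the variant table; ``truth.planted`` is
    set to the same frame including the true site class.
    """
    rng = np.random.default_rng(seed)
    ref_row = aln.codons[aln.row(REFERENCE_TAXON)]
    eligible = np.array([
        j for j in range(aln.n_columns) if "-" not in ref_row[j]
    ])
    rates = truth.site_rate[eligible]
    decile = np.quantile(rates, 0.1)
    conserved_pool = eligible[rates <= decile]
    if n_conserved > len(conserved_pool):
        raise ValueError(
            f"requested {n_conserved} conserved-like variants, only "
            f"{len(conserved_pool)} eligible sites"
        )
    if n_variable > len(eligible):
        raise ValueError("requested more variable-like variants than sites")
    chosen_c = rng.choice(conserved_pool, size=n_conserved, replace=False)
    chosen_v = rng.choice(eligible, size=n_variable, replace=False)
    rows = []
    for status, cols, klass in (
        ("confirmed", chosen_c, "conserved"),
        ("reported", chosen_v, "uniform"),
    ):
        for j in cols:
            codon = ref_row[j]
            aa = translate_codon(codon)
            muts = []
            for i in range(3):
                for b in "ACGT":
                    if b == codon[i]:
                        continue
                    nb = codon[:i] + b + codon[i + 1 :]
                    nb_aa = translate_codon(nb)
                    if nb_aa not in ("*", aa):
                        muts.append((i, b, nb_aa))
            if not muts:
                continue
            # mimic the recurrence structure of reported variants: when
            # the column already shows a reachable residue in non-
            # reference taxa, prefer planting that residue
            present = {
                translate_codon(c)
                for c in aln.codons[:, j]
                if c != "---"
            } - {aa}
            recurrent = [m for m in muts if m[2] in present]
            pool = recurrent if (klass == "uniform" and recurrent) else muts
            i, b, nb_aa = pool[rng.integers(len(pool))]
            pos = 3 * j + i + 1
            rows.append(
                {
                    "notation": f"m.{pos}{codon[i]}>{b}",
                    "status": status,
                    "protein_change": f"{aa}{j + 1}{nb_aa}",
                    "phenotype": "synthetic",
                    "true_class": klass,
                    "true_rate": float(truth.site_rate[j]),
                    "column": int(j),
                }
            )
    df = pd.DataFrame(rows)
    truth.planted = df
    return df


def synthetic_gene_map_tsv(n_codons: int, path: str | Path) -> None:
    """Gene map for the synthetic single-gene coordinate system."""
    pd.DataFrame(
        [{"gene": "SYN1", "start": 1, "end": 3 * n_codons, "strand": "+"}]
    ).to_csv(path, sep="\t", index=False)


def write_bundle(
    outdir: str | Path,
    cfg: SimulationConfig,
    aln: CodonAlignment,
    tree: Phylogeny,
    truth: SimulationTruth,
    variants: pd.DataFrame | None = None,
) -> dict[str, str]:
    """Emit FASTA + newick + TSV + truth JSON; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aln.write_fasta(outdir / "alignment.fasta")
    tree.write_newick(outdir / "tree.nwk")
    synthetic_gene_map_tsv(cfg.n_codons, outdir / "gene_map.tsv")
    pd.DataFrame(
        [{"gene": "SYN1", "start": 1, "end": cfg.n_codons}]
    ).to_csv(outdir / "gene_offsets.tsv", sep="\t", index=False)
    files = {
        "alignment": "alignment.fasta",
        "tree": "tree.nwk",
        "gene_map": "gene_map.tsv",
        "gene_offsets": "gene_offsets.tsv",
    }
    if variants is not None:
        variants.drop(columns=["true_class", "true_rate", "column"]).to_csv(
            outdir / "variants.tsv", sep="\t", index=False
        )
        files["variants"] = "variants.tsv"
    truth_json = {
        "site_rate": truth.site_rate.tolist(),
        "site_omega": truth.site_omega.tolist(),
        "n_events": truth.n_events(),
        "gap_blocks": truth.gap_blocks,
        "planted": None
        if truth.planted is None
        else truth.planted.to_dict(orient="records"),
    }
    (outdir / "truth.json").write_text(json.dumps(truth_json))
    files["truth"] = "truth.json"
    manifest = {"seed": cfg.seed, "config": asdict(cfg), "files": files}
    manifest["config"].pop("tree_newick", None)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
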