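"""Generate a synthetic primate-like codon alignment and score it.

The generator evolves codons on a birth-death tree under purifying
selection (GY94-style, two-class omega mixture, gamma site rates); the
conservation stage then computes, per aligned codon column, the three
conservation indices and the SLAC-style negative-selection test.
"""

from mtconserv.pipeline import RunConfig, run_conserve, run_simulate
from mtconserv.simulate import SimulationConfig

run_simulate(
    SimulationConfig(n_taxa=30, n_codons=200, seed=11),
    "scratch/example_bundle", n_confirmed=8, n_reported=40,
)
cfg = RunConfig(
    alignment="scratch/example_bundle/alignment.fasta",
    tree="scratch/example_bundle/tree.nwk",
    gene_map="scratch/example_bundle/gene_map.tsv",
    gene_offsets="scratch/example_bundle/gene_offsets.tsv",
    variants="scratch/example_bundle/variants.tsv",
    outdir="scratch/example_out",
    reference_taxon="REF",
)
res = run_conserve(cfg)
site, dist = res["site"], res["distributions"]

print(f"aligned codon columns analyzed: {dist['n_columns']}")
print(f"invariant columns (Ind1 = 1): {dist['n_invariant']} "
      f"({dist['n_invariant'] / dist['n_columns']:.1%})")
print(f"columns flagged negatively selected (dN < dS, p <= 0.1): "
      f"{dist['fraction_negative']:.1%}")
print(f"Ind1 mean {dist['ind1']['mean']:.2f}, "
      f"Ind2 mean {dist['ind2']['mean']:.2f}")
print(f"fitted gamma shape for site rates: {dist['ind3_alpha']:.2f}")

# The invariant fraction reflects the strong purifying regime of the
# generator (85% of sites at omega = 0.05 plus an invariant-site
# class); the negatively-selected fraction rises with taxon sampling
# and tree depth because more substitutions inform the per-site test.
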