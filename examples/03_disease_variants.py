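"""Map planted disease variants and compare conservation distributions.

Confirmed-like variants are planted in the most conserved decile of
sites, reported-like variants uniformly; the Kolmogorov-Smirnov tests
then ask whether each group's conservation-index distribution differs
from the genome-wide background -- the study design for separating
credibly pathogenic variants from incidental associations.
"""

from mtconserv.pipeline import RunConfig, run_mapvariants, run_simulate
from mtconserv.simulate import SimulationConfig

run_simulate(
    SimulationConfig(n_taxa=40, n_codons=300, seed=23),
    "scratch/example_bundle3", n_confirmed=12, n_reported=60,
)
cfg = RunConfig(
    alignment="scratch/example_bundle3/alignment.fasta",
    tree="scratch/example_bundle3/tree.nwk",
    gene_map="scratch/example_bundle3/gene_map.tsv",
    gene_offsets="scratch/example_bundle3/gene_offsets.tsv",
    variants="scratch/example_bundle3/variants.tsv",
    outdir="scratch/example_out3",
    reference_taxon="REF",
)
res = run_mapvariants(cfg)

for index_name in ("ind1", "ind2", "ind3"):
    comp = res["stats"][index_name]
    for pair in ("all_vs_confirmed", "all_vs_reported"):
        r = comp[pair]
        print(f"KS {index_name:5s} {pair:18s} D={r['D']:.3f} p={r['p']:.2g}")

df = res["reports_df"]
recurrent = df[df["n_independent_origins"] > 1]
print(f"\nvariants whose residue arose independently more than once: "
      f"{len(recurrent)}")
print(recurrent[["notation", "status", "n_independent_origins",
                 "n_species_with_residue"]].head().to_string(index=False))

# Small p for the confirmed group (their sites are unusually conserved)
# and large p for the reported group (indistinguishable from background)
# reproduce the qualitative contrast between the two MITOMAP status
# tiers.  Residues with several independent origins across the tree are
# the recurrence signal that argues against severe pathogenicity.
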