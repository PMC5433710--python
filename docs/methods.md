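# Methods

## Coordinate system and reference data

All `m.` positions refer to the rCRS (NC_012920), 1-based. The packaged
gene map fixes the canonical boundaries of the 13 protein-coding genes;
ATP8/ATP6 and ND4L/ND4 overlap in shifted reading frames and are
numbered independently, each from its own start. mt-ND6 lies on the
light strand: codon 1 begins at the gene's highest rCRS coordinate and
callers receive heavy-strand bases, which the variant mapper
complements before editing a codon. Genes whose annotated interval is
not a multiple of three end in an incomplete, polyadenylation-completed
stop codon; those trailing one or two bases belong to no codon and map
to nothing.

The genetic code is NCBI translation table 2 (vertebrate mitochondrial)
taken from Biopython: ATA = Met, TGA = Trp, AGA/AGG = stop, 60 sense
codons. Codons containing `N` or gap characters translate to the
unknown sentinel `X` and count as missing data everywhere.

The 31 physicochemical property scales are compiled from the AAindex
database (via the bio3d distribution of AAindex) under the standard
radical-change property set's names — hydropathy, polarity, polar
requirement, isoelectric point, molecular volume/weight, helix, sheet,
turn and coil tendencies, buriedness, surrounding hydrophobicity,
non-bonded energy terms, and so on. Three properties of the historical
set have no exact AAindex entry and are represented by closely related
published scales (mean flexibility, mean area buried on transfer,
normalized B-value fluctuations). The packaged TSV is the single source
of truth for all category arithmetic and is versioned with the package.

## Ancestral reconstruction

Minimum change counts use unit-cost Sankoff dynamic programming — equal
to the Fitch minimum on binary trees and exact on polytomies — with
missing leaves compatible with every state. Substitution lists come
from one deterministic most-parsimonious reconstruction (MPR): the root
takes the lexicographically smallest optimal state and each child keeps
its parent's state whenever that is optimal for its subtree
(DELTRAN-like), so listings are reproducible and their length always
equals the parsimony minimum. Published counts from server-based
reconstructions are themselves MPR-policy-dependent, so desk
reproduction of event counts is expected to agree to within a few
events, not byte-for-byte.

Independent origins of a residue are the minimum, over *all* MPRs, of
branches gaining the residue, computed exactly by a second DP objective
layered on the Sankoff recursion; residue presence at the root counts
as one origin, which makes the count zero exactly when no leaf carries
the residue. This is a deliberate lower bound: recurrence claims built
on it are conservative.

## Conservation indices

**Ind1** is the number of distinct residues among defined cells.
**Ind2** is the number of missense events: parsimony substitutions of
the *translated* column. (Counting non-synonymous codon-level pathway
steps instead would score silent columns whose single residue is coded
by distant codon families — serine's TCN vs AGY — as non-zero, which
contradicts the index's meaning; the codon-level pathway counts remain
available in the site table as `nonsyn_pathway`.) **Ind3** is the
standardized empirical-Bayes rate described below.

The SLAC-style test reconstructs ancestral codons by the same parsimony
machinery, then per branch decomposes the codon change into all minimal
mutational pathways that avoid stop codons, averaging synonymous and
non-synonymous step counts over pathways (if every ordering passes
through a stop, all orderings count). Expected synonymous site
fractions are branch-length-weighted averages over ancestral codons of
each codon's synonymous fraction among its non-stop single-nucleotide
neighbours, scaled to 3 sites per codon. dS and dN are observed events
per expected site class; the p-value is a two-tailed extended binomial
on the non-synonymous share of observed events against the expected
neutral share, implemented with regularized incomplete beta functions
so fractional event counts are handled continuously. The default
negative-selection call is dN < dS with p ≤ 0.1 (the counting-method
convention); a strict α = 0.05 flag is reported alongside, since both
readings of the published procedure are defensible. Invariant columns
have no observed events, hence dN = dS = 0 and no flag.

Column inclusion drops reference-row stop codons and columns gapped or
undefined in the designated reference sequence (both configurable);
"codon position in humans" numbering counts non-gap reference cells
within each gene block.

## Empirical-Bayes site rates (Ind3)

Per-site rates follow the Rate4Site recipe: a fixed empirical
replacement matrix — mtREV24, estimated from vertebrate mitochondrial
proteins — with its equilibrium frequencies, normalized to one expected
replacement per unit branch length; a discrete-gamma prior over rate
multipliers (16 equal-probability categories, category means); the
gamma shape α fitted by bounded scalar maximization of the summed
per-site marginal log-likelihood via Felsenstein pruning (symmetric
eigendecomposition of the reversible generator, per-site scaling
against underflow); and the reported rate being each site's posterior
mean category rate. Rates are standardized to mean 0 / SD 1 across the
scored columns, so conserved sites score negative. Because the exact
settings of the web services historically used for such scores are
unpublished, Ind3 agreement is a rank-level property, which is how the
tests treat it (Spearman ≥ 0.8 against simulated truth at 150 taxa ×
1,000 sites under the rate-variation-only design, where the gamma
multiplier *is* the true amino-acid rate; under a purifying ω mixture
the multiplier and the residue-level rate decouple by construction and
rank agreement is lower).

## Gene distances and indels

Mean per-gene divergence uses GTR+Γ+I pairwise maximum-likelihood
distances under shared gene-level parameters: empirical base
frequencies; exchangeabilities, gamma shape (4 categories) and
invariant proportion fitted by composite likelihood over all pairwise
count matrices (two rounds of alternating shared-parameter and per-pair
branch-length optimization); distances capped at 10 substitutions/site
with a warning. Identical pairs give 0. Gene size vs mean distance and
gene size vs fraction-negatively-selected are Pearson correlations
reported as r² with two-sided p.

Indel events: per taxon, maximal runs of fully gapped codon columns
define gap blocks; each distinct block is a binary presence/absence
character whose parsimony changes on the tree are the independent
events, labelled deletion (gap appears) or insertion (gap disappears),
with root ties resolved toward residues-present so an ambiguous block
is scored as a derived deletion.

## Radical physicochemical changes

For a replacement and a property, the absolute value change is binned
into 8 equal-width categories spanning that property's maximum
attainable pairwise change; categories 6–8 are candidate radical
changes. At dataset level, observed branch substitutions are compared
per (property, category) against the neutral expectation — every
single-nucleotide missense change the mitochondrial code permits,
weighted by the dataset's codon usage — and a cell is significant when
its binomial z exceeds 3.09 (p < 0.001). The default radical call
requires both the category and the z criterion; a category-only mode
exists for small datasets where z is unstable (and is selected
automatically when the inventory is empty). Per column the pipeline
reports the number of substitutions with at least one radical property
and the maximum number of properties radically affected by any single
substitution.

## Variant mapping and recurrence

A parsed variant maps to one target per overlapping gene; per target
the reference codon comes from the designated reference row and the
mutant codon is built strand-aware, classifying the variant missense,
samesense or nonsense in that frame. The disease residue is taken from
the protein-change annotation when present, otherwise derived from the
frame; disagreements are recorded on the report, and a
strict-coordinates mode lets the derived residue win. Clade presence
uses a registry of nested taxon sets (for synthetic trees,
automatically nested ancestral clades around the reference leaf);
species counts collapse multiple sequences per species to one vote and
exclude the reference taxon. A reversion is called when an ancestor on
the root-to-reference path is reconstructed with the disease residue
and a later branch on that path substitutes away from it.

Summary tables count deduplicated aligned positions per gene and
status, with per-mutation tallies emitted alongside because both
denominators are informative; the invariant list (Ind1 = 1) and the
never-radical list (variable columns whose substitutions were never
radical) mirror the study's report layout.

## Comparative statistics

Two-sample Kolmogorov–Smirnov with the asymptotic p (the indices are
heavily tied and discrete; an explicit permutation p is available and
is the defensible choice at small n), Student's pooled-variance t (df =
n₁+n₂−2, Welch optional), and a χ² goodness of fit of each index
distribution against a maximum-likelihood exponential (rate = 1/mean)
over equal-width bins with an open tail, df = bins − 2; Ind3 is shifted
to positive support before fitting. No multiple-testing correction is
applied across the battery, mirroring the procedure the pipeline
reproduces; treat the p-values accordingly.

## Synthetic data

The generator emulates a primate-mitogenome-like regime, with defaults
chosen once as that regime's study conditions: 60 taxa / 600 codons per
dataset (larger sizes are used where a check prescribes them); a
birth–death tree (birth 1.0, death 0.3) rescaled to 8 expected neutral
nucleotide substitutions per site of total branch length, matching deep
primate-wide mtDNA divergence; transition/transversion ratio κ = 8
(mtDNA-typical); gamma site rates with shape 0.7 plus a 15% invariant
class; a purifying two-class ω mixture (85% of sites at ω = 0.05, the
rest at ω = 0.6); uniform codon frequencies; sparse clade-consistent
whole-codon gap blocks. Substitutions into stops are rejected with the
rate renormalized by the rejection. The full event log is retained and
replaying it from the root reproduces every leaf sequence exactly — the
generator's internal consistency proof. All randomness flows from one
seed through named per-component generators (tree, sites, events,
gaps, planting).

Planted variants: confirmed-like at sites in the lowest true-rate
decile, reported-like uniform; reported-like variants prefer a mutant
residue already reachable in one nucleotide step *and* present in
non-reference taxa, mimicking the recurrence structure of reported
disease variants. Coordinates use a synthetic single-gene map starting
at position 1.

What the generator does not emulate — realistic codon usage, indel
length distributions, heterotachy, among-gene rate differences,
sequencing error — bounds what green tests show about real data:
they validate the machinery and its statistical behaviour under the
assumed regime, not the published dataset's specific values, which
require the deposited alignment/tree/variant files (see
`data/external/README`).

## Numerical choices and degenerate inputs

Parsimony ties resolve lexicographically (stable across runs); gap
blocks at the root resolve toward residues-present; pairwise distances
are bounded in [10⁻⁶, 10]; likelihood scaling is per site per node;
α for Ind3 is searched in [0.05, 20] with 10⁻² tolerance; the extended
binomial returns p = 1 for zero events; columns with no informative
leaf yield sentinels (None/NaN) and are excluded from standardization
and distribution fits. Outputs are plain TSV/JSON with a header naming
the package version and the configuration hash, and identical inputs
and configuration give byte-identical outputs.

## Known limitations

Event counts are reconstruction-policy-dependent (±1–2 per column
against other MPR conventions); the independent-origin count is a lower
bound; the SLAC p-value is approximate for fractional counts; the
composite-likelihood GTR+Γ+I fit is not a full joint ML (adequate for
mean distances, not for parameter inference); Ind3 values are
comparable within a run only (standardization is per-dataset); and the
31-property table is a faithful stand-in for, not a byte-level copy of,
the historical property set.
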