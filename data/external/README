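Full-data inputs
================

The full-scale analysis consumes the deposited study data, which is too
large to ship in this repository:

  alignment.fasta   concatenated codon alignment of the 13 mitochondrial
                    protein-coding genes, 148 primate mitogenomes,
                    11,406 bp (deposited as supplementary data S1 of
                    doi:10.1371/journal.pone.0177403)
  tree.nwk          the maximum-likelihood tree for those sequences,
                    newick with branch lengths (S2)
  variants.tsv      the MITOMAP/UniProt disease-variant table in the
                    package's TSV dialect: columns
                    notation / status / protein_change / phenotype /
                    score (optional), derived from S3

Place the three files in this directory to enable the full-data
reproduction test (tests/test_acceptance.py) and full-scale pipeline
runs.  Everything else in the test suite runs on generated data and
needs no downloads.
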