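"""Map mtDNA variant positions to genes and codons.

Positions in ``m.`` notation refer to the human rCRS coordinate system.
A position inside the ATP8/ATP6 overlap maps to both reading frames at
once; mt-ND6 positions are numbered along the light strand.
"""

from mtconserv import map_mtdna_position, parse_variant

for notation in ["m.10158T>C", "m.8528T>C", "m.14484T>C", "m.16100A>G"]:
    pos, ref, alt = parse_variant(notation)
    hits = map_mtdna_position(pos)
    if not hits:
        print(f"{notation}: outside the 13 protein-coding genes")
        continue
    where = ", ".join(
        f"{gene} codon {codon} (position {off + 1} in codon)"
        for gene, codon, off in hits
    )
    print(f"{notation}: {where}")

# Expected output:
#   m.10158T>C: mt-ND3 codon 34 (position 1 in codon)
#   m.8528T>C: mt-ATP8 codon 55 (...), mt-ATP6 codon 1 (...)
#       -> one nucleotide change, two proteins affected
#   m.14484T>C: mt-ND6 codon 64 -- light-strand gene, codons counted
#       from the highest rCRS coordinate
#   m.16100A>G: control-region position, no protein gene
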