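"""Encode alleles as 7-dimensional structural vectors (14 per genotype).

Run:  python examples/02_structure_features.py
"""

from pahpheno import (canonical_genotype, default_pah_exon_map, derive_aa_change,
                      encode_genotype_structure, encode_mutation_structure,
                      parse_hgvs_cdna)

xmap = default_pah_exon_map()
m = parse_hgvs_cdna("c.158G>A")
vec = encode_mutation_structure(m, xmap)
print(f"{m.label} -> {vec.round(4).tolist()}")
print("  [scaled position, ref-nt code, alt-nt code, ref-aa code,")
print("   alt-aa code, exon/intron index, variant-kind code]")

g = canonical_genotype(parse_hgvs_cdna("c.728G>A"), m)
print(f"\ngenotype {g.label}: vector length {len(encode_genotype_structure(g, xmap))}"
      " (two alleles, canonical order)")

# amino-acid consequence on a toy 30-nt coding sequence
cds = "ATGGCTCGTAAACTGGAACCGTTTATCTAA"
aa_ref, aa_alt, residue = derive_aa_change(parse_hgvs_cdna("c.8G>A"), cds)
print(f"\nc.8G>A on a toy CDS: residue {residue} changes {aa_ref} -> {aa_alt}")
print("(the mutated codon is translated; indels get frameshift sentinels)")
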