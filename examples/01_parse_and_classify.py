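"""Parse PAH cDNA variant labels, resolve their exons, classify Phe levels.

Run:  python examples/01_parse_and_classify.py
"""

from pahpheno import classify_phenotype, default_pah_exon_map, locate_region, parse_hgvs_cdna

xmap = default_pah_exon_map()

print("Variant parsing and exon/intron resolution:")
for label in ["c.728G>A", "c.158G>A", "c.208_210del", "c.442-1G>A"]:
    m = parse_hgvs_cdna(label)
    region = locate_region(m, xmap)
    where = f"exon {region}" if region > 0 else f"intron {-region}"
    print(f"  {label:>14}  kind={m.kind.value:<12} span={m.start}..{m.end}  -> {where}")

print()
print("Pretreatment blood Phe (umol/L) -> metabolic phenotype:")
for phe in [300.0, 800.0, 1500.0]:
    print(f"  {phe:7.1f} -> {classify_phenotype(phe).value}")
print("(cPKU above 1200, mPKU 600-1200, MHP 120-600; below 120 is rejected")
print(" as not hyperphenylalaninemia.)")
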