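"""Draw a synthetic PKU cohort and inspect its latent structure.

Run:  python examples/04_simulate_cohort.py
"""

from pahpheno import Phenotype, SimulationConfig, generate_cohort

cfg = SimulationConfig(n_patients=600, n_mutations=100,
                       phe_noise_sigma=0.1, seed=42)
db, truth = generate_cohort(cfg)

counts = db.class_counts()
print(f"{len(db)} patients over {len(db.mutation_index)} mutations:")
print("  " + "  ".join(f"{p.value}={counts[p]}" for p in Phenotype))

hubs = truth.true_hubs
print(f"designated hubs: cPKU={hubs.hub_cpku.label} "
      f"(severity {truth.severities[hubs.hub_cpku]:.2f}), "
      f"mPKU={hubs.hub_mpku.label} ({truth.severities[hubs.hub_mpku]:.2f}), "
      f"MHP={hubs.hub_mhp.label} ({truth.severities[hubs.hub_mhp]:.2f})")

rec = db.records[0]
s = truth.patient_severity[rec.patient_id]
print(f"\nexample patient {rec.patient_id}: {rec.genotype.label}")
print(f"  latent genotype severity {s:.3f} (the milder allele dominates),")
print(f"  Phe {rec.phe_pretreatment:.0f} umol/L -> {rec.phenotype.value}")
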