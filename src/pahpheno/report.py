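"""Human- and machine-readable prediction reports.

A report for one query genotype carries the predicted phenotype with its
normalised per-class probabilities, the matching genotypes already in
the training database ("supporting cases") with their phenotypes, and
per-class pretreatment-Phe statistics (max, min, mean) over those
supporting cases — the summary a genetic counsellor needs alongside the
bare prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from .cases import Genotype
from .classify import ModelBundle, predict_phenotype
from .phenotype import Phenotype

__all__ = ["PredictionReport", "build_prediction_report"]


@dataclass
class PredictionReport:
    genotype_label: str
    predicted: Phenotype
    probabilities: dict[Phenotype, float]
    supporting_cases: list[dict]           # patient_id, phenotype, phe_umol_l
    phe_stats: dict[Phenotype, dict]       # per class: n, max, min, mean

    def to_dict(self) -> dict:
        return {
            "genotype": self.genotype_label,
            "predicted_phenotype": self.predicted.value,
            "probabilities": {p.value: q for p, q in self.probabilities.items()},
            "supporting_cases": self.supporting_cases,
            "phe_stats": {p.value: s for p, s in self.phe_stats.items()},
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    def to_text(self) -> str:
        lines = [
            f"Genotype:  {self.genotype_label}",
            f"Predicted phenotype: {self.predicted.value}",
            "Probabilities: " + "  ".join(
                f"{p.value}={q:.3f}" for p, q in self.probabilities.items()),
        ]
        if self.supporting_cases:
            lines.append(f"Supporting cases in database: {len(self.supporting_cases)}")
            for phen, stats in self.phe_stats.items():
                lines.append(
                    f"  {phen.value}: n={stats['n']}  Phe max={stats['max']:g} "
                    f"min={stats['min']:g} mean={stats['mean']:g} µmol/L"
                )
        else:
            lines.append("Supporting cases in database: none")
        return "\n".join(lines)


def build_prediction_report(g: Genotype, bundle: ModelBundle,
                            strict: bool = True) -> PredictionReport:
    """Predict one genotype and assemble its full report from the bundle."""
    predicted, probs = predict_phenotype(g, bundle, strict=strict)
    supporting = [
        {"patient_id": rec.patient_id,
         "phenotype": rec.phenotype.value,
         "phe_umol_l": rec.phe_pretreatment}
        for rec in bundle.db.records if rec.genotype == g
    ]
    stats: dict[Phenotype, dict] = {}
    for phen in Phenotype:
        values = [c["phe_umol_l"] for c in supporting if c["phenotype"] == phen.value]
        if values:
            stats[phen] = {
                "n": len(values),
                "max": max(values),
                "min": min(values),
                "mean": sum(values) / len(values),
            }
    return PredictionReport(
        genotype_label=g.label,
        predicted=predicted,
        probabilities=probs,
        supporting_cases=supporting,
        phe_stats=stats,
    )
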