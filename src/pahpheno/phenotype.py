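"""PKU metabolic phenotype classes and the pretreatment-Phe thresholding rule.

Pretreatment blood phenylalanine (µmol/L) defines three phenotype classes:
classical PKU above 1200, mild PKU between 600 and 1200, and mild
hyperphenylalaninemia from 120 up to 600.  Values below 120 µmol/L are not
hyperphenylalaninemia at all and are rejected rather than silently binned.

Boundary convention (each value gets exactly one label):
mPKU is the closed interval [600, 1200], cPKU is (1200, ∞), MHP is [120, 600).
"""

from __future__ import annotations

from enum import Enum

__all__ = ["Phenotype", "classify_phenotype", "PheOutOfRangeError",
           "HPA_THRESHOLD", "MPKU_THRESHOLD", "CPKU_THRESHOLD", "SEVERITY_ORDER"]

HPA_THRESHOLD = 120.0   # µmol/L; below this is not hyperphenylalaninemia
MPKU_THRESHOLD = 600.0  # µmol/L; MHP/mPKU boundary
CPKU_THRESHOLD = 1200.0  # µmol/L; mPKU/cPKU boundary


class PheOutOfRangeError(ValueError):
    """Pretreatment Phe outside the hyperphenylalaninemia domain."""


class Phenotype(str, Enum):
    CPKU = "cPKU"
    MPKU = "mPKU"
    MHP = "MHP"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Most to least severe; used for tie-breaking in multiclass prediction.
SEVERITY_ORDER = (Phenotype.CPKU, Phenotype.MPKU, Phenotype.MHP)


def classify_phenotype(phe_umol_l: float) -> Phenotype:
    """Map a pretreatment blood Phe concentration to a phenotype class.

    Parameters
    ----------
    phe_umol_l
        Pretreatment blood phenylalanine in µmol/L; must be ≥ 120.

    Returns
    -------
    Phenotype
        cPKU if phe > 1200; mPKU if 600 ≤ phe ≤ 1200; MHP if 120 ≤ phe < 600.

    Raises
    ------
    PheOutOfRangeError
        If phe < 120 µmol/L (not hyperphenylalaninemia) or not finite/positive.
    """
    phe = float(phe_umol_l)
    if not phe >= HPA_THRESHOLD:
        raise PheOutOfRangeError(
            f"pretreatment Phe {phe!r} µmol/L is below the {HPA_THRESHOLD:g} µmol/L "
            "hyperphenylalaninemia threshold (or not a number)"
        )
    if phe > CPKU_THRESHOLD:
        return Phenotype.CPKU
    if phe >= MPKU_THRESHOLD:
        return Phenotype.MPKU
    return Phenotype.MHP
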