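"""Structural feature encoding: 7 real dimensions per mutation, 14 per genotype.

Each allele is summarised by the information a clinical geneticist reads
off the HGVS label: where on the coding sequence it falls, which
nucleotides change, which amino acids change, which exon or intron is
hit, and what class of event it is.  The concrete real-number codes are
a declared convention held in :class:`EncodingScheme` (serialisable to
YAML so a run can be reproduced bit-for-bit); the geometry of the codes
carries no meaning beyond injectivity.

Vector layout per mutation::

    [position/scale, ref-nt code, alt-nt code, ref-aa code, alt-aa code,
     region index, variant-kind code]

Genotype vectors concatenate the two allele vectors in canonical order
(7 + 7 = 14), so encoding is invariant to the input order of alleles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from Bio.Seq import Seq

from .cases import Genotype
from .hgvs import AA_FRAMESHIFT, AA_UNKNOWN, Mutation, VariantKind
from .regions import ExonMap, TranscriptRangeError, locate_region

logger = logging.getLogger(__name__)

__all__ = ["EncodingScheme", "default_scheme", "encode_mutation_structure",
           "encode_genotype_structure", "derive_aa_change", "annotate_aa_changes",
           "STRUCTURE_DIMS_PER_MUTATION"]

STRUCTURE_DIMS_PER_MUTATION = 7

_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def _default_nt_codes() -> dict[str, float]:
    return {"": 0.0, "A": 1.0, "C": 2.0, "G": 3.0, "T": 4.0}


def _default_aa_codes() -> dict[str, float]:
    codes = {aa: float(i + 1) for i, aa in enumerate(_AA_ALPHABET)}
    codes["*"] = 21.0            # stop codon
    codes[AA_UNKNOWN] = 0.0      # unresolved / non-coding
    codes[AA_FRAMESHIFT] = -1.0  # frameshifting or other indel consequence
    return codes


def _default_kind_codes() -> dict[str, float]:
    return {
        VariantKind.SUBSTITUTION.value: 1.0,
        VariantKind.DELETION.value: 2.0,
        VariantKind.INSERTION.value: 3.0,
        VariantKind.DUPLICATION.value: 4.0,
        VariantKind.DELINS.value: 5.0,
        VariantKind.OTHER.value: 6.0,
    }


@dataclass
class EncodingScheme:
    """Real-number codes for nucleotides, amino acids and variant kinds.

    ``position_scale`` divides the cDNA coordinate so position lives on a
    scale comparable with the categorical codes (default 1500 ≈ the PAH
    coding-sequence length).
    """

    nt_codes: dict[str, float] = field(default_factory=_default_nt_codes)
    aa_codes: dict[str, float] = field(default_factory=_default_aa_codes)
    kind_codes: dict[str, float] = field(default_factory=_default_kind_codes)
    position_scale: float = 1500.0

    def __post_init__(self) -> None:
        for name, codes in (("nt_codes", self.nt_codes),
                            ("aa_codes", self.aa_codes),
                            ("kind_codes", self.kind_codes)):
            if len(set(codes.values())) != len(codes):
                raise ValueError(f"{name} must be injective")
        if not self.position_scale > 0:
            raise ValueError("position_scale must be positive")

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "nt_codes": self.nt_codes,
            "aa_codes": self.aa_codes,
            "kind_codes": self.kind_codes,
            "position_scale": self.position_scale,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EncodingScheme":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            nt_codes={str(k): float(v) for k, v in payload["nt_codes"].items()},
            aa_codes={str(k): float(v) for k, v in payload["aa_codes"].items()},
            kind_codes={str(k): float(v) for k, v in payload["kind_codes"].items()},
            position_scale=float(payload["position_scale"]),
        )


def default_scheme() -> EncodingScheme:
    return EncodingScheme()


def derive_aa_change(m: Mutation, cds: str) -> tuple[str, str, int]:
    """Amino-acid consequence of an exonic variant on a coding sequence.

    For an exonic substitution, translates the reference and mutated codon
    and returns ``(aa_ref, aa_alt, protein_position)`` with a 1-based
    residue number.  Indels and delins return frameshift sentinels (in- or
    out-of-frame alike: the single-residue summary does not apply).

    Raises
    ------
    TranscriptRangeError
        If the variant position lies beyond the coding sequence.
    ValueError
        If the CDS length is not a multiple of 3.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    if m.is_intronic:
        return (AA_UNKNOWN, AA_UNKNOWN, 0)
    if m.kind is not VariantKind.SUBSTITUTION:
        codon_idx = (m.start - 1) // 3
        return (AA_FRAMESHIFT, AA_FRAMESHIFT, codon_idx + 1)
    if m.start > len(cds):
        raise TranscriptRangeError(
            f"{m.raw_label}: position {m.start} beyond CDS of length {len(cds)}"
        )
    codon_idx = (m.start - 1) // 3
    within = (m.start - 1) % 3
    codon = cds[codon_idx * 3: codon_idx * 3 + 3]
    if m.ref_allele and codon[within] != m.ref_allele:
        logger.warning(
            "%s: reference base %s disagrees with CDS base %s at c.%d",
            m.raw_label, m.ref_allele, codon[within], m.start,
        )
    mutated = codon[:within] + m.alt_allele + codon[within + 1:]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutated).translate())
    return (aa_ref, aa_alt, codon_idx + 1)


def annotate_aa_changes(mutations: list[Mutation], cds: str) -> list[Mutation]:
    """Attach amino-acid consequences to each mutation where derivable."""
    out = []
    for m in mutations:
        try:
            aa_ref, aa_alt, _ = derive_aa_change(m, cds)
        except TranscriptRangeError:
            aa_ref = aa_alt = AA_UNKNOWN
        out.append(m.with_aa(aa_ref, aa_alt))
    return out


def _aa_code(scheme: EncodingScheme, aa: str) -> float:
    if aa in scheme.aa_codes:
        return scheme.aa_codes[aa]
    logger.warning("amino-acid symbol %r not in scheme; using sentinel", aa)
    return scheme.aa_codes[AA_UNKNOWN]


def encode_mutation_structure(
    m: Mutation, xmap: ExonMap, scheme: EncodingScheme | None = None
) -> np.ndarray:
    """Encode one mutation as its 7-dimensional structural vector.

    Multi-base events use the first affected base for the nucleotide
    codes (fixed dimensionality); intronic or unresolved consequences use
    the amino-acid sentinel codes rather than failing.
    """
    scheme = scheme or default_scheme()
    region = locate_region(m, xmap)
    ref_nt = m.ref_allele[:1]
    alt_nt = m.alt_allele[:1]
    vec = np.array([
        m.start / scheme.position_scale,
        scheme.nt_codes.get(ref_nt, scheme.nt_codes[""]),
        scheme.nt_codes.get(alt_nt, scheme.nt_codes[""]),
        _aa_code(scheme, m.aa_ref),
        _aa_code(scheme, m.aa_alt),
        float(region),
        scheme.kind_codes[m.kind.value],
    ], dtype=float)
    assert vec.shape == (STRUCTURE_DIMS_PER_MUTATION,) and np.all(np.isfinite(vec))
    return vec


def encode_genotype_structure(
    g: Genotype, xmap: ExonMap, scheme: EncodingScheme | None = None
) -> np.ndarray:
    """Concatenate the two allele vectors in canonical order (14 dims)."""
    return np.concatenate([
        encode_mutation_structure(g.mut_a, xmap, scheme),
        encode_mutation_structure(g.mut_b, xmap, scheme),
    ])
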