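"""Parsing and formatting of PAH coding-DNA variants (HGVS ``c.`` notation).

The clinical literature reports PAH alleles as HGVS cDNA labels such as
``c.728G>A``, ``c.208_210del`` or ``c.442-1G>A``.  This module covers the
variant classes those cohorts actually contain — substitution, deletion,
duplication, insertion and deletion-insertion, with optional intronic
offsets — and refuses anything else loudly rather than misparsing it.

Coordinates are 1-based positions on the coding sequence; intronic bases
are expressed as an anchor coding position plus a signed offset
(``442-1`` → position 442, offset −1), exactly as HGVS writes them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum

__all__ = [
    "VariantKind",
    "Mutation",
    "HgvsParseError",
    "UnsupportedVariantError",
    "parse_hgvs_cdna",
    "format_hgvs",
]


class HgvsParseError(ValueError):
    """A cDNA variant label that could not be parsed."""


class UnsupportedVariantError(HgvsParseError):
    """A syntactically recognisable HGVS class that this package does not model."""


class VariantKind(str, Enum):
    SUBSTITUTION = "substitution"
    DELETION = "deletion"
    INSERTION = "insertion"
    DUPLICATION = "duplication"
    DELINS = "delins"
    OTHER = "other"


# Sentinel amino-acid annotations (see structure.EncodingScheme for codes).
AA_UNKNOWN = ""
AA_FRAMESHIFT = "fs"
AA_STOP = "*"


@dataclass(frozen=True)
class Mutation:
    """A single parsed PAH cDNA variant.

    ``start``/``end`` are 1-based coding coordinates (closed interval);
    ``start_offset``/``end_offset`` carry intronic offsets and are 0 for
    exonic positions.  ``region_index`` is +k for exon k, −k for intron k
    and 0 when unresolved; it is attached by :func:`pahpheno.regions.locate_region`.
    Identity (equality/hash) is the variant itself — coordinates, alleles
    and kind — not derived annotations.
    """

    raw_label: str
    start: int
    end: int
    ref_allele: str = ""
    alt_allele: str = ""
    kind: VariantKind = VariantKind.SUBSTITUTION
    start_offset: int = 0
    end_offset: int = 0
    region_index: int = field(default=0, compare=False)
    aa_ref: str = field(default=AA_UNKNOWN, compare=False)
    aa_alt: str = field(default=AA_UNKNOWN, compare=False)

    def __post_init__(self) -> None:
        if self.start < 1:
            raise HgvsParseError(f"coding coordinate must be >= 1, got {self.start}")
        if self.end < self.start:
            raise HgvsParseError(f"end {self.end} precedes start {self.start}")
        if self.kind is VariantKind.SUBSTITUTION and not (
            len(self.ref_allele) == 1 and len(self.alt_allele) == 1
        ):
            raise HgvsParseError(
                f"substitution requires single-base alleles, got "
                f"{self.ref_allele!r}>{self.alt_allele!r}"
            )

    def __eq__(self, other: object) -> bool:  # identity on the variant itself
        if not isinstance(other, Mutation):
            return NotImplemented
        return self._key() == other._key()

    def __hash__(self) -> int:
        return hash(self._key())

    def _key(self) -> tuple:
        return (
            self.start,
            self.start_offset,
            self.end,
            self.end_offset,
            self.ref_allele,
            self.alt_allele,
            self.kind.value,
        )

    @property
    def is_intronic(self) -> bool:
        return self.start_offset != 0 or self.end_offset != 0

    @property
    def label(self) -> str:
        return format_hgvs(self)

    def with_region(self, region_index: int) -> "Mutation":
        return replace(self, region_index=region_index)

    def with_aa(self, aa_ref: str, aa_alt: str) -> "Mutation":
        return replace(self, aa_ref=aa_ref, aa_alt=aa_alt)

    def sort_key(self) -> tuple:
        """Deterministic ordering used for canonical genotypes and hub ties."""
        return (self.start, self.start_offset, self.end, self.end_offset,
                self.alt_allele, self.raw_label)


_SUB = re.compile(r"c\.(\d+)([+-]\d+)?([ACGT])>([ACGT])$")
_DELINS = re.compile(r"c\.(\d+)([+-]\d+)?(?:_(\d+)([+-]\d+)?)?delins([ACGT]+)$")
_DELDUP = re.compile(r"c\.(\d+)([+-]\d+)?(?:_(\d+)([+-]\d+)?)?(del|dup)([ACGT]*)$")
_INS = re.compile(r"c\.(\d+)([+-]\d+)?_(\d+)([+-]\d+)?ins([ACGT]+)$")

# HGVS classes we recognise but deliberately do not model.
_UNSUPPORTED_TOKENS = ("inv", "con", "ext", "[", ";", "=", "(")


def _offset(tok: str | None) -> int:
    return int(tok) if tok else 0


def parse_hgvs_cdna(label: str) -> Mutation:
    """Parse one HGVS cDNA label into a :class:`Mutation`.

    Supports substitution (``c.728G>A``), deletion (``c.208_210del``,
    optionally with the deleted sequence), duplication, insertion
    (``c.47_48insT``) and delins.  Intronic offsets (``c.442-1G>A``)
    parse; exon/intron resolution is done later against an exon map.

    Raises
    ------
    UnsupportedVariantError
        For recognisable HGVS classes outside the modelled subset
        (inversions, alleles-in-cis, extensions, uncertain positions).
    HgvsParseError
        For anything else that is not valid input.
    """
    if not isinstance(label, str):
        raise HgvsParseError(f"expected a string label, got {type(label).__name__}")
    label = label.strip()
    if not label.startswith("c."):
        raise HgvsParseError(f"label must start with 'c.': {label!r}")

    m = _SUB.match(label)
    if m:
        pos, off, ref, alt = m.groups()
        return Mutation(
            raw_label=label, start=int(pos), end=int(pos),
            start_offset=_offset(off), end_offset=_offset(off),
            ref_allele=ref, alt_allele=alt, kind=VariantKind.SUBSTITUTION,
        )

    m = _INS.match(label)
    if m:
        s, soff, e, eoff, seq = m.groups()
        start, end = int(s), int(e)
        if _offset(soff) == 0 and _offset(eoff) == 0 and end != start + 1:
            raise HgvsParseError(
                f"insertion flanks must be adjacent positions: {label!r}"
            )
        return Mutation(
            raw_label=label, start=start, end=end,
            start_offset=_offset(soff), end_offset=_offset(eoff),
            ref_allele="", alt_allele=seq, kind=VariantKind.INSERTION,
        )

    m = _DELINS.match(label)
    if m:
        s, soff, e, eoff, seq = m.groups()
        start = int(s)
        end = int(e) if e else start
        return Mutation(
            raw_label=label, start=start, end=end,
            start_offset=_offset(soff), end_offset=_offset(eoff) if e else _offset(soff),
            ref_allele="", alt_allele=seq, kind=VariantKind.DELINS,
        )

    m = _DELDUP.match(label)
    if m:
        s, soff, e, eoff, op, seq = m.groups()
        start = int(s)
        if e:
            end = int(e)
            eo = _offset(eoff)
        else:
            end = start + max(len(seq), 1) - 1
            eo = _offset(soff)
        if seq and _offset(soff) == 0 and eo == 0 and len(seq) != end - start + 1:
            raise HgvsParseError(
                f"sequence length {len(seq)} does not match span "
                f"{start}_{end} in {label!r}"
            )
        kind = VariantKind.DELETION if op == "del" else VariantKind.DUPLICATION
        return Mutation(
            raw_label=label, start=start, end=end,
            start_offset=_offset(soff), end_offset=eo,
            ref_allele=seq, alt_allele="", kind=kind,
        )

    for tok in _UNSUPPORTED_TOKENS:
        if tok in label:
            raise UnsupportedVariantError(
                f"HGVS class containing {tok!r} is not supported: {label!r}"
            )
    raise HgvsParseError(f"could not parse cDNA label: {label!r}")


def _fmt_pos(pos: int, off: int) -> str:
    return f"{pos}{off:+d}" if off else str(pos)


def format_hgvs(m: Mutation) -> str:
    """Render a :class:`Mutation` back to a normalised HGVS cDNA label.

    ``parse_hgvs_cdna(format_hgvs(parse_hgvs_cdna(x)))`` equals
    ``parse_hgvs_cdna(x)`` for every supported label.
    """
    s = _fmt_pos(m.start, m.start_offset)
    e = _fmt_pos(m.end, m.end_offset)
    if m.kind is VariantKind.SUBSTITUTION:
        return f"c.{s}{m.ref_allele}>{m.alt_allele}"
    if m.kind is VariantKind.INSERTION:
        return f"c.{s}_{e}ins{m.alt_allele}"
    span = s if (m.end == m.start and m.end_offset == m.start_offset) else f"{s}_{e}"
    if m.kind is VariantKind.DELETION:
        return f"c.{span}del{m.ref_allele}"
    if m.kind is VariantKind.DUPLICATION:
        return f"c.{span}dup{m.ref_allele}"
    if m.kind is VariantKind.DELINS:
        return f"c.{span}delins{m.alt_allele}"
    raise HgvsParseError(f"cannot format variant kind {m.kind}")
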