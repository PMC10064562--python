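"""Exon/intron structure of the PAH coding sequence and region lookup.

The PAH gene has 13 exons; the bundled map gives each exon's span in
1-based coding (cDNA) coordinates, closed intervals.  Region indices are
signed: exon k → +k, intron k (between exons k and k+1) → −k, unknown → 0.
Users may supply their own map as a TSV with columns
``region_index, cdna_start, cdna_end``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .hgvs import Mutation

__all__ = ["ExonMap", "TranscriptRangeError", "default_pah_exon_map",
           "locate_region", "read_exon_map", "write_exon_map", "PAH_CDS_LENGTH"]

#: Length of the PAH coding sequence in nucleotides (452 residues + stop).
PAH_CDS_LENGTH = 1359

# Exon spans of the canonical 13-exon PAH transcript in coding coordinates.
# Consistent with the standard intron nomenclature (e.g. the c.442-1 splice
# acceptor lies in intron 4 because exon 5 starts at c.442).
_PAH_EXONS: tuple[tuple[int, int, int], ...] = (
    (1, 1, 60),
    (2, 61, 168),
    (3, 169, 352),
    (4, 353, 441),
    (5, 442, 509),
    (6, 510, 706),
    (7, 707, 842),
    (8, 843, 912),
    (9, 913, 969),
    (10, 970, 1065),
    (11, 1066, 1199),
    (12, 1200, 1315),
    (13, 1316, 1359),
)


class TranscriptRangeError(ValueError):
    """A coordinate beyond the transcript covered by the exon map."""


@dataclass(frozen=True)
class ExonMap:
    """Ordered exon spans in cDNA coordinates (1-based, closed)."""

    entries: tuple[tuple[int, int, int], ...]  # (region_index, start, end)

    def __post_init__(self) -> None:
        prev_end = 0
        for idx, start, end in self.entries:
            if idx <= 0:
                raise ValueError(f"exon map entries must have positive indices, got {idx}")
            if start <= prev_end or end < start:
                raise ValueError(
                    f"exon {idx} span [{start}, {end}] overlaps or is out of order"
                )
            prev_end = end

    @property
    def transcript_end(self) -> int:
        return self.entries[-1][2]

    def exon_containing(self, pos: int) -> int:
        """Exon index whose span contains the coding position ``pos``."""
        if pos < 1 or pos > self.transcript_end:
            raise TranscriptRangeError(
                f"coding position {pos} outside transcript [1, {self.transcript_end}]"
            )
        for idx, start, end in self.entries:
            if start <= pos <= end:
                return idx
        # Positions falling in a gap between listed exons should not occur
        # for a contiguous coding map; treat as unresolvable.
        raise TranscriptRangeError(f"coding position {pos} not covered by the exon map")


def default_pah_exon_map() -> ExonMap:
    """The bundled 13-exon PAH coding-coordinate map."""
    return ExonMap(entries=_PAH_EXONS)


def locate_region(m: Mutation, xmap: ExonMap) -> int:
    """Resolve a mutation's signed region index against an exon map.

    Exonic positions return +k for exon k.  Intronic positions use the
    standard nomenclature: a positive offset from the last base of exon k
    lies in intron k (−k); a negative offset from the first base of exon k
    lies in intron k−1 (−(k−1)).

    Raises
    ------
    TranscriptRangeError
        If the anchor coordinate lies beyond the transcript, or a negative
        offset is anchored on exon 1 (5' UTR, not an intron).
    """
    k = xmap.exon_containing(m.start)
    if m.start_offset == 0:
        return k
    if m.start_offset > 0:
        return -k
    if k == 1:
        raise TranscriptRangeError(
            f"{m.raw_label}: negative offset upstream of exon 1 is not intronic"
        )
    return -(k - 1)


def read_exon_map(path: str | Path) -> ExonMap:
    """Read an exon map TSV (columns region_index, cdna_start, cdna_end)."""
    df = pd.read_csv(path, sep="\t")
    required = {"region_index", "cdna_start", "cdna_end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"exon map {path} missing columns: {sorted(missing)}")
    entries = tuple(
        (int(r.region_index), int(r.cdna_start), int(r.cdna_end))
        for r in df.itertuples()
    )
    return ExonMap(entries=entries)


def write_exon_map(xmap: ExonMap, path: str | Path) -> None:
    df = pd.DataFrame(xmap.entries, columns=["region_index", "cdna_start", "cdna_end"])
    df.to_csv(path, sep="\t", index=False)
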