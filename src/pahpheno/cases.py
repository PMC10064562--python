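"""Allelic genotypes, patient case records and the tabular case database.

A case is one patient: two PAH alleles (compound heterozygous or
homozygous), a pretreatment blood Phe concentration, and the phenotype
class it implies.  The on-disk format is a delimited text table with a
header ``patient_id, mutation_1, mutation_2, phe_umol_l[, phenotype]``;
tab-separated is the canonical dialect and comma is accepted on read.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from .hgvs import HgvsParseError, Mutation, parse_hgvs_cdna
from .phenotype import Phenotype, PheOutOfRangeError, classify_phenotype

logger = logging.getLogger(__name__)

__all__ = ["Zygosity", "Genotype", "canonical_genotype", "CaseRecord",
           "CaseDatabase", "CaseTableError", "read_case_table", "write_case_table"]


class Zygosity(str, Enum):
    HOMOZYGOUS = "homozygous"
    COMPOUND_HETEROZYGOUS = "compound_heterozygous"


@dataclass(frozen=True)
class Genotype:
    """An unordered pair of PAH alleles stored in canonical order."""

    mut_a: Mutation
    mut_b: Mutation
    zygosity: Zygosity

    @property
    def label(self) -> str:
        return f"{self.mut_a.label}/{self.mut_b.label}"

    @property
    def mutations(self) -> tuple[Mutation, Mutation]:
        return (self.mut_a, self.mut_b)


def canonical_genotype(a: Mutation, b: Mutation) -> Genotype:
    """Build a genotype with a deterministic allele order.

    Alleles are sorted by (start, end, alt allele, label); the result is
    identical whichever order the alleles are given in, and homozygosity
    is detected by variant identity.
    """
    first, second = sorted((a, b), key=Mutation.sort_key)
    zyg = Zygosity.HOMOZYGOUS if a == b else Zygosity.COMPOUND_HETEROZYGOUS
    return Genotype(mut_a=first, mut_b=second, zygosity=zyg)


@dataclass(frozen=True)
class CaseRecord:
    patient_id: str
    genotype: Genotype
    phe_pretreatment: float  # µmol/L
    phenotype: Phenotype

    def __post_init__(self) -> None:
        if not self.phe_pretreatment > 0:
            raise ValueError(f"{self.patient_id}: Phe must be positive")


@dataclass
class CaseDatabase:
    """An ordered collection of case records plus the observed allele set."""

    records: list[CaseRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def mutation_index(self) -> list[Mutation]:
        """Distinct mutations across all records, in canonical order."""
        seen: dict[Mutation, None] = {}
        for rec in self.records:
            for m in rec.genotype.mutations:
                seen.setdefault(m, None)
        return sorted(seen, key=Mutation.sort_key)

    def class_counts(self) -> dict[Phenotype, int]:
        counts = {p: 0 for p in Phenotype}
        for rec in self.records:
            counts[rec.phenotype] += 1
        return counts

    def validate(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CaseTableError(f"duplicate patient ids: {dupes[:5]}")


class CaseTableError(ValueError):
    """A case table that failed validation; carries per-row diagnostics."""

    def __init__(self, message: str, row_errors: list[tuple[int, str]] | None = None):
        super().__init__(message)
        self.row_errors = row_errors or []


_REQUIRED_COLUMNS = ("patient_id", "mutation_1", "mutation_2", "phe_umol_l")


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_case_table(path: str | Path, strict: bool = True) -> CaseDatabase:
    """Read a patient case table into a :class:`CaseDatabase`.

    Every row either parses or is reported with its line number.  In
    strict mode any bad row aborts the read; in lenient mode bad rows
    (unparseable mutations, Phe below the 120 µmol/L hyperphenylalaninemia
    threshold, phenotype labels inconsistent with the Phe value, duplicate
    patient ids) are skipped with a logged reason.  A missing phenotype
    column is derived from Phe.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        first = fh.readline()
        if not first:
            raise CaseTableError(f"{path}: empty file")
        delim = _sniff_delimiter(first)
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        cols = [c.strip() for c in (reader.fieldnames or [])]
        missing = [c for c in _REQUIRED_COLUMNS if c not in cols]
        if missing:
            raise CaseTableError(f"{path}: missing required columns {missing}")
        has_phenotype = "phenotype" in cols

        records: list[CaseRecord] = []
        seen_ids: set[str] = set()
        errors: list[tuple[int, str]] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                pid = (row["patient_id"] or "").strip()
                if not pid:
                    raise CaseTableError("empty patient_id")
                if pid in seen_ids:
                    raise CaseTableError(f"duplicate patient_id {pid!r}")
                mut_a = parse_hgvs_cdna(row["mutation_1"].strip())
                mut_b = parse_hgvs_cdna(row["mutation_2"].strip())
                phe = float(row["phe_umol_l"])
                derived = classify_phenotype(phe)
                if has_phenotype and (row.get("phenotype") or "").strip():
                    supplied = Phenotype((row["phenotype"]).strip())
                    if supplied is not derived:
                        raise CaseTableError(
                            f"supplied phenotype {supplied.value} contradicts "
                            f"Phe {phe:g} µmol/L (implies {derived.value})"
                        )
                records.append(
                    CaseRecord(
                        patient_id=pid,
                        genotype=canonical_genotype(mut_a, mut_b),
                        phe_pretreatment=phe,
                        phenotype=derived,
                    )
                )
                seen_ids.add(pid)
            except (HgvsParseError, PheOutOfRangeError, CaseTableError,
                    ValueError, KeyError) as exc:
                errors.append((lineno, str(exc)))
                if strict:
                    raise CaseTableError(
                        f"{path}:{lineno}: {exc}", row_errors=errors
                    ) from exc
                logger.warning("%s:%d skipped: %s", path, lineno, exc)

    db = CaseDatabase(records=records)
    db.validate()
    if errors and not strict:
        logger.info("%s: %d rows skipped in lenient mode", path, len(errors))
    return db


def write_case_table(db: CaseDatabase, path: str | Path) -> None:
    """Write a case database as canonical TSV (UTF-8, header included)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow([*_REQUIRED_COLUMNS, "phenotype"])
        for rec in db.records:
            writer.writerow([
                rec.patient_id,
                rec.genotype.mut_a.label,
                rec.genotype.mut_b.label,
                f"{rec.phe_pretreatment:g}",
                rec.phenotype.value,
            ])
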