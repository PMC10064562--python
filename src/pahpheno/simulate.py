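"""Synthetic PKU cohort generation.

Real PAH cohorts have three statistical signatures this generator
reproduces: (i) a hub-dominated allele spectrum — a few mutations
(c.728G>A-like) account for a large share of alleles, here a Zipf
frequency law; (ii) a bimodal allele-severity structure — most alleles
are either near-null (severe) or retain residual enzyme activity (mild),
here a two-component Beta mixture on a latent severity s ∈ [0, 1]; and
(iii) milder-allele dominance — the residual activity of the milder
allele sets the metabolic outcome, so genotype severity is
min(s_a, s_b) and one mild allele forces the MHP phenotype.  Pretreatment
Phe is a monotone map of genotype severity times mean-preserving
lognormal noise, truncated at the 120 µmol/L hyperphenylalaninemia floor,
and the phenotype label follows the standard thresholds.

Ground truth (per-allele severities, latent patient severities, the
designated hub mutation per phenotype) is returned alongside every
cohort so recovery tests can score the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cases import CaseDatabase, CaseRecord, canonical_genotype
from .graph import HubSet
from .hgvs import Mutation, parse_hgvs_cdna
from .phenotype import (CPKU_THRESHOLD, HPA_THRESHOLD, MPKU_THRESHOLD,
                        Phenotype, classify_phenotype)
from .regions import PAH_CDS_LENGTH

__all__ = ["SimulationConfig", "GroundTruth", "SimulationError",
           "generate_cohort", "generate_labelled_cohort",
           "generate_worked_fixture"]


class SimulationError(RuntimeError):
    """A simulation configuration that cannot produce a usable cohort."""


@dataclass
class SimulationConfig:
    """Knobs of the cohort generator; the defaults emulate a national
    newborn-screening PKU cohort (~1300 patients, ~235 distinct alleles,
    roughly half classical PKU).

    severity mixture: allele severity ~ w·Beta(a_sev) + (1−w)·Beta(a_mild);
    allele frequency: P(rank r) ∝ r^(−zipf_exponent);
    Phe map: mean Phe = phe_floor + phe_span · s^phe_gamma (µmol/L);
    noise: multiplicative lognormal with sigma phe_noise_sigma,
    mean-preserving, truncated below at 120 µmol/L.
    """

    n_patients: int = 1291
    n_mutations: int = 235
    severe_weight: float = 0.7
    severe_beta: tuple[float, float] = (8.0, 2.0)
    mild_beta: tuple[float, float] = (2.0, 8.0)
    zipf_exponent: float = 1.2
    #: Severity ranges pinned to the three most frequent alleles
    #: (severe, intermediate, mild), mirroring the hub structure of real
    #: cohorts; set to None to leave all severities to the mixture.
    hub_severity_ranges: tuple[tuple[float, float], ...] | None = (
        (0.70, 0.95), (0.40, 0.52), (0.05, 0.20))
    phe_floor: float = 120.0
    phe_span: float = 2880.0
    phe_gamma: float = 1.5
    phe_noise_sigma: float = 0.25
    seed: int = 0
    max_attempts: int = 20

    def validate(self) -> None:
        if self.n_patients < 10:
            raise SimulationError("need at least 10 patients")
        if not 5 <= self.n_mutations <= PAH_CDS_LENGTH:
            raise SimulationError(
                f"n_mutations must lie in [5, {PAH_CDS_LENGTH}]")
        if not 0.0 <= self.severe_weight <= 1.0:
            raise SimulationError("severe_weight must lie in [0, 1]")
        if self.phe_noise_sigma < 0 or self.zipf_exponent < 0:
            raise SimulationError("noise sigma and Zipf exponent must be >= 0")
        if self.phe_span <= 0 or self.phe_gamma <= 0:
            raise SimulationError("the Phe map must be monotone increasing")


@dataclass
class GroundTruth:
    """Latent quantities behind a generated cohort."""

    severities: dict[Mutation, float]
    patient_severity: dict[str, float]
    noise_free_phenotype: dict[str, Phenotype]
    true_hubs: HubSet
    allele_probs: np.ndarray = field(repr=False, default=None)


def _mutation_pool(n: int, rng: np.random.Generator) -> list[Mutation]:
    """n distinct synthetic substitutions spread over the PAH CDS."""
    positions = rng.choice(np.arange(1, PAH_CDS_LENGTH + 1), size=n, replace=False)
    bases = "ACGT"
    pool = []
    for pos in positions:
        ref = bases[int(pos) % 4]
        alt = bases[(int(pos) + 1 + int(rng.integers(0, 3))) % 4]
        if alt == ref:  # pragma: no cover - arithmetic above avoids this
            alt = bases[(bases.index(ref) + 1) % 4]
        pool.append(parse_hgvs_cdna(f"c.{int(pos)}{ref}>{alt}"))
    return pool


def _mean_phe(cfg: SimulationConfig, severity: float) -> float:
    return cfg.phe_floor + cfg.phe_span * severity ** cfg.phe_gamma


def generate_cohort(cfg: SimulationConfig) -> tuple[CaseDatabase, GroundTruth]:
    """Draw one synthetic cohort; fully determined by ``cfg.seed``.

    Raises :class:`SimulationError` if, after a bounded number of
    attempts, some phenotype class remains unpopulated (infeasible
    noise/severity settings).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    for _ in range(cfg.max_attempts):
        pool = _mutation_pool(cfg.n_mutations, rng)
        ranks = np.arange(1, cfg.n_mutations + 1, dtype=float)
        probs = ranks ** -cfg.zipf_exponent
        probs /= probs.sum()

        is_severe = rng.random(cfg.n_mutations) < cfg.severe_weight
        sev = np.where(
            is_severe,
            rng.beta(*cfg.severe_beta, size=cfg.n_mutations),
            rng.beta(*cfg.mild_beta, size=cfg.n_mutations),
        )
        if cfg.hub_severity_ranges:
            # Frequency ranks 1..len(ranges) get designated severities.
            for rank, (lo, hi) in enumerate(cfg.hub_severity_ranges):
                if rank < cfg.n_mutations:
                    sev[rank] = rng.uniform(lo, hi)
        severities = {m: float(s) for m, s in zip(pool, sev)}

        allele_idx = rng.choice(cfg.n_mutations, size=(cfg.n_patients, 2), p=probs)
        noise = np.exp(
            cfg.phe_noise_sigma * rng.standard_normal(cfg.n_patients)
            - 0.5 * cfg.phe_noise_sigma ** 2
        )

        records, patient_sev, nf_label = [], {}, {}
        for i in range(cfg.n_patients):
            a, b = pool[allele_idx[i, 0]], pool[allele_idx[i, 1]]
            s = min(severities[a], severities[b])  # milder allele dominates
            mean = _mean_phe(cfg, s)
            phe = max(HPA_THRESHOLD, mean * noise[i])
            pid = f"S{i + 1:05d}"
            records.append(CaseRecord(
                patient_id=pid,
                genotype=canonical_genotype(a, b),
                phe_pretreatment=float(phe),
                phenotype=classify_phenotype(phe),
            ))
            patient_sev[pid] = s
            nf_label[pid] = classify_phenotype(max(HPA_THRESHOLD, mean))

        db = CaseDatabase(records=records)
        counts = db.class_counts()
        if all(counts[p] > 0 for p in Phenotype):
            truth = GroundTruth(
                severities=severities,
                patient_severity=patient_sev,
                noise_free_phenotype=nf_label,
                true_hubs=_true_hubs(db, nf_label),
                allele_probs=probs,
            )
            return db, truth
    raise SimulationError(
        f"no cohort with all three classes populated after "
        f"{cfg.max_attempts} attempts; config is infeasible"
    )


def _true_hubs(db: CaseDatabase, nf_label: dict[str, Phenotype]) -> HubSet:
    """Designated hub per class: the mutation carried by the most patients
    whose noise-free phenotype is that class (ties → canonical order)."""
    counts: dict[Phenotype, dict[Mutation, int]] = {p: {} for p in Phenotype}
    for rec in db.records:
        label = nf_label.get(rec.patient_id, rec.phenotype)
        for m in set(rec.genotype.mutations):
            counts[label][m] = counts[label].get(m, 0) + 1
    chosen = {}
    for phen in Phenotype:
        tally = counts[phen] or {
            m: sum(1 for r in db.records
                   if r.phenotype is phen and m in r.genotype.mutations)
            for m in db.mutation_index
        }
        best = max(tally.values())
        chosen[phen] = min(
            (m for m, c in tally.items() if c == best), key=Mutation.sort_key)
    return HubSet(hub_cpku=chosen[Phenotype.CPKU],
                  hub_mpku=chosen[Phenotype.MPKU],
                  hub_mhp=chosen[Phenotype.MHP])


def generate_labelled_cohort(
    class_counts: dict[Phenotype, int],
    n_mutations: int = 235,
    zipf_exponent: float = 1.2,
    seed: int = 0,
) -> CaseDatabase:
    """A cohort with an exact phenotype histogram.

    Genotypes are drawn from the Zipf allele law; each patient's Phe is
    drawn uniformly inside the target class's interval, so the class
    histogram is exact by construction.  Used for count identities and
    pipeline plumbing, not for signal-recovery experiments (Phe is
    independent of genotype here).
    """
    rng = np.random.default_rng(seed)
    pool = _mutation_pool(n_mutations, rng)
    ranks = np.arange(1, n_mutations + 1, dtype=float)
    probs = ranks ** -zipf_exponent
    probs /= probs.sum()
    intervals = {
        Phenotype.CPKU: (CPKU_THRESHOLD + 50.0, 2.0 * CPKU_THRESHOLD),
        Phenotype.MPKU: (MPKU_THRESHOLD, CPKU_THRESHOLD),
        Phenotype.MHP: (HPA_THRESHOLD, MPKU_THRESHOLD - 1.0),
    }
    records = []
    i = 0
    for phen in Phenotype:
        lo, hi = intervals[phen]
        for _ in range(class_counts.get(phen, 0)):
            a, b = rng.choice(n_mutations, size=2, p=probs)
            phe = float(rng.uniform(lo, hi))
            i += 1
            records.append(CaseRecord(
                patient_id=f"L{i:05d}",
                genotype=canonical_genotype(pool[int(a)], pool[int(b)]),
                phe_pretreatment=phe,
                phenotype=classify_phenotype(phe),
            ))
    return CaseDatabase(records=records)


# ---------------------------------------------------------------------------
# the worked miniature cohort

# 41 hand-designed patients over the 17 PAH mutation labels most frequent
# in Chinese PKU cohorts.  Constructed so that phenotype-weighted-degree
# hub identification returns (c.728G>A for cPKU, c.721C>T for mPKU,
# c.158G>A for MHP), the network is a single connected component, and one
# mild allele (c.158G>A) always yields MHP.
_WORKED_ROWS: tuple[tuple[str, str, str, float], ...] = (
    ("C01", "c.728G>A", "c.611A>G", 1520.0),
    ("C02", "c.728G>A", "c.611A>G", 1610.0),
    ("C03", "c.728G>A", "c.611A>G", 1450.0),
    ("C04", "c.728G>A", "c.1068C>A", 1710.0),
    ("C05", "c.728G>A", "c.1068C>A", 1380.0),
    ("C06", "c.728G>A", "c.1068C>A", 1995.0),
    ("C07", "c.728G>A", "c.1197A>T", 1530.0),
    ("C08", "c.728G>A", "c.1197A>T", 1640.0),
    ("C09", "c.728G>A", "c.740G>A", 1815.0),
    ("C10", "c.728G>A", "c.740G>A", 1475.0),
    ("C11", "c.728G>A", "c.782G>A", 1560.0),
    ("C12", "c.728G>A", "c.782G>A", 1925.0),
    ("C13", "c.728G>A", "c.728G>A", 2100.0),
    ("C14", "c.728G>A", "c.728G>A", 1760.0),
    ("C15", "c.611A>G", "c.1068C>A", 1490.0),
    ("C16", "c.611A>G", "c.1068C>A", 1585.0),
    ("C17", "c.1197A>T", "c.1301C>A", 1430.0),
    ("M01", "c.721C>T", "c.728G>A", 830.0),
    ("M02", "c.721C>T", "c.728G>A", 905.0),
    ("M03", "c.721C>T", "c.728G>A", 760.0),
    ("M04", "c.721C>T", "c.611A>G", 880.0),
    ("M05", "c.721C>T", "c.611A>G", 940.0),
    ("M06", "c.721C>T", "c.1068C>A", 700.0),
    ("M07", "c.721C>T", "c.1068C>A", 1010.0),
    ("M08", "c.721C>T", "c.740G>A", 655.0),
    ("M09", "c.611A>G", "c.740G>A", 985.0),
    ("H01", "c.158G>A", "c.728G>A", 310.0),
    ("H02", "c.158G>A", "c.728G>A", 365.0),
    ("H03", "c.158G>A", "c.721C>T", 280.0),
    ("H04", "c.158G>A", "c.721C>T", 455.0),
    ("H05", "c.158G>A", "c.611A>G", 390.0),
    ("H06", "c.158G>A", "c.194T>C", 245.0),
    ("H07", "c.158G>A", "c.208_210del", 505.0),
    ("H08", "c.158G>A", "c.301G>A", 330.0),
    ("H09", "c.158G>A", "c.320A>G", 415.0),
    ("H10", "c.158G>A", "c.311C>T", 290.0),
    ("H11", "c.158G>A", "c.526C>T", 350.0),
    ("H12", "c.158G>A", "c.1174T>A", 480.0),
    ("H13", "c.158G>A", "c.1238G>C", 265.0),
    ("H14", "c.158G>A", "c.1301C>A", 440.0),
    ("H15", "c.721C>T", "c.721C>T", 520.0),
)


def generate_worked_fixture() -> CaseDatabase:
    """The fixed miniature cohort used throughout the examples and tests."""
    records = [
        CaseRecord(
            patient_id=pid,
            genotype=canonical_genotype(parse_hgvs_cdna(m1), parse_hgvs_cdna(m2)),
            phe_pretreatment=phe,
            phenotype=classify_phenotype(phe),
        )
        for pid, m1, m2, phe in _WORKED_ROWS
    ]
    return CaseDatabase(records=records)
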