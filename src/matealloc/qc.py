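"""Genotype quality control and trait construction.

SNP filters are applied in the order call rate -> minor allele frequency ->
Hardy-Weinberg equilibrium, attributing each removed SNP to the first
criterion it fails. The HWE test is a Pearson chi-square with 1 df on the
observed versus HWE-expected genotype counts among non-missing calls (no
continuity correction). Animals are filtered on their own call rate, and
offspring showing an excess of Mendelian conflicts with their genotyped
parents are flagged for removal.

Trait construction covers the standard adjustments of growth and backfat to
a 100 kg live weight and the per-litter average piglet birth weight.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .genotypes import GenotypeMatrix, PedigreeTable

__all__ = [
    "QcReport",
    "RawPerformanceRecord",
    "filter_snps",
    "filter_animals",
    "mendelian_check",
    "intersect_panels",
    "adjust_age",
    "adjust_bd",
    "compute_apwl",
    "run_qc",
]


@dataclass
class QcReport:
    n_snps_in: int = 0
    n_removed_callrate: int = 0
    n_removed_maf: int = 0
    n_removed_hwe: int = 0
    n_animals_removed: int = 0
    n_mendelian_removed: int = 0
    n_snps_out: int = 0
    snps_removed_callrate: list = dataclasses.field(default_factory=list)
    snps_removed_maf: list = dataclasses.field(default_factory=list)
    snps_removed_hwe: list = dataclasses.field(default_factory=list)
    animals_removed_callrate: list = dataclasses.field(default_factory=list)
    animals_removed_mendelian: list = dataclasses.field(default_factory=list)

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class RawPerformanceRecord:
    """One raw test-station record (growth/backfat) or litter record."""

    animal_id: str
    sex: str  # "male" | "female"
    age_test: float | None = None
    w_test: float | None = None
    age_batch: float | None = None
    w_batch: float | None = None
    bd_six_site: tuple[float, ...] | None = None
    litter_piglet_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")


def hwe_pvalue(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Pearson 1-df chi-square test of Hardy-Weinberg proportions."""
    n = n_AA + n_Aa + n_aa
    if n == 0:
        return 1.0
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1.0 - p
    expected = np.array([p * p, 2 * p * q, q * q]) * n
    observed = np.array([n_AA, n_Aa, n_aa], dtype=float)
    mask = expected > 0
    if np.any(~mask & (observed > 0)):
        return 0.0  # observed genotypes that are impossible under HWE
    stat = float(np.sum((observed[mask] - expected[mask]) ** 2 / expected[mask]))
    return float(chi2.sf(stat, df=1))


def filter_snps(
    geno: GenotypeMatrix,
    callrate_min: float = 0.98,
    maf_min: float = 0.05,
    hwe_alpha: float = 0.05,
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove SNPs failing call rate, then MAF, then HWE."""
    if geno.n_snps == 0:
        raise ValueError("empty genotype matrix")
    report = QcReport(n_snps_in=geno.n_snps)

    call = geno.snp_call_rates()
    fail_call = call < callrate_min

    p = geno.observed_freqs()
    maf = np.minimum(p, 1.0 - p)
    fail_maf = (maf < maf_min) & ~fail_call

    fail_hwe = np.zeros(geno.n_snps, dtype=bool)
    candidates = np.flatnonzero(~fail_call & ~fail_maf)
    for j in candidates:
        col = geno.counts[:, j]
        n_AA = int(np.sum(col == 2.0))
        n_Aa = int(np.sum(col == 1.0))
        n_aa = int(np.sum(col == 0.0))
        if hwe_pvalue(n_AA, n_Aa, n_aa) < hwe_alpha:
            fail_hwe[j] = True

    snp_ids = np.asarray(geno.snp_ids)
    report.n_removed_callrate = int(fail_call.sum())
    report.n_removed_maf = int(fail_maf.sum())
    report.n_removed_hwe = int(fail_hwe.sum())
    report.snps_removed_callrate = snp_ids[fail_call].tolist()
    report.snps_removed_maf = snp_ids[fail_maf].tolist()
    report.snps_removed_hwe = snp_ids[fail_hwe].tolist()
    keep = ~(fail_call | fail_maf | fail_hwe)
    report.n_snps_out = int(keep.sum())
    return geno.subset(snps=keep), report


def filter_animals(geno: GenotypeMatrix, callrate_min: float = 0.98) -> GenotypeMatrix:
    """Drop animals whose genotype call rate is below the threshold."""
    keep = geno.animal_call_rates() >= callrate_min
    return geno.subset(animals=keep)


def mendelian_check(
    geno: GenotypeMatrix,
    ped: PedigreeTable,
    conflict_rate_max: float = 0.02,
) -> list[str]:
    """Offspring whose conflict rate with genotyped parents is too high.

    A conflict is a locus where the offspring and a genotyped parent are
    opposite homozygotes, or where the offspring is homozygous for an allele
    carried by neither genotyped parent. Offspring with no genotyped parent
    are skipped. The rate denominator is the number of loci where the
    offspring and at least one parent are both called.
    """
    index = {a: i for i, a in enumerate(geno.animal_ids)}
    flagged = []
    for animal, sire, dam in ped.table.itertuples(index=False):
        if animal not in index:
            continue
        child = geno.counts[index[animal]]
        parent_rows = [geno.counts[index[p]] for p in (sire, dam) if p in index]
        if not parent_rows:
            continue
        child_called = ~np.isnan(child)
        conflict = np.zeros(geno.n_snps, dtype=bool)
        co_typed = np.zeros(geno.n_snps, dtype=bool)
        for par in parent_rows:
            both = child_called & ~np.isnan(par)
            co_typed |= both
            conflict |= both & (np.abs(child - par) == 2.0)
        if len(parent_rows) == 2:
            s, d = parent_rows
            both = child_called & ~np.isnan(s) & ~np.isnan(d)
            # homozygous child for an allele absent in both parents
            conflict |= both & (child == 2.0) & (s == 0.0) & (d == 0.0)
            conflict |= both & (child == 0.0) & (s == 2.0) & (d == 2.0)
        n_co = int(co_typed.sum())
        if n_co and conflict.sum() / n_co > conflict_rate_max:
            flagged.append(animal)
    return flagged


def intersect_panels(geno1: GenotypeMatrix, geno2: GenotypeMatrix) -> GenotypeMatrix:
    """Keep SNPs common to both panels (by id) and concatenate animals."""
    common = [s for s in geno1.snp_ids if s in set(geno2.snp_ids)]
    if not common:
        raise ValueError("panels share no SNPs")
    overlap = set(geno1.animal_ids) & set(geno2.animal_ids)
    if overlap:
        raise ValueError(f"animals present on both panels: {sorted(overlap)[:5]}")
    idx1 = [geno1.snp_ids.index(s) for s in common]
    idx2 = [geno2.snp_ids.index(s) for s in common]
    counts = np.vstack([geno1.counts[:, idx1], geno2.counts[:, idx2]])
    return GenotypeMatrix(counts, geno1.animal_ids + geno2.animal_ids, common)


# ---------------------------------------------------------------------------
# trait construction
# ---------------------------------------------------------------------------

_AGE_R = {"male": 1.05, "female": 1.125}
_BD_R = {"male": 0.1, "female": 0.12}


def adjust_age(rec: RawPerformanceRecord) -> float:
    """Age at 100 kg: age_test + [r - 0.0077 w_batch + 0.0047 age_batch] (100 - w_test)."""
    for fld in ("age_test", "w_test", "age_batch", "w_batch"):
        if getattr(rec, fld) is None:
            raise ValueError(f"record {rec.animal_id}: missing {fld}")
    if rec.w_test <= 0 or rec.w_batch <= 0:
        raise ValueError(f"record {rec.animal_id}: weights must be positive")
    r = _AGE_R[rec.sex]
    return rec.age_test + (r - 0.0077 * rec.w_batch + 0.0047 * rec.age_batch) * (
        100.0 - rec.w_test
    )


def adjust_bd(rec: RawPerformanceRecord) -> float:
    """Backfat at 100 kg: mean of the six ultrasonic depths + r (100 - w_test)."""
    if rec.bd_six_site is None or len(rec.bd_six_site) != 6:
        raise ValueError(f"record {rec.animal_id}: six backfat measures required")
    if rec.w_test is None or rec.w_test <= 0:
        raise ValueError(f"record {rec.animal_id}: positive w_test required")
    return float(np.mean(rec.bd_six_site)) + _BD_R[rec.sex] * (100.0 - rec.w_test)


def compute_apwl(litter_piglet_weights) -> float:
    """Average piglet birth weight within one litter (one record per litter)."""
    weights = list(litter_piglet_weights)
    if not weights:
        raise ValueError("empty litter: APWL undefined")
    return float(np.mean(weights))


# ---------------------------------------------------------------------------
# composite
# ---------------------------------------------------------------------------

def run_qc(
    geno: GenotypeMatrix,
    ped: PedigreeTable | None = None,
    callrate_min_snp: float = 0.98,
    callrate_min_animal: float = 0.98,
    maf_min: float = 0.05,
    hwe_alpha: float = 0.05,
    conflict_rate_max: float = 0.02,
) -> tuple[GenotypeMatrix, QcReport]:
    """Full QC: animal call rate -> Mendelian removal -> SNP filters.

    Flagged Mendelian-inconsistent offspring are removed whole (not single
    genotypes). Allele frequencies for the SNP filters, and the frequencies
    frozen on the returned matrix, are computed after the animal removals.
    """
    before = set(geno.animal_ids)
    geno1 = filter_animals(geno, callrate_min_animal)
    dropped_callrate = sorted(before - set(geno1.animal_ids))

    flagged: set[str] = set()
    if ped is not None:
        flagged = set(mendelian_check(geno1, ped, conflict_rate_max))
        if flagged:
            keep = [a not in flagged for a in geno1.animal_ids]
            geno1 = geno1.subset(animals=np.array(keep, dtype=bool))

    geno2, report = filter_snps(geno1, callrate_min_snp, maf_min, hwe_alpha)
    report.n_animals_removed = len(dropped_callrate)
    report.n_mendelian_removed = len(flagged)
    report.animals_removed_callrate = dropped_callrate
    report.animals_removed_mendelian = sorted(flagged)
    geno2.freeze_freqs()
    return geno2, report
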