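"""Synthetic family-structured pig data with additive and dominance effects.

The generator emulates the statistical structure the analysis assumes: a
founder population of boars and sows in Hardy-Weinberg equilibrium at
independent loci, full-sib litters from random boar x sow matings, and
phenotypes built from per-SNP additive and dominance effects whose variances
reproduce requested animal-level components. Directional dominance (and
hence inbreeding depression) is induced through the mean of the dominance
effects, mu_d = -b/m, not through an explicit homozygosity covariate, so
recovering b from the fitted models is a genuine test.

All randomness derives from one master seed through named substreams, so the
founder genotypes do not change when, say, the number of phenotype records
does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from ._rng import substream
from .genotypes import GenotypeMatrix, PedigreeTable
from .markerfx import genetic_to_marker_variance, substitution_effects
from .relmat import build_M, build_W

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_founder_genotypes",
    "simulate_matings_and_offspring",
    "simulate_effects_and_phenotypes",
    "make_qc_fixture",
]


class SimConfig(BaseModel):
    """Study-condition parameters for one simulated dataset.

    Variances are on the trait scale (units^2); ``inb_depression_b`` is the
    phenotypic change per unit increase in genomic homozygosity.
    """

    n_boars: int = Field(default=100, gt=0)
    n_sows: int = Field(default=300, gt=0)
    litters_per_sow: int = Field(default=1, gt=0)
    piglets_per_litter: int = Field(default=10, gt=0)
    m_snps: int = Field(default=500, ge=0)
    maf_range: tuple[float, float] = (0.05, 0.5)
    sigma2_A: float = Field(default=16.26, ge=0.0)
    sigma2_D: float = Field(default=3.31, ge=0.0)
    sigma2_pe: float = Field(default=0.0, ge=0.0)
    sigma2_e: float = Field(default=42.80, ge=0.0)
    inb_depression_b: float = 42.9
    n_fixed_levels: int = Field(default=20, gt=0)
    sigma2_fixed: float = Field(default=5.0, ge=0.0)
    repeated_records: bool = False
    n_records_per_animal: int = Field(default=3, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check_maf(self) -> "SimConfig":
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        return self


@dataclass
class SimTruth:
    """True effects and components behind one simulated phenotype set."""

    true_a: np.ndarray
    true_d: np.ndarray
    true_components: dict[str, float]
    true_u: pd.Series
    true_v: pd.Series
    fixed_level_values: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def as_dict(self) -> dict:
        return {
            "true_a": self.true_a.tolist(),
            "true_d": self.true_d.tolist(),
            "true_components": self.true_components,
            "true_u": {k: float(v) for k, v in self.true_u.items()},
            "true_v": {k: float(v) for k, v in self.true_v.items()},
        }


def simulate_founder_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Unrelated founders in Hardy-Weinberg equilibrium.

    Per SNP the allele-A frequency is uniform in ``maf_range`` and genotypes
    are ``Binomial(2, p_k)``; boars come first (ids ``B0001``...), then sows
    (``S0001``...). No missing calls.
    """
    rng = substream(cfg.seed, "founders")
    n = cfg.n_boars + cfg.n_sows
    p = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.m_snps)
    counts = rng.binomial(2, p, size=(n, cfg.m_snps)).astype(float)
    ids = [f"B{i + 1:04d}" for i in range(cfg.n_boars)] + [
        f"S{i + 1:04d}" for i in range(cfg.n_sows)
    ]
    return GenotypeMatrix(counts, ids, [f"snp{k + 1:05d}" for k in range(cfg.m_snps)])


def simulate_matings_and_offspring(
    parents: GenotypeMatrix, cfg: SimConfig
) -> tuple[GenotypeMatrix, PedigreeTable]:
    """One generation of random boar x sow litters.

    Every sow produces ``litters_per_sow`` litters, each sired by a boar
    drawn uniformly at random, with ``piglets_per_litter`` full sibs. Each
    offspring genotype is the sum of one gamete per parent; the transmitted
    allele at a locus is drawn uniformly from the parent's two alleles and
    loci segregate independently.
    """
    if parents.n_animals == 0:
        raise ValueError("parents must be non-empty")
    rng = substream(cfg.seed, "matings")
    boars = [a for a in parents.animal_ids if a.startswith("B")]
    sows = [a for a in parents.animal_ids if a.startswith("S")]
    if not boars or not sows:
        # fall back: first half are sires, second half dams
        half = parents.n_animals // 2
        boars = parents.animal_ids[:half]
        sows = parents.animal_ids[half:]
    rows = {a: i for i, a in enumerate(parents.animal_ids)}

    records = []
    sire_rows = []
    dam_rows = []
    child_ids = []
    child = 0
    for sow in sows:
        for _ in range(cfg.litters_per_sow):
            boar = boars[rng.integers(len(boars))]
            for _ in range(cfg.piglets_per_litter):
                child += 1
                cid = f"P{child:05d}"
                child_ids.append(cid)
                records.append((cid, boar, sow))
                sire_rows.append(rows[boar])
                dam_rows.append(rows[sow])

    tau_s = parents.counts[sire_rows] / 2.0
    tau_d = parents.counts[dam_rows] / 2.0
    gam_s = rng.random(tau_s.shape) < tau_s
    gam_d = rng.random(tau_d.shape) < tau_d
    counts = (gam_s.astype(float) + gam_d.astype(float))
    geno = GenotypeMatrix(counts, child_ids, list(parents.snp_ids))
    ped = PedigreeTable(pd.DataFrame(records, columns=["animal", "sire", "dam"]))
    return geno, ped


def simulate_effects_and_phenotypes(
    geno: GenotypeMatrix, cfg: SimConfig
) -> tuple[pd.DataFrame, SimTruth]:
    """Draw SNP effects and build phenotypes for the given animals.

    Per-SNP effects are ``a_k ~ N(0, sigma_a^2)`` and
    ``d_k = mu_d + delta_k`` with ``delta_k ~ N(0, sigma_d^2)`` re-centred so
    the realised mean of ``d`` is exactly ``mu_d = -b/m``. The marker
    variances invert the animal-level components at the frequencies frozen on
    ``geno``. The genotypic value of an animal is ``sum_k [a, d, -a]`` picked
    by its genotype; phenotypes add a categorical fixed effect, optionally a
    permanent-environment effect with repeated records, and a residual.
    """
    if np.isnan(geno.counts).any():
        raise ValueError("phenotype simulation requires complete genotypes")
    m = geno.n_snps
    if cfg.sigma2_D > 0 and m == 0:
        raise ValueError("cannot place dominance variance on zero SNPs")

    p = geno.p
    rng_fx = substream(cfg.seed, "effects")
    if m > 0:
        sigma2_a, sigma2_d = genetic_to_marker_variance(cfg.sigma2_A, cfg.sigma2_D, p)
        a = rng_fx.normal(0.0, np.sqrt(sigma2_a), size=m) if sigma2_a > 0 else np.zeros(m)
        mu_d = -cfg.inb_depression_b / m
        if sigma2_d > 0:
            delta = rng_fx.normal(0.0, np.sqrt(sigma2_d), size=m)
            delta -= delta.mean()
        else:
            delta = np.zeros(m)
        d = mu_d + delta
    else:
        a = np.zeros(0)
        d = np.zeros(0)

    c = geno.counts
    g_val = (c == 2.0) @ a + (c == 1.0) @ d - (c == 0.0) @ a

    alpha = substitution_effects(a, d, p)
    true_u = pd.Series(build_M(geno) @ alpha, index=geno.animal_ids)
    true_v = pd.Series(build_W(geno) @ d, index=geno.animal_ids)

    rng_ph = substream(cfg.seed, "phenotypes")
    n = geno.n_animals
    level_values = rng_ph.normal(0.0, np.sqrt(cfg.sigma2_fixed), size=cfg.n_fixed_levels)
    levels = rng_ph.integers(cfg.n_fixed_levels, size=n)
    pe = (
        rng_ph.normal(0.0, np.sqrt(cfg.sigma2_pe), size=n)
        if cfg.repeated_records and cfg.sigma2_pe > 0
        else np.zeros(n)
    )
    n_rec = cfg.n_records_per_animal if cfg.repeated_records else 1

    rows = []
    for r in range(n_rec):
        e = rng_ph.normal(0.0, np.sqrt(cfg.sigma2_e), size=n)
        y = level_values[levels] + g_val + pe + e
        rows.append(
            pd.DataFrame(
                {
                    "animal": geno.animal_ids,
                    "record_index": r,
                    "batch": [f"L{lv + 1:02d}" for lv in levels],
                    "y": y,
                }
            )
        )
    pheno = pd.concat(rows, ignore_index=True)

    truth = SimTruth(
        true_a=a,
        true_d=d,
        true_components={
            "sigma2_A": cfg.sigma2_A,
            "sigma2_D": cfg.sigma2_D,
            "sigma2_pe": cfg.sigma2_pe if cfg.repeated_records else 0.0,
            "sigma2_e": cfg.sigma2_e,
            "b": cfg.inb_depression_b,
        },
        true_u=true_u,
        true_v=true_v,
        fixed_level_values=level_values,
    )
    return pheno, truth


# ---------------------------------------------------------------------------
# QC fixture with planted violations
# ---------------------------------------------------------------------------

def make_qc_fixture(
    seed: int,
    n_animals: int = 100,
    m_clean: int = 400,
    k_callrate_snps: int = 5,
    k_maf_snps: int = 4,
    k_hwe_snps: int = 3,
    k_callrate_animals: int = 3,
    k_mendel_offspring: int = 3,
) -> tuple[GenotypeMatrix, PedigreeTable, dict]:
    """Genotype set with known quality-control violations planted.

    The planted counts are exact for the pipeline order animal-filter ->
    Mendelian check -> SNP filters (and, by construction, the SNP-level
    plants also hold on the unfiltered matrix). Returns
    ``(genotypes, pedigree, planted)`` where ``planted`` maps violation type
    to the planted ids.
    """
    rng = substream(seed, "qc-fixture")
    snp_specs = []  # (id, kind)
    counts_cols = []

    def hwe_column(p: float, n: int) -> np.ndarray:
        n_aa = int(round((1 - p) ** 2 * n))
        n_AA = int(round(p**2 * n))
        n_het = n - n_aa - n_AA
        col = np.array([2.0] * n_AA + [1.0] * n_het + [0.0] * n_aa)
        rng.shuffle(col)
        return col

    m_total = m_clean + k_callrate_snps + k_maf_snps + k_hwe_snps
    kinds = (
        ["clean"] * m_clean
        + ["callrate"] * k_callrate_snps
        + ["maf"] * k_maf_snps
        + ["hwe"] * k_hwe_snps
    )
    for j, kind in enumerate(kinds):
        sid = f"snp{j + 1:05d}"
        if kind == "clean" or kind == "callrate":
            col = hwe_column(rng.uniform(0.2, 0.45), n_animals)
        elif kind == "maf":
            col = np.array([1.0] * 4 + [0.0] * (n_animals - 4))
            rng.shuffle(col)
        else:  # hwe: all homozygous, half and half
            col = np.array([2.0] * (n_animals // 2) + [0.0] * (n_animals - n_animals // 2))
            rng.shuffle(col)
        counts_cols.append(col)
        snp_specs.append((sid, kind))

    counts = np.column_stack(counts_cols)
    founder_ids = [f"F{i + 1:04d}" for i in range(n_animals)]

    # Mendelian-conflict offspring plus two clean offspring
    ped_rows = []
    extra_rows = []
    extra_ids = []
    n_off = k_mendel_offspring + 2
    for j in range(n_off):
        sire, dam = founder_ids[2 * j], founder_ids[2 * j + 1]
        s_row = counts[2 * j]
        d_row = counts[2 * j + 1]
        gam_s = (rng.random(m_total) < s_row / 2.0).astype(float)
        gam_d = (rng.random(m_total) < d_row / 2.0).astype(float)
        child = gam_s + gam_d
        cid = f"O{j + 1:04d}"
        if j < k_mendel_offspring:
            # plant opposite-homozygote conflicts at 10% of loci where a parent
            # is homozygous
            hom = np.flatnonzero((s_row == 2.0) | (s_row == 0.0))
            n_conf = max(1, int(0.10 * m_total))
            conf = rng.choice(hom, size=min(n_conf, hom.size), replace=False)
            child[conf] = 2.0 - counts[2 * j][conf]  # opposite homozygote to sire
        extra_rows.append(child)
        extra_ids.append(cid)
        ped_rows.append((cid, sire, dam))

    all_counts = np.vstack([counts, np.array(extra_rows)])
    all_ids = founder_ids + extra_ids
    n_total = len(all_ids)

    # low-call-rate animals: 3% of SNPs missing, disjoint clean-SNP sets, all
    # distinct from the planted low-call-rate SNP columns
    clean_idx = [j for j, (_, kind) in enumerate(snp_specs) if kind == "clean"]
    bad_animals = founder_ids[-k_callrate_animals:] if k_callrate_animals else []
    n_miss = int(np.ceil(0.03 * m_total))
    pool = rng.permutation(clean_idx)
    for t, aid in enumerate(bad_animals):
        i = all_ids.index(aid)
        cols = pool[t * n_miss:(t + 1) * n_miss]
        all_counts[i, cols] = np.nan

    # low-call-rate SNPs: missing in >2% of the animals that survive the
    # animal filters, one missing call per surviving animal
    survivors = [
        i for i, aid in enumerate(all_ids)
        if aid not in bad_animals and not (aid.startswith("O") and int(aid[1:]) <= k_mendel_offspring)
    ]
    n_surv = len(survivors)
    n_miss_animals = int(np.floor(0.02 * n_surv)) + 2
    callrate_snps = [j for j, (_, kind) in enumerate(snp_specs) if kind == "callrate"]
    for j in callrate_snps:
        hit = rng.choice(survivors, size=n_miss_animals, replace=False)
        all_counts[hit, j] = np.nan

    geno = GenotypeMatrix(all_counts, all_ids, [sid for sid, _ in snp_specs])
    ped = PedigreeTable(pd.DataFrame(ped_rows, columns=["animal", "sire", "dam"]))
    planted = {
        "callrate_snps": [sid for sid, kind in snp_specs if kind == "callrate"],
        "maf_snps": [sid for sid, kind in snp_specs if kind == "maf"],
        "hwe_snps": [sid for sid, kind in snp_specs if kind == "hwe"],
        "callrate_animals": bad_animals,
        "mendel_offspring": extra_ids[:k_mendel_offspring],
    }
    return geno, ped, planted
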