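"""SNP-level additive and dominance effects (SNP-BLUP) and GEBVs.

The marker model is the genotypic-coding ridge model

    y = X beta + f b + K a + T d* + Z pe + e,

where ``K`` codes genotypes AA/Aa/aa as 1/0/-1 and ``T`` as 0/1/0, with
``a ~ N(0, I sigma_a^2)`` and ``d* ~ N(0, I sigma_d^2)``. The marker
variances come from the animal-level components through

    sigma_d^2 = sigma_D^2 / sum (2 p q)^2
    sigma_a^2 = [sigma_A^2 - sum 2 p q (q - p)^2 sigma_d^2] / sum 2 p q

Directional dominance is folded into the genomic-inbreeding covariate f, so
``d*`` is centred; the raw dominance effects are recovered as
``d = d* - b / m`` and the allele substitution effect is
``alpha = a + d (q - p)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .genotypes import GenotypeMatrix
from .relmat import additive_denominator, dominance_denominator, genomic_inbreeding

__all__ = [
    "MarkerEffects",
    "genetic_to_marker_variance",
    "marker_to_genetic_variance",
    "build_K",
    "build_T",
    "solve_snp_blup",
    "recover_dominance",
    "substitution_effects",
    "gebv",
]


@dataclass
class MarkerEffects:
    """Per-SNP effect estimates plus the inbreeding-depression coefficient."""

    snp_ids: list[str]
    a: np.ndarray
    d_star: np.ndarray
    b_hat: float
    p: np.ndarray
    sigma2_a: float
    sigma2_d: float

    def __post_init__(self) -> None:
        m = len(self.snp_ids)
        for name in ("a", "d_star", "p"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (m,):
                raise ValueError(f"{name} must have one entry per SNP")
            setattr(self, name, arr)

    @property
    def m(self) -> int:
        return len(self.snp_ids)

    @property
    def d(self) -> np.ndarray:
        return recover_dominance(self.d_star, self.b_hat, self.m)

    @property
    def alpha(self) -> np.ndarray:
        return substitution_effects(self.a, self.d, self.p)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"snp_id": self.snp_ids, "a": self.a, "d_star": self.d_star,
             "d": self.d, "alpha": self.alpha, "p": self.p}
        )


# ---------------------------------------------------------------------------
# variance conversions
# ---------------------------------------------------------------------------

def genetic_to_marker_variance(
    sigma2_A: float, sigma2_D: float, p: np.ndarray
) -> tuple[float, float]:
    """Animal-level (sigma_A^2, sigma_D^2) -> marker-level (sigma_a^2, sigma_d^2)."""
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    sum2pq = additive_denominator(p)
    sum2pq2 = dominance_denominator(p)
    if sum2pq <= 0:
        raise ZeroDivisionError("sum 2pq is zero: all SNPs monomorphic")
    sigma2_d = sigma2_D / sum2pq2 if sigma2_D > 0 else 0.0
    cross = float(np.sum(2.0 * p * q * (q - p) ** 2)) * sigma2_d
    sigma2_a = (sigma2_A - cross) / sum2pq
    if sigma2_a < 0:
        raise ValueError(
            "negative additive marker variance: sigma_D^2 too large relative to "
            f"sigma_A^2 given the frequencies (cross term {cross:.4g} > {sigma2_A:.4g})"
        )
    return sigma2_a, sigma2_d


def marker_to_genetic_variance(
    sigma2_a: float, sigma2_d: float, p: np.ndarray
) -> tuple[float, float]:
    """Inverse map, used by the simulator to set per-SNP effect variances."""
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    sigma2_D = sigma2_d * dominance_denominator(p)
    sigma2_A = sigma2_a * additive_denominator(p) + float(
        np.sum(2.0 * p * q * (q - p) ** 2)
    ) * sigma2_d
    return sigma2_A, sigma2_D


# ---------------------------------------------------------------------------
# designs
# ---------------------------------------------------------------------------

def build_K(geno: GenotypeMatrix) -> np.ndarray:
    """Genotypic additive coding 1/0/-1 for AA/Aa/aa.

    Missing calls take the population-average coding p^2 - q^2 = p - q so
    that they are neutral at the average genotype.
    """
    c = geno.counts
    K = c - 1.0
    pmq = geno.p - geno.q
    return np.where(np.isnan(K), np.broadcast_to(pmq, K.shape), K)


def build_T(geno: GenotypeMatrix) -> np.ndarray:
    """Heterozygosity coding 0/1/0; missing -> HWE mean 2pq."""
    c = geno.counts
    T = np.where(c == 1.0, 1.0, 0.0)
    two_pq = 2.0 * geno.p * geno.q
    return np.where(np.isnan(c), np.broadcast_to(two_pq, c.shape), T)


# ---------------------------------------------------------------------------
# the marker mixed model
# ---------------------------------------------------------------------------

def solve_snp_blup(
    y: np.ndarray,
    X: np.ndarray,
    geno: GenotypeMatrix,
    sigma2_a: float,
    sigma2_d: float,
    sigma2_e: float,
    record_animals: list[str] | None = None,
    sigma2_pe: float = 0.0,
    include_f: bool = True,
) -> MarkerEffects:
    """Solve the ridge MME for additive and dominance marker effects.

    ``X`` holds the fixed effects *without* the genomic-inbreeding covariate,
    which is appended internally (set ``include_f=False`` to omit it, e.g.
    for purely additive toy problems). ``record_animals`` maps phenotype rows
    to genotyped animals; by default records are the genotype rows in order.
    ``sigma2_pe > 0`` adds an animal permanent-environment term for
    repeated-record traits.
    """
    if geno.n_snps == 0:
        raise ValueError("no SNPs to estimate effects for")
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]

    if record_animals is None:
        rows = np.arange(geno.n_animals)
        record_animals = list(geno.animal_ids)
    else:
        rows = geno.rows_for(record_animals)

    Kfull = build_K(geno)
    Tfull = build_T(geno)
    K = Kfull[rows]
    T = Tfull[rows]

    if include_f:
        f = genomic_inbreeding(geno).f[rows]
        X = np.hstack([X, f[:, None]])
    p_fix = X.shape[1]

    m = geno.n_snps
    blocks = [X, K]
    lambdas = [np.zeros(p_fix)]
    if sigma2_a <= 0:
        raise ValueError("sigma2_a must be positive")
    lambdas.append(np.full(m, sigma2_e / sigma2_a))
    use_dom = sigma2_d > 0
    if use_dom:
        blocks.append(T)
        lambdas.append(np.full(m, sigma2_e / sigma2_d))
    use_pe = sigma2_pe > 0
    if use_pe:
        ids = sorted(set(record_animals))
        index = {a: i for i, a in enumerate(ids)}
        Zpe = np.zeros((len(y), len(ids)))
        for r, a in enumerate(record_animals):
            Zpe[r, index[str(a)]] = 1.0
        blocks.append(Zpe)
        lambdas.append(np.full(len(ids), sigma2_e / sigma2_pe))

    W = np.hstack(blocks)
    C = W.T @ W
    C[np.diag_indices_from(C)] += np.concatenate(lambdas)
    sol = cho_solve(cho_factor(C, lower=True), W.T @ y)

    a = sol[p_fix:p_fix + m]
    d_star = sol[p_fix + m:p_fix + 2 * m] if use_dom else np.zeros(m)
    b_hat = float(sol[p_fix - 1]) if include_f else 0.0

    return MarkerEffects(
        snp_ids=list(geno.snp_ids),
        a=a,
        d_star=d_star,
        b_hat=b_hat,
        p=geno.p.copy(),
        sigma2_a=sigma2_a,
        sigma2_d=sigma2_d if use_dom else 0.0,
    )


def recover_dominance(d_star: np.ndarray, b_hat: float, m: int) -> np.ndarray:
    """Undo the centring of dominance effects: ``d = d* - b/m``."""
    if m <= 0:
        raise ValueError("m must be positive")
    return np.asarray(d_star, dtype=float) - b_hat / m


def substitution_effects(a: np.ndarray, d: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Allele substitution effects ``alpha = a + d (q - p)``."""
    a = np.asarray(a, dtype=float)
    d = np.asarray(d, dtype=float)
    p = np.asarray(p, dtype=float)
    return a + d * (1.0 - 2.0 * p)


def gebv(geno: GenotypeMatrix, alpha: np.ndarray, p: np.ndarray | None = None) -> pd.Series:
    """Genomic estimated breeding values ``sum_k (count - 2 p) alpha``.

    Uses the centred coding so GEBVs are deviations from the population mean;
    missing calls contribute zero (mean substitution). Centring shifts every
    animal by the same constant, so rankings and allocations are unaffected
    by this choice.
    """
    alpha = np.asarray(alpha, dtype=float)
    p = geno.p if p is None else np.asarray(p, dtype=float)
    M = geno.counts - 2.0 * p
    M = np.where(np.isnan(M), 0.0, M)
    return pd.Series(M @ alpha, index=geno.animal_ids)
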