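"""Pedigree and genomic relationship matrices, blending, genomic inbreeding.

The additive genomic matrix is the standard centered-gene-content form,
``G = MM' / (2 * sum_k p_k q_k)`` with coding ``(2 - 2p, 1 - 2p, -2p)`` for
genotypes AA/Aa/aa, and the dominance matrix uses the breeding-value
(statistical) parameterisation of dominance deviations,
``D = WW' / sum_k (2 p_k q_k)^2`` with coding ``(-2q^2, 2pq, -2p^2)``.
Missing calls contribute the population-average coding, i.e. zero. Allele
frequencies are the *frozen* frequencies carried on the GenotypeMatrix, so
every matrix built from the same post-QC data uses the same p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import GenotypeMatrix, PedigreeTable, UNKNOWN_PARENT

__all__ = [
    "RelationshipMatrix",
    "InbreedingVector",
    "build_M",
    "build_W",
    "build_G",
    "build_D",
    "blend",
    "genomic_inbreeding",
    "build_A",
]


@dataclass
class RelationshipMatrix:
    """Symmetric relationship matrix with its animal index."""

    kind: str  # A, G, D, G_blend, D_blend
    animal_ids: list[str]
    values: np.ndarray
    blend_weight: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.animal_ids)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")

    def submatrix(self, animal_ids: list[str]) -> np.ndarray:
        index = {a: i for i, a in enumerate(self.animal_ids)}
        idx = np.array([index[str(a)] for a in animal_ids])
        return self.values[np.ix_(idx, idx)]


@dataclass
class InbreedingVector:
    """Per-animal genomic inbreeding: the proportion of homozygous calls."""

    animal_ids: list[str]
    f: np.ndarray

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if self.f.shape != (len(self.animal_ids),):
            raise ValueError("inbreeding vector length mismatch")
        if ((self.f < 0) | (self.f > 1)).any():
            raise ValueError("inbreeding coefficients must lie in [0, 1]")

    def for_animals(self, animal_ids: list[str]) -> np.ndarray:
        index = {a: i for i, a in enumerate(self.animal_ids)}
        return self.f[[index[str(a)] for a in animal_ids]]


# ---------------------------------------------------------------------------
# marker designs
# ---------------------------------------------------------------------------

def build_M(geno: GenotypeMatrix) -> np.ndarray:
    """Centered additive design: counts minus 2p, missing -> 0."""
    p = geno.p
    if p.shape != (geno.n_snps,):
        raise ValueError("allele frequencies unavailable")
    M = geno.counts - 2.0 * p
    return np.where(np.isnan(M), 0.0, M)


def build_W(geno: GenotypeMatrix) -> np.ndarray:
    """Dominance-deviation design: (-2q^2, 2pq, -2p^2) for AA/Aa/aa; missing -> 0."""
    p = geno.p
    q = 1.0 - p
    c = geno.counts
    W = np.select(
        [c == 2.0, c == 1.0, c == 0.0],
        [np.broadcast_to(-2.0 * q * q, c.shape), np.broadcast_to(2.0 * p * q, c.shape),
         np.broadcast_to(-2.0 * p * p, c.shape)],
        default=0.0,
    )
    return W


def _scaled_cross(design: np.ndarray, denom: float, what: str) -> np.ndarray:
    if denom <= 0.0:
        raise ZeroDivisionError(
            f"cannot scale {what}: all SNPs are monomorphic (denominator 0)"
        )
    return design @ design.T / denom


def additive_denominator(p: np.ndarray) -> float:
    return float(2.0 * np.sum(p * (1.0 - p)))


def dominance_denominator(p: np.ndarray) -> float:
    return float(np.sum((2.0 * p * (1.0 - p)) ** 2))


def build_G(geno: GenotypeMatrix) -> RelationshipMatrix:
    """VanRaden additive genomic relationship matrix."""
    G = _scaled_cross(build_M(geno), additive_denominator(geno.p), "G")
    return RelationshipMatrix("G", list(geno.animal_ids), G)


def build_D(geno: GenotypeMatrix) -> RelationshipMatrix:
    """Dominance genomic relationship matrix (breeding-value parameterisation)."""
    D = _scaled_cross(build_W(geno), dominance_denominator(geno.p), "D")
    return RelationshipMatrix("D", list(geno.animal_ids), D)


def blend(K: RelationshipMatrix, w: float = 0.95) -> RelationshipMatrix:
    """Shrink toward the identity: ``w K + (1 - w) I`` (numerical stability)."""
    if not 0.0 <= w <= 1.0:
        raise ValueError("blend weight must be in [0, 1]")
    values = w * K.values + (1.0 - w) * np.eye(len(K.animal_ids))
    kind = K.kind if w == 1.0 else f"{K.kind.split('_')[0]}_blend"
    return RelationshipMatrix(kind, list(K.animal_ids), values, blend_weight=w)


def genomic_inbreeding(geno: GenotypeMatrix) -> InbreedingVector:
    """Proportion of homozygous genotypes among an animal's non-missing calls."""
    called = ~np.isnan(geno.counts)
    n_called = called.sum(axis=1)
    if (n_called == 0).any():
        bad = [geno.animal_ids[i] for i in np.flatnonzero(n_called == 0)]
        raise ValueError(f"animals with no genotype calls: {bad[:5]}")
    hom = ((geno.counts == 0.0) | (geno.counts == 2.0)).sum(axis=1)
    return InbreedingVector(list(geno.animal_ids), hom / n_called)


# ---------------------------------------------------------------------------
# pedigree numerator relationship matrix
# ---------------------------------------------------------------------------

def build_A(ped: PedigreeTable) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    Unknown parents are treated as unrelated, non-inbred founders; inbreeding
    of descendants emerges from the recursion itself.
    """
    order = ped.topological_order()
    pos = {a: i for i, a in enumerate(order)}
    parents = {a: (s, d) for a, s, d in ped.table.itertuples(index=False)}
    n = len(order)
    A = np.zeros((n, n))
    for i, animal in enumerate(order):
        s, d = parents.get(animal, (UNKNOWN_PARENT, UNKNOWN_PARENT))
        si = pos[s] if s != UNKNOWN_PARENT else None
        di = pos[d] if d != UNKNOWN_PARENT else None
        a_sd = A[si, di] if si is not None and di is not None else 0.0
        A[i, i] = 1.0 + 0.5 * a_sd
        row = np.zeros(i)
        if si is not None:
            row += 0.5 * A[si, :i]
        if di is not None:
            row += 0.5 * A[di, :i]
        A[i, :i] = row
        A[:i, i] = row
    return RelationshipMatrix("A", order, A)
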