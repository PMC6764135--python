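"""Core data containers: SNP genotype matrix and pedigree table.

Genotypes are stored as allele-A counts (0, 1, 2) with ``numpy.nan`` marking
missing calls. Allele frequencies are computed once from the observed calls
and then *frozen* on the container, so that every downstream consumer (the
relationship matrices, the marker-effect model, the mating predictions) uses
the same frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "PedigreeTable"]

UNKNOWN_PARENT = "0"


@dataclass
class GenotypeMatrix:
    """Animals x SNPs matrix of allele-A counts with missing values.

    Parameters
    ----------
    counts
        ``(n, m)`` float array with entries in ``{0, 1, 2, nan}``.
    animal_ids, snp_ids
        Row and column labels, unique.
    p
        Optional frozen per-SNP frequency of allele A. When absent it is
        computed from the observed (non-missing) calls on first access and
        cached; quality control freezes it explicitly post-filtering.
    """

    counts: np.ndarray
    animal_ids: list[str]
    snp_ids: list[str]
    _p: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.animal_ids = [str(a) for a in self.animal_ids]
        self.snp_ids = [str(s) for s in self.snp_ids]
        n, m = self.counts.shape
        if n != len(self.animal_ids) or m != len(self.snp_ids):
            raise ValueError("counts shape inconsistent with id lists")
        if len(set(self.animal_ids)) != n:
            raise ValueError("duplicate animal ids")
        if len(set(self.snp_ids)) != m:
            raise ValueError("duplicate SNP ids")
        ok = np.isnan(self.counts) | np.isin(self.counts, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("genotype counts must be 0, 1, 2 or missing")
        if self._p is not None:
            self._p = np.asarray(self._p, dtype=float)

    # -- dimensions ---------------------------------------------------------
    @property
    def n_animals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_snps(self) -> int:
        return self.counts.shape[1]

    # -- allele frequencies -------------------------------------------------
    def observed_freqs(self) -> np.ndarray:
        """Per-SNP frequency of allele A among non-missing calls.

        A SNP with no observed calls gets frequency 0 (it is monomorphic for
        all practical purposes and is dropped by QC).
        """
        called = ~np.isnan(self.counts)
        n_called = called.sum(axis=0)
        total = np.nansum(self.counts, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_called > 0, total / (2.0 * np.maximum(n_called, 1)), 0.0)
        return p

    @property
    def p(self) -> np.ndarray:
        if self._p is None:
            self._p = self.observed_freqs()
        return self._p

    @property
    def q(self) -> np.ndarray:
        return 1.0 - self.p

    def freeze_freqs(self, p: np.ndarray | None = None) -> "GenotypeMatrix":
        """Freeze allele frequencies (defaults to the observed ones)."""
        self._p = self.observed_freqs() if p is None else np.asarray(p, float)
        if self._p.shape != (self.n_snps,):
            raise ValueError("frequency vector length mismatch")
        return self

    # -- call rates ---------------------------------------------------------
    def snp_call_rates(self) -> np.ndarray:
        return 1.0 - np.isnan(self.counts).mean(axis=0)

    def animal_call_rates(self) -> np.ndarray:
        return 1.0 - np.isnan(self.counts).mean(axis=1)

    # -- subsetting ---------------------------------------------------------
    def subset(
        self,
        animals: np.ndarray | list | None = None,
        snps: np.ndarray | list | None = None,
        keep_freqs: bool = False,
    ) -> "GenotypeMatrix":
        """Return a copy restricted to the given animal/SNP index arrays.

        ``keep_freqs`` carries the frozen frequencies over to the subset
        (QC wants fresh frequencies; the mating stage wants the frozen ones).
        """
        a_idx = np.arange(self.n_animals) if animals is None else np.asarray(animals)
        if a_idx.dtype == bool:
            a_idx = np.flatnonzero(a_idx)
        s_idx = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        if s_idx.dtype == bool:
            s_idx = np.flatnonzero(s_idx)
        sub = GenotypeMatrix(
            self.counts[np.ix_(a_idx, s_idx)],
            [self.animal_ids[i] for i in a_idx],
            [self.snp_ids[j] for j in s_idx],
        )
        if keep_freqs and self._p is not None:
            sub.freeze_freqs(self._p[s_idx])
        return sub

    def rows_for(self, animal_ids: list[str]) -> np.ndarray:
        index = {a: i for i, a in enumerate(self.animal_ids)}
        try:
            return np.array([index[str(a)] for a in animal_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message clarity only
            raise KeyError(f"animal {exc} not genotyped") from exc

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.animal_ids, columns=self.snp_ids)


@dataclass
class PedigreeTable:
    """Animal / sire / dam triplets; ``"0"`` marks an unknown parent."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"animal", "sire", "dam"}
        if not required.issubset(self.table.columns):
            raise ValueError("pedigree needs animal, sire, dam columns")
        self.table = self.table[["animal", "sire", "dam"]].astype(str).reset_index(drop=True)
        if self.table["animal"].duplicated().any():
            dup = self.table.loc[self.table["animal"].duplicated(), "animal"].iloc[0]
            raise ValueError(f"animal {dup!r} appears twice in the pedigree")

    @property
    def animals(self) -> list[str]:
        return self.table["animal"].tolist()

    def parents_of(self, animal: str) -> tuple[str, str]:
        row = self.table.loc[self.table["animal"] == str(animal)]
        if row.empty:
            return UNKNOWN_PARENT, UNKNOWN_PARENT
        return row["sire"].iloc[0], row["dam"].iloc[0]

    def topological_order(self) -> list[str]:
        """Animals sorted parents-before-offspring; raises on cycles."""
        import graphlib

        parent_map = {
            a: {p for p in (s, d) if p != UNKNOWN_PARENT}
            for a, s, d in self.table.itertuples(index=False)
        }
        for parents in list(parent_map.values()):
            for p in parents:
                parent_map.setdefault(p, set())
        try:
            return list(graphlib.TopologicalSorter(parent_map).static_order())
        except graphlib.CycleError as exc:
            chain = " -> ".join(exc.args[1])
            raise ValueError(f"pedigree contains a cycle: {chain}") from exc
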