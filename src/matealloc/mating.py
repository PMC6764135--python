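"""Progeny merit prediction and optimal mate allocation.

For every candidate boar x sow pair the expected progeny total genetic value

    g_ij = sum_k [ P_ijk(AA) a_k + P_ijk(Aa) d_k + P_ijk(aa) (-a_k) ]

and expected progeny breeding value

    u_ij = sum_k [ P_ijk(AA) (2-2p) + P_ijk(Aa) (1-2p) + P_ijk(aa) (-2p) ] alpha_k

are computed from single-locus Mendelian genotype probabilities under random
gamete transmission; loci where either parent is ungenotyped are skipped.
With complete genotypes ``u_ij`` reduces exactly to the parental GEBV
average, so optimising on it reproduces truncation selection on GEBV.

The mating set itself is chosen by an integer linear program on the
transportation polytope: at most ``boar_capacity`` sows per boar, at most
one boar per sow, exactly ``n_matings`` matings in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import LinearConstraint, milp

from .genotypes import GenotypeMatrix
from .markerfx import MarkerEffects

__all__ = [
    "MatingGrid",
    "MatingPlan",
    "progeny_genotype_probs",
    "predict_mating",
    "preselect_boars",
    "allocate",
    "gains",
]


@dataclass
class MatingGrid:
    """Expected progeny values for every candidate boar x sow pair."""

    boar_ids: list[str]
    sow_ids: list[str]
    g_hat: np.ndarray  # nb x ns
    u_hat: np.ndarray  # nb x ns

    def __post_init__(self) -> None:
        shape = (len(self.boar_ids), len(self.sow_ids))
        self.g_hat = np.asarray(self.g_hat, dtype=float)
        self.u_hat = np.asarray(self.u_hat, dtype=float)
        if self.g_hat.shape != shape or self.u_hat.shape != shape:
            raise ValueError("grid shape inconsistent with id lists")
        if not (np.isfinite(self.g_hat).all() and np.isfinite(self.u_hat).all()):
            raise ValueError("grid contains non-finite entries")

    def to_frame(self) -> pd.DataFrame:
        nb, ns = self.g_hat.shape
        return pd.DataFrame(
            {
                "boar": np.repeat(self.boar_ids, ns),
                "sow": np.tile(self.sow_ids, nb),
                "u_hat": self.u_hat.ravel(),
                "g_hat": self.g_hat.ravel(),
            }
        )


@dataclass
class MatingPlan:
    """A selected set of matings and its audit numbers."""

    pairs: list[tuple[str, str]]
    objective: str  # "u" | "g"
    objective_value: float
    n_matings: int
    boar_capacity: int
    direction: str
    delta_U: float = float("nan")
    delta_G: float = float("nan")
    delta_U_sd: float = float("nan")
    delta_G_sd: float = float("nan")

    def boar_usage(self) -> pd.Series:
        return pd.Series([b for b, _ in self.pairs]).value_counts()

    def summary(self) -> dict:
        return {
            "objective": self.objective,
            "objective_value": self.objective_value,
            "n_matings": self.n_matings,
            "boar_capacity": self.boar_capacity,
            "direction": self.direction,
            "n_boars_used": int(self.boar_usage().shape[0]),
            "delta_U": self.delta_U,
            "delta_G": self.delta_G,
            "delta_U_sd": self.delta_U_sd,
            "delta_G_sd": self.delta_G_sd,
        }


def progeny_genotype_probs(
    g_sire: float, g_dam: float
) -> tuple[float, float, float] | None:
    """Single-locus progeny genotype probabilities (P_AA, P_Aa, P_aa).

    Parents transmit one of their two alleles uniformly at random. Returns
    ``None`` when either parent's genotype is missing (the locus is skipped).
    """
    if g_sire is None or g_dam is None or np.isnan(g_sire) or np.isnan(g_dam):
        return None
    ts, td = g_sire / 2.0, g_dam / 2.0
    p_AA = ts * td
    p_aa = (1.0 - ts) * (1.0 - td)
    return (p_AA, 1.0 - p_AA - p_aa, p_aa)


def predict_mating(
    geno_sires: GenotypeMatrix,
    geno_dams: GenotypeMatrix,
    fx: MarkerEffects,
) -> MatingGrid:
    """Expected progeny g and u for all sire x dam pairs, vectorised.

    Uses the transmission probabilities tau = count/2 per parent: for a pair,
    P(AA) = tau_s tau_d, P(aa) = (1-tau_s)(1-tau_d), P(Aa) the remainder.
    Loci with a missing call in either parent contribute nothing to that
    pair's sums.
    """
    if list(geno_sires.snp_ids) != fx.snp_ids or list(geno_dams.snp_ids) != fx.snp_ids:
        common = set(geno_sires.snp_ids) & set(geno_dams.snp_ids) & set(fx.snp_ids)
        if not common:
            raise ValueError("no shared SNPs between genotypes and marker effects")
        order = [s for s in fx.snp_ids if s in common]
        fx_idx = [fx.snp_ids.index(s) for s in order]
        fx = MarkerEffects(
            snp_ids=order,
            a=fx.a[fx_idx],
            d_star=fx.d_star[fx_idx],
            b_hat=fx.b_hat * len(order) / fx.m,  # keep d = d* - b/m consistent
            p=fx.p[fx_idx],
            sigma2_a=fx.sigma2_a,
            sigma2_d=fx.sigma2_d,
        )
        geno_sires = geno_sires.subset(
            snps=[geno_sires.snp_ids.index(s) for s in order], keep_freqs=True
        )
        geno_dams = geno_dams.subset(
            snps=[geno_dams.snp_ids.index(s) for s in order], keep_freqs=True
        )

    a, d, alpha, p = fx.a, fx.d, fx.alpha, fx.p

    S = geno_sires.counts / 2.0
    D = geno_dams.counts / 2.0
    Ms = np.isfinite(S).astype(float)
    Md = np.isfinite(D).astype(float)
    S0 = np.where(np.isfinite(S), S, 0.0)
    D0 = np.where(np.isfinite(D), D, 0.0)

    # g = sum (tau_s + tau_d - 1) a + (tau_s + tau_d - 2 tau_s tau_d) d over valid loci
    g = (
        (S0 * a) @ Md.T
        + Ms @ (D0 * a).T
        - Ms @ (Md * a).T
        + (S0 * d) @ Md.T
        + Ms @ (D0 * d).T
        - 2.0 * (S0 * d) @ D0.T
    )
    # u = sum (tau_s + tau_d - 2p) alpha over valid loci
    u = (S0 * alpha) @ Md.T + Ms @ (D0 * alpha).T - Ms @ (Md * (2.0 * p * alpha)).T
    return MatingGrid(list(geno_sires.animal_ids), list(geno_dams.animal_ids), g, u)


def preselect_boars(
    gebv: pd.Series,
    n_keep: int = 120,
    direction: str = "lower_better",
    random_rng: np.random.Generator | None = None,
) -> list[str]:
    """Keep the best ``n_keep`` boars by GEBV (ties broken by animal id).

    Passing a Generator in ``random_rng`` switches to random preselection
    (the robustness scenario where boars are drawn at random instead of on
    merit).
    """
    if direction not in ("lower_better", "higher_better"):
        raise ValueError("direction must be 'lower_better' or 'higher_better'")
    ids = list(gebv.index.astype(str))
    if random_rng is not None:
        pick = random_rng.choice(len(ids), size=min(n_keep, len(ids)), replace=False)
        return sorted(ids[i] for i in pick)
    sign = 1.0 if direction == "lower_better" else -1.0
    ranked = sorted(zip(sign * gebv.to_numpy(float), ids))
    return [aid for _, aid in ranked[:n_keep]]


def allocate(
    grid: MatingGrid,
    objective: str = "g",
    n_matings: int = 600,
    boar_capacity: int = 15,
    direction: str = "higher_better",
) -> MatingPlan:
    """Select the optimal mating set by integer linear programming.

    Maximises (or minimises, for lower-is-better traits) the summed expected
    progeny value subject to: at most ``boar_capacity`` sows per boar, at
    most one boar per sow, exactly ``n_matings`` matings. The constraint
    matrix is totally unimodular (a transportation structure), so the
    optimum is integral; HiGHS solves it exactly. Among equal-objective
    optima a microscopic lexicographic preference for low (boar, sow)
    indices makes the solution deterministic.
    """
    nb, ns = len(grid.boar_ids), len(grid.sow_ids)
    if objective not in ("u", "g"):
        raise ValueError("objective must be 'u' or 'g'")
    if direction not in ("lower_better", "higher_better"):
        raise ValueError("direction must be 'lower_better' or 'higher_better'")
    if n_matings > ns or n_matings > nb * boar_capacity:
        raise ValueError(
            f"infeasible: n_matings={n_matings} exceeds "
            f"min(ns={ns}, nb*capacity={nb * boar_capacity})"
        )

    values = grid.g_hat if objective == "g" else grid.u_hat
    sign = 1.0 if direction == "lower_better" else -1.0  # milp minimises
    c = sign * values.ravel()

    # deterministic tie-break: prefer lexicographically early (boar, sow) pairs
    scale = max(1.0, float(np.abs(c).max()))
    eps = 1e-9 * scale
    c = c + eps * np.linspace(0.0, 1.0, nb * ns)

    n_var = nb * ns
    rows, cols = [], []
    for i in range(nb):
        rows.extend([i] * ns)
        cols.extend(range(i * ns, (i + 1) * ns))
    A_boar = sp.csr_matrix((np.ones(n_var), (rows, cols)), shape=(nb, n_var))
    rows = list(range(ns)) * nb
    cols = list(range(n_var))
    A_sow = sp.csr_matrix((np.ones(n_var), (rows, cols)), shape=(ns, n_var))
    A_tot = sp.csr_matrix(np.ones((1, n_var)))

    constraints = [
        LinearConstraint(A_boar, 0, boar_capacity),
        LinearConstraint(A_sow, 0, 1),
        LinearConstraint(A_tot, n_matings, n_matings),
    ]
    res = milp(
        c,
        constraints=constraints,
        integrality=np.ones(n_var),
        bounds=(0, 1),
    )
    if not res.success:
        raise RuntimeError(f"allocation solver failed: {res.message}")
    x = np.round(res.x).astype(int).reshape(nb, ns)
    pairs = [
        (grid.boar_ids[i], grid.sow_ids[j]) for i, j in zip(*np.nonzero(x))
    ]
    obj_val = float(values.ravel() @ x.ravel())
    return MatingPlan(
        pairs=pairs,
        objective=objective,
        objective_value=obj_val,
        n_matings=n_matings,
        boar_capacity=boar_capacity,
        direction=direction,
    )


def gains(plan: MatingPlan, grid: MatingGrid, sigma2_A: float) -> MatingPlan:
    """Fill in the expected gains of a plan relative to all possible matings.

    Delta U (Delta G) is the mean u (g) of the selected matings minus the
    mean over the full grid; the SD-unit versions divide by the additive
    genetic standard deviation.
    """
    b_index = {b: i for i, b in enumerate(grid.boar_ids)}
    s_index = {s: j for j, s in enumerate(grid.sow_ids)}
    sel = [(b_index[b], s_index[s]) for b, s in plan.pairs]
    ii = [i for i, _ in sel]
    jj = [j for _, j in sel]
    plan.delta_U = float(grid.u_hat[ii, jj].mean() - grid.u_hat.mean())
    plan.delta_G = float(grid.g_hat[ii, jj].mean() - grid.g_hat.mean())
    sd = float(np.sqrt(sigma2_A))
    plan.delta_U_sd = plan.delta_U / sd
    plan.delta_G_sd = plan.delta_G / sd
    return plan
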