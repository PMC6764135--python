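"""REML variance-component estimation for additive/dominance mixed models.

The engine fits the linear mixed model

    y = X beta + sum_t Z_t u_t + e,    u_t ~ N(0, K_t sigma_t^2),  e ~ N(0, I sigma_e^2)

by EM-REML on Henderson's mixed-model equations, with an optional
average-information (AI) acceleration that falls back to an EM step whenever
the AI update leaves the parameter space. The inbreeding-depression
coefficient b is the fixed-effect coefficient of the genomic-homozygosity
covariate f, so it is estimated jointly with the other fixed effects.

Three model flavours are orchestrated by :func:`fit_model`:

* ``A``  -- pedigree relationship matrix, no f covariate;
* ``G``  -- blended genomic additive matrix plus f;
* ``GD`` -- additive and dominance genomic matrices plus f.

Random-effect covariances can be supplied as dense matrices or, for the
unblended genomic terms, as low-rank marker designs (``Z = M / sqrt(2*sum pq)``
with identity covariance), which is the exact SNP-level reformulation of
GBLUP and keeps the equation count at the number of markers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "RandomTerm",
    "REMLResult",
    "ModelSpec",
    "VarianceEstimates",
    "build_mme",
    "em_reml",
    "compute_aic",
    "asymptotic_se",
    "fit_model",
    "build_design",
]

_FLOOR_FRAC = 1e-8  # variance floor, as a fraction of var(y)


@dataclass
class RandomTerm:
    """One random effect: design ``Z`` (n x q) and covariance ``K`` (q x q).

    ``K=None`` means the identity (no inverse ever formed), which is the fast
    path for marker-scale terms and permanent environment.
    """

    name: str
    Z: np.ndarray
    K: np.ndarray | None = None

    _K_chol: tuple | None = field(default=None, repr=False)
    _K_inv: np.ndarray | None = field(default=None, repr=False)
    _K_logdet: float = field(default=0.0, repr=False)

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        if self.K is not None:
            self.K = np.asarray(self.K, dtype=float)
            if self.K.shape != (self.q, self.q):
                raise ValueError(f"term {self.name}: K shape mismatch")
            try:
                self._K_chol = cho_factor(self.K, lower=True)
            except np.linalg.LinAlgError as exc:
                raise ValueError(
                    f"covariance for term {self.name!r} is singular; "
                    "blend it toward the identity (e.g. 0.95 K + 0.05 I)"
                ) from exc
            self._K_inv = cho_solve(self._K_chol, np.eye(self.q))
            self._K_logdet = 2.0 * float(np.sum(np.log(np.diag(self._K_chol[0]))))

    @property
    def q(self) -> int:
        return self.Z.shape[1]

    @property
    def K_inv(self) -> np.ndarray | None:
        return self._K_inv

    @property
    def K_logdet(self) -> float:
        return self._K_logdet

    def quad_Kinv(self, u: np.ndarray) -> float:
        """u' K^{-1} u (u'u for identity covariance)."""
        if self.K is None:
            return float(u @ u)
        return float(u @ (self._K_inv @ u))


@dataclass
class REMLResult:
    """Raw engine output: components keyed by term name, plus 'e'."""

    components: dict[str, float]
    beta: np.ndarray
    beta_se: np.ndarray
    x_names: list[str]
    u: dict[str, np.ndarray]
    logL: float
    logL_path: list[float]
    n_iter: int
    converged: bool
    se: dict[str, float]
    boundary: list[str]
    n_obs: int
    rank_x: int
    cov_theta: np.ndarray | None = None
    theta_names: list[str] | None = None

    def fixed_effect(self, name: str) -> tuple[float, float]:
        i = self.x_names.index(name)
        return float(self.beta[i]), float(self.beta_se[i])


def build_mme(
    y: np.ndarray,
    X: np.ndarray,
    terms: list[RandomTerm],
    variances: dict[str, float],
    sigma2_e: float,
):
    """Assemble Henderson's MME coefficient matrix and right-hand side.

    Returns ``(C, rhs, slices)`` where ``C`` is the lambda-form coefficient
    matrix (so ``C^{-1} * sigma_e^2`` is the prediction-error covariance) and
    ``slices`` maps ``"beta"`` and each term name to its equation block.
    """
    p = X.shape[1]
    designs = [X] + [t.Z for t in terms]
    W = np.hstack(designs)
    C = W.T @ W
    rhs = W.T @ y
    slices: dict[str, slice] = {"beta": slice(0, p)}
    offset = p
    for t in terms:
        sl = slice(offset, offset + t.q)
        slices[t.name] = sl
        lam = sigma2_e / variances[t.name]
        if t.K is None:
            C[sl, sl] += lam * np.eye(t.q)
        else:
            C[sl, sl] += lam * t.K_inv
        offset += t.q
    return C, rhs, slices


def _restricted_loglik(
    n: int,
    p: int,
    terms: list[RandomTerm],
    variances: dict[str, float],
    sigma2_e: float,
    C_logdet: float,
    yPy_scaled: float,
) -> float:
    """Restricted log-likelihood from MME quantities.

    ``yPy_scaled`` is ``y'y - sol'rhs`` (i.e. sigma_e^2 * y'Py).
    """
    q_tot = sum(t.q for t in terms)
    val = (n - p) * math.log(2.0 * math.pi) + (n - p - q_tot) * math.log(sigma2_e)
    for t in terms:
        val += t.q * math.log(variances[t.name]) + t.K_logdet
    val += C_logdet + yPy_scaled / sigma2_e
    return -0.5 * val


def em_reml(
    y: np.ndarray,
    X: np.ndarray,
    terms: list[RandomTerm],
    init: dict[str, float] | None = None,
    tol: float = 1e-8,
    max_iter: int = 5000,
    method: str = "em",
    x_names: list[str] | None = None,
) -> REMLResult:
    """Estimate variance components by (accelerated) EM-REML.

    ``method="em"`` performs pure EM fixed-point iterations, whose restricted
    log-likelihood is non-decreasing (asserted). ``method="ai"`` takes
    average-information Newton steps and falls back to an EM step whenever a
    proposed update leaves the parameter space; monotonicity is then only
    asserted for the EM steps.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design is rank deficient; drop aliased columns")
    if method not in ("em", "ai"):
        raise ValueError("method must be 'em' or 'ai'")
    names = [t.name for t in terms]
    if len(set(names)) != len(names):
        raise ValueError("random term names must be unique")

    vary = float(np.var(y))
    floor = max(_FLOOR_FRAC * vary, 1e-12)
    n_terms = len(terms)
    if init is None:
        init = {t.name: vary / (2 * max(n_terms, 1)) for t in terms}
    var = {t.name: max(float(init[t.name]), floor) for t in terms}
    sigma2_e = max(float(init.get("e", vary / 2)) if init else vary / 2, floor)

    yty = float(y @ y)
    # cross-products are parameter-free: assemble once, re-add the shrinkage
    # diagonal each iteration
    W = np.hstack([X] + [t.Z for t in terms])
    WtW = W.T @ W
    rhs = W.T @ y
    n_eq = WtW.shape[0]
    slices: dict[str, slice] = {"beta": slice(0, p)}
    offset = p
    for t in terms:
        slices[t.name] = slice(offset, offset + t.q)
        offset += t.q

    def factor_mme(variances: dict[str, float], s2e: float):
        C = WtW.copy()
        for t in terms:
            sl = slices[t.name]
            lam = s2e / variances[t.name]
            if t.K is None:
                idx = np.arange(sl.start, sl.stop)
                C[idx, idx] += lam
            else:
                C[sl, sl] += lam * t.K_inv
        return cho_factor(C, lower=True)

    logL_path: list[float] = []
    boundary_count = {t.name: 0 for t in terms}
    converged = False
    it = 0
    prev_logL = -np.inf
    prev_step_was_em = False

    for it in range(1, max_iter + 1):
        C_fac = factor_mme(var, sigma2_e)
        sol = cho_solve(C_fac, rhs)
        C_logdet = 2.0 * float(np.sum(np.log(np.diag(C_fac[0]))))
        yPy_scaled = yty - float(sol @ rhs)
        logL = _restricted_loglik(n, p, terms, var, sigma2_e, C_logdet, yPy_scaled)

        C_inv = cho_solve(C_fac, np.eye(n_eq))
        traces = {}
        for t in terms:
            sl = slices[t.name]
            block = C_inv[sl, sl]
            traces[t.name] = float(np.trace(block)) if t.K is None else float(
                np.sum(t.K_inv * block)
            )

        em_var = {}
        for t in terms:
            u = sol[slices[t.name]]
            em_var[t.name] = (t.quad_Kinv(u) + sigma2_e * traces[t.name]) / t.q
        em_e = yPy_scaled / (n - p)

        new_var, new_e, used_em = None, None, True
        if method == "ai":
            step = _ai_step(y, W, terms, var, sigma2_e, sol, slices, C_fac, traces, n, p)
            if step is not None:
                cand_var, cand_e = step
                if all(v > floor for v in cand_var.values()) and cand_e > floor:
                    new_var, new_e, used_em = cand_var, cand_e, False
        if new_var is None:
            new_var, new_e = em_var, em_e

        if prev_step_was_em and logL_path:
            # EM guarantees a monotone restricted likelihood (tiny numerical slack)
            assert logL >= prev_logL - 1e-6 * (1.0 + abs(prev_logL)), (
                f"EM-REML restricted logL decreased: {prev_logL} -> {logL}"
            )
        logL_path.append(logL)
        prev_logL = logL
        prev_step_was_em = used_em

        delta = max(
            abs(new_var[k] - var[k]) / max(var[k], floor) for k in var
        ) if var else 0.0
        delta = max(delta, abs(new_e - sigma2_e) / max(sigma2_e, floor))

        for k in var:
            var[k] = max(new_var[k], floor)
            boundary_count[k] = boundary_count[k] + 1 if var[k] == floor else 0
        sigma2_e = max(new_e, floor)

        if delta < tol:
            converged = True
            break

    # final solve at the converged parameters
    C_fac = factor_mme(var, sigma2_e)
    sol = cho_solve(C_fac, rhs)
    C_logdet = 2.0 * float(np.sum(np.log(np.diag(C_fac[0]))))
    yPy_scaled = yty - float(sol @ rhs)
    logL = _restricted_loglik(n, p, terms, var, sigma2_e, C_logdet, yPy_scaled)
    C_inv = cho_solve(C_fac, np.eye(n_eq))

    beta = sol[slices["beta"]]
    beta_se = np.sqrt(np.maximum(np.diag(C_inv[slices["beta"], slices["beta"]]), 0.0) * sigma2_e)
    u = {t.name: sol[slices[t.name]] for t in terms}

    info = _information_matrix(y, W, terms, var, sigma2_e, sol, slices, C_fac, n, p)
    theta_names = names + ["e"]
    se = asymptotic_se(info, theta_names)
    try:
        cov_theta = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov_theta = np.linalg.pinv(info)
    components = dict(var)
    components["e"] = sigma2_e
    return REMLResult(
        components=components,
        beta=beta,
        beta_se=beta_se,
        x_names=x_names or [f"x{i}" for i in range(p)],
        u=u,
        logL=logL,
        logL_path=logL_path,
        n_iter=it,
        converged=converged,
        se=se,
        boundary=[k for k, c in boundary_count.items() if c >= 50],
        n_obs=n,
        rank_x=p,
        cov_theta=cov_theta,
        theta_names=theta_names,
    )


def _project(
    f: np.ndarray,
    y_designs: np.ndarray,
    C_fac,
    sigma2_e: float,
) -> np.ndarray:
    """Apply the REML projection P to a vector using the factorised MME."""
    rhs = y_designs.T @ f
    sol = cho_solve(C_fac, rhs)
    return (f - y_designs @ sol) / sigma2_e


def _ai_step(y, W, terms, var, sigma2_e, sol, slices, C_fac, traces, n, p):
    """One average-information update; None if the AI matrix is not PD."""
    e_hat = y - W @ sol
    Py = e_hat / sigma2_e

    names = [t.name for t in terms]
    # f_t = (dV/dsigma_t^2) P y = Z_t K_t Z_t' P y = Z_t u_t / sigma_t^2
    fvecs = [t.Z @ sol[slices[t.name]] / var[t.name] for t in terms]
    fvecs.append(Py)  # dV/dsigma_e^2 = I

    Pf = [_project(f, W, C_fac, sigma2_e) for f in fvecs]
    k = len(fvecs)
    AI = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            AI[i, j] = AI[j, i] = 0.5 * float(fvecs[i] @ Pf[j])

    # score vector
    score = np.empty(k)
    for i, t in enumerate(terms):
        u = sol[slices[t.name]]
        s2 = var[t.name]
        uKu = t.quad_Kinv(u)
        trPV = t.q / s2 - (sigma2_e / s2**2) * traces[t.name]
        score[i] = -0.5 * (trPV - uKu / s2**2)
    trP = (n - p - sum(
        var[t.name] * (t.q / var[t.name] - (sigma2_e / var[t.name] ** 2) * traces[t.name])
        for t in terms
    )) / sigma2_e
    score[-1] = -0.5 * (trP - float(Py @ Py))

    try:
        step = np.linalg.solve(AI, score)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(step)):
        return None
    theta = np.array([var[nm] for nm in names] + [sigma2_e]) + step
    return {nm: theta[i] for i, nm in enumerate(names)}, theta[-1]


def _information_matrix(y, W, terms, var, sigma2_e, sol, slices, C_fac, n, p):
    """Average-information matrix at the converged parameter values."""
    e_hat = y - W @ sol
    Py = e_hat / sigma2_e
    fvecs = [t.Z @ sol[slices[t.name]] / var[t.name] for t in terms]
    fvecs.append(Py)
    Pf = [_project(f, W, C_fac, sigma2_e) for f in fvecs]
    k = len(fvecs)
    AI = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            AI[i, j] = AI[j, i] = 0.5 * float(fvecs[i] @ Pf[j])
    return AI


def asymptotic_se(information: np.ndarray, names: list[str]) -> dict[str, float]:
    """Standard errors as sqrt of the diagonal of the inverse information.

    A singular information matrix (components at the boundary) yields a
    pseudo-inverse, which is the conventional fallback.
    """
    information = np.asarray(information, dtype=float)
    try:
        cov = np.linalg.inv(information)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(information)
    diag = np.clip(np.diag(cov), 0.0, None)
    return {nm: float(np.sqrt(d)) for nm, d in zip(names, diag)}


def compute_aic(logL_restricted: float, n_var_params: int) -> float:
    """Akaike information criterion: -2 logL + 2 * (number of variance params)."""
    return -2.0 * logL_restricted + 2.0 * n_var_params


# ---------------------------------------------------------------------------
# model-level orchestration
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Declarative description of one analysis model.

    ``name`` follows the field's convention: ``A`` is the pedigree additive
    model (no genomic-inbreeding covariate), ``G`` the genomic additive model
    with the f covariate, and ``GD`` adds dominance. ``random_terms`` is a
    subset of ``{"additive", "dominance", "pe"}``.
    """

    name: str
    trait: str
    fixed_effects: list[str] = field(default_factory=list)
    covariates: list[str] = field(default_factory=list)
    random_terms: tuple[str, ...] = ("additive",)
    covariance_for_additive: str = "G_blend"  # A | G_blend | marker

    def __post_init__(self) -> None:
        if self.name not in ("A", "G", "GD"):
            raise ValueError("model name must be A, G or GD")
        if "dominance" in self.random_terms and self.name != "GD":
            raise ValueError("dominance term requires model GD")
        if self.name == "GD" and "dominance" not in self.random_terms:
            self.random_terms = tuple(self.random_terms) + ("dominance",)

    @property
    def includes_f(self) -> bool:
        return self.name in ("G", "GD")


@dataclass
class VarianceEstimates:
    """Variance components with derived ratios, fit statistics and SEs."""

    model: str
    trait: str
    sigma2_A: float
    sigma2_D: float
    sigma2_pe: float
    sigma2_e: float
    b_hat: float | None
    b_se: float | None
    h2: float
    ratio_D_A: float
    ratio_D_P: float
    logL_restricted: float
    aic: float
    se: dict[str, float]
    n_iter: int
    converged: bool
    boundary: list[str]
    ebv: pd.Series | None = None
    dominance_dev: pd.Series | None = None

    @property
    def sigma2_P(self) -> float:
        return self.sigma2_A + self.sigma2_D + self.sigma2_pe + self.sigma2_e

    def as_dict(self) -> dict:
        return {
            "model": self.model,
            "trait": self.trait,
            "sigma2_A": self.sigma2_A,
            "sigma2_D": self.sigma2_D,
            "sigma2_pe": self.sigma2_pe,
            "sigma2_e": self.sigma2_e,
            "sigma2_P": self.sigma2_P,
            "b_hat": self.b_hat,
            "b_se": self.b_se,
            "b_per_10pct": None if self.b_hat is None else 0.1 * self.b_hat,
            "h2": self.h2,
            "ratio_D_A": self.ratio_D_A,
            "ratio_D_P": self.ratio_D_P,
            "logL_restricted": self.logL_restricted,
            "aic": self.aic,
            "se": self.se,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "boundary": self.boundary,
        }


def build_design(
    pheno: pd.DataFrame,
    fixed_effects: list[str],
    covariates: list[str],
    f_values: np.ndarray | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design: intercept, dummy-coded factors (reference level
    dropped), covariates, and optionally the genomic-inbreeding covariate f
    as the last column (named ``"f"``)."""
    cols = [np.ones(len(pheno))]
    names = ["intercept"]
    for factor in fixed_effects:
        dummies = pd.get_dummies(pheno[factor].astype("category"), drop_first=True)
        for level in dummies.columns:
            cols.append(dummies[level].to_numpy(float))
            names.append(f"{factor}[{level}]")
    for cov in covariates:
        cols.append(pheno[cov].to_numpy(float))
        names.append(cov)
    if f_values is not None:
        cols.append(np.asarray(f_values, dtype=float))
        names.append("f")
    return np.column_stack(cols), names


def _indicator(record_animals: list[str], animal_ids: list[str]) -> np.ndarray:
    index = {a: i for i, a in enumerate(animal_ids)}
    Z = np.zeros((len(record_animals), len(animal_ids)))
    for r, a in enumerate(record_animals):
        Z[r, index[str(a)]] = 1.0
    return Z


def fit_model(
    pheno: pd.DataFrame,
    spec: ModelSpec,
    covstructs: dict,
    f: "np.ndarray | None" = None,
    init: dict[str, float] | None = None,
    tol: float = 1e-8,
    max_iter: int = 5000,
    method: str = "em",
) -> VarianceEstimates:
    """Fit one model on a phenotype table.

    ``pheno`` needs an ``animal`` column, the trait column, and every factor
    or covariate named in the spec. ``covstructs`` supplies the covariance
    structures by term: for ``additive`` either a RelationshipMatrix (A or a
    blended G) or a pair ``(design, animal_ids)`` of a marker design whose
    cross-product is the unblended relationship matrix; for ``dominance``
    likewise. ``f`` is the per-record genomic inbreeding covariate (required
    for models G and GD).
    """
    y = pheno[spec.trait].to_numpy(float)
    animals = pheno["animal"].astype(str).tolist()
    if spec.includes_f:
        if f is None:
            raise ValueError(f"model {spec.name} requires the inbreeding covariate f")
        X, x_names = build_design(pheno, spec.fixed_effects, spec.covariates, f)
    else:
        X, x_names = build_design(pheno, spec.fixed_effects, spec.covariates, None)

    terms: list[RandomTerm] = []
    animal_index_by_term: dict[str, list[str]] = {}
    for term_name in spec.random_terms:
        struct = covstructs[term_name] if term_name != "pe" else None
        if term_name == "pe":
            ids = sorted(set(animals))
            terms.append(RandomTerm("pe", _indicator(animals, ids)))
            animal_index_by_term["pe"] = ids
        elif isinstance(struct, tuple):
            design, ids = struct
            Zmap = _indicator(animals, list(ids))
            terms.append(RandomTerm(term_name, Zmap @ np.asarray(design, float)))
            animal_index_by_term[term_name] = list(ids)
        else:
            ids = list(struct.animal_ids)
            Zmap = _indicator(animals, ids)
            terms.append(RandomTerm(term_name, Zmap, K=struct.submatrix(ids)))
            animal_index_by_term[term_name] = ids

    res = em_reml(
        y, X, terms, init=init, tol=tol, max_iter=max_iter, method=method, x_names=x_names
    )

    sigma2_A = res.components.get("additive", 0.0)
    sigma2_D = res.components.get("dominance", 0.0)
    sigma2_pe = res.components.get("pe", 0.0)
    sigma2_e = res.components["e"]

    sigma2_P = sigma2_A + sigma2_D + sigma2_pe + sigma2_e
    b_hat = b_se = None
    if spec.includes_f:
        b_hat, b_se = res.fixed_effect("f")

    aic = compute_aic(res.logL, len(res.components))

    se = dict(res.se)
    se.update(_derived_se(res, sigma2_A, sigma2_D, sigma2_pe, sigma2_e))

    ebv = dom = None
    if "additive" in res.u:
        if isinstance(covstructs.get("additive"), tuple):
            design, ids = covstructs["additive"]
            vals = np.asarray(design, float) @ res.u["additive"]
            ebv = pd.Series(vals, index=list(ids))
        else:
            ebv = pd.Series(res.u["additive"], index=animal_index_by_term["additive"])
    if "dominance" in res.u:
        if isinstance(covstructs.get("dominance"), tuple):
            design, ids = covstructs["dominance"]
            dom = pd.Series(np.asarray(design, float) @ res.u["dominance"], index=list(ids))
        else:
            dom = pd.Series(res.u["dominance"], index=animal_index_by_term["dominance"])

    return VarianceEstimates(
        model=spec.name,
        trait=spec.trait,
        sigma2_A=sigma2_A,
        sigma2_D=sigma2_D,
        sigma2_pe=sigma2_pe,
        sigma2_e=sigma2_e,
        b_hat=b_hat,
        b_se=b_se,
        h2=sigma2_A / sigma2_P,
        ratio_D_A=sigma2_D / sigma2_A if sigma2_A > 0 else float("nan"),
        ratio_D_P=sigma2_D / sigma2_P,
        logL_restricted=res.logL,
        aic=aic,
        se=se,
        n_iter=res.n_iter,
        converged=res.converged,
        boundary=res.boundary,
        ebv=ebv,
        dominance_dev=dom,
    )


def _derived_se(res: REMLResult, sA: float, sD: float, spe: float, se2: float) -> dict[str, float]:
    """First-order delta-method SEs for h2 and the dominance ratios,
    propagated through the full inverse-information covariance."""
    if res.cov_theta is None or res.theta_names is None:
        return {}
    names = res.theta_names
    cov = res.cov_theta
    sP = sA + sD + spe + se2
    out: dict[str, float] = {}

    def delta(grads: dict[str, float]) -> float:
        g = np.array([grads.get(n, 0.0) for n in names])
        return float(np.sqrt(max(g @ cov @ g, 0.0)))

    grads = {n: -sA / sP**2 for n in names}
    grads["additive"] = (sP - sA) / sP**2
    out["h2"] = delta(grads)
    if sA > 0:
        out["ratio_D_A"] = delta({"dominance": 1.0 / sA, "additive": -sD / sA**2})
        grads = {n: -sD / sP**2 for n in names}
        grads["dominance"] = (sP - sD) / sP**2
        out["ratio_D_P"] = delta(grads)
    return out
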