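"""Configuration-driven end-to-end orchestration.

A run simulates (or loads) genotypes and phenotypes, applies quality
control, builds relationship matrices and genomic inbreeding, estimates
variance components under the pedigree model A and the genomic models G and
GD, derives SNP effects from the GD components, predicts all candidate
matings and allocates an optimal mating set on both the expected breeding
value u and the expected total genetic value g, reporting the expected
gains of each plan.

Variance components for the genomic models are estimated in the exact
SNP-level reformulation of GBLUP (design ``M / sqrt(2 sum pq)`` with
identity covariance), which never inverts a genomic relationship matrix and
therefore needs no blending; the blend weight in the configuration governs
the dense matrices that are persisted and any dense animal-level fit.
"""

from __future__ import annotations

import time
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import io as io_
from ._rng import substream
from .genotypes import GenotypeMatrix, PedigreeTable
from .markerfx import gebv, genetic_to_marker_variance, solve_snp_blup
from .mating import allocate, gains, predict_mating, preselect_boars
from .qc import run_qc
from .relmat import (
    additive_denominator,
    blend,
    build_A,
    build_D,
    build_G,
    build_M,
    build_W,
    dominance_denominator,
    genomic_inbreeding,
)
from .simdata import SimConfig, simulate_effects_and_phenotypes, simulate_founder_genotypes, simulate_matings_and_offspring
from .varcomp import ModelSpec, VarianceEstimates, build_design, fit_model

__all__ = ["RunConfig", "RunReport", "run", "compare_models"]


class QcSettings(BaseModel):
    callrate_min_snp: float = 0.98
    callrate_min_animal: float = 0.98
    maf_min: float = 0.05
    hwe_alpha: float = 0.05
    conflict_rate_max: float = 0.02


class RemlSettings(BaseModel):
    method: str = "ai"  # "em" | "ai" (AI with EM fallback)
    tol: float = 1e-8
    max_iter: int = 2000
    models: tuple[str, ...] = ("A", "G", "GD")


class AllocationSettings(BaseModel):
    n_matings: int = 600
    boar_capacity: int = 15
    n_boars_preselect: int = 120
    preselect: str = "gebv"  # "gebv" | "random" | "none"
    direction: str = "lower_better"


class RunConfig(BaseModel):
    """Everything one reproducible run needs."""

    sim: SimConfig = Field(default_factory=SimConfig)
    qc: QcSettings = Field(default_factory=QcSettings)
    blend_weight: float = 0.95
    reml: RemlSettings = Field(default_factory=RemlSettings)
    allocation: AllocationSettings = Field(default_factory=AllocationSettings)
    outdir: str | None = None
    seed: int = 0


class RunReport(dict):
    """Plain dict of stage outputs; kept JSON-serialisable."""


def compare_models(estimates: dict[str, VarianceEstimates]) -> pd.DataFrame:
    """AIC ranking table over the fitted models (lowest AIC first; ties keep
    the stable order A, G, GD). Missing models are simply absent."""
    order = {"A": 0, "G": 1, "GD": 2}
    rows = [
        {"model": name, "aic": est.aic, "logL": est.logL_restricted}
        for name, est in estimates.items()
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df = df.sort_values(["aic", "model"], key=lambda s: s.map(order) if s.name == "model" else s)
    df["rank"] = range(1, len(df) + 1)
    return df.reset_index(drop=True)


def run(config: RunConfig) -> RunReport:
    """Execute the full pipeline on simulated data; see module docstring."""
    t0 = time.time()
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    cfg = config.sim.model_copy(update={"seed": config.seed})

    # --- stage 1: simulate --------------------------------------------------
    parents = simulate_founder_genotypes(cfg)
    offspring, ped = simulate_matings_and_offspring(parents, cfg)
    pheno, truth = simulate_effects_and_phenotypes(offspring, cfg)
    report["n_parents"] = parents.n_animals
    report["n_offspring"] = offspring.n_animals
    report["n_records"] = len(pheno)

    # --- stage 2: QC ----------------------------------------------------------
    combined = GenotypeMatrix(
        np.vstack([parents.counts, offspring.counts]),
        parents.animal_ids + offspring.animal_ids,
        list(parents.snp_ids),
    )
    geno, qc_report = run_qc(
        combined,
        ped,
        callrate_min_snp=config.qc.callrate_min_snp,
        callrate_min_animal=config.qc.callrate_min_animal,
        maf_min=config.qc.maf_min,
        hwe_alpha=config.qc.hwe_alpha,
        conflict_rate_max=config.qc.conflict_rate_max,
    )
    report["qc"] = qc_report.as_dict()
    pheno = pheno[pheno["animal"].isin(geno.animal_ids)].reset_index(drop=True)

    # --- stage 3: relationship structures and inbreeding ---------------------
    f_vec = genomic_inbreeding(geno)
    report["inbreeding"] = {
        "mean_f": float(np.mean(f_vec.f)),
        "sd_f": float(np.std(f_vec.f)),
    }
    M = build_M(geno)
    Wd = build_W(geno)
    denom_a = additive_denominator(geno.p)
    denom_d = dominance_denominator(geno.p)
    marker_add = (M / np.sqrt(denom_a), geno.animal_ids)
    marker_dom = (Wd / np.sqrt(denom_d), geno.animal_ids)
    if outdir:
        G_star = blend(build_G(geno), config.blend_weight)
        D_star = blend(build_D(geno), config.blend_weight)
        io_.write_matrix_csv(G_star.values, G_star.animal_ids, outdir / "G_blend.csv")
        io_.write_matrix_csv(D_star.values, D_star.animal_ids, outdir / "D_blend.csv")
        io_.write_genotype_csv(geno, outdir / "genotypes_qc.csv")
        io_.write_pedigree_csv(ped, outdir / "pedigree.csv")
        pheno.to_csv(outdir / "phenotypes.csv", index=False)
        io_.write_json(qc_report.as_dict(), outdir / "qc_report.json")

    # --- stage 4: variance components ----------------------------------------
    f_records = f_vec.for_animals(pheno["animal"].tolist())
    estimates: dict[str, VarianceEstimates] = {}
    fit_kwargs = dict(
        tol=config.reml.tol, max_iter=config.reml.max_iter, method=config.reml.method
    )
    random_terms = ("additive",) + (("pe",) if cfg.repeated_records else ())
    if "A" in config.reml.models:
        A = build_A(ped)
        spec = ModelSpec("A", "y", ["batch"], [], random_terms, "A")
        estimates["A"] = fit_model(pheno, spec, {"additive": A}, **fit_kwargs)
    if "G" in config.reml.models:
        spec = ModelSpec("G", "y", ["batch"], [], random_terms, "marker")
        estimates["G"] = fit_model(
            pheno, spec, {"additive": marker_add}, f=f_records, **fit_kwargs
        )
    if "GD" in config.reml.models:
        spec = ModelSpec(
            "GD", "y", ["batch"], [], random_terms + ("dominance",), "marker"
        )
        estimates["GD"] = fit_model(
            pheno,
            spec,
            {"additive": marker_add, "dominance": marker_dom},
            f=f_records,
            **fit_kwargs,
        )
    report["variance_components"] = {k: v.as_dict() for k, v in estimates.items()}
    aic_table = compare_models(estimates)
    report["aic_table"] = aic_table.to_dict(orient="records")
    gd = estimates.get("GD") or estimates.get("G")
    if gd is not None and gd.b_hat is not None:
        report["inbreeding"]["b_hat_per_unit_f"] = gd.b_hat
        report["inbreeding"]["b_hat_per_10pct"] = 0.1 * gd.b_hat

    # --- stage 5: SNP effects -------------------------------------------------
    if gd is None:
        raise RuntimeError("need a genomic model fit to derive SNP effects")
    sigma2_a, sigma2_d = genetic_to_marker_variance(gd.sigma2_A, gd.sigma2_D, geno.p)
    X_fix, _ = build_design(pheno, ["batch"], [])
    fx = solve_snp_blup(
        pheno["y"].to_numpy(float),
        X_fix,
        geno,
        sigma2_a=sigma2_a,
        sigma2_d=max(sigma2_d, 0.0),
        sigma2_e=gd.sigma2_e,
        record_animals=pheno["animal"].tolist(),
        sigma2_pe=gd.sigma2_pe,
    )
    report["snp_effects"] = {
        "m": fx.m,
        "b_hat": fx.b_hat,
        "sigma2_a": fx.sigma2_a,
        "sigma2_d": fx.sigma2_d,
    }
    if outdir:
        fx.to_frame().to_csv(outdir / "marker_effects.csv", index=False)
        io_.write_json(report["variance_components"], outdir / "variance_components.json")

    # --- stage 6: mating grid --------------------------------------------------
    alloc = config.allocation
    boar_ids = [a for a in geno.animal_ids if a.startswith("B")]
    sow_ids = [a for a in geno.animal_ids if a.startswith("S")]
    boar_geno = geno.subset(animals=geno.rows_for(boar_ids), keep_freqs=True)
    sow_geno = geno.subset(animals=geno.rows_for(sow_ids), keep_freqs=True)

    if alloc.preselect != "none" and alloc.n_boars_preselect < len(boar_ids):
        boar_gebv = gebv(boar_geno, fx.alpha, fx.p)
        rng = substream(config.seed, "preselect") if alloc.preselect == "random" else None
        keep = preselect_boars(
            boar_gebv, alloc.n_boars_preselect, alloc.direction, random_rng=rng
        )
        boar_geno = boar_geno.subset(animals=boar_geno.rows_for(keep), keep_freqs=True)
    grid = predict_mating(boar_geno, sow_geno, fx)
    if outdir:
        grid.to_frame().to_csv(outdir / "mating_grid.csv", index=False)

    # --- stage 7: allocation ----------------------------------------------------
    n_matings = min(alloc.n_matings, len(grid.sow_ids),
                    len(grid.boar_ids) * alloc.boar_capacity)
    plans = {}
    for objective in ("u", "g"):
        plan = allocate(
            grid,
            objective=objective,
            n_matings=n_matings,
            boar_capacity=alloc.boar_capacity,
            direction=alloc.direction,
        )
        plans[objective] = gains(plan, grid, gd.sigma2_A)
    report["gains"] = {
        f"plan_{obj}": plan.summary() for obj, plan in plans.items()
    }
    report["mean_u_all"] = float(grid.u_hat.mean())
    report["mean_g_all"] = float(grid.g_hat.mean())
    if outdir:
        for obj, plan in plans.items():
            pd.DataFrame(plan.pairs, columns=["boar", "sow"]).to_csv(
                outdir / f"mating_plan_{obj}.csv", index=False
            )
        io_.write_json(report["gains"], outdir / "gains.json")
        io_.write_json(
            {k: v for k, v in report.items() if k not in ("gains",)},
            outdir / "run_report.json",
        )

    report["runtime_s"] = time.time() - t0
    return report
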