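# Methods note

This note records the statistical models, the default parameters (with
units), what the data generator does and does not capture, and the main
numerical choices.

## 1. Data model

A phenotype record of animal *i* is

```
y = Xβ + f·b + Z u + Z v + Z pe + e
```

- `Xβ` — fixed effects: intercept, a contemporary-group factor (`batch`,
  dummy-coded with the reference level dropped) and optional covariates.
- `f·b` — genomic inbreeding covariate: `f` is the proportion of homozygous
  SNP calls of the animal (unitless, in [0, 1]); `b` is the inbreeding
  depression slope in trait units per unit of `f` (for a trait recorded in
  days, `b/10` is days per 10% increase in homozygosity). Included in the
  genomic models only.
- `u ~ N(0, K_A σ²_A)` — breeding values; `K_A` is the pedigree matrix `A` in
  model **A** and the genomic matrix `G` in models **G**/**GD**.
- `v ~ N(0, D σ²_D)` — dominance deviations, model **GD** only.
- `pe ~ N(0, I σ²_pe)` — permanent environment, only with repeated records.
- `e ~ N(0, I σ²_e)` — residual.

All variances are in squared trait units.

### Codings

With `p` the allele-A frequency (computed in a defining set and frozen), per
SNP and animal:

- additive coding `M`: genotype AA → `2 − 2p`, Aa → `1 − 2p`, aa → `−2p`;
  missing → `0` (population average).
- dominance coding `W`: AA → `−2q²`, Aa → `2pq`, aa → `−2p²`; missing → `0`.
- `G = MM′ / 2Σ p_k q_k`, `D = WW′ / Σ (2 p_k q_k)²`. For dense animal-level
  use a blend `K* = wK + (1 − w)I` with default `w = 0.95` guarantees
  invertibility; the REML path below does not need it.

### Marker-level reformulation

REML for the genomic models uses the exact factorization `G σ²_A =
(M/√(2Σpq)) I (M/√(2Σpq))′ σ²_A`: the additive term enters the mixed-model
equations with design `Z M/√(2Σpq)` and identity prior covariance, likewise
the dominance term with `W/√Σ(2pq)²`. This (i) estimates σ²_A on the `G`
scale directly, (ii) requires no inversion or blending of `G`, and (iii)
keeps the equation count at `p + 2m + (q_pe)` regardless of the number of
animals — for the default 3000 records and 500 SNPs the MME are ~1000×1000.

## 2. REML

Variance components are estimated on Henderson's mixed-model equations
`C = W′W + blockdiag(0, λ_t K_t⁻¹)`, `λ_t = σ²_e/σ²_t`:

- **EM-REML** (default `method="em"`): fixed-point updates
  `σ²_t ← (û′K⁻¹û + σ²_e·tr(K⁻¹C^{tt}))/q_t`,
  `σ²_e ← (y′y − sol′rhs)/(n − p)`. The restricted log-likelihood is
  non-decreasing along EM steps; this is asserted on every iteration (slack
  `1e-6·(1+|logL|)` for round-off).
- **AI-REML** (`method="ai"`): average-information Newton steps with exact
  score, falling back to an EM step whenever the proposed update leaves the
  parameter space. Monotonicity is only guaranteed (and asserted) for the EM
  steps. AI converges in ~10 iterations where EM needs hundreds; the
  pipeline default is AI.
- Convergence: relative parameter change below `tol` (default `1e-8`;
  pipeline uses `1e-6`). Variances are floored at
  `max(1e-8·var(y), 1e-12)`; a component pinned at the floor for ≥50
  iterations is reported in `boundary`.
- Standard errors: inverse average-information matrix at the optimum;
  derived quantities (h², D/A ratio, b per 10%) get delta-method SEs from
  the full covariance of the variance components.
- Model choice: `AIC = −2 logL_restricted + 2k`, `k` = number of estimated
  (co)variance components; ties in the comparison table keep the stable
  order A, G, GD.

## 3. SNP effects and mating prediction

Given variance components, a single mixed-model solve estimates per-SNP
additive effects `a` (gene-content coding 1/0/−1, missing → `p − q`),
apparent dominance effects `d*` (heterozygosity coding 0/1/0, missing →
`2pq`) and the depression slope `b` (on `f`). Shrinkage variances convert
from the genetic scale:

```
σ²_d = σ²_D / Σ(2pq)²          σ²_a = [σ²_A − Σ 2pq (q−p)² σ²_d] / Σ 2pq
```

The genuine dominance effect restores the part absorbed by the `f`
regression: `d = d* − b/m` (`m` = SNP count). Substitution effects are
`α = a + d(q − p)`; `GEBV_i = Σ (count_ik − 2p_k) α_k`.

For a candidate sire × dam pair, per-locus transmission probabilities
`τ = count/2` give progeny genotype probabilities `P(AA) = τ_s τ_d`,
`P(aa) = (1−τ_s)(1−τ_d)`, `P(Aa)` the remainder. Summing over loci yields
the expected progeny breeding value `û` (algebraically the parental GEBV
average when genotypes are complete) and total genetic value
`ĝ = Σ P(AA)a + P(Aa)d − P(aa)a`; loci with a missing parental call are
skipped. The whole boar × sow grid is computed with masked matrix products.

## 4. Allocation

The mating set solves an integer linear program: maximize (or minimize, for
lower-is-better traits) the summed expected progeny value subject to at most
`boar_capacity` sows per boar, at most one boar per sow, and exactly
`n_matings` matings. The constraint matrix is a transportation structure
(totally unimodular), so the LP optimum is integral; `scipy.optimize.milp`
(HiGHS) solves it exactly. A microscopic ramp (`1e-9` of the value scale)
over the flattened grid breaks ties deterministically in favor of
lexicographically early (boar, sow) pairs; the reported objective is
recomputed from the unperturbed values. Plans are audited by
`ΔU = mean û(selected) − mean û(all candidates)` (likewise ΔG), also
reported in additive-SD units (÷ √σ²_A).

## 5. Data generator: scope and realism

`simdata` produces one discrete generation: unrelated founders in
Hardy–Weinberg equilibrium (allele frequencies uniform in `maf_range`),
random boar-per-litter matings, full-sib litters by Mendelian gamete
sampling, and phenotypes from true per-SNP effects
(`a_k ~ N(0, σ²_a)`; `d_k = −b/m +` centered Gaussian noise, so directional
dominance reproduces the inbreeding-depression slope exactly in the sample).
Deliberately **not** modeled: linkage (SNPs segregate independently),
selection, multiple overlapping generations, genotyping-platform error
patterns, maternal effects. These omissions are irrelevant to the estimators
under test — which condition only on observed genotypes — but mean the
generator understates the LD structure of real pig data. The QC fixture
plants exact, attributable defects (low-call SNPs and animals, low-MAF and
HWE-violating SNPs, Mendelian-inconsistent offspring) into an otherwise
clean panel constructed to pass every filter with margin.

### Default parameters (SimConfig)

| parameter | default | units / meaning |
|---|---|---|
| n_boars / n_sows | 100 / 300 | founder counts |
| piglets_per_litter | 10 | full sibs per litter |
| m_snps | 500 | SNP count |
| maf_range | (0.05, 0.5) | founder allele-frequency range |
| sigma2_A / sigma2_D / sigma2_e | 16.26 / 3.31 / 42.80 | squared trait units (an age-at-100kg-like trait, days²) |
| inb_depression_b | 42.9 | trait units per unit f (= 4.29 per 10%) |
| n_fixed_levels / sigma2_fixed | 20 / 5.0 | batch levels and their variance |
| blend weight w | 0.95 | persisted dense G*/D* |
| QC thresholds | call rate 0.98, MAF 0.05, HWE α 0.05, conflict rate 0.02 | |
| allocation | 600 matings, capacity 15, preselect 120 boars | pipeline defaults |

All randomness flows through named, CRC-derived substreams of a single seed,
so adding records never perturbs founder genotypes.

## 6. Numerical choices

- Problem sizes in tests (300–3400 animals, 150–1000 SNPs, 20 replicates)
  are package choices balancing statistical resolution against a
  single-CPU time budget; the estimators contain no size-dependent logic.
- The unblended `G` from observed-frequency centering is singular
  (`1′M = 0`), so the GBLUP↔SNP-BLUP equivalence is verified through the
  variance-route BLUP `û = σ²_A G V⁻¹(y − Xβ̂)`, which needs no `G` inverse.
- Cholesky factorizations everywhere; the MME cross-products are built once
  per fit and only the shrinkage diagonal is refreshed per REML iteration.
- Reproducibility: identical seeds give identical output bytes on one
  platform; across BLAS builds results agree to ≥10 significant digits.
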