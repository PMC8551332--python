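# Methods

This note documents the models, algorithms, numerical choices, and known
limitations of `purgekit`. It states no empirical result beyond what the
test suite and `scripts/acceptance.py` themselves compute.

## Pedigree coefficients

A studbook is a list of individuals with possibly unknown sire/dam links;
wild-born animals with both parents unknown are unrelated founders.
Pedigrees are validated (unique ids, resolvable parents, acyclicity — a
cycle is reported with one offending path) and stored in topological
order, so all coefficients are single forward passes.

* **F** (Wright): tabular kinship method, `f(i,j) = [f(s_i,j)+f(d_i,j)]/2`,
  self-term `f(a,a) = (1+F_a)/2`; `F_i` is the kinship of i's parents, 0 if
  either is unknown. O(N²) time and memory — ample for studbook scale
  (thousands).
* **EqG** (equivalent complete generations): `Σ (1/2)^n` over known
  ancestors, one term per distinct path, computed by the recursion
  `EqG_i = (1+EqG_s)/2 + (1+EqG_d)/2` with unknown parents contributing
  nothing.
* **%PC** (pedigree completeness): studbook reports rarely define this
  figure; we use the fraction of known parent links among individuals
  with at least one known parent (founders excluded from the
  denominator). MacCluer-style multi-generation completeness would be a
  reasonable alternative; the choice only affects a descriptive summary.
* **Pruning**: individuals of uncertain ancestry are removed together
  with all descendants (their inbreeding and accumulated purging would be
  understated). The operation is idempotent and closed under descent.
* Unparseable dates degrade to "unknown" with a logged warning rather
  than failing a whole studbook; individuals appearing only as parents
  are a hard error unless `insert_missing_parents=True`.

## Purged inbreeding

The purged inbreeding coefficient g represents E[F·q/q₀]: inbreeding
discounted by the decline of deleterious-allele frequency under purging,
governed by d = s(½−h) ∈ [0, 0.5] (negative d — reinforcing alleles — is
rejected, not clamped: the IP model does not cover it).

For an idealized panmictic population of effective size N:

    F_t = 1/2N + (1 − 1/2N) F_{t−1}
    g_t = [1/2N + (1 − 1/2N) g_{t−1}] · (1 − 2d F_{t−1})

whose fixed point (F → 1) is ĝ = (1−2d)/(1+2d(2N−1)); purging efficiency
is 1 − ĝ, increasing in dN. The approximation is intended for dN ≥ 1.

**Pedigree recursion.** Per-individual g follows a modified tabular
kinship: with D_i = 1 − 2d·F̄_p(i) (mean parental F, unknown → 0), each
new row of the purged-kinship table is formed as

    f_g(i,j) = √D_i · [f_g(s_i,j) + f_g(d_i,j)]/2
    g_i      = D_i · f_g(s_i, d_i)
    f_g(i,i) = (1 + g_i)/2

The placement of the discount is the one genuinely open design choice in
the whole package. The √D per row is one lineage's share of the
per-generation discount: a contemporary pair then accumulates the full
factor per generation, and the mean-field limit of the recursion over
idealized random-mating pedigrees reproduces the panmictic recursion
(and hence ĝ) exactly. Two simpler placements were considered and
rejected because their pedigree means diverge from the panmictic
recursion on simulated idealized populations: discounting only g_i (rows
undiscounted) under-purges badly, and discounting rows by the full D
over-purges. The adopted form is validated empirically (mean pedigree g
per generation within 3 Monte-Carlo SE of the recursion at N ∈ {10, 25},
30 generations, 60 replicates) and preserves the exact reductions:
g ≡ F bitwise at d = 0, g = F for the first inbred generation, g
non-increasing in d, 0 ≤ g ≤ F.

**t_m.** Expected ancestral inbreeding F_a = 1 − (1 − 1/2N)^{t(t−1)/2}
has its fastest growth at t_m = ½ + √(1/log(1+1/(2N−1))) ≈ √(2N) (or
√(2N)+1 without selfing, the default for the target species). It is a
heuristic minimum horizon: before t_m there has been little opportunity
for purging, so non-detection is uninformative.

## Demography

* **Target population**: individuals with EqG within 1.0 of the pedigree
  maximum (real-valued window — EqG is continuous in real studbooks) and
  both parents known.
* **Ne**: ΔF_i = 1 − (1−F_i)^{1/(EqG_i−1)} per TP individual;
  Ne = 1/(2·mean ΔF). TP members with EqG ≤ 1 have no defined rate and
  are excluded with a logged count. The standard error is delta-method
  from the SE of mean ΔF (SE(Ne) = SE/2ΔF̄²); a jackknife would be a
  drop-in alternative but the first-order form matches common practice.
  The exponent convention (EqG − 1) is calibrated for populations without
  selfing, where inbreeding lags one generation; the estimator is checked
  against dioecious idealized simulations (relative bias < 15% at
  N ≤ 25).
* **Founders**: contributions are expected genome proportions (probability
  of gene origin, halving per generation), averaged over the TP —
  deterministic, no gene-drop sampling. N_ef = 1/Σp²; it equals N_f iff
  contributions are balanced. A half-unknown parentage attributes the
  unknown half to the individual itself as a phantom partial founder so
  contributions always sum to 1 (never triggered in fully known
  pedigrees).
* **Cohort intervals**: width = recorded-year span / ceil(max EqG), the
  rule used for cohort summaries of survival and inbreeding trajectories.

## Trait preparation

Early survival W_S is 1 if the individual survived ≥ 15 days (individuals
lacking a death date are assumed to have survived the early period, since
early deaths are always recorded), 0 otherwise; accidental deaths inside
the window are not measurements and are dropped, as are founders (they
are survivors of an unobserved wild phase, not a random sample).
Productivity W_P counts pedigree offspring per female; females whose
reproductive window may extend past the record — born within W years of
the last recorded birth, W = floor of the 90th percentile
(linear-interpolation) of longevity — are excluded, as are females
without a death date.

## IP estimation

The mean model is W = W0·exp(−δ·g_self − δ_M·g_dam + β_S·x_S +
β_POM·x_POM + β_Y·yob_c). Factors act inside the exponent — this keeps
predictions positive and composes naturally with the load terms; an
additive placement would be an equally defensible reading, and the choice
is isolated behind `predict()`. YOB is centered at its mean to
decorrelate it from the intercept; POM and YOB are never included
together (they are strongly associated).

The objective is the residual sum of squares on the observed scale, also
for binary survival — a deliberate choice to match the established
estimation practice for this model rather than a logistic likelihood.
Consequences: logL = −(n/2)(ln(2πRSS/n)+1) is a Gaussian *working*
log-likelihood, and AICc = −2logL + 2k + 2k(k+1)/(n−k−1) (k counts W0, d
and every included term) and the LRT inherit its approximations.

Optimization: d is profiled on an 11-point grid over [0, 0.5] with
warm-started inner solves and Brent refinement (xatol 1e-3) around the
grid optimum; for each candidate d the g table is recomputed from the
pedigree (cached per rounded d and shared across runs, nested fits and
scans — this dominates cost). The inner problem solves the remaining
parameters by bounded trust-region least squares (δ, δ_M ≥ 0 — loads are
nonnegative by definition; boundary solutions are flagged since LRT
regularity degrades there) with W0 profiled analytically
(W0* = ΣWu/Σu², u = e^η — variable projection). `runs` independent
multi-starts draw random inner initializations; the best-RSS solution
wins and the run-to-run standard deviation of every estimate is reported
as a convergence diagnostic. A model without d uses d = 0, for which the
purged-inbreeding recursion returns F bit-for-bit, so "no purging" and
"d fixed at 0" are the identical objective.

**Likelihood-ratio tests.** `lrt()` refers 2ΔlogL (clipped at 0) to χ²
with df = parameter-count difference. When the dropped parameter lies on
the boundary of its space under the null — the purging test d = 0 with
d ∈ [0, 0.5], or a load test δ = 0 with δ ≥ 0 — the plain χ² reference is
conservative (the statistic is 0 with probability ~½), so those tests use
the Self–Liang 50:50 mixture of χ²_{df−1} and χ²_df, which keeps the size
at its nominal level; simulation places the empirical size at 0.05 in the
study regime. Software that applies the plain χ²(1) reference would
report p-values about twice ours for the same statistic.

## Synthetic data

`simulate_pedigree` emulates the studied breeding programs: a handful of
wild-caught founders (default 6, ~1 male : 2 females); yearly breeding
seasons over 30 years; available females (breeding ages 2–6, capped at a
facility carrying capacity) partitioned into harems of 5–8 and assigned a
male at random or by minimum mean coancestry with the harem; offspring
counts Poisson per female; newborn survival Bernoulli with
p = clamp(W0·e^{−δg−δ_M·g_dam+β_S·S+β_POM·POM}, 0, 1) evaluated at the
generating d — only survivors ever breed, which is where purging acts.
Default generating values follow the strongest-purging study population:
W0 = 0.95, δ = 0.67, δ_M = 0.66, β_S = −0.10, d = 0.48. The default
census parameters were calibrated once so the realized conditions match
the target regime (realized Ne ≈ 13–14, ~9–10 equivalent generations,
~1000 survival records; the "full regime" used by the recovery
experiments doubles the female cap for ~1700 records). Extinction is a
flagged result, not an exception; clamped survival probabilities are
counted.

What it does **not** emulate: age-specific fecundity, mid-record
management changes, transfers between institutions, pedigree errors, new
mutation, or environmental trends beyond the POM indicator. Passing
recovery tests therefore show the estimator works when the IP model is
the true generating process at studbook-like sample sizes — not that real
studbooks satisfy the model.

`simulate_idealized` provides constant-size Wright–Fisher pedigrees:
monoecious with selfing (the model underlying the panmictic recursions)
and dioecious without selfing (the model underlying the ΔF/EqG
machinery). `simulate_genic` is the independent oracle at the allele
level: diploid genotypes at L unlinked loci, multiplicative viability
(1, 1−hs, 1−s), uniform parent choice with replacement in constant N;
it verifies that mean q_t/q₀ tracks g_t/F_t (e.g. a recessive lethal at
N = 25 declines toward the ĝ = 0 asymptote; a neutral control stays at
1). The comparison allows 3 Monte-Carlo SE plus a 0.02 absolute band,
fixed a priori, because the IP prediction is itself a rare-allele
approximation.

Experiment drivers: `recovery_experiment` (bias, RMSE, LRT power and
size per condition cell) and `detection_horizon` (smallest generation
count — median max EqG — at which the median purging p-value falls below
α, per true d), with all randomness derived from one seed.

## Problem sizes and numerical conventions

Default experiment sizes (replicates, grid sizes, multi-start counts) are
chosen so each check has clear statistical resolution at desk scale:
recovery/power cells use 25–50 replicates with 3 multi-starts, the size
check 500 replicates with 2, the oracle comparisons 50–200 replicates.
Convergence tolerances: d refinement 1e-3 (grid step 0.05), inner least
squares ftol 1e-12, fixed-point checks 1e-6. Ties in AICc ranking break
toward fewer parameters. Degenerate inputs: empty pedigrees, empty
target populations and all-founder pedigrees raise informative errors;
mean ΔF = 0 reports Ne = ∞ with a warning.

## Known limitations

* The "full model" with non-purging selection and overdominance is out of
  scope; g assumes purging-type selection only.
* Least squares on binary survival is heteroskedastic; the Gaussian
  working likelihood makes AICc and LRT approximate (the boundary-mixture
  calibration is verified by simulation in the study regime only).
* Run-to-run SE measures optimizer stability, not sampling uncertainty;
  no bootstrap standard errors are provided.
* The founder-contribution treatment of half-known parentage (phantom
  partial founders) is a convention; alternatives redistribute the
  unknown share.
* Real-studbook estimates depend on data filters (location, accidental
  deaths, windows) that are supported but can only be validated against
  the original records.
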