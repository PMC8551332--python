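# purgekit

Inbreeding–purging analysis of pedigreed (studbook) populations.

Small captive populations of endangered species accumulate inbreeding,
which depresses fitness by exposing (partially) recessive deleterious
alleles in homozygosis — but that same exposure lets natural selection
remove them (**genetic purging**). `purgekit` implements the
inbreeding–purging (IP) toolkit needed to quantify this process from a
studbook: pedigree coefficients, demographic parameters, the minimum
number of generations before purging is detectable, and estimation of the
purging coefficient and inbreeding loads from individual fitness records.
A synthetic studbook/fitness generator and an individual-locus forward
simulator make every stage testable without external data.

## The model

The expected fitness of individual *i* is

```
W_i = W0 · exp(−δ·g_i − δ_M·g_dam(i) + β_S·S + β_POM·POM + β_Y·YOB_c)
```

* **F** — Wright's inbreeding coefficient (kinship of the parents).
* **g(d)** — the *purged* inbreeding coefficient: F discounted by the
  expected reduction in deleterious-allele frequency, g = E[F·q/q₀].
  It is computed from the pedigree by a tabular kinship recursion in which
  each generation of descent carries the purging discount `1 − 2d·F̄_p`
  (F̄_p = mean parental inbreeding), or for an idealized population of
  effective size N by the recursion
  `g_t = [1/2N + (1 − 1/2N)·g_{t−1}]·(1 − 2d·F_{t−1})`,
  whose fixed point is the asymptotic ratio
  `ĝ = (1 − 2d)/(1 + 2d(2N − 1))`; purging efficiency is `1 − ĝ`.
* **d = s(½ − h)** — the purging coefficient: the recessive component of a
  deleterious effect, 0 for additive gene action to 0.5 for a fully
  recessive lethal.
* **δ, δ_M** — inbreeding loads (haploid lethal equivalents) expressed
  through the individual's own and its mother's genotype.
* **t_m** — the generation at which expected ancestral inbreeding
  `F_a = 1 − (1 − 1/2N)^{t(t−1)/2}` grows fastest:
  `t_m = ½ + √(1/log(1 + 1/(2N−1)))`, approximately `√(2N) + 1` without
  self-fertilization. Detecting purging before t_m generations is
  unlikely.

Parameters are estimated by multi-start least squares with *d* profiled on
[0, 0.5] (the g table is recomputed from the pedigree for each candidate
d), and significance by likelihood-ratio tests (with the boundary-aware
χ² mixture when a bounded parameter is tested at 0). Demography follows
the overlapping-generation machinery: equivalent complete generations
EqG, realized effective size `Ne = 1/(2·mean ΔF)` with
`ΔF_i = 1 − (1 − F_i)^{1/(EqG_i−1)}`, and founder statistics
(N_ef = 1/Σp_k² over expected founder contributions).

## Worked example

```python
from purgekit import (SimConfig, simulate_pedigree, demography_report,
                      ModelSpec, fit_with_tests, t_m)

sim = simulate_pedigree(SimConfig(years=22, max_breeding_females=14,
                                  mean_offspring=1.9), seed=11)
rep = demography_report(sim.pedigree)
print(f"Ne = {rep.Ne:.2f}, N_ef = {rep.N_ef:.2f}, "
      f"t_m = {t_m(rep.Ne, 'no_selfing'):.2f}")

best = fit_with_tests(sim.traits, sim.pedigree,
                      ModelSpec(d=True, delta=True, delta_m=True, sex=True),
                      runs=10, seed=11)
print({k: round(v, 3) for k, v in best.estimates.items()}, round(best.p_d, 3))
```

prints

```
Ne = 13.48, N_ef = 4.68, t_m = 6.19
{'W0': 0.963, 'd': 0.374, 'delta': 0.11, 'delta_m': 0.996, 'beta_s': -0.142} 0.152
```

i.e. this 542-individual program has a realized effective size of ~13, an
effective number of founders of 4.7, and would need ≥ 6.2 generations of
records before purging could plausibly be detected; at its ~500 survival
records the purging coefficient (generated at d = 0.48) is recovered only
imprecisely (d̂ = 0.37, p = 0.15) — at 1500–2000 records the same
experiment recovers d within ±0.15 in >90% of replicates
(`analysis/05_detection_power.py`).

The numbered scripts under `analysis/` rebuild the full workflow
(synthetic studbook → demography → theoretical predictions → IP fit →
power/detectability) and write their tables under `results/`.

The command line mirrors the library:

```bash
purgekit coeffs --pedigree studbook.csv          # id,F,EqG
purgekit g --pedigree studbook.csv --d 0.48      # purged inbreeding
purgekit demog --pedigree studbook.csv --json
purgekit tm --n 14.01 --mode no_selfing
purgekit fit --pedigree studbook.csv --trait survival --runs 100 --seed 42
```

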