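"""Synthetic studbooks, idealized pedigrees, and a genic forward simulator.

Three generators with the statistical structure the analysis assumes:

* :func:`simulate_pedigree` -- a studbook-like captive population: a
  handful of wild-caught founders, polygynous harem breeding (one male per
  5-8 females, chosen at random or by minimum mean coancestry with his
  harem), overlapping yearly cohorts, and early survival drawn from the
  inbreeding-purging model itself (with maternal load and sex / period
  effects); only survivors breed, which is where purging acts.
* :func:`simulate_idealized` -- constant-size Wright-Fisher pedigrees
  (with or without selfing), the idealized populations behind the
  panmictic recursions and the Ne estimator.
* :func:`simulate_genic` -- an individual-based simulation of deleterious
  recessives at unlinked loci with multiplicative viability selection: the
  independent oracle for purged-inbreeding dynamics (g predicts E[q/q0]).

Plus the experiment drivers :func:`recovery_experiment` (parameter
recovery, type-I error, power) and :func:`detection_horizon` (generations
needed to detect purging as a function of d, compared with t_m).

All randomness flows from a single seed; identical seeds reproduce
pedigrees byte for byte.
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .demography import effective_size, select_target_population
from .ip_model import (
    GTableCache,
    IPFit,
    ModelSpec,
    fit,
    lrt,
    prepare_survival,
)
from .pedigree import Individual, Pedigree, equivalent_generations, inbreeding

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic studbook generator.

    Defaults emulate a captive ungulate program of the kind the analysis
    targets: few wild-caught founders, three decades of records, harems of
    5-8 females, roughly one offspring per female-year, and survival
    generated by the IP model with a strong purging coefficient and an
    overall inbreeding load (delta + delta_m) of about 1.3.
    """

    n_founders: int = 6
    years: int = 30
    harem_min: int = 5
    harem_max: int = 8
    mean_offspring: float = 2.1
    max_breeding_females: int = 18
    min_breeding_age: int = 2
    max_breeding_age: int = 6
    mean_longevity: float = 6.0
    start_year: int = 1975
    vet_year: int | None = 1993
    w0: float = 0.95
    delta: float = 0.67
    delta_m: float = 0.66
    beta_s: float = -0.10
    beta_pom: float = 0.0
    d_true: float = 0.48
    accident_prob: float = 0.01
    management: str = "random_mating"  # or "min_coancestry_males"
    location: str = "Almeria"

    def __post_init__(self) -> None:
        if self.n_founders < 2 or self.years < 1:
            raise ValueError("need at least two founders and one year")
        if not 0.0 <= self.d_true <= 0.5:
            raise ValueError("d_true must be in [0, 0.5]")
        if self.management not in ("random_mating", "min_coancestry_males"):
            raise ValueError(f"unknown management mode {self.management!r}")


@dataclass(frozen=True)
class GenicConfig:
    """Configuration of the individual-locus forward simulator."""

    L: int = 100
    q0: float = 0.05
    s: float = 1.0
    h: float = 0.0
    N: int = 25
    generations: int = 30

    def __post_init__(self) -> None:
        if not 0.0 < self.q0 < 1.0:
            raise ValueError("q0 must be in (0, 1)")
        if not 0.0 <= self.s <= 1.0 or not 0.0 <= self.h <= 0.5:
            raise ValueError("need s in [0, 1] and h in [0, 1/2]")


# ---------------------------------------------------------------------------
# incremental kinship bookkeeping
# ---------------------------------------------------------------------------

class _GrowingKinship:
    """Kinship and purged-kinship matrices grown one individual at a time."""

    def __init__(self, d: float, capacity: int = 512):
        self.d = d
        self.K = np.zeros((capacity, capacity))
        self.Kg = np.zeros((capacity, capacity))
        self.F = np.zeros(capacity)
        self.g = np.zeros(capacity)
        self.n = 0

    def _ensure(self) -> None:
        if self.n < self.K.shape[0]:
            return
        cap = self.K.shape[0] * 2
        for name in ("K", "Kg"):
            old = getattr(self, name)
            new = np.zeros((cap, cap))
            new[: self.n, : self.n] = old[: self.n, : self.n]
            setattr(self, name, new)
        for name in ("F", "g"):
            old = getattr(self, name)
            new = np.zeros(cap)
            new[: self.n] = old[: self.n]
            setattr(self, name, new)

    def add_founder(self) -> int:
        self._ensure()
        i = self.n
        self.K[i, i] = 0.5
        self.Kg[i, i] = 0.5
        self.n += 1
        return i

    def add(self, s: int, d_: int) -> int:
        self._ensure()
        i = self.n
        row = 0.5 * (self.K[s, :i] + self.K[d_, :i])
        self.K[i, :i] = row
        self.K[:i, i] = row
        f_i = self.K[s, d_]
        self.F[i] = f_i
        self.K[i, i] = 0.5 * (1.0 + f_i)
        D_i = 1.0 - self.d * (self.F[s] + self.F[d_])
        rowg = 0.5 * (self.Kg[s, :i] + self.Kg[d_, :i])
        if D_i != 1.0:
            rowg *= math.sqrt(D_i)
        self.Kg[i, :i] = rowg
        self.Kg[:i, i] = rowg
        g_i = D_i * self.Kg[s, d_]
        self.g[i] = g_i
        self.Kg[i, i] = 0.5 * (1.0 + g_i)
        self.n += 1
        return i


# ---------------------------------------------------------------------------
# studbook simulator
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    """A simulated studbook with its generating coefficients."""

    pedigree: Pedigree
    traits: pd.DataFrame
    F: pd.Series = field(repr=False)
    g: pd.Series = field(repr=False)
    extinct: bool = False
    n_clamped: int = 0
    config: SimConfig | None = None


def simulate_pedigree(cfg: SimConfig, seed: int | None = None) -> SimResult:
    """Simulate a studbook pedigree plus early-survival trait records.

    Each breeding season the available females (capped at the facility's
    carrying capacity) are partitioned into harems of 5-8 and assigned a
    breeding male -- at random, or minimizing his mean coancestry with the
    harem under ``min_coancestry_males`` management.  Offspring counts are
    Poisson per female; every newborn survives its first 15 days with
    probability clamp(W0 exp(-delta g - delta_m g_dam + beta_S x_S +
    beta_POM x_POM), 0, 1) evaluated at the generating purging coefficient
    ``d_true``, and only survivors ever breed.  Extinction is flagged on
    the result, not raised.
    """
    rng = np.random.default_rng(seed)
    kin = _GrowingKinship(cfg.d_true)
    sex: list[str] = []
    birth_year: list[int] = []
    death_time: list[float] = []  # years since start; inf = beyond record
    records: list[Individual] = []
    n_clamped = 0
    end_time = float(cfg.years)

    def _register(ind: Individual) -> None:
        records.append(ind)

    def _birth_date(year: int) -> _dt.date:
        month = int(rng.integers(1, 13))
        day = int(rng.integers(1, 28))
        return _dt.date(cfg.start_year + year, month, day)

    # founders arrive in year 0, already adult; roughly 1 male : 2 females
    n_males = max(1, cfg.n_founders // 3)
    for i in range(cfg.n_founders):
        idx = kin.add_founder()
        sx = "M" if i < n_males else "F"
        sex.append(sx)
        birth_year.append(-cfg.min_breeding_age)
        lifespan = max(2.0, rng.normal(cfg.mean_longevity, 2.0))
        death_time.append(lifespan - cfg.min_breeding_age)
        bdate = _dt.date(cfg.start_year - cfg.min_breeding_age, 1, 1)
        dtime = death_time[idx]
        ddate = (
            None
            if dtime >= end_time
            else bdate + _dt.timedelta(days=int((dtime - birth_year[idx]) * 365.25))
        )
        _register(
            Individual(
                id=f"I{idx + 1:05d}",
                sex=sx,
                birth_date=bdate,
                death_date=ddate,
                location=cfg.location,
            )
        )

    for year in range(cfg.years):
        mid = year + 0.5
        alive = [
            i
            for i in range(kin.n)
            if death_time[i] > mid
            and cfg.min_breeding_age <= year - birth_year[i] <= cfg.max_breeding_age
        ]
        females = [i for i in alive if sex[i] == "F"]
        males = [i for i in alive if sex[i] == "M"]
        if not females or not males:
            continue
        rng.shuffle(females)
        females = females[: cfg.max_breeding_females]

        harems: list[list[int]] = []
        pos = 0
        while pos < len(females):
            size = int(rng.integers(cfg.harem_min, cfg.harem_max + 1))
            harems.append(females[pos : pos + size])
            pos += size

        male_pool = list(males)
        rng.shuffle(male_pool)
        for harem in harems:
            if not male_pool:
                male_pool = list(males)
                rng.shuffle(male_pool)
            if cfg.management == "min_coancestry_males":
                mean_kin = [kin.K[m, harem].mean() for m in male_pool]
                chosen = int(np.argmin(mean_kin))
            else:
                chosen = 0
            sire = male_pool.pop(chosen)
            for dam in harem:
                for _ in range(rng.poisson(cfg.mean_offspring)):
                    idx = kin.add(sire, dam)
                    child_sex = "M" if rng.random() < 0.5 else "F"
                    x_s = 1.0 if child_sex == "M" else 0.0
                    x_pom = (
                        1.0
                        if cfg.vet_year is not None
                        and cfg.start_year + year >= cfg.vet_year
                        else 0.0
                    )
                    eta = (
                        -cfg.delta * kin.g[idx]
                        - cfg.delta_m * kin.g[dam]
                        + cfg.beta_s * x_s
                        + cfg.beta_pom * x_pom
                    )
                    p = cfg.w0 * math.exp(eta)
                    if p > 1.0 or p < 0.0:
                        n_clamped += 1
                        p = min(1.0, max(0.0, p))
                    bdate = _birth_date(year)
                    accidental = rng.random() < cfg.accident_prob
                    survives = (not accidental) and rng.random() < p
                    if survives:
                        lifespan = max(1.0, rng.normal(cfg.mean_longevity, 2.0))
                        dtime = year + lifespan
                        ddate = (
                            None
                            if dtime >= end_time
                            else bdate + _dt.timedelta(days=int(lifespan * 365.25))
                        )
                    else:
                        dtime = year + 0.01
                        ddate = bdate + _dt.timedelta(days=int(rng.integers(0, 15)))
                    sex.append(child_sex)
                    birth_year.append(year)
                    death_time.append(dtime)
                    _register(
                        Individual(
                            id=f"I{idx + 1:05d}",
                            sire=records[sire].id,
                            dam=records[dam].id,
                            sex=child_sex,
                            birth_date=bdate,
                            death_date=ddate,
                            location=cfg.location,
                            accidental_death=accidental,
                        )
                    )

    ped = Pedigree(records)
    final = cfg.years - 0.5
    extinct = not any(
        death_time[i] > final and cfg.years - birth_year[i] <= cfg.max_breeding_age + 1
        for i in range(kin.n)
    )
    traits = prepare_survival(ped, vet_year=cfg.vet_year)
    ids = [records[i].id for i in range(kin.n)]
    if n_clamped:
        logger.info("simulate_pedigree: clamped %d survival probabilities", n_clamped)
    return SimResult(
        pedigree=ped,
        traits=traits,
        F=pd.Series(kin.F[: kin.n], index=ids, name="F"),
        g=pd.Series(kin.g[: kin.n], index=ids, name="g"),
        extinct=extinct,
        n_clamped=n_clamped,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# idealized Wright-Fisher pedigrees
# ---------------------------------------------------------------------------

def simulate_idealized(
    N: int,
    generations: int,
    *,
    selfing: bool = True,
    seed: int | None = None,
) -> Pedigree:
    """Constant-size Wright-Fisher pedigree over discrete generations.

    With ``selfing=True`` each offspring draws two parents uniformly with
    replacement (the idealized monoecious population whose inbreeding
    follows F_t = 1/2N + (1 - 1/2N) F_{t-1} exactly).  With
    ``selfing=False`` the population is split into N/2 sires and N/2 dams
    per generation, the idealized dioecious population for which the
    per-generation rate-of-inbreeding machinery (exponent 1/(EqG-1)) is
    calibrated.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    rng = np.random.default_rng(seed)
    records: list[Individual] = []
    half = N // 2

    def _id(t: int, i: int) -> str:
        return f"G{t:03d}_{i:04d}"

    def _sex(i: int) -> str:
        return "M" if i < half else "F"

    prev = []
    for i in range(N):
        records.append(
            Individual(
                id=_id(0, i),
                sex="U" if selfing else _sex(i),
                birth_date=_dt.date(2000, 1, 1),
            )
        )
        prev.append(_id(0, i))
    for t in range(1, generations + 1):
        current = []
        for i in range(N):
            if selfing:
                s, d = rng.integers(0, N, size=2)
            else:
                s = rng.integers(0, half)
                d = rng.integers(half, N)
            records.append(
                Individual(
                    id=_id(t, i),
                    sire=prev[int(s)],
                    dam=prev[int(d)],
                    sex="U" if selfing else _sex(i),
                    birth_date=_dt.date(2000 + t, 1, 1),
                )
            )
            current.append(_id(t, i))
        prev = current
    return Pedigree(records)


def generation_of(ped: Pedigree) -> pd.Series:
    """Generation index encoded in idealized-pedigree ids (G###_####)."""
    return pd.Series({ind.id: int(ind.id[1:4]) for ind in ped}, name="generation")


# ---------------------------------------------------------------------------
# genic forward simulator
# ---------------------------------------------------------------------------

@dataclass
class GenicResult:
    """Trajectories from the individual-locus simulator."""

    q: np.ndarray  # mean deleterious frequency per generation, 0..T
    mean_fitness: np.ndarray
    pedigree: Pedigree | None = None

    @property
    def q_ratio(self) -> np.ndarray:
        """Mean q_t / q_0 relative to the realized founder frequency."""
        return self.q / self.q[0]


def simulate_genic(
    cfg: GenicConfig, seed: int | None = None, record_pedigree: bool = False
) -> GenicResult:
    """Wright-Fisher simulation of deleterious recessives under viability selection.

    Diploid genotypes at L unlinked loci; fitness is multiplicative across
    loci with genotype weights (1, 1-hs, 1-s); each generation, parent
    pairs are drawn uniformly with replacement (selfing allowed, matching
    the idealized population of the asymptotic-g prediction) and offspring
    are accepted with probability equal to their viability until N
    survivors are recruited.
    """
    rng = np.random.default_rng(seed)
    N, L = cfg.N, cfg.L
    geno = rng.binomial(2, cfg.q0, size=(N, L))
    if geno.sum() == 0:
        geno[0, 0] = 1  # guarantee a nonzero founder frequency
    q = [geno.mean() / 2.0]
    fitness = []
    log_whom = math.log(1.0 - cfg.s) if cfg.s < 1.0 else -math.inf
    log_whet = math.log(1.0 - cfg.h * cfg.s)
    ped_records: list[Individual] = []
    parent_ids = None
    if record_pedigree:
        parent_ids = [f"T000_{i:04d}" for i in range(N)]
        ped_records = [
            Individual(id=i, birth_date=_dt.date(2000, 1, 1)) for i in parent_ids
        ]
    for t in range(1, cfg.generations + 1):
        children = np.empty((0, L), dtype=np.int64)
        child_parents: list[tuple[int, int]] = []
        w_sum, w_n = 0.0, 0
        while children.shape[0] < N:
            m = 4 * N
            sires = rng.integers(0, N, size=m)
            dams = rng.integers(0, N, size=m)
            gam_s = rng.binomial(1, geno[sires] / 2.0)
            gam_d = rng.binomial(1, geno[dams] / 2.0)
            child = gam_s + gam_d
            n_hom = (child == 2).sum(axis=1)
            n_het = (child == 1).sum(axis=1)
            if cfg.s < 1.0:
                logw = n_hom * log_whom + n_het * log_whet
                w = np.exp(logw)
            else:
                w = np.where(n_hom > 0, 0.0, np.exp(n_het * log_whet))
            w_sum += float(w.sum())
            w_n += m
            accept = rng.random(m) < w
            children = np.vstack([children, child[accept]])
            if record_pedigree:
                child_parents.extend(
                    zip(sires[accept].tolist(), dams[accept].tolist())
                )
        geno = children[:N]
        if record_pedigree:
            new_ids = [f"T{t:03d}_{i:04d}" for i in range(N)]
            for i, (s, d) in enumerate(child_parents[:N]):
                ped_records.append(
                    Individual(
                        id=new_ids[i],
                        sire=parent_ids[s],
                        dam=parent_ids[d],
                        birth_date=_dt.date(2000 + t, 1, 1),
                    )
                )
            parent_ids = new_ids
        q.append(geno.mean() / 2.0)
        fitness.append(w_sum / w_n)
    return GenicResult(
        q=np.array(q),
        mean_fitness=np.array(fitness),
        pedigree=Pedigree(ped_records) if record_pedigree else None,
    )


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def _child_seeds(seed: int | None, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def recovery_experiment(
    cells: Mapping[str, SimConfig],
    replicates: int = 20,
    seed: int | None = None,
    *,
    fit_spec: ModelSpec = ModelSpec(d=True, delta=True, delta_m=True, sex=True),
    runs: int = 3,
    d_grid: int = 11,
    refine: bool = True,
) -> pd.DataFrame:
    """Simulate each cell, fit the IP model, and tabulate recovery per replicate.

    Returns one row per (cell, replicate) with true and estimated
    parameters and the LRT p-value for purging (full fit against the same
    model with d = 0).  Extinct replicates are recorded with NaN
    estimates.  Use :func:`summarize_recovery` for bias / RMSE / power.
    """
    rows = []
    cell_names = list(cells)
    seeds = _child_seeds(seed, len(cell_names) * replicates)
    k = 0
    reduced_spec = ModelSpec(
        d=False,
        delta=fit_spec.delta,
        delta_m=fit_spec.delta_m,
        sex=fit_spec.sex,
        pom=fit_spec.pom,
        yob=fit_spec.yob,
    )
    for name in cell_names:
        cfg = cells[name]
        for rep in range(replicates):
            s = seeds[k]
            k += 1
            row = {
                "cell": name,
                "rep": rep,
                "d_true": cfg.d_true,
                "delta_true": cfg.delta,
                "delta_m_true": cfg.delta_m,
            }
            sim = simulate_pedigree(cfg, seed=s)
            row["extinct"] = sim.extinct
            if sim.extinct or len(sim.traits) <= fit_spec.k + 2:
                rows.append(row)
                continue
            cache = GTableCache(sim.pedigree)
            full = fit(
                sim.traits,
                sim.pedigree,
                fit_spec,
                runs=runs,
                seed=s,
                d_grid=d_grid,
                refine=refine,
                cache=cache,
            )
            reduced = fit(
                sim.traits,
                sim.pedigree,
                reduced_spec,
                runs=runs,
                seed=s,
                d_grid=d_grid,
                refine=refine,
                cache=cache,
            )
            row.update(
                {
                    "n": full.n,
                    "d_hat": full.estimates.get("d", 0.0),
                    "delta_hat": full.estimates.get("delta", np.nan),
                    "delta_m_hat": full.estimates.get("delta_m", np.nan),
                    "w0_hat": full.estimates["W0"],
                    "rss": full.rss,
                    "p_d": lrt(full, reduced, boundary=True),
                }
            )
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_recovery(df: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-cell bias, RMSE, detection power, and recovery rate for d."""
    out = []
    for name, sub in df.groupby("cell"):
        ok = sub.dropna(subset=["d_hat"])
        if len(ok) == 0:
            continue
        err = ok["d_hat"] - ok["d_true"]
        out.append(
            {
                "cell": name,
                "replicates": len(sub),
                "analyzed": len(ok),
                "d_true": float(ok["d_true"].iloc[0]),
                "bias_d": float(err.mean()),
                "rmse_d": float(np.sqrt((err**2).mean())),
                "frac_d_within_015": float((err.abs() <= 0.15).mean()),
                "bias_delta": float((ok["delta_hat"] - ok["delta_true"]).mean()),
                "power": float((ok["p_d"] < alpha).mean()),
            }
        )
    return pd.DataFrame(out)


def truncate_pedigree(ped: Pedigree, max_birth_year: int) -> Pedigree:
    """Restrict a pedigree to individuals born up to ``max_birth_year``.

    Parents are always born before offspring, so the truncation is closed
    under parent links; undated individuals (founders) are kept.
    """
    keep = [
        ind
        for ind in ped
        if ind.birth_year is None or ind.birth_year <= max_birth_year
    ]
    return Pedigree(keep)


def detection_horizon(
    cfg: SimConfig,
    d_values: Sequence[float],
    horizons: Sequence[int],
    replicates: int = 10,
    seed: int | None = None,
    *,
    alpha: float = 0.05,
    fit_spec: ModelSpec = ModelSpec(d=True, delta=True, delta_m=True, sex=True),
    runs: int = 2,
    d_grid: int = 11,
) -> pd.DataFrame:
    """Generations needed before purging becomes detectable, per true d.

    For each d and each horizon (years of records kept), the full-length
    simulation is truncated and refit; a cell counts as detected when the
    median LRT p-value across replicates falls below ``alpha``.  The
    ``generations`` column reports the median maximum EqG at that horizon,
    the scale on which t_m is expressed.
    """
    rows = []
    seeds = _child_seeds(seed, len(d_values) * replicates)
    reduced_spec = ModelSpec(
        d=False,
        delta=fit_spec.delta,
        delta_m=fit_spec.delta_m,
        sex=fit_spec.sex,
        pom=fit_spec.pom,
        yob=fit_spec.yob,
    )
    k = 0
    for d_true in d_values:
        cell_cfg = replace(cfg, d_true=float(d_true), years=max(horizons))
        sims = []
        for rep in range(replicates):
            sims.append(simulate_pedigree(cell_cfg, seed=seeds[k]))
            k += 1
        for horizon in horizons:
            cutoff = cfg.start_year + horizon - 1
            p_values, gens = [], []
            for sim in sims:
                if sim.extinct:
                    continue
                sub = truncate_pedigree(sim.pedigree, cutoff)
                traits = prepare_survival(sub, vet_year=cell_cfg.vet_year)
                if len(traits) <= fit_spec.k + 2:
                    continue
                cache = GTableCache(sub)
                full = fit(
                    sub_traits := traits,
                    sub,
                    fit_spec,
                    runs=runs,
                    seed=seeds[k - 1],
                    d_grid=d_grid,
                    refine=False,
                    cache=cache,
                )
                reduced = fit(
                    sub_traits,
                    sub,
                    reduced_spec,
                    runs=runs,
                    seed=seeds[k - 1],
                    d_grid=d_grid,
                    refine=False,
                    cache=cache,
                )
                p_values.append(lrt(full, reduced, boundary=True))
                gens.append(float(equivalent_generations(sub).max()))
            if not p_values:
                continue
            rows.append(
                {
                    "d_true": float(d_true),
                    "horizon_years": horizon,
                    "generations": float(np.median(gens)),
                    "median_p": float(np.median(p_values)),
                    "detected": bool(np.median(p_values) < alpha),
                    "replicates": len(p_values),
                }
            )
    return pd.DataFrame(rows)


def detection_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Smallest generation count with detection per d (NaN when censored)."""
    out = []
    for d_true, sub in df.groupby("d_true"):
        detected = sub[sub["detected"]]
        out.append(
            {
                "d_true": float(d_true),
                "detection_generation": float(detected["generations"].min())
                if len(detected)
                else np.nan,
            }
        )
    return pd.DataFrame(out)


def realized_breeding_numbers(ped: Pedigree, window_years: int) -> pd.DataFrame:
    """Distinct sires/dams per window of births, with 4NmNf/(Nm+Nf).

    A demographic yardstick for the pedigree-based Ne estimate on
    simulated studbooks: windows of roughly one generation are scanned and
    the classical unequal-sex-ratio effective number computed per window.
    """
    rows = []
    years = [ind.birth_year for ind in ped if ind.birth_year is not None and not ind.is_founder]
    if not years:
        return pd.DataFrame(columns=["start", "Nm", "Nf", "Ne_demo"])
    start, last = min(years), max(years)
    while start <= last:
        sires = set()
        dams = set()
        for ind in ped:
            if (
                ind.birth_year is not None
                and start <= ind.birth_year < start + window_years
            ):
                if ind.sire:
                    sires.add(ind.sire)
                if ind.dam:
                    dams.add(ind.dam)
        if sires and dams:
            nm, nf = len(sires), len(dams)
            rows.append(
                {"start": start, "Nm": nm, "Nf": nf, "Ne_demo": 4.0 * nm * nf / (nm + nf)}
            )
        start += window_years
    return pd.DataFrame(rows)
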