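"""Inbreeding-purging (IP) model: trait preparation and parameter estimation.

The expected fitness of individual i under the IP model is

    W_i = W0 * exp(-delta * g_i - delta_M * g_dam(i)
                   + beta_S * x_S + beta_POM * x_POM + beta_Y * yob_c)

where g is the purged inbreeding coefficient at purging strength d
(:func:`purgekit.purging.purged_inbreeding`), delta is the inbreeding load
expressed through the individual's own genotype (haploid lethal
equivalents), delta_M the load expressed through the mother's genotype,
and S / POM / YOB are a male-sex indicator, a period-of-management
indicator (regular veterinary care), and the centered year of birth.
Factors act in the exponent so predictions stay positive and compose with
the load terms.

Estimation minimizes the residual sum of squares between observed and
expected fitness -- including for the binary survival trait, matching
standard practice for this model -- with d profiled on [0, 0.5] (the g
table is recomputed from the pedigree for each candidate d) and the
remaining parameters found by bounded least squares from multiple random
starts.  A Gaussian working likelihood based on the RSS supplies logL,
AICc and likelihood-ratio tests.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .pedigree import Pedigree, PedigreeError, inbreeding
from .purging import purged_kinship_matrix

logger = logging.getLogger(__name__)

TRAIT_COLUMNS = ["W", "x_S", "x_POM", "yob", "dam_id"]


# ---------------------------------------------------------------------------
# trait preparation
# ---------------------------------------------------------------------------

def _eligible(ped: Pedigree, location: str | None):
    for ind in ped:
        if ind.is_founder:
            # founders are survivors of an unobserved wild phase, not a
            # random sample; their trait values are treated as unknown
            continue
        if location is not None and ind.location != location:
            continue
        yield ind


def prepare_survival(
    ped: Pedigree,
    location: str | None = None,
    vet_year: int | None = None,
    survival_days: int = 15,
) -> pd.DataFrame:
    """Early-survival trait table (W_S: surviving ``survival_days`` days).

    Rules: individuals without a death date are assumed to have survived
    the early period (early deaths are always recorded), accidental deaths
    inside the early period are not trait measurements and are dropped,
    founders are dropped, and rows without a birth date are dropped with a
    logged count.
    """
    rows = []
    n_undated = 0
    for ind in _eligible(ped, location):
        if ind.birth_date is None:
            n_undated += 1
            continue
        if ind.death_date is None:
            w = 1.0
        else:
            age_days = (ind.death_date - ind.birth_date).days
            if age_days < survival_days and ind.accidental_death:
                continue
            w = 1.0 if age_days >= survival_days else 0.0
        rows.append(_trait_row(ind, w, vet_year))
    if n_undated:
        logger.info("prepare_survival: dropped %d rows without birth date", n_undated)
    return _trait_frame(rows)


def longevity_window(ped: Pedigree, q: float = 0.90) -> int:
    """Rounded-down q-quantile of longevity (years), linear interpolation.

    Used to exclude females that were still expected to breed by the end
    of the record from the productivity analysis.
    """
    spans = [
        (ind.death_date - ind.birth_date).days / 365.25
        for ind in ped
        if ind.birth_date is not None and ind.death_date is not None
    ]
    if not spans:
        raise PedigreeError("no individuals with both birth and death dates")
    return math.floor(float(np.percentile(spans, 100 * q, method="linear")))


def prepare_productivity(
    ped: Pedigree,
    location: str | None = None,
    vet_year: int | None = None,
    window_years: int | None = None,
) -> pd.DataFrame:
    """Lifetime female productivity table (W_P: offspring count per female).

    Only females with completed reproductive windows qualify: those born
    within ``window_years`` of the last recorded birth year are excluded
    (default window: rounded-down 90th percentile of longevity).  Females
    without a death date are excluded for the same reason.  Founders are
    excluded.
    """
    if window_years is None:
        window_years = longevity_window(ped)
    birth_years = [ind.birth_year for ind in ped if ind.birth_year is not None]
    if not birth_years:
        raise PedigreeError("no individuals with known birth dates")
    last_year = max(birth_years)
    n_offspring: dict[str, int] = {}
    for ind in ped:
        if ind.dam is not None:
            n_offspring[ind.dam] = n_offspring.get(ind.dam, 0) + 1
    rows = []
    for ind in _eligible(ped, location):
        if ind.sex != "F" or ind.birth_year is None:
            continue
        if ind.death_date is None:
            continue
        if last_year - ind.birth_year < window_years:
            continue
        rows.append(_trait_row(ind, float(n_offspring.get(ind.id, 0)), vet_year))
    if not rows:
        raise PedigreeError("no eligible females for productivity analysis")
    return _trait_frame(rows)


def _trait_row(ind, w: float, vet_year: int | None) -> dict:
    return {
        "id": ind.id,
        "W": w,
        "x_S": 1.0 if ind.sex == "M" else 0.0,
        "x_POM": 1.0
        if (vet_year is not None and ind.birth_year is not None and ind.birth_year >= vet_year)
        else 0.0,
        "yob": float(ind.birth_year) if ind.birth_year is not None else np.nan,
        "dam_id": ind.dam,
    }


def _trait_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["id"] + TRAIT_COLUMNS)
    return df.set_index("id")


# ---------------------------------------------------------------------------
# model specification and prediction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Which IP parameters and factors a model includes.

    ``delta`` must be included whenever ``d`` is (purging without a load is
    meaningless), and ``pom``/``yob`` are mutually exclusive (they are
    strongly associated in real studbooks).
    """

    d: bool = True
    delta: bool = True
    delta_m: bool = False
    sex: bool = False
    pom: bool = False
    yob: bool = False

    def __post_init__(self) -> None:
        if self.d and not self.delta:
            raise ValueError("a model with d must also estimate delta")
        if self.pom and self.yob:
            raise ValueError("POM and YOB are never considered together")

    @property
    def theta_names(self) -> tuple[str, ...]:
        names = []
        if self.delta:
            names.append("delta")
        if self.delta_m:
            names.append("delta_m")
        if self.sex:
            names.append("beta_s")
        if self.pom:
            names.append("beta_pom")
        if self.yob:
            names.append("beta_yob")
        return tuple(names)

    @property
    def k(self) -> int:
        """Number of estimated parameters (W0 plus every included term)."""
        return 1 + int(self.d) + len(self.theta_names)

    def nested_in(self, other: "ModelSpec") -> bool:
        return all(
            (not getattr(self, f)) or getattr(other, f)
            for f in ("d", "delta", "delta_m", "sex", "pom", "yob")
        )


def predict(
    params: dict,
    g_self,
    g_dam,
    x_s=0.0,
    x_pom=0.0,
    yob_c=0.0,
):
    """Expected fitness under the IP model for given parameter values.

    ``params`` maps parameter names (``W0``, ``delta``, ``delta_m``,
    ``beta_s``, ``beta_pom``, ``beta_yob``) to values; missing entries are
    treated as 0 (``W0`` defaults to 1).
    """
    eta = (
        -params.get("delta", 0.0) * np.asarray(g_self, dtype=float)
        - params.get("delta_m", 0.0) * np.asarray(g_dam, dtype=float)
        + params.get("beta_s", 0.0) * np.asarray(x_s, dtype=float)
        + params.get("beta_pom", 0.0) * np.asarray(x_pom, dtype=float)
        + params.get("beta_yob", 0.0) * np.asarray(yob_c, dtype=float)
    )
    return params.get("W0", 1.0) * np.exp(eta)


# ---------------------------------------------------------------------------
# purged-inbreeding cache and the least-squares objective
# ---------------------------------------------------------------------------

class GTableCache:
    """Cache of per-individual purged inbreeding g(d) for one pedigree.

    Profiling d dominates the cost of a fit because every candidate d
    requires a full pedigree recursion; g tables are therefore cached on a
    rounded-d key and shared across runs, nested fits and model scans.
    """

    def __init__(self, ped: Pedigree):
        self.ped = ped
        self.F = inbreeding(ped).to_numpy()
        self._tables: dict[float, np.ndarray] = {}

    def g(self, d: float) -> np.ndarray:
        key = round(float(d), 6)
        if key not in self._tables:
            _, g = purged_kinship_matrix(self.ped, key, F=self.F)
            self._tables[key] = g
        return self._tables[key]


class _Design:
    """Trait table bound to pedigree positions, ready for the objective."""

    def __init__(self, table: pd.DataFrame, ped: Pedigree, spec: ModelSpec):
        missing = [i for i in table.index if i not in ped]
        if missing:
            raise PedigreeError(f"trait rows not in pedigree: {missing[:5]}")
        dams = table["dam_id"]
        missing_dams = [d for d in dams.dropna() if d not in ped]
        if missing_dams:
            raise PedigreeError(f"dams not in pedigree: {missing_dams[:5]}")
        self.spec = spec
        self.W = table["W"].to_numpy(dtype=float)
        self.self_pos = np.array([ped.position(i) for i in table.index])
        self.dam_pos = np.array(
            [ped.position(d) if isinstance(d, str) else -1 for d in dams]
        )
        self.x_s = table["x_S"].to_numpy(dtype=float)
        self.x_pom = table["x_POM"].to_numpy(dtype=float)
        yob = table["yob"].to_numpy(dtype=float)
        self.yob_mean = float(np.nanmean(yob)) if spec.yob else 0.0
        self.yob_c = np.nan_to_num(yob - self.yob_mean)

    def covariates(self, g_table: np.ndarray) -> np.ndarray:
        """Stack [-g_self, -g_dam, x_S, x_POM, yob_c] columns for included terms."""
        cols = []
        if self.spec.delta:
            cols.append(-g_table[self.self_pos])
        if self.spec.delta_m:
            g_dam = np.where(self.dam_pos >= 0, g_table[self.dam_pos], 0.0)
            cols.append(-g_dam)
        if self.spec.sex:
            cols.append(self.x_s)
        if self.spec.pom:
            cols.append(self.x_pom)
        if self.spec.yob:
            cols.append(self.yob_c)
        if not cols:
            return np.empty((len(self.W), 0))
        return np.column_stack(cols)


def _profiled_residuals(theta: np.ndarray, X: np.ndarray, W: np.ndarray):
    """Residuals W - W0* exp(X theta) with W0 profiled analytically.

    For fixed exponent coefficients the optimal scale is
    W0* = sum(W u) / sum(u^2), u = exp(X theta) (variable projection),
    clipped to stay positive.
    """
    eta = np.clip(X @ theta, -40.0, 40.0)
    u = np.exp(eta)
    denom = float(u @ u)
    w0 = max(float(W @ u) / denom, 1e-12) if denom > 0 else 1e-12
    return W - w0 * u, w0


def _solve_theta(
    X: np.ndarray, W: np.ndarray, spec: ModelSpec, x0: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Bounded least squares for the non-d parameters at one candidate d."""
    names = spec.theta_names
    if not names:
        w0 = max(float(W.mean()), 1e-12)
        return np.empty(0), w0, float(((W - w0) ** 2).sum())
    lower = np.array([0.0 if n in ("delta", "delta_m") else -5.0 for n in names])
    upper = np.array([10.0 if n in ("delta", "delta_m") else 5.0 for n in names])
    x0 = np.clip(x0, lower + 1e-9, upper - 1e-9)
    res = optimize.least_squares(
        lambda th: _profiled_residuals(th, X, W)[0],
        x0,
        bounds=(lower, upper),
        method="trf",
        xtol=1e-10,
        ftol=1e-12,
        gtol=1e-10,
    )
    _, w0 = _profiled_residuals(res.x, X, W)
    return res.x, w0, float(2.0 * res.cost)


@dataclass
class IPFit:
    """Result of one IP model fit."""

    spec: ModelSpec
    estimates: dict[str, float]
    rss: float
    n: int
    logl: float
    aicc: float
    run_se: dict[str, float] = field(default_factory=dict)
    boundary: tuple[str, ...] = ()
    p_d: float | None = None
    p_delta: float | None = None
    yob_mean: float = 0.0

    @property
    def k(self) -> int:
        return self.spec.k

    def summary(self) -> pd.Series:
        out = dict(self.estimates)
        out.update(
            {"RSS": self.rss, "n": self.n, "logL": self.logl, "AICc": self.aicc}
        )
        if self.p_d is not None:
            out["p_d"] = self.p_d
        if self.p_delta is not None:
            out["p_delta"] = self.p_delta
        return pd.Series(out)


def _gaussian_loglik(rss: float, n: int) -> float:
    rss = max(rss, 1e-300)
    return -0.5 * n * (math.log(2.0 * math.pi * rss / n) + 1.0)


def aicc(logl: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion."""
    return -2.0 * logl + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def fit(
    table: pd.DataFrame,
    ped: Pedigree,
    spec: ModelSpec = ModelSpec(),
    *,
    runs: int = 10,
    seed: int | None = None,
    d_grid: int = 11,
    refine: bool = True,
    cache: GTableCache | None = None,
) -> IPFit:
    """Estimate IP parameters by multi-start profiled least squares.

    ``runs`` independent searches are performed, each profiling d over a
    grid on [0, 0.5] (with warm-started inner solves and an optional local
    refinement around the grid optimum) from its own random start; the
    best-RSS solution wins and the run-to-run standard error of every
    estimate is reported as a convergence diagnostic.
    """
    if len(table) == 0:
        raise PedigreeError("trait table is empty")
    if len(table) <= spec.k + 2:
        raise ValueError(f"need n > k + 2 observations (n={len(table)}, k={spec.k})")
    rng = np.random.default_rng(seed)
    if cache is None:
        cache = GTableCache(ped)
    design = _Design(table, ped, spec)
    W = design.W
    d_values = np.linspace(0.0, 0.5, d_grid) if spec.d else np.array([0.0])

    def rss_at_d(d: float, x0: np.ndarray):
        X = design.covariates(cache.g(d))
        return _solve_theta(X, W, spec, x0)

    run_results = []
    n_theta = len(spec.theta_names)
    for _ in range(max(1, runs)):
        x0 = np.array(
            [
                rng.uniform(0.0, 2.0) if n in ("delta", "delta_m") else rng.uniform(-0.3, 0.3)
                for n in spec.theta_names
            ]
        )
        best = None
        warm = x0
        for d in d_values:
            theta, w0, rss = rss_at_d(d, warm)
            warm = theta if n_theta else warm
            if best is None or rss < best[3]:
                best = (d, theta, w0, rss)
        d_best, theta_best, w0_best, rss_best = best
        if spec.d and refine and len(d_values) > 1:
            step = d_values[1] - d_values[0]
            lo = max(0.0, d_best - step)
            hi = min(0.5, d_best + step)

            def neg(dv):
                return rss_at_d(dv, theta_best)[2]

            r = optimize.minimize_scalar(
                neg, bounds=(lo, hi), method="bounded", options={"xatol": 1e-3}
            )
            if r.fun < rss_best:
                d_best = float(r.x)
                theta_best, w0_best, rss_best = rss_at_d(d_best, theta_best)
        run_results.append((d_best, theta_best, w0_best, rss_best))

    run_results.sort(key=lambda r: r[3])
    d_hat, theta_hat, w0_hat, rss = run_results[0]
    estimates: dict[str, float] = {"W0": float(w0_hat)}
    if spec.d:
        estimates["d"] = float(d_hat)
    for name, value in zip(spec.theta_names, theta_hat):
        estimates[name] = float(value)

    per_run: dict[str, list[float]] = {k: [] for k in estimates}
    for d_r, th_r, w0_r, _ in run_results:
        per_run["W0"].append(w0_r)
        if spec.d:
            per_run["d"].append(d_r)
        for name, value in zip(spec.theta_names, th_r):
            per_run[name].append(value)
    run_se = {
        k: (float(np.std(v, ddof=1)) if len(v) > 1 else math.nan)
        for k, v in per_run.items()
    }

    boundary = []
    if spec.d and (d_hat <= 1e-9 or d_hat >= 0.5 - 1e-9):
        boundary.append("d")
    for name, value in zip(spec.theta_names, theta_hat):
        if name in ("delta", "delta_m") and value <= 1e-9:
            boundary.append(name)

    n = len(table)
    logl = _gaussian_loglik(rss, n)
    return IPFit(
        spec=spec,
        estimates=estimates,
        rss=float(rss),
        n=n,
        logl=logl,
        aicc=aicc(logl, spec.k, n),
        run_se=run_se,
        boundary=tuple(boundary),
        yob_mean=design.yob_mean,
    )


def lrt(full: IPFit, reduced: IPFit, *, boundary: bool = False) -> float:
    """Likelihood-ratio p-value for nested IP fits.

    Statistic 2(logL_full - logL_reduced), clipped at 0 when the reduced
    model fits better, referred to chi-square with df equal to the
    parameter-count difference.

    With ``boundary=True`` the dropped parameter is constrained to lie on
    the boundary of its space under the null (as when testing d = 0 with
    d in [0, 0.5], or a load delta = 0 with delta >= 0), and the null
    distribution of the statistic is the Self-Liang 50:50 mixture of
    chi-square(df-1) and chi-square(df) (chi-square(0) being a point mass
    at zero).  The mixture keeps the test's size at its nominal level;
    the plain chi-square version is conservative by about a factor two.
    """
    if not reduced.spec.nested_in(full.spec):
        raise ValueError("reduced model is not nested in the full model")
    df = full.k - reduced.k
    if df < 1:
        raise ValueError("nested comparison needs at least one dropped parameter")
    if full.n != reduced.n:
        raise ValueError("fits compare different data sizes")
    statistic = max(0.0, 2.0 * (full.logl - reduced.logl))
    if not boundary:
        return float(stats.chi2.sf(statistic, df))
    lower = stats.chi2.sf(statistic, df - 1) if df > 1 else (1.0 if statistic <= 0.0 else 0.0)
    return float(0.5 * stats.chi2.sf(statistic, df) + 0.5 * lower)


def fit_with_tests(
    table: pd.DataFrame,
    ped: Pedigree,
    spec: ModelSpec = ModelSpec(d=True, delta=True, delta_m=True, sex=True),
    *,
    runs: int = 10,
    seed: int | None = None,
    cache: GTableCache | None = None,
    **kwargs,
) -> IPFit:
    """Fit a model and attach LRT p-values for purging (d) and for the load.

    p_d compares the fit against the same model with d = 0 (g computed as
    F); p_delta compares the no-purging model estimating the load against
    one with the load also removed (no maternal effects), the procedure
    used when purging is non-significant.
    """
    if cache is None:
        cache = GTableCache(ped)
    full = fit(table, ped, spec, runs=runs, seed=seed, cache=cache, **kwargs)
    if spec.d:
        reduced_spec = ModelSpec(
            d=False,
            delta=spec.delta,
            delta_m=spec.delta_m,
            sex=spec.sex,
            pom=spec.pom,
            yob=spec.yob,
        )
        reduced = fit(table, ped, reduced_spec, runs=runs, seed=seed, cache=cache, **kwargs)
        full.p_d = lrt(full, reduced, boundary=True)
    if spec.delta:
        load_spec = ModelSpec(
            d=False, delta=True, delta_m=False, sex=spec.sex, pom=spec.pom, yob=spec.yob
        )
        null_spec = ModelSpec(
            d=False, delta=False, delta_m=False, sex=spec.sex, pom=spec.pom, yob=spec.yob
        )
        load_fit = fit(table, ped, load_spec, runs=runs, seed=seed, cache=cache, **kwargs)
        null_fit = fit(table, ped, null_spec, runs=runs, seed=seed, cache=cache, **kwargs)
        full.p_delta = lrt(load_fit, null_fit, boundary=True)
    return full


def legal_model_specs(
    *, with_d: bool = True, factors: Sequence[str] = ("delta_m", "sex", "pom", "yob")
) -> list[ModelSpec]:
    """All legal ModelSpecs over the requested factor set."""
    specs = []
    dd_combos = [(False, False), (False, True)] + ([(True, True)] if with_d else [])
    factor_flags = [f for f in ("delta_m", "sex", "pom", "yob") if f in factors]
    for d_flag, delta_flag in dd_combos:
        for included in itertools.chain.from_iterable(
            itertools.combinations(factor_flags, r) for r in range(len(factor_flags) + 1)
        ):
            kw = {f: (f in included) for f in ("delta_m", "sex", "pom", "yob")}
            if kw["pom"] and kw["yob"]:
                continue
            specs.append(ModelSpec(d=d_flag, delta=delta_flag, **kw))
    return specs


def model_scan(
    table: pd.DataFrame,
    ped: Pedigree,
    specs: Iterable[ModelSpec] | None = None,
    *,
    runs: int = 10,
    seed: int | None = None,
    cache: GTableCache | None = None,
    **kwargs,
) -> list[IPFit]:
    """Fit every legal model and rank by AICc (ties broken by fewer parameters)."""
    if cache is None:
        cache = GTableCache(ped)
    if specs is None:
        specs = legal_model_specs()
    fits = [
        fit(table, ped, s, runs=runs, seed=seed, cache=cache, **kwargs) for s in specs
    ]
    fits.sort(key=lambda f: (f.aicc, f.k))
    return fits


def naive_reference_mean(
    table: pd.DataFrame, ped: Pedigree, F: pd.Series | None = None
) -> tuple[float, float]:
    """Mean fitness W'0 of non-inbred individuals with non-inbred ancestors.

    The classical model-free estimate of the reference fitness: the mean
    (with its empirical standard error) of W over individuals with F = 0
    all of whose known ancestors also have F = 0.  Returns (nan, nan) with
    a warning when no individual qualifies.
    """
    if F is None:
        F = inbreeding(ped)
    qualifying = []
    for id_ in table.index:
        if F[id_] != 0.0:
            continue
        if any(F[a] != 0.0 for a in ped.ancestors(id_)):
            continue
        qualifying.append(table.at[id_, "W"])
    if not qualifying:
        logger.warning("no non-inbred individuals with non-inbred ancestors; W'0 undefined")
        return math.nan, math.nan
    values = np.asarray(qualifying, dtype=float)
    se = float(values.std(ddof=0) / math.sqrt(len(values)))
    return float(values.mean()), se
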