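"""Genetic purging: purged inbreeding, asymptotic efficiency, and t_m.

Inbreeding exposes (partially) recessive deleterious alleles in
homozygosis, which both depresses fitness and lets selection remove them
(genetic purging).  The strength of purging at a locus is the purging
coefficient d = s(1/2 - h): the recessive component of the deleterious
effect, from 0 for additive gene action up to 0.5 for a fully recessive
lethal.  The purged inbreeding coefficient g of an individual is its
inbreeding F discounted by the expected reduction of deleterious-allele
frequency caused by purging, g = E[F q/q0].

This module implements

* :func:`purging_coefficient`    -- d from a locus effect (s, h),
* :func:`panmictic_trajectory`   -- per-generation F_t and g_t for an
  idealized population of effective size N,
* :func:`purged_inbreeding`      -- per-individual g from a pedigree,
* :func:`asymptotic_g`           -- the long-run ratio
  g_hat = (1-2d)/(1+2d(2N-1)) and purging efficiency 1 - g_hat,
* :func:`expected_ancestral_inbreeding` -- E[F_a] after t generations,
* :func:`t_m`                    -- the generation at which ancestral
  inbreeding grows fastest, a minimum horizon for detecting purging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, NamedTuple

import numpy as np
import pandas as pd

from .pedigree import Pedigree, inbreeding


@dataclass(frozen=True)
class LocusEffect:
    """Deleterious-locus effect: selection coefficient s, dominance h."""

    s: float
    h: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.s <= 1.0:
            raise ValueError("selection coefficient s must be in [0, 1]")
        if not 0.0 <= self.h <= 1.0:
            raise ValueError("dominance coefficient h must be in [0, 1]")


def purging_coefficient(effect: LocusEffect) -> float:
    """d = s(1/2 - h), the recessive deleterious component exposed by inbreeding.

    Rejects h > 1/2 (negative d would describe a reinforcing allele, which
    the inbreeding-purging model does not cover).
    """
    if effect.h > 0.5:
        raise ValueError(
            "h > 1/2 gives a negative purging coefficient; outside the IP model"
        )
    return effect.s * (0.5 - effect.h)


def _check_d(d: float) -> None:
    if not 0.0 <= d <= 0.5:
        raise ValueError("purging coefficient d must be in [0, 0.5]")


@dataclass(frozen=True)
class IPTrajectory:
    """Per-generation standard (F) and purged (g) inbreeding, index 0..t_max."""

    t: np.ndarray
    F: np.ndarray
    g: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "F": self.F, "g": self.g})


def panmictic_trajectory(N: float, d: float, t_max: int) -> IPTrajectory:
    """F_t and g_t for an idealized panmictic population of effective size N.

    F_t follows the classical drift recursion
    ``F_t = 1/(2N) + (1 - 1/(2N)) F_{t-1}``, and purged inbreeding follows

    ``g_t = [1/(2N) + (1 - 1/(2N)) g_{t-1}] * (1 - 2 d F_{t-1})``

    starting from F_0 = g_0 = 0.  The fixed point of the g recursion (as
    F -> 1) is exactly the asymptotic ratio of :func:`asymptotic_g`.  The
    approximation is good for d*N >= 1.
    """
    if N < 1:
        raise ValueError("effective size N must be >= 1")
    _check_d(d)
    F = np.zeros(t_max + 1)
    g = np.zeros(t_max + 1)
    dF = 1.0 / (2.0 * N)
    for t in range(1, t_max + 1):
        F[t] = dF + (1.0 - dF) * F[t - 1]
        g[t] = (dF + (1.0 - dF) * g[t - 1]) * (1.0 - 2.0 * d * F[t - 1])
    return IPTrajectory(t=np.arange(t_max + 1), F=F, g=g)


class AsymptoticPurging(NamedTuple):
    g_hat: float
    efficiency: float


def asymptotic_g(N: float, d: float) -> AsymptoticPurging:
    """Long-run expected q/q0 ratio and purging efficiency.

    ``g_hat = (1 - 2d) / (1 + 2d(2N - 1))`` is the asymptotically expected
    ratio of deleterious-allele frequency to its founder value; the
    efficiency of purging is 1 - g_hat (the expected proportional reduction
    of those frequencies), increasing with d*N.
    """
    if N < 1:
        raise ValueError("effective size N must be >= 1")
    _check_d(d)
    g_hat = (1.0 - 2.0 * d) / (1.0 + 2.0 * d * (2.0 * N - 1.0))
    return AsymptoticPurging(g_hat=g_hat, efficiency=1.0 - g_hat)


def purged_kinship_matrix(
    ped: Pedigree, d: float, F: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Purged kinship matrix and per-individual g by the tabular method.

    Purged kinship f_g follows the ordinary kinship recursion with
    self-term ``f_g(a,a) = (1+g_a)/2``, but every generation of descent
    discounts the surviving deleterious-allele frequency by the purging
    opportunity created by the parents' inbreeding, D_i = 1 - 2 d Fbar_p
    (Fbar_p = mean Wright inbreeding of i's parents).  Each pair entry
    carries one lineage's share of that generation discount,

    ``f_g(i,j) = sqrt(D_i) * [f_g(sire_i,j) + f_g(dam_i,j)] / 2``

    so that a contemporary pair accumulates the full per-generation factor,
    while an individual's own purged inbreeding takes it whole:

    ``g_i = D_i * f_g(sire_i, dam_i)``.

    Averaged over idealized random-mating pedigrees this recursion
    reproduces the panmictic g_t recursion -- and hence the asymptotic
    g_hat -- which is the property that pins the placement of the
    discount.  With d = 0 it reduces bitwise to the ordinary kinship
    recursion, so g = F.  g_i = 0 when either parent is unknown, but
    purging accumulated in the known line still propagates to descendants
    through f_g.

    Returns ``(Kg, g)``.
    """
    _check_d(d)
    n = len(ped)
    if F is None:
        F = inbreeding(ped).to_numpy()
    Kg = np.zeros((n, n))
    g = np.zeros(n)
    sire, dam = ped.sire_idx, ped.dam_idx
    for i in range(n):
        s, dm = sire[i], dam[i]
        F_s = F[s] if s >= 0 else 0.0
        F_d = F[dm] if dm >= 0 else 0.0
        D_i = 1.0 - d * (F_s + F_d)  # 1 - 2 d Fbar_p, unknown parents F = 0
        if i:
            row = np.zeros(i)
            if s >= 0:
                row += 0.5 * Kg[s, :i]
            if dm >= 0:
                row += 0.5 * Kg[dm, :i]
            if D_i != 1.0:
                row *= math.sqrt(D_i)
            Kg[i, :i] = row
            Kg[:i, i] = row
        if s >= 0 and dm >= 0:
            g[i] = D_i * Kg[s, dm]
        Kg[i, i] = 0.5 * (1.0 + g[i])
    return Kg, g


def purged_inbreeding(ped: Pedigree, d: float) -> pd.Series:
    """Per-individual purged inbreeding coefficient g for purging strength d."""
    _, g = purged_kinship_matrix(ped, d)
    return pd.Series(g, index=ped.ids, name="g")


def expected_ancestral_inbreeding(N: float, t: int) -> float:
    """Expected ancestral inbreeding F_a after t generations at constant size N.

    F_a is the fraction of the genome that has been exposed to inbreeding
    in at least one ancestor; its expectation is
    ``1 - (1 - 1/(2N))^{t(t-1)/2}``, increasing monotonically to 1.
    """
    if N < 1:
        raise ValueError("effective size N must be >= 1")
    if t < 1:
        raise ValueError("t must be >= 1")
    return 1.0 - (1.0 - 1.0 / (2.0 * N)) ** (0.5 * t * (t - 1))


TmMode = Literal["exact", "sqrt2N", "no_selfing"]


def t_m(N: float, mode: TmMode = "no_selfing") -> float:
    """Minimum number of generations before purging is likely detectable.

    t_m is the generation at which expected ancestral inbreeding increases
    fastest (inflection of E[F_a]); before it there has been little
    opportunity for purging to act, so detecting it is unlikely.

    modes:
      * ``exact``      -- 1/2 + sqrt(1 / log(1 + 1/(2N-1)))
      * ``sqrt2N``     -- sqrt(2N)
      * ``no_selfing`` -- sqrt(2N) + 1, for populations without
        self-fertilization (the default for studbook species)
    """
    if N <= 0.5:
        raise ValueError("t_m requires N > 1/2")
    if mode == "exact":
        return 0.5 + math.sqrt(1.0 / math.log1p(1.0 / (2.0 * N - 1.0)))
    if mode == "sqrt2N":
        return math.sqrt(2.0 * N)
    if mode == "no_selfing":
        return math.sqrt(2.0 * N) + 1.0
    raise ValueError(f"unknown t_m mode {mode!r}")
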