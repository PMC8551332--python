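"""Demographic parameters of a studbook population.

With overlapping cohorts, generations are not discrete; demographic rates
are therefore referred to the *target population* (TP) -- the individuals
at the end of the pedigree with the deepest known ancestry -- and measured
on the scale of equivalent complete generations (EqG).

Provided here:

* :func:`select_target_population` -- TP = individuals with EqG within one
  generation of the pedigree maximum and both parents known,
* :func:`effective_size` -- realized Ne from per-individual rates of
  inbreeding, Ne = 1/(2 mean(dF_i)) with
  dF_i = 1 - (1 - F_i)^(1/(EqG_i - 1)),
* :func:`effective_size_classical` -- Ne solving the non-overlapping
  generation expression F = 1 - (1 - 1/2N)^t,
* :func:`founder_analysis` -- founder counts and the effective number of
  founders N_ef from expected genome contributions (probability of gene
  origin),
* :func:`cohort_bins` -- birth-year intervals of width span/ceil(max EqG),
* :func:`demography_report` -- the bundled :class:`DemographyReport`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .pedigree import (
    Pedigree,
    PedigreeError,
    completeness,
    equivalent_generations,
    inbreeding,
)

logger = logging.getLogger(__name__)


def select_target_population(ped: Pedigree, eqg: pd.Series | None = None) -> set[str]:
    """Individuals with EqG in [max(EqG) - 1, max(EqG)] and both parents known.

    This roughly captures the cohorts at the end of the pedigree; the
    window is applied on real-valued EqG, which is continuous in real
    studbooks.
    """
    if len(ped) == 0:
        raise PedigreeError("cannot select a target population in an empty pedigree")
    if eqg is None:
        eqg = equivalent_generations(ped)
    top = float(eqg.max())
    tp = set()
    for ind in ped:
        if ind.sire is None or ind.dam is None:
            continue
        if eqg[ind.id] >= top - 1.0:
            tp.add(ind.id)
    return tp


def rate_of_inbreeding(F: pd.Series, eqg: pd.Series, ids: Iterable[str]) -> pd.Series:
    """Per-individual realized rate of inbreeding dF_i = 1 - (1-F_i)^(1/(EqG_i-1)).

    Individuals with EqG <= 1 have no defined per-generation rate and are
    excluded (with a logged count).
    """
    ids = list(ids)
    eligible = [i for i in ids if eqg[i] > 1.0]
    dropped = len(ids) - len(eligible)
    if dropped:
        logger.info("rate_of_inbreeding: excluded %d individuals with EqG <= 1", dropped)
    values = {i: 1.0 - (1.0 - F[i]) ** (1.0 / (eqg[i] - 1.0)) for i in eligible}
    return pd.Series(values, name="dF", dtype=float)


def effective_size(
    ped: Pedigree,
    tp: Iterable[str],
    F: pd.Series | None = None,
    eqg: pd.Series | None = None,
) -> tuple[float, float]:
    """Realized effective population size from TP rates of inbreeding.

    Ne = 1/(2 mean(dF)) with the mean taken over the target population;
    the standard error follows by the delta method from the SE of the mean
    rate: SE(Ne) = SE(mean dF) / (2 mean(dF)^2).

    Returns ``(Ne, SE)``; Ne is ``inf`` (with a warning) when no
    inbreeding has accumulated.
    """
    tp = list(tp)
    if not tp:
        raise PedigreeError("target population is empty")
    if F is None:
        F = inbreeding(ped)
    if eqg is None:
        eqg = equivalent_generations(ped)
    dF = rate_of_inbreeding(F, eqg, tp)
    if len(dF) == 0:
        raise PedigreeError("no TP individual has EqG > 1; Ne is undefined")
    mean_dF = float(dF.mean())
    if mean_dF <= 0.0:
        logger.warning("mean rate of inbreeding is 0; Ne reported as infinite")
        return math.inf, math.nan
    se_mean = float(dF.std(ddof=1) / math.sqrt(len(dF))) if len(dF) > 1 else math.nan
    ne = 1.0 / (2.0 * mean_dF)
    se_ne = se_mean / (2.0 * mean_dF**2) if not math.isnan(se_mean) else math.nan
    return ne, se_ne


def effective_size_classical(F_bar: float, t: float) -> float:
    """Ne solving F = 1 - (1 - 1/2N)^t for non-overlapping generations."""
    if not 0.0 < F_bar < 1.0:
        raise ValueError("mean inbreeding must be in (0, 1)")
    if t <= 0:
        raise ValueError("t must be positive")
    return 1.0 / (2.0 * (1.0 - (1.0 - F_bar) ** (1.0 / t)))


def founder_contributions(ped: Pedigree, tp: Iterable[str]) -> pd.Series:
    """Expected proportional genome contributions of founders to the TP.

    Each individual's genome derives half from each parent, recursively
    back to founders (probability of gene origin), averaged over the TP.
    An unknown parent's half-share is attributed to the individual carrying
    it, treated as a phantom (partial) founder, so contributions always sum
    to 1; in a pedigree fully known back to its founders this never occurs.
    """
    tp = list(tp)
    n = len(ped)
    contrib: list[dict[int, float]] = []
    for i in range(n):
        s, d = ped.sire_idx[i], ped.dam_idx[i]
        here: dict[int, float] = {}
        own_share = 0.0
        for p in (s, d):
            if p < 0:
                own_share += 0.5
            else:
                for k, v in contrib[p].items():
                    here[k] = here.get(k, 0.0) + 0.5 * v
        if own_share:
            here[i] = here.get(i, 0.0) + own_share
        contrib.append(here)
    total: dict[int, float] = {}
    for id_ in tp:
        for k, v in contrib[ped.position(id_)].items():
            total[k] = total.get(k, 0.0) + v / len(tp)
    ids = ped.ids
    return pd.Series({ids[k]: v for k, v in total.items()}, name="contribution").sort_index()


@dataclass
class DemographyReport:
    """Summary demographic parameters of a studbook pedigree."""

    N: int
    pct_complete: float
    mean_eqg: float
    se_eqg: float
    tp: set[str]
    n_tp: int
    Ne: float
    se_Ne: float
    AN_f: int
    N_f: int
    N_ef: float
    founder_contributions: pd.Series = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "N": self.N,
            "pct_complete": self.pct_complete,
            "mean_EqG": self.mean_eqg,
            "SE_EqG": self.se_eqg,
            "N_TP": self.n_tp,
            "Ne": self.Ne,
            "SE_Ne": self.se_Ne,
            "AN_f": self.AN_f,
            "N_f": self.N_f,
            "N_ef": self.N_ef,
            "founder_contributions": {
                k: float(v) for k, v in self.founder_contributions.items()
            },
        }


def founder_analysis(
    ped: Pedigree, tp: Iterable[str]
) -> tuple[int, int, float, pd.Series]:
    """Founder statistics of the target population.

    Returns ``(AN_f, N_f, N_ef, contributions)``:

    * AN_f -- actual founders: individuals with both parents unknown,
      counted over the whole pedigree;
    * N_f  -- founders that are ancestors of at least one TP member (or TP
      members themselves, for a founder inside the TP);
    * N_ef -- effective number of founders, 1 / sum(p_k^2) over expected
      contributions p_k: the number of equally contributing founders that
      would account for the TP's gene pool.
    """
    tp = list(tp)
    if not tp:
        raise PedigreeError("target population is empty")
    founders = set(ped.founders)
    an_f = len(founders)
    tp_ancestors = set(tp)
    for id_ in tp:
        tp_ancestors |= ped.ancestors(id_)
    n_f = len(founders & tp_ancestors)
    contributions = founder_contributions(ped, tp)
    n_ef = 1.0 / float((contributions**2).sum())
    return an_f, n_f, n_ef, contributions


def cohort_bins(ped: Pedigree, eqg: pd.Series | None = None) -> list[tuple[int, int]]:
    """Birth-year intervals for cohort plots and summaries.

    Interval width = (span of recorded birth years) / ceil(max EqG);
    returns half-open [start, end) year intervals covering the record.
    With max EqG <= 1 a single interval spans all years.
    """
    years = sorted({ind.birth_year for ind in ped if ind.birth_year is not None})
    if not years:
        raise PedigreeError("no individuals with known birth dates")
    if eqg is None:
        eqg = equivalent_generations(ped)
    n_bins = max(1, math.ceil(float(eqg.max())))
    first, last = years[0], years[-1]
    span = last - first + 1
    width = max(1, math.ceil(span / n_bins))
    bins = []
    start = first
    while start <= last:
        bins.append((start, min(start + width, last + 1)))
        start += width
    return bins


def demography_report(ped: Pedigree) -> DemographyReport:
    """Compute the full demographic summary for a pedigree."""
    F = inbreeding(ped)
    eqg = equivalent_generations(ped)
    tp = select_target_population(ped, eqg)
    ne, se_ne = effective_size(ped, tp, F, eqg)
    an_f, n_f, n_ef, contributions = founder_analysis(ped, tp)
    eqg_tp = eqg[list(tp)]
    return DemographyReport(
        N=len(ped),
        pct_complete=completeness(ped),
        mean_eqg=float(eqg_tp.mean()),
        se_eqg=float(eqg_tp.std(ddof=1) / math.sqrt(len(eqg_tp)))
        if len(eqg_tp) > 1
        else math.nan,
        tp=tp,
        n_tp=len(tp),
        Ne=ne,
        se_Ne=se_ne,
        AN_f=an_f,
        N_f=n_f,
        N_ef=n_ef,
        founder_contributions=contributions,
    )
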