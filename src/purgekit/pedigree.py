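"""Studbook pedigrees: reading, validation, pruning, and classical coefficients.

A studbook pedigree is a registry of individuals with (possibly unknown)
sire and dam links.  Wild-born animals with both parents unknown are
treated as unrelated founders.  This module provides

* :class:`Individual` / :class:`Pedigree` -- validated, topologically
  ordered containers,
* :func:`load_pedigree` / :meth:`Pedigree.to_csv` -- the CSV studbook
  dialect (``id,sire,dam,sex,birth_date,death_date,location,accidental_death``),
* :func:`inbreeding` -- Wright's inbreeding coefficient F via the tabular
  kinship method,
* :func:`equivalent_generations` -- Boichard's equivalent complete
  generations EqG,
* :func:`completeness` -- proportion of known parent links,
* :func:`prune_uncertain` -- removal of uncertain-ancestry individuals and
  all their descendants.
"""

from __future__ import annotations

import datetime as _dt
import io
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CSV_COLUMNS = [
    "id",
    "sire",
    "dam",
    "sex",
    "birth_date",
    "death_date",
    "location",
    "accidental_death",
]

_SEXES = {"M", "F", "U"}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (duplicates, cycles, gaps)."""


@dataclass(frozen=True)
class Individual:
    """One studbook record.

    ``sire`` / ``dam`` are ``None`` when the parent is unknown; a founder
    has both unknown.  Dates are ISO calendar dates or ``None``.
    """

    id: str
    sire: str | None = None
    dam: str | None = None
    sex: str = "U"
    birth_date: _dt.date | None = None
    death_date: _dt.date | None = None
    location: str | None = None
    accidental_death: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise PedigreeError("individual id must be nonempty")
        if self.sire == self.id or self.dam == self.id:
            raise PedigreeError(f"individual {self.id!r} is its own parent")
        if self.sex not in _SEXES:
            raise PedigreeError(f"sex of {self.id!r} must be one of M/F/U")
        if (
            self.birth_date is not None
            and self.death_date is not None
            and self.death_date < self.birth_date
        ):
            raise PedigreeError(f"individual {self.id!r} dies before it is born")

    @property
    def is_founder(self) -> bool:
        return self.sire is None and self.dam is None

    @property
    def birth_year(self) -> int | None:
        return None if self.birth_date is None else self.birth_date.year


class Pedigree:
    """A validated, topologically ordered collection of individuals.

    Parents always precede their offspring in the stored order, so single
    forward passes suffice for every recursive coefficient.  Index arrays
    ``sire_idx`` / ``dam_idx`` hold positional parent indices (-1 for
    unknown) for vectorised computation.
    """

    def __init__(self, individuals: Iterable[Individual]):
        members = list(individuals)
        ids = [ind.id for ind in members]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise PedigreeError(f"duplicate individual id {i!r}")
                seen.add(i)
        index = {i: k for k, i in enumerate(ids)}
        for ind in members:
            for parent in (ind.sire, ind.dam):
                if parent is not None and parent not in index:
                    raise PedigreeError(
                        f"parent {parent!r} of {ind.id!r} is not in the pedigree"
                    )
        members = _toposort(members, index)
        self._members: list[Individual] = members
        self._index: dict[str, int] = {ind.id: k for k, ind in enumerate(members)}
        n = len(members)
        self.sire_idx = np.full(n, -1, dtype=np.int64)
        self.dam_idx = np.full(n, -1, dtype=np.int64)
        for k, ind in enumerate(members):
            if ind.sire is not None:
                self.sire_idx[k] = self._index[ind.sire]
            if ind.dam is not None:
                self.dam_idx[k] = self._index[ind.dam]

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._members)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self._members)

    def __contains__(self, id_: str) -> bool:
        return id_ in self._index

    def __getitem__(self, id_: str) -> Individual:
        return self._members[self._index[id_]]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Pedigree):
            return NotImplemented
        return self._members == other._members

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self._members]

    def position(self, id_: str) -> int:
        return self._index[id_]

    @property
    def founders(self) -> list[str]:
        return [ind.id for ind in self._members if ind.is_founder]

    # -- relationships ------------------------------------------------------
    def children_map(self) -> dict[str, list[str]]:
        """Mapping id -> ids of direct offspring."""
        out: dict[str, list[str]] = {i: [] for i in self._index}
        for ind in self._members:
            for parent in (ind.sire, ind.dam):
                if parent is not None:
                    out[parent].append(ind.id)
        return out

    def descendants(self, ids: Iterable[str]) -> set[str]:
        """All strict descendants of ``ids`` (transitive closure)."""
        children = self.children_map()
        stack = list(ids)
        seen: set[str] = set()
        while stack:
            for child in children[stack.pop()]:
                if child not in seen:
                    seen.add(child)
                    stack.append(child)
        return seen - set(ids)

    def ancestors(self, id_: str) -> set[str]:
        """All known strict ancestors of ``id_``."""
        out: set[str] = set()
        stack = [id_]
        while stack:
            ind = self[stack.pop()]
            for parent in (ind.sire, ind.dam):
                if parent is not None and parent not in out:
                    out.add(parent)
                    stack.append(parent)
        return out

    # -- i/o ----------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ind in self._members:
            rows.append(
                {
                    "id": ind.id,
                    "sire": ind.sire or "",
                    "dam": ind.dam or "",
                    "sex": ind.sex,
                    "birth_date": ind.birth_date.isoformat() if ind.birth_date else "",
                    "death_date": ind.death_date.isoformat() if ind.death_date else "",
                    "location": ind.location or "",
                    "accidental_death": "1" if ind.accidental_death else "",
                }
            )
        return pd.DataFrame(rows, columns=CSV_COLUMNS)

    def to_csv(self, path_or_buf=None):
        return self.to_frame().to_csv(path_or_buf, index=False)


def _toposort(members: list[Individual], index: Mapping[str, int]) -> list[Individual]:
    """Normalise storage order so every parent precedes its offspring.

    Ties are broken by input order, so an already-topological file
    round-trips unchanged.  Cycles raise with one offending cycle listed.
    """
    graph = nx.DiGraph()
    graph.add_nodes_from(ind.id for ind in members)
    for ind in members:
        for parent in (ind.sire, ind.dam):
            if parent is not None:
                graph.add_edge(parent, ind.id)
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        pretty = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
        raise PedigreeError(f"pedigree contains a cycle: {pretty}")
    order = list(
        nx.lexicographical_topological_sort(graph, key=lambda i: index[i])
    )
    return [members[index[i]] for i in order]


def _parse_date(token: str, id_: str, field_name: str) -> _dt.date | None:
    if not token:
        return None
    try:
        return _dt.date.fromisoformat(token)
    except ValueError:
        logger.warning(
            "individual %r: unparseable %s %r, treated as unknown", id_, field_name, token
        )
        return None


def load_pedigree(
    source,
    *,
    unknown: str = "",
    insert_missing_parents: bool = False,
) -> Pedigree:
    """Read a studbook CSV into a validated :class:`Pedigree`.

    Parameters
    ----------
    source:
        Path, file object, or CSV text.  Must have a header naming at least
        ``id``, ``sire`` and ``dam``; the remaining studbook columns are
        optional.
    unknown:
        Sentinel encoding an unknown parent (besides the empty field).
    insert_missing_parents:
        If True, ids that appear only as parents are auto-inserted as
        founders; the default is a strict error, which prevents silent
        pedigree gaps.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("id", "sire", "dam"):
        if col not in df.columns:
            raise PedigreeError(f"pedigree file lacks required column {col!r}")

    def _clean(token: str) -> str | None:
        token = token.strip()
        return None if token == "" or token == unknown else token

    records: list[Individual] = []
    ids = set()
    for row in df.itertuples(index=False):
        row = row._asdict()
        id_ = row["id"].strip()
        ids.add(id_)
        records.append(
            Individual(
                id=id_,
                sire=_clean(row["sire"]),
                dam=_clean(row["dam"]),
                sex=(row.get("sex", "U").strip().upper() or "U"),
                birth_date=_parse_date(row.get("birth_date", "").strip(), id_, "birth date"),
                death_date=_parse_date(row.get("death_date", "").strip(), id_, "death date"),
                location=_clean(row.get("location", "")),
                accidental_death=row.get("accidental_death", "").strip()
                in {"1", "true", "True", "yes"},
            )
        )
    if insert_missing_parents:
        missing = {
            p for ind in records for p in (ind.sire, ind.dam) if p is not None and p not in ids
        }
        records = [Individual(id=p) for p in sorted(missing)] + records
    return Pedigree(records)


def prune_uncertain(ped: Pedigree, flagged: Iterable[str]) -> Pedigree:
    """Drop flagged individuals and every (transitive) descendant.

    Individuals of unknown or uncertain ancestry are removed together with
    all their descendants, because their inbreeding -- and the purging
    accumulated along their lines -- would otherwise be understated.
    Idempotent; an empty flag set returns an equal pedigree.
    """
    flagged = set(flagged)
    unknown_ids = flagged - set(ped.ids)
    if unknown_ids:
        raise PedigreeError(f"flagged ids not in pedigree: {sorted(unknown_ids)}")
    doomed = flagged | ped.descendants(flagged)
    survivors = []
    for ind in ped:
        if ind.id in doomed:
            continue
        # parents can never be doomed while the child survives (descendant
        # closure), so links need no rewriting
        survivors.append(ind)
    return Pedigree(survivors)


def kinship_matrix(ped: Pedigree) -> np.ndarray:
    """Full kinship (coancestry) matrix by the tabular method.

    f(i,j) = [f(sire_i, j) + f(dam_i, j)] / 2 for j preceding i, with
    unknown parents contributing 0, and self-kinship f(i,i) = (1+F_i)/2.
    O(n^2) memory; fine for studbook-scale pedigrees.
    """
    n = len(ped)
    K = np.zeros((n, n))
    sire, dam = ped.sire_idx, ped.dam_idx
    for i in range(n):
        s, d = sire[i], dam[i]
        if i:
            row = np.zeros(i)
            if s >= 0:
                row += 0.5 * K[s, :i]
            if d >= 0:
                row += 0.5 * K[d, :i]
            K[i, :i] = row
            K[:i, i] = row
        f_i = K[s, d] if (s >= 0 and d >= 0) else 0.0
        K[i, i] = 0.5 * (1.0 + f_i)
    return K


def inbreeding(ped: Pedigree) -> pd.Series:
    """Wright's inbreeding coefficient F for every individual.

    F_i is the kinship of i's parents; F = 0 whenever either parent is
    unknown (unknown parents are unrelated founders).
    """
    n = len(ped)
    K = kinship_matrix(ped)
    F = np.zeros(n)
    both = (ped.sire_idx >= 0) & (ped.dam_idx >= 0)
    F[both] = K[ped.sire_idx[both], ped.dam_idx[both]]
    return pd.Series(F, index=ped.ids, name="F")


def equivalent_generations(ped: Pedigree) -> pd.Series:
    """Equivalent complete generations EqG_i = sum over known ancestors of (1/2)^n.

    n is the generation distance; an ancestor reachable along several paths
    contributes once per path (each path is a distinct expected genome
    contribution).  Computed by the forward recursion
    EqG_i = (1 + EqG_sire)/2 + (1 + EqG_dam)/2 with unknown parents
    contributing nothing.
    """
    n = len(ped)
    eqg = np.zeros(n)
    for i in range(n):
        s, d = ped.sire_idx[i], ped.dam_idx[i]
        total = 0.0
        if s >= 0:
            total += 0.5 * (1.0 + eqg[s])
        if d >= 0:
            total += 0.5 * (1.0 + eqg[d])
        eqg[i] = total
    return pd.Series(eqg, index=ped.ids, name="EqG")


def completeness(ped: Pedigree) -> float:
    """Pedigree completeness %PC: percent of known parent links.

    Counted over individuals with at least one known parent (wild-caught
    founders are excluded from the denominator):
    100 * known links / (2 * number of such individuals).
    """
    if len(ped) == 0:
        raise PedigreeError("completeness of an empty pedigree is undefined")
    known = 0
    considered = 0
    for ind in ped:
        links = (ind.sire is not None) + (ind.dam is not None)
        if links:
            considered += 1
            known += links
    if considered == 0:
        return 100.0
    return 100.0 * known / (2.0 * considered)
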