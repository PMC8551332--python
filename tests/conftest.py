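import datetime as dt

import numpy as np
import pytest

from purgekit.pedigree import Individual, Pedigree


@pytest.fixture
def trio():
    """A, B founders; C their offspring."""
    return Pedigree(
        [Individual("A"), Individual("B"), Individual("C", "A", "B")]
    )


@pytest.fixture
def sib_line():
    """Two generations of full-sib mating: A,B -> C,D -> E,F2 -> G."""
    return Pedigree(
        [
            Individual("A"),
            Individual("B"),
            Individual("C", "A", "B"),
            Individual("D", "A", "B"),
            Individual("E", "C", "D"),
            Individual("F2", "C", "D"),
            Individual("G", "E", "F2"),
        ]
    )


def random_pedigree(rng: np.random.Generator, n: int, p_known: float = 0.75) -> Pedigree:
    """A random valid pedigree of ``n`` individuals.

    Each individual after the first two draws each parent, with
    probability ``p_known``, uniformly from earlier individuals (parents
    may coincide, emulating selfing; founders have unknown parents).
    """
    records = []
    for i in range(n):
        sire = dam = None
        if i >= 2:
            if rng.random() < p_known:
                sire = f"I{rng.integers(0, i)}"
            if rng.random() < p_known:
                dam = f"I{rng.integers(0, i)}"
        records.append(
            Individual(
                f"I{i}",
                sire,
                dam,
                sex="U",
                birth_date=dt.date(2000 + i, 1, 1),
            )
        )
    return Pedigree(records)
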