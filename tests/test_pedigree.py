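"""Pedigree container, I/O, pruning, and the classical coefficients F / EqG / %PC."""

import numpy as np
import pytest

from purgekit.pedigree import (
    Individual,
    Pedigree,
    PedigreeError,
    completeness,
    equivalent_generations,
    inbreeding,
    load_pedigree,
    prune_uncertain,
)

from conftest import random_pedigree

CSV = """id,sire,dam,sex,birth_date,death_date,location,accidental_death
A,,,M,1990-01-01,,Almeria,
B,,,F,1990-06-01,,Almeria,
C,A,B,F,1992-03-15,1999-01-01,Almeria,
"""


class TestLoadPedigree:
    def test_smallest_family(self):
        ped = load_pedigree(CSV)
        assert len(ped) == 3
        assert ped.ids[-1] == "C"
        assert ped["C"].sire == "A" and ped["C"].dam == "B"
        assert ped["A"].is_founder

    def test_child_listed_before_parent_is_normalized(self):
        shuffled = (
            "id,sire,dam\nC,A,B\nA,,\nB,,\n"
        )
        ped = load_pedigree(shuffled)
        # order is topological: C must come after both parents
        pos = {i: k for k, i in enumerate(ped.ids)}
        assert pos["C"] > pos["A"] and pos["C"] > pos["B"]
        assert ped == load_pedigree("id,sire,dam\nA,,\nB,,\nC,A,B\n")

    def test_cycle_detected(self):
        with pytest.raises(PedigreeError, match="cycle"):
            load_pedigree("id,sire,dam\nC,A,\nA,C,\n")

    def test_duplicate_id(self):
        with pytest.raises(PedigreeError, match="duplicate.*A"):
            load_pedigree("id,sire,dam\nA,,\nA,,\n")

    def test_missing_parent_strict_vs_insert(self):
        text = "id,sire,dam\nC,A,\n"
        with pytest.raises(PedigreeError, match="A"):
            load_pedigree(text)
        ped = load_pedigree(text, insert_missing_parents=True)
        assert "A" in ped and ped["A"].is_founder

    def test_bad_date_becomes_unknown_not_error(self):
        ped = load_pedigree("id,sire,dam,birth_date\nA,,,not-a-date\n")
        assert ped["A"].birth_date is None

    def test_round_trip(self):
        ped = load_pedigree(CSV)
        again = load_pedigree(ped.to_csv())
        assert again == ped

    def test_round_trip_random(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            ped = random_pedigree(rng, int(rng.integers(2, 20)))
            assert load_pedigree(ped.to_csv()) == ped

    def test_self_parent_rejected(self):
        with pytest.raises(PedigreeError):
            Individual("A", sire="A")


class TestPrune:
    def test_empty_flag_set_is_identity(self, trio):
        assert prune_uncertain(trio, set()) == trio

    def test_chain_removed_entirely(self):
        ped = Pedigree(
            [Individual("A"), Individual("B", "A", None), Individual("C", "B", None)]
        )
        assert len(prune_uncertain(ped, {"A"})) == 0

    def test_partial_removal(self):
        ped = Pedigree(
            [
                Individual("A"),
                Individual("B"),
                Individual("C", "A", "B"),
                Individual("D", "B", None),
            ]
        )
        pruned = prune_uncertain(ped, {"A"})
        assert set(pruned.ids) == {"B", "D"}

    def test_idempotent_and_closed_random(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            ped = random_pedigree(rng, int(rng.integers(3, 25)))
            flagged = {
                i for i in ped.ids if rng.random() < 0.2
            }
            pruned = prune_uncertain(ped, flagged)
            # brute-force descendant closure oracle
            doomed = set(flagged)
            changed = True
            while changed:
                changed = False
                for ind in ped:
                    if ind.id in doomed:
                        continue
                    if (ind.sire in doomed) or (ind.dam in doomed):
                        doomed.add(ind.id)
                        changed = True
            assert set(pruned.ids) == set(ped.ids) - doomed
            assert prune_uncertain(pruned, flagged & set(pruned.ids)) == pruned


def _wright_path_F(ped: Pedigree, id_: str) -> float:
    """Independent oracle: Wright's path-counting formula.

    F_X = sum over common ancestors A and over pairs of ancestral paths
    (sire..A, dam..A) sharing only A of (1/2)^(L1+L2+1) (1 + F_A).
    """

    def paths_up(start: str):
        # all ancestral paths [start, ..., ancestor]
        out = [[start]]
        ind = ped[start]
        for parent in (ind.sire, ind.dam):
            if parent is not None:
                out.extend([[start] + p for p in paths_up(parent)])
        return out

    ind = ped[id_]
    if ind.sire is None or ind.dam is None:
        return 0.0
    total = 0.0
    for p1 in paths_up(ind.sire):
        for p2 in paths_up(ind.dam):
            if p1[-1] != p2[-1]:
                continue
            if set(p1[:-1]) & set(p2[:-1]):
                continue  # paths must be disjoint except at the ancestor
            ancestor = p1[-1]
            L = (len(p1) - 1) + (len(p2) - 1)
            total += 0.5 ** (L + 1) * (1.0 + _wright_path_F(ped, ancestor))
    return total


class TestInbreeding:
    def test_founders_zero(self, trio):
        F = inbreeding(trio)
        assert F["A"] == F["B"] == F["C"] == 0.0

    def test_full_sib_mating(self, sib_line):
        assert inbreeding(sib_line)["E"] == 0.25

    def test_parent_offspring_mating(self):
        ped = Pedigree(
            [
                Individual("A"),
                Individual("B"),
                Individual("C", "A", "B"),
                Individual("D", "A", "C"),
            ]
        )
        F = inbreeding(ped)
        assert F["D"] == 0.25
        assert F["D"] == pytest.approx(_wright_path_F(ped, "D"))

    def test_unrelated_parents_give_zero(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            ped = random_pedigree(rng, 10, p_known=0.5)
            F = inbreeding(ped)
            for ind in ped:
                if ind.sire is None or ind.dam is None:
                    assert F[ind.id] == 0.0
                elif not (ped.ancestors(ind.sire) | {ind.sire}) & (
                    ped.ancestors(ind.dam) | {ind.dam}
                ):
                    assert F[ind.id] == 0.0

    def test_against_path_counting_oracle(self):
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(60):
            ped = random_pedigree(rng, int(rng.integers(4, 9)), p_known=0.85)
            F = inbreeding(ped)
            for id_ in ped.ids:
                assert F[id_] == pytest.approx(_wright_path_F(ped, id_), abs=1e-12)
                checked += 1
        assert checked > 200


class TestEquivalentGenerations:
    def test_founder_zero(self, trio):
        assert equivalent_generations(trio)["A"] == 0.0

    def test_complete_two_generations(self):
        records = [Individual(f"G{i}") for i in range(4)]
        records += [
            Individual("P1", "G0", "G1"),
            Individual("P2", "G2", "G3"),
            Individual("X", "P1", "P2"),
        ]
        assert equivalent_generations(Pedigree(records))["X"] == 2.0

    def test_single_known_founder_parent(self):
        ped = Pedigree([Individual("A"), Individual("B", "A", None)])
        assert equivalent_generations(ped)["B"] == 0.5

    def test_fully_known_depth_equals_t(self):
        from purgekit.synthetic_data import simulate_idealized, generation_of

        ped = simulate_idealized(6, 5, selfing=True, seed=0)
        eqg = equivalent_generations(ped)
        gen = generation_of(ped)
        for id_ in ped.ids:
            assert eqg[id_] == pytest.approx(float(gen[id_]))


class TestCompleteness:
    def test_all_known(self, trio):
        assert completeness(trio) == 100.0

    def test_every_nonfounder_missing_one_parent(self):
        ped = Pedigree(
            [Individual("A"), Individual("B", "A", None), Individual("C", "A", None)]
        )
        assert completeness(ped) == 50.0

    def test_mixed(self):
        ped = Pedigree(
            [
                Individual("A"),
                Individual("B"),
                Individual("C", "A", "B"),
                Individual("D", "A", None),
            ]
        )
        assert completeness(ped) == 75.0

    def test_empty_pedigree_errors(self):
        with pytest.raises(PedigreeError):
            completeness(Pedigree([]))
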