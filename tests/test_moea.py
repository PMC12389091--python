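"""Dominance, non-dominated sorting, crowding, and population updates."""

import itertools
import math

import numpy as np
import pytest

from mogata.chem import compute_fingerprint, parse_molecule, tanimoto_distance
from mogata.moea import (
    AcceptanceSchedule,
    Individual,
    Population,
    acceptance_probability,
    dominates,
    fast_nondominated_sort,
    objective_crowding,
    select_parents,
    tanimoto_crowding,
    update_population,
)


def ind(scores, smiles="c1ccccc1"):
    return Individual(molecule=parse_molecule(smiles), scores=np.asarray(scores, float))


def brute_force_fronts(scores):
    """Peel non-dominated sets by exhaustive pairwise comparison."""
    remaining = list(range(len(scores)))
    fronts = []
    while remaining:
        front = [
            i
            for i in remaining
            if not any(dominates(scores[j], scores[i]) for j in remaining if j != i)
        ]
        fronts.append(sorted(front))
        remaining = [i for i in remaining if i not in front]
    return fronts


class TestDominance:
    def test_strict_improvement_everywhere(self):
        assert dominates([0.9, 0.9], [0.5, 0.5])

    def test_no_self_domination(self):
        assert not dominates([0.5, 0.5], [0.5, 0.5])

    def test_incomparable_pair(self):
        assert not dominates([0.9, 0.4], [0.5, 0.5])
        assert not dominates([0.5, 0.5], [0.9, 0.4])

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            dominates([0.1], [0.1, 0.2])


class TestNondominatedSort:
    def test_mutually_nondominated_set_is_one_front(self):
        pop = [ind([1.0, 0.0]), ind([0.5, 0.5]), ind([0.0, 1.0])]
        fronts = fast_nondominated_sort(pop)
        assert len(fronts) == 1 and len(fronts[0]) == 3
        assert all(p.rank == 0 for p in pop)

    def test_dominance_chain_gives_singleton_fronts(self):
        pop = [ind([0.1, 0.1]), ind([0.9, 0.9]), ind([0.5, 0.5])]
        fronts = fast_nondominated_sort(pop)
        assert [len(f) for f in fronts] == [1, 1, 1]
        assert [f[0].scores[0] for f in fronts] == [0.9, 0.5, 0.1]

    def test_empty_input(self):
        assert fast_nondominated_sort([]) == []

    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 51))
            m = int(rng.integers(2, 6))
            scores = rng.random((n, m)).round(2)  # rounding forces ties
            pop = [ind(s) for s in scores]
            fronts = fast_nondominated_sort(pop)
            got = [sorted(pop.index(p) for p in front) for front in fronts]
            assert got == brute_force_fronts(scores)
            # partition property
            assert sorted(itertools.chain.from_iterable(got)) == list(range(n))


class TestTanimotoCrowding:
    def test_identical_molecules_have_zero_crowding(self):
        front = [ind([0.5, 0.5], "Cc1ccccc1"), ind([0.4, 0.6], "Cc1ccccc1")]
        assert tanimoto_crowding(front) == [0.0, 0.0]

    def test_singleton_front_is_maximally_isolated(self):
        front = [ind([1.0, 1.0])]
        assert tanimoto_crowding(front) == [1.0]
        assert front[0].crowding == 1.0

    def test_empty_front_raises(self):
        with pytest.raises(ValueError):
            tanimoto_crowding([])

    def test_matches_pairwise_mean_oracle(self, fixture_library):
        front = [ind([0.5, 0.5], m.smiles) for m in fixture_library[:12]]
        got = tanimoto_crowding(front, "ECFP4")
        fps = [compute_fingerprint(p.molecule, "ECFP4") for p in front]
        n = len(fps)
        for i in range(n):
            expected = (
                sum(tanimoto_distance(fps[i], fps[j]) for j in range(n) if j != i)
                / (n - 1)
            )
            assert abs(got[i] - expected) <= 1e-12
            assert 0.0 <= got[i] <= 1.0

    def test_row_means_of_distance_matrix(self, fixture_library):
        mols = fixture_library[:3]
        front = [ind([0.5, 0.5], m.smiles) for m in mols]
        fps = [compute_fingerprint(m, "ECFP4") for m in mols]
        d = lambda i, j: tanimoto_distance(fps[i], fps[j])
        expected = [
            (d(0, 1) + d(0, 2)) / 2,
            (d(1, 0) + d(1, 2)) / 2,
            (d(2, 0) + d(2, 1)) / 2,
        ]
        assert tanimoto_crowding(front) == pytest.approx(expected, abs=1e-15)


class TestAcceptanceProbability:
    @pytest.mark.parametrize("beta", [0.1, 0.45, 2.0])
    def test_first_generation_is_e_minus_one(self, beta):
        p = acceptance_probability(1, AcceptanceSchedule(beta=beta))
        assert p == pytest.approx(math.exp(-1), abs=1e-12)

    def test_strictly_increasing_and_bounded(self):
        sched = AcceptanceSchedule(beta=0.45)
        ps = [acceptance_probability(g, sched) for g in range(1, 200)]
        assert all(b > a for a, b in zip(ps, ps[1:]))
        assert all(math.exp(-1) <= p < 1.0 for p in ps)

    def test_limit_approaches_one(self):
        assert acceptance_probability(10**9, AcceptanceSchedule()) == pytest.approx(
            1.0, abs=1e-3
        )

    def test_generation_counter_is_one_based(self):
        with pytest.raises(ValueError):
            acceptance_probability(0, AcceptanceSchedule())


def _diverse_individuals(fixture_library, scores):
    return [ind(s, m.smiles) for s, m in zip(scores, fixture_library)]


class TestUpdatePopulation:
    def test_pool_at_capacity_is_fully_retained(self, fixture_library, rng):
        members = _diverse_individuals(fixture_library, np.eye(3))
        parents = Population(members=members[:2], capacity=3)
        new = update_population(parents, [members[2]], g=1, rng=rng)
        assert {p.molecule.smiles for p in new.members} == {
            m.molecule.smiles for m in members
        }

    def test_result_is_exactly_capacity(self, fixture_library, rng):
        scores = np.random.default_rng(0).random((30, 3))
        members = _diverse_individuals(fixture_library, scores)
        parents = Population(members=members[:10], capacity=10)
        new = update_population(parents, members[10:], g=1, rng=rng)
        assert len(new) == 10

    def test_fitting_fronts_carried_whole_despite_low_acceptance(
        self, fixture_library, rng
    ):
        # a dominant pair always survives even at g=1 (p_a = e^-1)
        elite = _diverse_individuals(fixture_library, [[0.9, 0.9], [0.95, 0.95]])
        rest = _diverse_individuals(
            fixture_library[2:], np.random.default_rng(1).random((10, 2)) * 0.5
        )
        parents = Population(members=elite + rest[:2], capacity=4)
        for trial_seed in range(5):
            new = update_population(
                parents, rest[2:], g=1, rng=np.random.default_rng(trial_seed)
            )
            kept = {p.molecule.smiles for p in new.members}
            assert elite[1].molecule.smiles in kept

    def test_mogat_equals_classical_truncation_with_tanimoto_crowding(
        self, fixture_library, rng
    ):
        scores = np.random.default_rng(2).random((40, 3)).round(1)
        members = _diverse_individuals(fixture_library, scores)
        parents = Population(members=members[:20], capacity=20)
        new = update_population(
            parents, members[20:], g=3, mode="mogat", rng=np.random.default_rng(0)
        )
        # oracle: rank then crowding-descending truncation
        merged = members
        fronts = fast_nondominated_sort(merged)
        expected = []
        for front in fronts:
            tanimoto_crowding(front)
            if len(expected) + len(front) <= 20:
                expected.extend(front)
            else:
                order = sorted(
                    front, key=lambda p: (-p.crowding, -p.fitness)
                )
                expected.extend(order[: 20 - len(expected)])
                break
        assert sorted(p.molecule.smiles for p in new.members) == sorted(
            p.molecule.smiles for p in expected
        )

    def test_mogata_at_huge_generation_matches_mogat(self, fixture_library):
        scores = np.random.default_rng(3).random((30, 3))
        members = _diverse_individuals(fixture_library, scores)
        parents = Population(members=members[:15], capacity=15)
        a = update_population(
            parents, members[15:], g=10**9, mode="mogata", rng=np.random.default_rng(7)
        )
        b = update_population(
            parents, members[15:], g=10**9, mode="mogat", rng=np.random.default_rng(7)
        )
        assert [p.molecule.smiles for p in a.members] == [
            p.molecule.smiles for p in b.members
        ]

    def test_fixed_seed_reproducibility(self, fixture_library):
        scores = np.random.default_rng(4).random((30, 3))
        members = _diverse_individuals(fixture_library, scores)
        parents = Population(members=members[:15], capacity=15)
        runs = [
            update_population(
                parents, members[15:], g=2, mode="mogata", rng=np.random.default_rng(11)
            )
            for _ in range(2)
        ]
        assert [p.molecule.smiles for p in runs[0].members] == [
            p.molecule.smiles for p in runs[1].members
        ]

    def test_capacity_beyond_pool_raises(self, fixture_library, rng):
        members = _diverse_individuals(fixture_library, [[0.1, 0.2], [0.3, 0.1]])
        parents = Population(members=members, capacity=5)
        with pytest.raises(ValueError):
            update_population(parents, [], g=1, rng=rng)

    def test_nsga2_mode_uses_objective_space_crowding(self, fixture_library):
        # boundary solutions of the splitting front get infinite crowding and
        # are always retained by classical truncation
        scores = [[1.0, 0.0], [0.0, 1.0], [0.52, 0.51], [0.51, 0.52], [0.4, 0.4]]
        members = _diverse_individuals(fixture_library, scores)
        parents = Population(members=members[:3], capacity=3)
        new = update_population(
            parents, members[3:], g=1, mode="nsga2", rng=np.random.default_rng(0)
        )
        kept = {p.molecule.smiles for p in new.members}
        assert members[0].molecule.smiles in kept
        assert members[1].molecule.smiles in kept


class TestObjectiveCrowding:
    def test_boundaries_infinite_interior_accumulates_gaps(self, fixture_library):
        front = _diverse_individuals(
            fixture_library, [[0.0, 1.0], [0.5, 0.5], [1.0, 0.0]]
        )
        vals = objective_crowding(front)
        assert vals[0] == math.inf and vals[2] == math.inf
        assert vals[1] == pytest.approx(2.0)  # (1-0)/1 per objective


class TestSelectParents:
    def test_uniform_when_fitness_equal(self, fixture_library):
        members = [ind([0.5, 0.5], m.smiles) for m in fixture_library[:4]]
        pop = Population(members=members, capacity=4)
        draws = select_parents(pop, 8000, np.random.default_rng(5))
        counts = np.array(
            [sum(d is m for d in draws) for m in members], dtype=float
        )
        freqs = counts / counts.sum()
        assert np.allclose(freqs, 0.25, atol=0.02)

    def test_proportional_to_fitness(self, fixture_library):
        members = [
            ind([0.2, 0.2], fixture_library[0].smiles),
            ind([0.8, 0.8], fixture_library[1].smiles),
        ]
        pop = Population(members=members, capacity=2)
        n = 100_000
        draws = select_parents(pop, n, np.random.default_rng(6))
        f1 = sum(d is members[1] for d in draws) / n
        p = 0.8
        assert abs(f1 - p) < 3 * math.sqrt(p * (1 - p) / n)

    def test_zero_fitness_floor_keeps_wheel_defined(self, fixture_library):
        members = [
            ind([0.9, 0.9], fixture_library[0].smiles),
            ind([0.0, 0.5], fixture_library[1].smiles),
            ind([0.5, 0.0], fixture_library[2].smiles),
        ]
        pop = Population(members=members, capacity=3)
        draws = select_parents(pop, 2000, np.random.default_rng(8))
        share = sum(d is members[0] for d in draws) / 2000
        assert share > 0.99

    def test_invalid_k_raises(self, fixture_library, rng):
        pop = Population(members=[ind([0.5, 0.5])], capacity=1)
        with pytest.raises(ValueError):
            select_parents(pop, 0, rng)
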