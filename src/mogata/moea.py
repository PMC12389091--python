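"""Evolutionary core: dominance, non-dominated sorting, crowding, selection.

Three population-update modes share one code path:

* ``mogata`` — Tanimoto-fingerprint crowding on the splitting front plus a
  generation-dependent Bernoulli acceptance pass with
  p_a(g) = exp(−(1/g)^β) (β = 0.45 by default), so early generations admit
  candidates more randomly (exploration) and late ones almost always keep the
  crowding order (exploitation);
* ``mogat``  — the same but with acceptance probability forced to 1
  (the ablation arm: Tanimoto crowding, deterministic truncation);
* ``nsga2``  — classical NSGA-II: objective-space crowding distance and
  deterministic rank/crowding truncation.

Crowding here is computed within each front.  For the Tanimoto variant it is
the mean Jaccard distance between a molecule's fingerprint and every other
frontmate's — a structural isolation measure in chemical space rather than an
objective-space density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chem import Molecule, compute_fingerprint, tanimoto_distance
from .scoring import Task, check_success, geometric_mean, score_molecule

MODES = ("mogata", "mogat", "nsga2")

FITNESS_FLOOR = 1e-6  # keeps the roulette wheel defined when all scores are 0


@dataclass(eq=False)
class Individual:
    """A molecule with its objective image and selection bookkeeping.

    Identity-compared: two individuals are distinct members even when they
    wrap the same canonical SMILES (duplicates are legal in a population).
    """

    molecule: Molecule
    scores: np.ndarray
    rank: int = -1
    crowding: float = 0.0
    fitness: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.fitness is None:
            self.fitness = geometric_mean(self.scores)


def make_individual(mol: Molecule, task: Task) -> Individual:
    return Individual(molecule=mol, scores=score_molecule(mol, task))


@dataclass
class Population:
    members: list[Individual]
    capacity: int

    def __len__(self) -> int:
        return len(self.members)

    def scores_matrix(self) -> np.ndarray:
        return np.array([ind.scores for ind in self.members])


@dataclass(frozen=True)
class AcceptanceSchedule:
    """Generation-indexed acceptance probability p_a(g) = exp(−(1/g)^β)."""

    beta: float = 0.45

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")

    def probability(self, g: int) -> float:
        return acceptance_probability(g, self)


def acceptance_probability(g: int, schedule: AcceptanceSchedule) -> float:
    """p_a = exp(−(1/g)^β); e^{-1} at g=1 regardless of β, → 1 as g → ∞."""
    if g < 1:
        raise ValueError("generation counter is 1-based")
    return math.exp(-((1.0 / g) ** schedule.beta))


def dominates(u: np.ndarray, v: np.ndarray) -> bool:
    """Pareto dominance for maximization: u ≥ v everywhere, > somewhere."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("score vectors differ in length")
    return bool(np.all(u >= v) and np.any(u > v))


def fast_nondominated_sort(individuals: list[Individual]) -> list[list[Individual]]:
    """Partition into successive non-dominated fronts; writes ranks back.

    Standard O(n² m) bookkeeping: each individual records whom it dominates
    and how many dominate it; front k+1 is peeled off by decrementing the
    domination counts of front k's dominatees.
    """
    n = len(individuals)
    if n == 0:
        return []
    scores = np.array([ind.scores for ind in individuals])
    # pairwise dominance via broadcasting
    ge = np.all(scores[:, None, :] >= scores[None, :, :], axis=2)
    gt = np.any(scores[:, None, :] > scores[None, :, :], axis=2)
    dom = ge & gt  # dom[i, j]: i dominates j
    n_dominators = dom.sum(axis=0)
    fronts: list[list[Individual]] = []
    current = [i for i in range(n) if n_dominators[i] == 0]
    rank = 0
    while current:
        for i in current:
            individuals[i].rank = rank
        fronts.append([individuals[i] for i in current])
        nxt = []
        for i in current:
            for j in np.nonzero(dom[i])[0]:
                n_dominators[j] -= 1
                if n_dominators[j] == 0:
                    nxt.append(int(j))
        current = sorted(set(nxt))
        rank += 1
    return fronts


def tanimoto_crowding(
    front: list[Individual], fp_kind: str = "ECFP4", nbits: int = 2048
) -> list[float]:
    """Mean Tanimoto distance from each member to all other frontmates.

    A singleton front gets crowding 1 (maximally isolated).  Values are
    written back onto the individuals and returned in input order.
    """
    if not front:
        raise ValueError("empty front")
    if len(front) == 1:
        front[0].crowding = 1.0
        return [1.0]
    fps = [compute_fingerprint(ind.molecule, fp_kind, nbits) for ind in front]
    values = []
    for i, fp_i in enumerate(fps):
        total = sum(tanimoto_distance(fp_i, fp_j) for j, fp_j in enumerate(fps) if j != i)
        values.append(total / (len(fps) - 1))
    for ind, v in zip(front, values):
        ind.crowding = v
    return values


def objective_crowding(front: list[Individual]) -> list[float]:
    """Classical NSGA-II crowding distance in objective space.

    Boundary solutions on each objective get infinite distance; interior ones
    accumulate the normalized gap between their neighbours.
    """
    if not front:
        raise ValueError("empty front")
    n = len(front)
    if n <= 2:
        for ind in front:
            ind.crowding = math.inf
        return [math.inf] * n
    scores = np.array([ind.scores for ind in front])
    m = scores.shape[1]
    dist = np.zeros(n)
    for k in range(m):
        order = np.argsort(scores[:, k], kind="stable")
        lo, hi = scores[order[0], k], scores[order[-1], k]
        dist[order[0]] = dist[order[-1]] = math.inf
        if hi > lo:
            for pos in range(1, n - 1):
                i = order[pos]
                dist[i] += (scores[order[pos + 1], k] - scores[order[pos - 1], k]) / (
                    hi - lo
                )
    values = dist.tolist()
    for ind, v in zip(front, values):
        ind.crowding = v
    return values


def _crowding_order(front: list[Individual]) -> list[Individual]:
    """Descending crowding; ties broken by higher fitness, then input order."""
    return [
        ind
        for _, _, _, ind in sorted(
            ((-ind.crowding, -ind.fitness, i, ind) for i, ind in enumerate(front)),
            key=lambda t: t[:3],
        )
    ]


def update_population(
    parents: Population,
    offspring: list[Individual],
    g: int,
    mode: str = "mogata",
    rng: np.random.Generator | None = None,
    schedule: AcceptanceSchedule | None = None,
    fp_kind: str = "ECFP4",
) -> Population:
    """Merge parents and offspring and select the next generation.

    Whole fronts are carried while they fit.  The first front that would
    overflow capacity is sorted by crowding (descending); in ``mogata`` mode
    the remaining slots are filled by a single Bernoulli(p_a(g)) sweep down
    that order, then topped up deterministically from the rejected candidates
    in the same order so the population lands exactly on capacity.  ``mogat``
    forces p_a = 1 and ``nsga2`` uses objective-space crowding; both then
    reduce to deterministic rank + crowding truncation.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if schedule is None:
        schedule = AcceptanceSchedule()
    if rng is None:
        rng = np.random.default_rng()
    merged = list(parents.members) + list(offspring)
    capacity = parents.capacity
    if capacity > len(merged):
        raise ValueError("capacity exceeds merged pool size")

    fronts = fast_nondominated_sort(merged)
    selected: list[Individual] = []
    for front in fronts:
        if mode == "nsga2":
            objective_crowding(front)
        else:
            tanimoto_crowding(front, fp_kind)
        if len(selected) + len(front) <= capacity:
            selected.extend(front)
            if len(selected) == capacity:
                break
            continue
        # splitting front
        slots = capacity - len(selected)
        ordered = _crowding_order(front)
        p_a = 1.0 if mode != "mogata" else acceptance_probability(g, schedule)
        accepted: list[Individual] = []
        rejected: list[Individual] = []
        for ind in ordered:
            if len(accepted) == slots:
                rejected.append(ind)
            elif rng.random() < p_a:
                accepted.append(ind)
            else:
                rejected.append(ind)
        # deterministic top-up preserving crowding order among the rejected
        accepted.extend(rejected[: slots - len(accepted)])
        selected.extend(accepted)
        break
    return Population(members=selected, capacity=capacity)


def select_parents(
    pop: Population, k: int, rng: np.random.Generator
) -> list[Individual]:
    """k fitness-proportional draws with replacement (roulette wheel)."""
    if not pop.members:
        raise ValueError("empty population")
    if k <= 0:
        raise ValueError("k must be positive")
    weights = np.array([max(ind.fitness, FITNESS_FLOOR) for ind in pop.members])
    probs = weights / weights.sum()
    idx = rng.choice(len(pop.members), size=k, replace=True, p=probs)
    return [pop.members[i] for i in idx]


def rank_and_crowd(pop: Population, mode: str = "mogata", fp_kind: str = "ECFP4") -> None:
    """Recompute ranks and crowding in place (used on freshly scored populations)."""
    fronts = fast_nondominated_sort(pop.members)
    for front in fronts:
        if mode == "nsga2":
            objective_crowding(front)
        else:
            tanimoto_crowding(front, fp_kind)


def success_flags(pop: Population, task: Task) -> list[bool]:
    return [check_success(ind.molecule, task)[0] for ind in pop.members]
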