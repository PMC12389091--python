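"""Run-level evaluation: hypervolume, success rate, diversity summaries.

All objectives are desirabilities in [0, 1] and the hypervolume reference
point is the origin, so the hypervolume of a front — the Lebesgue measure of
the union of axis-aligned boxes [0, p] over its points — is itself in [0, 1].
The exact computation uses dimension-sweep slicing with Pareto pruning
(practical for up to five objectives, the largest benchmark here); higher
dimensions fall back to Monte Carlo integration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem import compute_fingerprint, tanimoto_similarity
from .moea import Population
from .scoring import Task, check_success


@dataclass(frozen=True)
class FrontSummary:
    """Per-generation metric snapshot (hypervolume is over the rank-0 front)."""

    generation: int
    hv: float
    success_rate: float
    max_geometric_mean: float
    internal_similarity: float
    n_valid: int = 0
    n_unique: int = 0


def _pareto_filter(pts: np.ndarray) -> np.ndarray:
    """Drop dominated and duplicate points (maximization)."""
    if len(pts) == 0:
        return pts
    pts = np.unique(pts, axis=0)
    keep = []
    for i, p in enumerate(pts):
        dominated = np.any(
            np.all(pts >= p, axis=1) & np.any(pts > p, axis=1)
        )
        if not dominated:
            keep.append(i)
    return pts[keep]


def _hv_exact(pts: np.ndarray) -> float:
    pts = _pareto_filter(pts)
    if len(pts) == 0:
        return 0.0
    m = pts.shape[1]
    if m == 1:
        return float(pts.max())
    if m == 2:
        # staircase sweep: sort by x descending, accumulate strips
        order = np.argsort(-pts[:, 0], kind="stable")
        vol, y_max = 0.0, 0.0
        prev_x = None
        for i in order:
            x, y = pts[i]
            if y > y_max:
                vol += x * (y - y_max)
                y_max = y
        return float(vol)
    # slicing on the last coordinate
    zs = np.unique(pts[:, -1])[::-1]
    vol = 0.0
    for k, z in enumerate(zs):
        z_next = zs[k + 1] if k + 1 < len(zs) else 0.0
        active = pts[pts[:, -1] >= z][:, :-1]
        vol += (z - z_next) * _hv_exact(active)
    return float(vol)


def hypervolume(
    points, rng: np.random.Generator | None = None, n_samples: int = 200_000
) -> float:
    """Hypervolume of a maximization front in [0, 1]^m against the origin.

    Dominated points contribute nothing; the empty set has hypervolume 0.
    Exact for m ≤ 5, Monte Carlo (``n_samples`` draws) beyond.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return 0.0
    if pts.ndim == 1:
        pts = pts[None, :]
    if np.any(pts < 0.0) or np.any(pts > 1.0):
        raise ValueError("coordinates must lie in [0, 1] for the origin reference")
    m = pts.shape[1]
    if m <= 5:
        return _hv_exact(pts)
    if rng is None:
        rng = np.random.default_rng()
    samples = rng.random((n_samples, m))
    covered = np.zeros(n_samples, dtype=bool)
    for p in _pareto_filter(pts):
        covered |= np.all(samples <= p, axis=1)
    return float(covered.mean())


def success_rate(pop: Population, task: Task) -> float:
    """Fraction of the population whose raw values satisfy every success window."""
    if not pop.members:
        raise ValueError("empty population")
    flags = [check_success(ind.molecule, task)[0] for ind in pop.members]
    return float(np.mean(flags))


def _fingerprints(pop: Population, fp_kind: str):
    return [
        compute_fingerprint(ind.molecule, fp_kind)
        for ind in pop.members
        if ind.molecule.valid
    ]


def internal_similarity(
    pop: Population, fp_kind: str = "ECFP4", method: str = "pairwise"
) -> float:
    """Structural homogeneity of the population, in [0, 1].

    ``pairwise`` (default) is the mean Tanimoto similarity over unordered
    pairs.  ``extended`` is an n-ary coincidence index computed column-wise
    on the fingerprint matrix: bits set in a strict majority of molecules
    count as agreements, bits set in a non-empty minority as disagreements,
    and the index is agreements / (agreements + disagreements).
    """
    fps = _fingerprints(pop, fp_kind)
    if len(fps) < 2:
        raise ValueError("internal similarity needs at least two valid molecules")
    if method == "pairwise":
        sims = [
            tanimoto_similarity(fps[i], fps[j])
            for i in range(len(fps))
            for j in range(i + 1, len(fps))
        ]
        return float(np.mean(sims))
    if method == "extended":
        n = len(fps)
        counts: dict[int, int] = {}
        for fp in fps:
            for bit in fp.bits:
                counts[bit] = counts.get(bit, 0) + 1
        agree = sum(1 for c in counts.values() if 2 * c > n)
        disagree = sum(1 for c in counts.values() if 2 * c <= n)
        if agree + disagree == 0:
            return 1.0  # all-empty fingerprints: indistinguishable
        return agree / (agree + disagree)
    raise ValueError(f"unknown internal-similarity method {method!r}")


def summarize_generation(
    pop: Population,
    task: Task,
    g: int,
    fp_kind: str = "ECFP4",
    similarity_method: str = "pairwise",
) -> FrontSummary:
    """Metric snapshot: HV over the rank-0 front, the rest population-wide."""
    front0 = [ind for ind in pop.members if ind.rank == 0]
    hv = hypervolume([ind.scores for ind in front0]) if front0 else 0.0
    valid = [ind for ind in pop.members if ind.molecule.valid]
    return FrontSummary(
        generation=g,
        hv=hv,
        success_rate=success_rate(pop, task),
        max_geometric_mean=max((ind.fitness for ind in pop.members), default=0.0),
        internal_similarity=internal_similarity(pop, fp_kind, similarity_method),
        n_valid=len(valid),
        n_unique=len({ind.molecule.smiles for ind in valid}),
    )
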