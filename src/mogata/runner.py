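"""Orchestration: run configuration, the optimization loop, and file I/O.

A run starts from a seeded random sample of a SMILES library (the built-in
synthetic fixture library by default), evolves it for a fixed number of
generations with the configured population-update mode, and records a metric
trace per generation.  Trials are independent repeats whose RNG seeds are
derived as ``seed + trial_index``, so a run is reproducible bit-for-bit from
its config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import Molecule, parse_molecule
from .fixtures import generate_fixture_library
from .metrics import FrontSummary, summarize_generation
from .moea import (
    AcceptanceSchedule,
    Population,
    acceptance_probability,
    make_individual,
    rank_and_crowd,
    update_population,
)
from .scoring import Task, check_success, get_task
from .variation import FragmentPool, make_offspring

logger = logging.getLogger("mogata")

TRACE_COLUMNS = (
    "trial",
    "generation",
    "hv",
    "success_rate",
    "max_gm",
    "internal_similarity",
    "n_valid",
    "n_unique",
)


@dataclass
class RunConfig:
    """Protocol parameters; the defaults are the benchmark protocol
    (20 trials, population 100, 150 generations, β = 0.45, ECFP4 crowding)."""

    task: str = "pioglitazone"
    population_size: int = 100
    generations: int = 150
    trials: int = 20
    beta: float = 0.45
    mode: str = "mogata"
    crowding_fp: str = "ECFP4"
    seed: int = 0
    crossover_fraction: float = 0.5
    bare_prob: float = 0.2
    max_attempts: int = 10
    offspring_per_generation: int | None = None  # defaults to population_size
    seed_library: str = "fixtures"  # or a path to a .smi file
    fixture_size: int = 500
    threshold_rule: str = "below"
    similarity_method: str = "pairwise"

    def resolve_task(self) -> Task:
        return get_task(self.task, threshold_rule=self.threshold_rule)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class TrialResult:
    seed: int
    trace: list[FrontSummary]
    final_population: Population

    @property
    def final_summary(self) -> FrontSummary:
        return self.trace[-1]


@dataclass
class RunResult:
    config: RunConfig
    trials: list[TrialResult] = field(default_factory=list)

    def trace_frame(self) -> pd.DataFrame:
        rows = []
        for t_idx, trial in enumerate(self.trials):
            for s in trial.trace:
                rows.append(
                    (
                        t_idx,
                        s.generation,
                        s.hv,
                        s.success_rate,
                        s.max_geometric_mean,
                        s.internal_similarity,
                        s.n_valid,
                        s.n_unique,
                    )
                )
        return pd.DataFrame(rows, columns=list(TRACE_COLUMNS))

    def mean_final(self) -> dict[str, float]:
        """Across-trial arithmetic means of the final-generation metrics."""
        finals = [t.final_summary for t in self.trials]
        return {
            "hv": float(np.mean([s.hv for s in finals])),
            "success_rate": float(np.mean([s.success_rate for s in finals])),
            "max_gm": float(np.mean([s.max_geometric_mean for s in finals])),
            "internal_similarity": float(
                np.mean([s.internal_similarity for s in finals])
            ),
        }


def read_smiles_library(path: str) -> list[Molecule]:
    """Read a .smi file (one ``SMILES [name]`` record per line).

    Invalid or unparsable lines are skipped with a logged warning; ``#``
    comment lines and blank lines are ignored; order is preserved.
    """
    molecules = []
    n_bad = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            smiles = line.split()[0]
            mol = parse_molecule(smiles)
            if mol.valid:
                molecules.append(mol)
            else:
                n_bad += 1
                logger.warning("%s:%d: skipping invalid SMILES %r", path, lineno, smiles)
    if n_bad:
        logger.warning("%s: skipped %d invalid record(s)", path, n_bad)
    return molecules


def write_smiles_library(molecules: list[Molecule], path: str) -> None:
    with open(path, "w") as fh:
        for mol in molecules:
            fh.write(mol.smiles + "\n")


def _load_library(cfg: RunConfig) -> list[Molecule]:
    if cfg.seed_library == "fixtures":
        lib = generate_fixture_library(cfg.fixture_size, seed=cfg.seed)
    else:
        lib = read_smiles_library(cfg.seed_library)
    # dedupe by canonical SMILES, preserving order
    seen: dict[str, Molecule] = {}
    for mol in lib:
        seen.setdefault(mol.smiles, mol)
    return list(seen.values())


def _run_trial(cfg: RunConfig, task: Task, library: list[Molecule], seed: int) -> TrialResult:
    rng = np.random.default_rng(seed)
    n = cfg.population_size
    if len(library) < n:
        raise ValueError(
            f"seed library has {len(library)} valid unique molecules; need {n}"
        )
    idx = rng.choice(len(library), size=n, replace=False)
    members = [make_individual(library[i], task) for i in idx]
    pop = Population(members=members, capacity=n)
    rank_and_crowd(pop, mode=cfg.mode, fp_kind=cfg.crowding_fp)
    trace = [summarize_generation(pop, task, 0, cfg.crowding_fp, cfg.similarity_method)]
    schedule = AcceptanceSchedule(beta=cfg.beta)
    n_offspring = cfg.offspring_per_generation or n

    for g in range(1, cfg.generations + 1):
        pool = FragmentPool()
        pool.add_from_population([ind.molecule for ind in pop.members])
        offspring = make_offspring(
            pop,
            n_offspring,
            task,
            rng,
            crossover_fraction=cfg.crossover_fraction,
            max_attempts=cfg.max_attempts,
            bare_prob=cfg.bare_prob,
            pool=pool,
        )
        pop = update_population(
            pop,
            offspring,
            g,
            mode=cfg.mode,
            rng=rng,
            schedule=schedule,
            fp_kind=cfg.crowding_fp,
        )
        summary = summarize_generation(
            pop, task, g, cfg.crowding_fp, cfg.similarity_method
        )
        trace.append(summary)
        logger.info(
            "trial seed=%d gen=%d p_a=%.3f hv=%.3f sr=%.3f max_gm=%.3f int_sim=%.3f",
            seed,
            g,
            acceptance_probability(g, schedule) if cfg.mode == "mogata" else 1.0,
            summary.hv,
            summary.success_rate,
            summary.max_geometric_mean,
            summary.internal_similarity,
        )
    return TrialResult(seed=seed, trace=trace, final_population=pop)


def run_optimization(cfg: RunConfig) -> RunResult:
    """Run the configured number of independent trials and aggregate them."""
    task = cfg.resolve_task()
    library = _load_library(cfg)
    result = RunResult(config=cfg)
    for trial in range(cfg.trials):
        result.trials.append(_run_trial(cfg, task, library, cfg.seed + trial))
    return result


def write_results(result: RunResult, outdir: str) -> dict[str, str]:
    """Emit config echo (JSON), per-generation trace (CSV), and the final
    populations (.smi plus a CSV with scores, rank, crowding, success)."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "config": os.path.join(outdir, "config.json"),
        "trace": os.path.join(outdir, "trace.csv"),
        "population": os.path.join(outdir, "final_population.csv"),
        "smiles": os.path.join(outdir, "final_population.smi"),
    }
    with open(paths["config"], "w") as fh:
        json.dump(result.config.to_dict(), fh, indent=2)
    result.trace_frame().to_csv(paths["trace"], index=False)

    task = result.config.resolve_task()
    rows = []
    smiles_out = []
    for t_idx, trial in enumerate(result.trials):
        for ind in trial.final_population.members:
            ok, _ = check_success(ind.molecule, task)
            row = {
                "trial": t_idx,
                "smiles": ind.molecule.smiles,
                "rank": ind.rank,
                "crowding": ind.crowding,
                "fitness": ind.fitness,
                "success": ok,
            }
            for obj, s in zip(task.objectives, ind.scores):
                row[f"score_{obj.name}"] = s
            rows.append(row)
            smiles_out.append(ind.molecule)
    pd.DataFrame(rows).to_csv(paths["population"], index=False)
    write_smiles_library(smiles_out, paths["smiles"])
    return paths
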