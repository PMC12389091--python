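"""Descriptors, desirability modifiers, and multi-property benchmark tasks.

A :class:`Task` is an ordered list of objectives.  Each objective pairs a raw
scoring function (a physicochemical descriptor, a fingerprint similarity to a
reference drug, or a registered plugin) with a modifier that maps the raw
value onto a [0, 1] desirability, plus a success window on the RAW value used
for success-rate reporting.

Modifier semantics follow the GuacaMol goal-directed benchmark conventions:

* ``Gaussian(mu, sigma)``   — exp(−(x−mu)² / (2σ²)), peaked at the target;
* ``MaxGaussian(mu, sigma)`` — 1 on [mu, ∞), Gaussian tail below (rewards
  values at or above mu);
* ``MinGaussian(mu, sigma)`` — 1 on (−∞, mu], Gaussian tail above;
* ``ThresholdedLinear(mu)`` — min(x, mu)/mu, capped linear.

Success windows default to mu ± sigma for the Gaussian family (closed at both
ends) and to ``raw < mu`` for ThresholdedLinear similarity objectives, i.e. a
novelty constraint: a generated molecule counts as a success only while it
stays below the similarity threshold.  The alternative saturation reading
(``raw ≥ mu``) is selectable per task via ``threshold_rule="above"``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Sequence

import numpy as np
from rdkit.Chem import Crippen, Descriptors, QED, rdMolDescriptors

from .chem import InvalidMoleculeError, Molecule, molecule_similarity, parse_molecule

DESCRIPTOR_KINDS = (
    "TPSA",
    "logP",
    "molecular_weight",
    "n_rotatable_bonds",
    "n_aromatic_rings",
    "n_fluorine",
    "QED",
    "CNS",
)

MODIFIER_KINDS = ("Gaussian", "MinGaussian", "MaxGaussian", "ThresholdedLinear")


# ---------------------------------------------------------------------------
# descriptors and plugin scorers


def _n_fluorine(mol) -> float:
    return float(sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "F"))


def _cns_mpo(mol) -> float:
    """Central-nervous-system drug-likeness score in [0, 1].

    Average of four piecewise-linear desirability components (calculated logP,
    molecular weight, TPSA, hydrogen-bond donors) in the spirit of the CNS
    multi-parameter-optimization desirability framework; the ionization (pKa)
    components are omitted because they need a pKa predictor.  Each component
    is 1 in its favourable range and ramps linearly to 0 outside it.
    """

    def ramp_down(x, lo, hi):  # 1 below lo, 0 above hi
        if x <= lo:
            return 1.0
        if x >= hi:
            return 0.0
        return (hi - x) / (hi - lo)

    logp = Crippen.MolLogP(mol)
    mw = Descriptors.MolWt(mol)
    tpsa = rdMolDescriptors.CalcTPSA(mol)
    hbd = rdMolDescriptors.CalcNumHBD(mol)

    d_logp = ramp_down(logp, 3.0, 5.0)
    d_mw = ramp_down(mw, 360.0, 500.0)
    # TPSA desirability is a hump: too low hurts solubility, too high hurts
    # permeation; full desirability on [40, 90] Å².
    if tpsa <= 20.0 or tpsa >= 120.0:
        d_tpsa = 0.0
    elif tpsa < 40.0:
        d_tpsa = (tpsa - 20.0) / 20.0
    elif tpsa <= 90.0:
        d_tpsa = 1.0
    else:
        d_tpsa = (120.0 - tpsa) / 30.0
    d_hbd = ramp_down(hbd, 0.5, 3.5)
    return float((d_logp + d_mw + d_tpsa + d_hbd) / 4.0)


_DESCRIPTOR_FUNCS: dict[str, Callable] = {
    "TPSA": rdMolDescriptors.CalcTPSA,
    "logP": Crippen.MolLogP,
    "molecular_weight": Descriptors.MolWt,
    "n_rotatable_bonds": lambda m: float(rdMolDescriptors.CalcNumRotatableBonds(m)),
    "n_aromatic_rings": lambda m: float(rdMolDescriptors.CalcNumAromaticRings(m)),
    "n_fluorine": _n_fluorine,
    "QED": QED.qed,
    "CNS": _cns_mpo,
}

# User-registrable raw scorers (Molecule -> float), e.g. bioactivity models.
_PLUGIN_SCORERS: dict[str, Callable[[Molecule], float]] = {}


def register_scorer(name: str, func: Callable[[Molecule], float]) -> None:
    """Register a plugin scoring function usable as ``scorer: plugin:<name>``."""
    _PLUGIN_SCORERS[name] = func


def compute_descriptor(mol: Molecule, kind: str) -> float:
    """Raw descriptor value; counts come back as floats."""
    if kind not in _DESCRIPTOR_FUNCS:
        raise ValueError(f"unknown descriptor kind {kind!r}")
    if not mol.valid:
        raise InvalidMoleculeError(f"cannot score invalid molecule {mol.smiles!r}")
    return float(_DESCRIPTOR_FUNCS[kind](mol.mol))


# ---------------------------------------------------------------------------
# modifiers


@dataclass(frozen=True)
class Modifier:
    kind: str
    mu: float
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in MODIFIER_KINDS:
            raise ValueError(f"unknown modifier kind {self.kind!r}")
        if self.kind == "ThresholdedLinear":
            if self.mu <= 0:
                raise ValueError("ThresholdedLinear needs a positive threshold")
        elif self.sigma is None or self.sigma <= 0:
            raise ValueError(f"{self.kind} needs sigma > 0")

    def __call__(self, x: float) -> float:
        return apply_modifier(self, x)


def apply_modifier(m: Modifier, x: float) -> float:
    """Map a raw value to [0, 1] desirability."""
    if m.kind == "ThresholdedLinear":
        return min(x, m.mu) / m.mu
    gauss = math.exp(-((x - m.mu) ** 2) / (2.0 * m.sigma**2))
    if m.kind == "Gaussian":
        return gauss
    if m.kind == "MaxGaussian":
        return 1.0 if x >= m.mu else gauss
    return 1.0 if x <= m.mu else gauss  # MinGaussian


@dataclass(frozen=True)
class Interval:
    """A (possibly half-open, possibly unbounded) window on a raw score."""

    lo: float = -math.inf
    hi: float = math.inf
    lo_inclusive: bool = True
    hi_inclusive: bool = True

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError(f"malformed interval [{self.lo}, {self.hi}]")

    def contains(self, x: float) -> bool:
        above = x >= self.lo if self.lo_inclusive else x > self.lo
        below = x <= self.hi if self.hi_inclusive else x < self.hi
        return above and below


def default_success_interval(modifier: Modifier | None, threshold_rule: str = "below") -> Interval:
    """Derive the success window implied by a modifier.

    Gaussian-family modifiers succeed within one sigma of the target (so
    MaxGaussian(90, 10) yields [80, 100]); ThresholdedLinear succeeds below
    the threshold under the default novelty rule, at/above it under
    ``threshold_rule="above"``.
    """
    if modifier is None:
        raise ValueError("objective without modifier needs an explicit success rule")
    if modifier.kind == "ThresholdedLinear":
        if threshold_rule == "below":
            return Interval(hi=modifier.mu, hi_inclusive=False)
        if threshold_rule == "above":
            return Interval(lo=modifier.mu)
        raise ValueError(f"unknown threshold rule {threshold_rule!r}")
    return Interval(lo=modifier.mu - modifier.sigma, hi=modifier.mu + modifier.sigma)


# ---------------------------------------------------------------------------
# objectives and tasks


@dataclass(frozen=True)
class Objective:
    """One scored property: raw scorer + modifier + success window.

    ``scorer`` is a selector string: a descriptor kind (``"TPSA"``), a similarity
    (``"similarity:AP"`` — with a target molecule), or ``"plugin:<name>"``.
    """

    name: str
    scorer: str
    modifier: Modifier | None
    success: Interval
    fp_kind: str | None = None
    target: Molecule | None = None

    def raw(self, mol: Molecule) -> float:
        if self.scorer.startswith("similarity"):
            return molecule_similarity(mol, self.target, self.fp_kind)
        if self.scorer.startswith("plugin:"):
            name = self.scorer.split(":", 1)[1]
            if name not in _PLUGIN_SCORERS:
                raise KeyError(f"plugin scorer {name!r} is not registered")
            return float(_PLUGIN_SCORERS[name](mol))
        return compute_descriptor(mol, self.scorer)

    def modified(self, raw: float) -> float:
        return apply_modifier(self.modifier, raw) if self.modifier else float(raw)


@dataclass(frozen=True)
class Task:
    """An ordered multi-property objective; all objectives are maximized."""

    name: str
    objectives: tuple[Objective, ...]

    def __post_init__(self) -> None:
        if len(self.objectives) < 2:
            raise ValueError("a task needs at least two objectives")

    @property
    def n_objectives(self) -> int:
        return len(self.objectives)


def raw_scores(mol: Molecule, task: Task) -> np.ndarray:
    return np.array([obj.raw(mol) for obj in task.objectives], dtype=float)


def score_molecule(mol: Molecule, task: Task) -> np.ndarray:
    """Modified objective vector in [0, 1]^n; invalid molecules score all-zero."""
    if not mol.valid:
        return np.zeros(task.n_objectives)
    return np.array(
        [obj.modified(obj.raw(mol)) for obj in task.objectives], dtype=float
    )


def geometric_mean(scores: Sequence[float]) -> float:
    """(∏ s_i)^(1/n) for s_i in [0, 1]; 0 whenever any component is 0."""
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("geometric mean of an empty vector")
    if np.any(s <= 0.0):
        return 0.0
    return float(np.exp(np.mean(np.log(s))))


def check_success(mol: Molecule, task: Task) -> tuple[bool, list[bool]]:
    """Per-objective and overall success on the RAW values (invalid → all False)."""
    if not mol.valid:
        return False, [False] * task.n_objectives
    flags = [obj.success.contains(obj.raw(mol)) for obj in task.objectives]
    return all(flags), flags


# ---------------------------------------------------------------------------
# built-in benchmarks

TASK_NAMES = ("fexofenadine", "pioglitazone", "osimertinib", "ranolazine", "cobimetinib")

# (objective name, scorer, fp kind, modifier kind, mu, sigma) per task;
# a None modifier means the raw score is already a [0,1] desirability.
_TASK_TABLE: dict[str, list[tuple]] = {
    "fexofenadine": [
        ("similarity_AP", "similarity", "AP", "ThresholdedLinear", 0.8, None),
        ("TPSA", "TPSA", None, "MaxGaussian", 90.0, 10.0),
        ("logP", "logP", None, "MinGaussian", 4.0, 2.0),
    ],
    "pioglitazone": [
        ("similarity_ECFP4", "similarity", "ECFP4", "Gaussian", 0.0, 0.1),
        ("molecular_weight", "molecular_weight", None, "Gaussian", 356.0, 10.0),
        ("n_rotatable_bonds", "n_rotatable_bonds", None, "Gaussian", 2.0, 0.5),
    ],
    "osimertinib": [
        ("similarity_FCFP4", "similarity", "FCFP4", "ThresholdedLinear", 0.8, None),
        ("similarity_ECFP6", "similarity", "ECFP6", "MinGaussian", 0.85, 2.0),
        ("TPSA", "TPSA", None, "MaxGaussian", 95.0, 20.0),
        ("logP", "logP", None, "MinGaussian", 1.0, 2.0),
    ],
    "ranolazine": [
        ("similarity_AP", "similarity", "AP", "ThresholdedLinear", 0.7, None),
        ("TPSA", "TPSA", None, "MaxGaussian", 95.0, 20.0),
        ("logP", "logP", None, "MaxGaussian", 7.0, 1.0),
        ("n_fluorine", "n_fluorine", None, "Gaussian", 1.0, 1.0),
    ],
    "cobimetinib": [
        ("similarity_FCFP4", "similarity", "FCFP4", "ThresholdedLinear", 0.7, None),
        ("similarity_ECFP6", "similarity", "ECFP6", "MinGaussian", 0.75, 0.1),
        ("n_rotatable_bonds", "n_rotatable_bonds", None, "MinGaussian", 3.0, 1.0),
        ("n_aromatic_rings", "n_aromatic_rings", None, "MaxGaussian", 3.0, 1.0),
        ("CNS", "CNS", None, None, 0.5, None),
    ],
}


def _load_targets() -> dict[str, Molecule]:
    out = {}
    text = resources.files("mogata.data").joinpath("targets.smi").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        smiles, name = line.split()
        out[name] = parse_molecule(smiles)
    return out


_TARGETS: dict[str, Molecule] | None = None


def builtin_targets() -> dict[str, Molecule]:
    global _TARGETS
    if _TARGETS is None:
        _TARGETS = _load_targets()
    return _TARGETS


def get_task(name: str, threshold_rule: str = "below") -> Task:
    """Build one of the five built-in benchmarks.

    ``threshold_rule`` chooses the success reading of ThresholdedLinear
    similarity objectives: "below" (novelty; default) or "above" (saturation).
    """
    key = name.lower()
    if key not in _TASK_TABLE:
        raise KeyError(f"unknown task {name!r}; built-ins: {TASK_NAMES}")
    target = builtin_targets()[key]
    objectives = []
    for oname, scorer, fp_kind, mkind, mu, sigma in _TASK_TABLE[key]:
        modifier = Modifier(mkind, mu, sigma) if mkind else None
        if modifier is None:
            # CNS desirability: raw score already in [0,1]; success at >= mu.
            success = Interval(lo=mu)
        else:
            success = default_success_interval(modifier, threshold_rule)
        objectives.append(
            Objective(
                name=oname,
                scorer=f"similarity:{fp_kind}" if scorer == "similarity" else scorer,
                modifier=modifier,
                success=success,
                fp_kind=fp_kind,
                target=target if scorer == "similarity" else None,
            )
        )
    return Task(name=key, objectives=tuple(objectives))


# ---------------------------------------------------------------------------
# (de)serialization of custom tasks


def task_to_dict(task: Task) -> dict:
    objs = []
    for o in task.objectives:
        d: dict = {"name": o.name, "scorer": o.scorer}
        if o.fp_kind:
            d["fp_kind"] = o.fp_kind
        if o.target is not None:
            d["target_smiles"] = o.target.smiles
        if o.modifier is not None:
            d["modifier"] = {"kind": o.modifier.kind, "mu": o.modifier.mu}
            if o.modifier.sigma is not None:
                d["modifier"]["sigma"] = o.modifier.sigma
        d["success"] = {
            "lo": None if math.isinf(o.success.lo) else o.success.lo,
            "hi": None if math.isinf(o.success.hi) else o.success.hi,
            "lo_inclusive": o.success.lo_inclusive,
            "hi_inclusive": o.success.hi_inclusive,
        }
        objs.append(d)
    return {"name": task.name, "objectives": objs}


def task_from_dict(d: dict, threshold_rule: str = "below") -> Task:
    objectives = []
    for od in d["objectives"]:
        modifier = None
        if od.get("modifier"):
            md = od["modifier"]
            modifier = Modifier(md["kind"], float(md["mu"]), md.get("sigma"))
        if od.get("success"):
            sd = od["success"]
            success = Interval(
                lo=-math.inf if sd.get("lo") is None else float(sd["lo"]),
                hi=math.inf if sd.get("hi") is None else float(sd["hi"]),
                lo_inclusive=bool(sd.get("lo_inclusive", True)),
                hi_inclusive=bool(sd.get("hi_inclusive", True)),
            )
        else:
            success = default_success_interval(modifier, threshold_rule)
        target = None
        if od.get("target_smiles"):
            target = parse_molecule(od["target_smiles"])
            if not target.valid:
                raise ValueError(f"invalid target SMILES {od['target_smiles']!r}")
        objectives.append(
            Objective(
                name=od["name"],
                scorer=od["scorer"],
                modifier=modifier,
                success=success,
                fp_kind=od.get("fp_kind"),
                target=target,
            )
        )
    return Task(name=d.get("name", "custom"), objectives=tuple(objectives))


def task_to_json(task: Task) -> str:
    return json.dumps(task_to_dict(task), indent=2)
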