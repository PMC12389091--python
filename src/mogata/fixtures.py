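"""Deterministic synthetic seed library of drug-like molecules.

Emulates a ChEMBL-style starting set without any download: a grid of common
ring scaffolds × medicinal-chemistry substituents × short alkyl linkers is
enumerated, validated with RDKit, deduplicated by canonical SMILES, shuffled
by the given seed and truncated.  The emitted set spans roughly TPSA 0–150,
logP −1–6, MW 78–500 and 0–8 rotatable bonds, which covers the success
windows of the built-in benchmark tasks.
"""

from __future__ import annotations

import functools

from .chem import Molecule, parse_molecule

# one-site scaffold templates; "{R}" is the substitution point
_TEMPLATES_1 = (
    "c1ccc({R})cc1",          # benzene
    "c1ccnc({R})c1",          # pyridine
    "C1CCC({R})CC1",          # cyclohexane
    "C1CCN({R})CC1",          # piperidine
    "O1CCN({R})CC1",          # morpholine
    "O=C1NC(=O)SC1{R}",       # thiazolidinedione
    "c1ccc(-c2ccc({R})cc2)cc1",  # biphenyl
    "c1ccc2cc({R})ccc2c1",    # naphthalene
    "c1cc({R})co1",           # furan
    "c1cc({R})cs1",           # thiophene
)

# two- and three-site templates push TPSA/MW/rotatable-bond coverage upward
_TEMPLATES_2 = (
    "c1cc({R1})ccc1{R2}",     # para-disubstituted benzene
    "C1CN({R1})CCN1{R2}",     # piperazine
    "O=C1NC(=O)SC1Cc1ccc({R1})c({R2})c1",  # benzyl-thiazolidinedione
)
_TEMPLATES_3 = ("c1c({R1})cc({R2})cc1{R3}",)

_SUBSTITUENTS = (
    "C",
    "CC",
    "CCC",
    "C(C)C",
    "O",
    "OC",
    "OCC",
    "N",
    "N(C)C",
    "F",
    "Cl",
    "Br",
    "C(F)(F)F",
    "C(=O)O",
    "C(=O)N",
    "S(N)(=O)=O",
    "C#N",
    "OCCOC",
    "CCCCCC",
    "CCN1CCOCC1",
)

_LINKERS = ("", "C", "CC")


@functools.lru_cache(maxsize=1)
def _enumerate_space() -> tuple[str, ...]:
    seen: dict[str, None] = {}
    # bare scaffolds first so the set reaches down to benzene-sized molecules
    raw: list[str] = [t.replace("({R})", "").replace("{R}", "") for t in _TEMPLATES_1]
    subs = [l + s for l in _LINKERS for s in _SUBSTITUENTS]
    for t in _TEMPLATES_1:
        for s in subs:
            raw.append(t.replace("{R}", s))
    for t in _TEMPLATES_2:
        for s1 in _SUBSTITUENTS:
            for s2 in _SUBSTITUENTS:
                raw.append(t.replace("{R1}", s1).replace("{R2}", s2))
    for t in _TEMPLATES_3:
        for s1 in _SUBSTITUENTS[::2]:
            for s2 in _SUBSTITUENTS[::3]:
                for s3 in _SUBSTITUENTS[::4]:
                    raw.append(t.replace("{R1}", s1).replace("{R2}", s2).replace("{R3}", s3))
    for smi in raw:
        mol = parse_molecule(smi)
        if mol.valid and mol.smiles not in seen:
            seen[mol.smiles] = None
    return tuple(seen)


def fixture_space_size() -> int:
    """Number of distinct molecules the generator can emit."""
    return len(_enumerate_space())


def generate_fixture_library(n: int, seed: int = 0) -> list[Molecule]:
    """Deterministically emit ``n`` valid, distinct drug-like molecules."""
    import numpy as np

    if n < 1:
        raise ValueError("n must be >= 1")
    space = _enumerate_space()
    if n > len(space):
        raise ValueError(
            f"requested {n} molecules but the enumerable space holds {len(space)}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(space))[:n]
    return [parse_molecule(space[i]) for i in idx]
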