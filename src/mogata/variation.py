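"""Decoupled crossover and mutation in chemical space.

Molecules are decomposed into a ring-and-linker scaffold (Bemis–Murcko style
core) and acyclic side chains with numbered attachment points.  Crossover
recombines one parent's core with side chains pooled from both parents;
mutation adds, replaces, or deletes side chains using fragments harvested
from the population plus a small built-in set.  Both operators sanitize their
products and fall back to a parent copy after a bounded number of failed
attempts, so they always return a valid molecule.

Atoms attached to the scaffold through double/triple bonds (e.g. carbonyl
oxygens on a ring) are kept inside the core so every side chain hangs off a
single breakable single bond, which is what makes decompose → reassemble an
exact round trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdmolops

from .chem import InvalidMoleculeError, Molecule, molecule_from_mol, parse_molecule

# Single-attachment fragments always available to mutation: small alkyl,
# hydroxyl, halogens, amino, methoxy, plus a few common medicinal-chemistry
# decorations.  The dummy atom marks the open valence.
BUILTIN_FRAGMENTS = (
    "*C",
    "*CC",
    "*CCC",
    "*C(C)C",
    "*O",
    "*OC",
    "*N",
    "*F",
    "*Cl",
    "*Br",
    "*C(F)(F)F",
    "*C(=O)O",
    "*C(=O)N",
    "*S(N)(=O)=O",
    "*C#N",
    "*OCC",
)

_ZIP_PARAMS = Chem.rdmolops.MolzipParams()
_ZIP_PARAMS.label = Chem.rdmolops.MolzipLabel.Isotope


@dataclass
class FragmentedMolecule:
    """Core scaffold with numbered open attachment points plus its side chains.

    The core SMILES carries dummy atoms with isotope labels 1..k; each side
    chain is ``(label, smiles)`` where the chain's dummy bears the same label.
    An acyclic molecule is all core with no side chains.
    """

    core: str
    side_chains: list[tuple[int, str]] = field(default_factory=list)

    @property
    def labels(self) -> list[int]:
        core_mol = Chem.MolFromSmiles(self.core)
        return sorted(
            a.GetIsotope() for a in core_mol.GetAtoms() if a.GetAtomicNum() == 0
        )


def _scaffold_atoms(mol: Chem.Mol) -> set[int]:
    """Ring systems + linkers, extended with multiply-bonded appendages."""
    ring_atoms = {
        a.GetIdx() for a in mol.GetAtoms() if a.IsInRing()
    }
    if not ring_atoms:
        return set()
    keep = {a.GetIdx() for a in mol.GetAtoms()}
    # iteratively prune acyclic leaves: what survives is rings plus linkers
    changed = True
    while changed:
        changed = False
        for idx in list(keep):
            if idx in ring_atoms:
                continue
            degree = sum(
                1 for nb in mol.GetAtomWithIdx(idx).GetNeighbors() if nb.GetIdx() in keep
            )
            if degree <= 1:
                keep.discard(idx)
                changed = True
    # pull multiply-bonded neighbours (e.g. =O, =N) back into the core so all
    # attachment bonds are single
    changed = True
    while changed:
        changed = False
        for bond in mol.GetBonds():
            if bond.GetBondType() == Chem.BondType.SINGLE:
                continue
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            if (i in keep) != (j in keep):
                keep.add(i if j in keep else j)
                changed = True
    return keep


def decompose(mol: Molecule) -> FragmentedMolecule:
    """Split into scaffold core and single-bond-attached acyclic side chains.

    Ring-free molecules are returned whole as the core with no side chains.
    """
    if not mol.valid:
        raise InvalidMoleculeError(f"cannot decompose invalid molecule {mol.smiles!r}")
    m = mol.mol
    core_atoms = _scaffold_atoms(m)
    if not core_atoms or len(core_atoms) == m.GetNumAtoms():
        return FragmentedMolecule(core=mol.smiles, side_chains=[])

    cut_bonds = []
    for bond in m.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if (i in core_atoms) != (j in core_atoms):
            cut_bonds.append(bond.GetIdx())
    labels = [(k, k) for k in range(1, len(cut_bonds) + 1)]
    fragmented = Chem.FragmentOnBonds(m, cut_bonds, addDummies=True, dummyLabels=labels)
    pieces = Chem.GetMolFrags(fragmented, asMols=True, sanitizeFrags=True)

    core_smiles = None
    chains: list[tuple[int, str]] = []
    for piece in pieces:
        dummies = [a for a in piece.GetAtoms() if a.GetAtomicNum() == 0]
        heavy_in_ring = any(a.IsInRing() for a in piece.GetAtoms())
        if heavy_in_ring:
            core_smiles = Chem.MolToSmiles(piece)
        else:
            assert len(dummies) == 1, "side chain must have one attachment point"
            chains.append((dummies[0].GetIsotope(), Chem.MolToSmiles(piece)))
    assert core_smiles is not None
    return FragmentedMolecule(core=core_smiles, side_chains=sorted(chains))


def _set_chain_label(chain_smiles: str, label: int) -> str:
    m = Chem.MolFromSmiles(chain_smiles)
    for a in m.GetAtoms():
        if a.GetAtomicNum() == 0:
            a.SetIsotope(label)
    return Chem.MolToSmiles(m)


def strip_label(chain_smiles: str) -> str:
    """Canonical side-chain SMILES with the attachment label removed."""
    return _set_chain_label(chain_smiles, 0)


def reassemble(frag: FragmentedMolecule) -> Molecule:
    """Zip core and side chains back together; bare labels are capped with H."""
    core = Chem.MolFromSmiles(frag.core)
    if core is None:
        raise ValueError(f"unparsable core {frag.core!r}")
    filled = {label for label, _ in frag.side_chains}
    combined = core
    for label, chain in frag.side_chains:
        chain_mol = Chem.MolFromSmiles(_set_chain_label(chain, label))
        combined = Chem.CombineMols(combined, chain_mol)
    zipped = Chem.molzip(combined, _ZIP_PARAMS)
    # cap any attachment points left bare
    rw = Chem.RWMol(zipped)
    bare = [
        a.GetIdx()
        for a in rw.GetAtoms()
        if a.GetAtomicNum() == 0 and a.GetIsotope() not in filled
    ]
    for idx in sorted(bare, reverse=True):
        rw.RemoveAtom(idx)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return molecule_from_mol(out)


@dataclass
class FragmentPool:
    """Multiset of single-attachment-point fragments for mutation.

    Fragments are stored as label-free canonical SMILES (``*C`` etc.); every
    one sanitizes when capped with hydrogen.
    """

    fragments: list[str] = field(default_factory=lambda: list(BUILTIN_FRAGMENTS))

    def add_from_population(self, molecules: list[Molecule]) -> None:
        for mol in molecules:
            if not mol.valid:
                continue
            try:
                frag = decompose(mol)
            except (InvalidMoleculeError, Chem.rdchem.MolSanitizeException):
                continue
            for _, chain in frag.side_chains:
                self.fragments.append(strip_label(chain))

    def sample(self, rng: np.random.Generator) -> str:
        return self.fragments[int(rng.integers(len(self.fragments)))]


def _substitutable_atoms(mol: Chem.Mol) -> list[int]:
    return [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() >= 1]


def _attach_fragment(mol: Chem.Mol, atom_idx: int, fragment_smiles: str) -> Chem.Mol:
    """Bond a *-marked fragment to the given atom via a new single bond."""
    frag = Chem.MolFromSmiles(fragment_smiles)
    dummy_local = next(a.GetIdx() for a in frag.GetAtoms() if a.GetAtomicNum() == 0)
    anchor_local = frag.GetAtomWithIdx(dummy_local).GetNeighbors()[0].GetIdx()
    offset = mol.GetNumAtoms()
    rw = Chem.RWMol(Chem.CombineMols(mol, frag))
    target = rw.GetAtomWithIdx(atom_idx)
    if target.GetNumExplicitHs() > 0:
        target.SetNumExplicitHs(target.GetNumExplicitHs() - 1)
    rw.AddBond(atom_idx, offset + anchor_local, Chem.BondType.SINGLE)
    rw.RemoveAtom(offset + dummy_local)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out


def crossover(
    a: Molecule,
    b: Molecule,
    rng: np.random.Generator,
    max_attempts: int = 10,
    bare_prob: float = 0.2,
) -> Molecule:
    """Recombine one parent's core with side chains pooled from both parents.

    Each attachment point of the chosen core receives a chain sampled
    uniformly from the union of both parents' side chains, or is left bare
    with probability ``bare_prob``.  Falls back to a copy of a random parent
    if every attempt fails to sanitize, so the result is always valid.
    """
    try:
        frag_a, frag_b = decompose(a), decompose(b)
    except (InvalidMoleculeError, Chem.rdchem.MolSanitizeException, ValueError):
        return a if rng.random() < 0.5 else b
    pool = [strip_label(c) for _, c in frag_a.side_chains + frag_b.side_chains]
    for _ in range(max_attempts):
        core_frag = frag_a if rng.random() < 0.5 else frag_b
        chains: list[tuple[int, str]] = []
        for label in core_frag.labels:
            if not pool or rng.random() < bare_prob:
                continue
            chains.append((label, pool[int(rng.integers(len(pool)))]))
        try:
            child = reassemble(FragmentedMolecule(core=core_frag.core, side_chains=chains))
            if child.valid:
                return child
        except (Chem.rdchem.MolSanitizeException, ValueError, RuntimeError):
            continue
    return a if rng.random() < 0.5 else b


def mutate(
    a: Molecule,
    pool: FragmentPool,
    rng: np.random.Generator,
    max_attempts: int = 10,
) -> Molecule:
    """Add, replace, or delete one side chain (uniform choice of operation).

    Delete/replace need an existing side chain and fall back to add when the
    molecule has none; add grafts a pool fragment onto a random atom with a
    free hydrogen.  Falls back to the unmodified parent after
    ``max_attempts`` failures — the output is always valid.
    """
    if not a.valid:
        raise InvalidMoleculeError("cannot mutate an invalid molecule")
    for _ in range(max_attempts):
        try:
            frag = decompose(a)
        except (Chem.rdchem.MolSanitizeException, ValueError):
            return a
        op = ("add", "replace", "delete")[int(rng.integers(3))]
        if op in ("replace", "delete") and not frag.side_chains:
            op = "add"
        try:
            if op == "add":
                candidates = _substitutable_atoms(a.mol)
                if not candidates:
                    return a
                atom_idx = candidates[int(rng.integers(len(candidates)))]
                out = _attach_fragment(a.mol, atom_idx, pool.sample(rng))
                child = molecule_from_mol(out)
            else:
                chains = list(frag.side_chains)
                pos = int(rng.integers(len(chains)))
                if op == "delete":
                    chains.pop(pos)
                else:
                    chains[pos] = (chains[pos][0], pool.sample(rng))
                child = reassemble(FragmentedMolecule(core=frag.core, side_chains=chains))
            if child.valid:
                return child
        except (Chem.rdchem.MolSanitizeException, ValueError, RuntimeError, Chem.rdchem.KekulizeException):
            continue
    return a


def make_offspring(
    pop,
    n_offspring: int,
    task,
    rng: np.random.Generator,
    crossover_fraction: float = 0.5,
    max_attempts: int = 10,
    bare_prob: float = 0.2,
    pool: FragmentPool | None = None,
):
    """Produce ``n_offspring`` scored individuals by crossover and mutation.

    Parents are drawn fitness-proportionally; a ``crossover_fraction`` share
    of the offspring comes from core/side-chain recombination and the rest
    from side-chain mutation against ``pool`` (harvested from the population
    plus the built-in fragments when not supplied).
    """
    from .moea import make_individual, select_parents

    if n_offspring <= 0:
        raise ValueError("n_offspring must be positive")
    if pool is None:
        pool = FragmentPool()
        pool.add_from_population([ind.molecule for ind in pop.members])
    n_cross = int(round(crossover_fraction * n_offspring))
    offspring = []
    for _ in range(n_cross):
        pa, pb = select_parents(pop, 2, rng)
        child = crossover(pa.molecule, pb.molecule, rng, max_attempts, bare_prob)
        offspring.append(make_individual(child, task))
    for _ in range(n_offspring - n_cross):
        (pa,) = select_parents(pop, 1, rng)
        child = mutate(pa.molecule, pool, rng, max_attempts)
        offspring.append(make_individual(child, task))
    return offspring
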