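"""Molecule handling, fingerprints, and Tanimoto similarity/distance.

A :class:`Molecule` is identified by its canonical SMILES; fingerprints are
typed on-bit sets supporting exact intersection/union counting, which makes
the Tanimoto (Jaccard) coefficient

    sim(A, B) = |A ∩ B| / |A ∪ B|,     dist = 1 − sim

exact on the folded bit space.  Five fingerprint kinds are supported:
extended-connectivity (ECFP4/ECFP6), their pharmacophoric-feature variants
(FCFP4/FCFP6), and the topological atom-pair fingerprint (AP).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

# The GA loop probes many candidate structures that fail sanitization; RDKit's
# per-molecule error/warning chatter would otherwise drown the run logs.
RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")

FINGERPRINT_KINDS = ("ECFP4", "ECFP6", "FCFP4", "FCFP6", "AP")

DEFAULT_NBITS = 2048


class InvalidMoleculeError(ValueError):
    """Raised when an operation requires a valid (sanitized) molecule."""


class FingerprintMismatchError(ValueError):
    """Raised when comparing fingerprints of different kind or folded length."""


@dataclass(frozen=True)
class Fingerprint:
    """A typed set of on-bit indices folded to ``nbits`` positions."""

    kind: str
    bits: frozenset[int]
    nbits: int = DEFAULT_NBITS

    def __post_init__(self) -> None:
        if self.kind not in FINGERPRINT_KINDS:
            raise ValueError(f"unknown fingerprint kind {self.kind!r}")
        if self.nbits <= 0 or (self.nbits & (self.nbits - 1)) != 0:
            raise ValueError(f"nbits must be a positive power of two, got {self.nbits}")
        if self.bits and (min(self.bits) < 0 or max(self.bits) >= self.nbits):
            raise ValueError("bit index out of range for folded length")

    def __len__(self) -> int:
        return len(self.bits)


@dataclass
class Molecule:
    """A sanitized structure with canonical-SMILES identity.

    Invalid inputs produce a ``Molecule`` with ``valid=False`` rather than an
    exception, so chemistry failures can flow through the GA loop as data.
    Fingerprints and the parsed RDKit mol are cached per instance; two
    molecules with equal canonical SMILES give identical fingerprints.
    """

    smiles: str
    valid: bool = True
    _mol: Chem.Mol | None = field(default=None, repr=False, compare=False)
    _fp_cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def mol(self) -> Chem.Mol:
        if not self.valid:
            raise InvalidMoleculeError(f"invalid molecule: {self.smiles!r}")
        if self._mol is None:
            self._mol = Chem.MolFromSmiles(self.smiles)
        return self._mol

    def __eq__(self, other) -> bool:
        return isinstance(other, Molecule) and (self.smiles, self.valid) == (
            other.smiles,
            other.valid,
        )

    def __hash__(self) -> int:
        return hash((self.smiles, self.valid))


def parse_molecule(smiles: str) -> Molecule:
    """Parse and sanitize a SMILES string.

    Returns a valid :class:`Molecule` carrying the canonical SMILES, or a
    marked-invalid one (never raises for bad input strings).
    """
    if not isinstance(smiles, str) or not smiles.strip():
        return Molecule(smiles=str(smiles), valid=False)
    mol = Chem.MolFromSmiles(smiles.strip())
    if mol is None:
        return Molecule(smiles=smiles.strip(), valid=False)
    return Molecule(smiles=Chem.MolToSmiles(mol), valid=True, _mol=mol)


def molecule_from_mol(mol: Chem.Mol) -> Molecule:
    """Wrap an already-sanitized RDKit mol."""
    return Molecule(smiles=Chem.MolToSmiles(mol), valid=True, _mol=mol)


@functools.lru_cache(maxsize=8)
def _generator(kind: str, nbits: int):
    if kind in ("ECFP4", "ECFP6", "FCFP4", "FCFP6"):
        radius = {"4": 2, "6": 3}[kind[-1]]
        inv = (
            rdFingerprintGenerator.GetMorganFeatureAtomInvGen()
            if kind.startswith("F")
            else None
        )
        return rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=nbits, atomInvariantsGenerator=inv
        )
    if kind == "AP":
        return rdFingerprintGenerator.GetAtomPairGenerator(fpSize=nbits)
    raise ValueError(f"unknown fingerprint kind {kind!r}")


def compute_fingerprint(
    mol: Molecule, kind: str = "ECFP4", nbits: int = DEFAULT_NBITS
) -> Fingerprint:
    """Folded on-bit set of the given kind; deterministic per canonical SMILES."""
    if kind not in FINGERPRINT_KINDS:
        raise ValueError(f"unknown fingerprint kind {kind!r}")
    if not mol.valid:
        raise InvalidMoleculeError(f"cannot fingerprint invalid molecule {mol.smiles!r}")
    key = (kind, nbits)
    cached = mol._fp_cache.get(key)
    if cached is None:
        bv = _generator(kind, nbits).GetFingerprint(mol.mol)
        cached = Fingerprint(kind=kind, bits=frozenset(bv.GetOnBits()), nbits=nbits)
        mol._fp_cache[key] = cached
    return cached


def _check_comparable(a: Fingerprint, b: Fingerprint) -> None:
    if a.kind != b.kind or a.nbits != b.nbits:
        raise FingerprintMismatchError(
            f"cannot compare {a.kind}/{a.nbits} with {b.kind}/{b.nbits}"
        )


def tanimoto_similarity(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto (Jaccard) coefficient |A∩B| / |A∪B| in [0, 1].

    Two empty fingerprints are identical objects, so their similarity is 1;
    empty versus non-empty is 0.
    """
    _check_comparable(a, b)
    union = len(a.bits | b.bits)
    if union == 0:
        return 1.0
    return len(a.bits & b.bits) / union


def tanimoto_distance(a: Fingerprint, b: Fingerprint) -> float:
    """Jaccard distance 1 − |A∩B|/|A∪B|; a metric on bit sets."""
    return 1.0 - tanimoto_similarity(a, b)


def molecule_similarity(
    a: Molecule, b: Molecule, kind: str = "ECFP4", nbits: int = DEFAULT_NBITS
) -> float:
    """Tanimoto similarity between two molecules on fingerprints of ``kind``."""
    return tanimoto_similarity(
        compute_fingerprint(a, kind, nbits), compute_fingerprint(b, kind, nbits)
    )
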