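"""Molecular handler: parsing, identity and descriptor perception.

All structure perception in the package goes through this module so that a
single toolkit (RDKit) defines atom typing, aromaticity and canonical
identity.  Structures are exchanged as MDL V2000 molblocks; identity is the
standard InChI with stereochemistry layers included, so two records are the
same molecule exactly when their InChI strings are equal.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from functools import lru_cache

from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski, inchi

RDLogger.DisableLog("rdApp.*")

HANDLER_NAME = "rdkit"

#: Halogen atomic numbers (F, Cl, Br, I).
HALOGENS = frozenset((9, 17, 35, 53))


class MoleculeError(ValueError):
    """A structure that the handler cannot perceive (bad format, valence...)."""


def mol_from_molblock(molblock: str) -> Chem.Mol:
    """Parse an MDL V2000 connection table into a sanitized molecule.

    V3000 records are rejected explicitly; any sanitization failure
    (e.g. impossible valence) raises :class:`MoleculeError` so that callers
    can record a per-record error instead of aborting a batch.
    """
    if "V3000" in molblock:
        raise MoleculeError("V3000 connection tables are not supported")
    mol = Chem.MolFromMolBlock(molblock, sanitize=True, removeHs=True)
    if mol is None:
        raise MoleculeError("handler could not perceive the connection table")
    return mol


def mol_to_molblock(mol: Chem.Mol) -> str:
    return Chem.MolToMolBlock(mol)


def mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeError(f"unparseable SMILES: {smiles!r}")
    return mol


def compute_inchi(molblock: str) -> tuple[str, str]:
    """Standard InChI and 27-character InChIKey for a molblock.

    Stereochemistry is kept: enantiomer molblocks map to distinct strings,
    while atom-order permutations of one structure map to the same string.
    """
    mol = mol_from_molblock(molblock)
    return inchi_for_mol(mol)


def inchi_for_mol(mol: Chem.Mol) -> tuple[str, str]:
    ich = inchi.MolToInchi(mol)
    if not ich:
        raise MoleculeError("InChI generation failed")
    return ich, inchi.InchiToInchiKey(ich)


@dataclass(frozen=True)
class DescriptorSet:
    """The simple physicochemical profile computed for every stored molecule.

    ``ring_count`` is the SSSR count and ``max_ring_size`` the size of the
    largest SSSR ring (0 for acyclic molecules).  ``hba``/``hbd`` follow the
    Lipinski N/O and NH/OH conventions.
    """

    weight: float
    logp: float
    heavy_atoms: int
    hba: int
    hbd: int
    halogens: int
    rot_bonds: int
    ring_count: int
    max_ring_size: int

    def as_dict(self) -> dict:
        return asdict(self)

    NAMES = (
        "weight", "logp", "heavy_atoms", "hba", "hbd",
        "halogens", "rot_bonds", "ring_count", "max_ring_size",
    )


def compute_descriptors(molblock: str) -> DescriptorSet:
    return descriptors_for_mol(mol_from_molblock(molblock))


def descriptors_for_mol(mol: Chem.Mol) -> DescriptorSet:
    ring_info = mol.GetRingInfo()
    ring_sizes = [len(r) for r in ring_info.AtomRings()]
    return DescriptorSet(
        weight=Descriptors.MolWt(mol),
        logp=Crippen.MolLogP(mol),
        heavy_atoms=mol.GetNumHeavyAtoms(),
        hba=Lipinski.NumHAcceptors(mol),
        hbd=Lipinski.NumHDonors(mol),
        halogens=sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() in HALOGENS),
        rot_bonds=Lipinski.NumRotatableBonds(mol),
        ring_count=ring_info.NumRings(),
        max_ring_size=max(ring_sizes, default=0),
    )


def n_fragments(mol: Chem.Mol) -> int:
    return len(Chem.GetMolFrags(mol))


@lru_cache(maxsize=8192)
def compile_smarts(smarts: str) -> Chem.Mol:
    """Compile a SMARTS query, merging explicit-hydrogen query atoms.

    Merging lets patterns written with explicit ``[#1]`` atoms (as the PAINS
    transcription is) match ordinary implicit-hydrogen molecules.  Compiled
    queries are memoised; treat them as read-only.
    """
    query = Chem.MolFromSmarts(smarts, mergeHs=True)
    if query is None:
        raise MoleculeError(f"unparseable SMARTS: {smarts!r}")
    return query


def matches_smarts(mol: Chem.Mol, query: Chem.Mol) -> bool:
    return mol.HasSubstructMatch(query)
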