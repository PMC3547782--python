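"""Scaffold and framework extraction and reporting.

The scaffold of a molecule is its Bemis–Murcko core: the union of ring
systems and the linker atoms connecting them, with lateral chains removed —
except that an atom attached by a double bond to a kept atom is retained
(exocyclic double bonds, e.g. the carbonyl oxygen of a ring ketone).  A
fully acyclic molecule maps to the single-carbon core, so every molecule
has exactly one scaffold.

The framework abstracts the scaffold to its graph: the exocyclic
double-bonded atoms are dropped, every remaining atom becomes carbon and
every bond becomes single — except bonds inside 6-membered aromatic rings,
which stay aromatic (pyridine and benzene share the benzene framework;
furan's 5-membered aromaticity is *not* kept and its framework is
cyclopentane).

Core identity is the InChI of the core structure, consistent with the
store-wide deduplication convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

from rdkit import Chem

from .chem import MoleculeError, inchi_for_mol, mol_from_molblock
from .store import MoleculeRecord, MoleculeStore, Scope

_SINGLE_CARBON = Chem.MolFromSmiles("C")


def _as_mol(molblock_or_mol) -> Chem.Mol:
    if isinstance(molblock_or_mol, Chem.Mol):
        return molblock_or_mol
    return mol_from_molblock(molblock_or_mol)


def _ring_linker_atoms(mol: Chem.Mol) -> set[int]:
    """Ring atoms plus the atoms on chains connecting rings, found by
    iteratively pruning non-ring leaves of the heavy-atom graph."""
    keep = {a.GetIdx() for a in mol.GetAtoms()}
    in_ring = {a.GetIdx() for a in mol.GetAtoms() if a.IsInRing()}
    changed = True
    while changed:
        changed = False
        for idx in list(keep):
            if idx in in_ring:
                continue
            atom = mol.GetAtomWithIdx(idx)
            degree = sum(1 for n in atom.GetNeighbors() if n.GetIdx() in keep)
            if degree <= 1:
                keep.discard(idx)
                changed = True
    return keep


def _scaffold_atoms(mol: Chem.Mol) -> set[int]:
    core = _ring_linker_atoms(mol)
    extra = set()
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.DOUBLE:
            continue
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if (a in core) != (b in core):
            extra.add(b if a in core else a)
    return core | extra


def _submol(mol: Chem.Mol, keep: set[int]) -> Chem.Mol:
    rw = Chem.RWMol(mol)
    for idx in sorted((a.GetIdx() for a in mol.GetAtoms() if a.GetIdx() not in keep), reverse=True):
        rw.RemoveAtom(idx)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out


def extract_scaffold(molblock_or_mol) -> str:
    """Scaffold of a molecule, as a canonical molblock."""
    return Chem.MolToMolBlock(scaffold_mol(_as_mol(molblock_or_mol)))


def scaffold_mol(mol: Chem.Mol) -> Chem.Mol:
    if mol.GetRingInfo().NumRings() == 0:
        return Chem.Mol(_SINGLE_CARBON)
    return _submol(mol, _scaffold_atoms(mol))


def extract_framework(molblock_or_mol) -> str:
    """Framework of a molecule, as a canonical molblock."""
    return Chem.MolToMolBlock(framework_mol(_as_mol(molblock_or_mol)))


def framework_mol(mol: Chem.Mol) -> Chem.Mol:
    if mol.GetRingInfo().NumRings() == 0:
        return Chem.Mol(_SINGLE_CARBON)
    core = _submol(mol, _ring_linker_atoms(mol))
    try:
        return _genericise(core, keep_aromatic_6=True)
    except Exception:
        # Valence-degenerate corner case: fall back to the all-single-bond
        # carbon skeleton.
        return _genericise(core, keep_aromatic_6=False)


def _genericise(core: Chem.Mol, keep_aromatic_6: bool) -> Chem.Mol:
    rw = Chem.RWMol(core)
    Chem.RemoveStereochemistry(rw)
    aromatic_bonds: set[int] = set()
    if keep_aromatic_6:
        ring_info = core.GetRingInfo()
        for bond_ring in ring_info.BondRings():
            if len(bond_ring) == 6 and all(
                core.GetBondWithIdx(b).GetIsAromatic() for b in bond_ring
            ):
                aromatic_bonds.update(bond_ring)
    aromatic_atoms = {
        a
        for b in aromatic_bonds
        for a in (
            rw.GetBondWithIdx(b).GetBeginAtomIdx(),
            rw.GetBondWithIdx(b).GetEndAtomIdx(),
        )
    }
    for atom in rw.GetAtoms():
        atom.SetAtomicNum(6)
        atom.SetFormalCharge(0)
        atom.SetNumRadicalElectrons(0)
        atom.SetIsotope(0)
        atom.SetNoImplicit(False)
        atom.SetNumExplicitHs(0)
        atom.SetIsAromatic(atom.GetIdx() in aromatic_atoms)
    for bond in rw.GetBonds():
        if bond.GetIdx() in aromatic_bonds:
            bond.SetBondType(Chem.BondType.AROMATIC)
            bond.SetIsAromatic(True)
        else:
            bond.SetBondType(Chem.BondType.SINGLE)
            bond.SetIsAromatic(False)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out


def assign_cores(store: MoleculeStore, mol: Chem.Mol) -> tuple[int, int]:
    """Scaffold and framework core ids for a molecule, creating the core
    entries on first sight."""
    smol = scaffold_mol(mol)
    fmol = framework_mol(mol)
    s_inchi, _ = inchi_for_mol(smol)
    f_inchi, _ = inchi_for_mol(fmol)
    scaffold_id = store.get_or_create_core("scaffold", s_inchi, Chem.MolToMolBlock(smol))
    framework_id = store.get_or_create_core("framework", f_inchi, Chem.MolToMolBlock(fmol))
    return scaffold_id, framework_id


@dataclass
class ScaffoldReport:
    """Representativity summary of the cores covering a molecule set."""

    mode: str
    n_molecules: int
    n_cores: int
    pct_of_molecules: float
    n_singletons: int
    pct_singleton_molecules: float
    cum_freq_50: tuple[int, float]  # (n cores, % of cores)
    cum_freq_80: tuple[int, float]
    top_k: list[tuple[int, str, int]]  # (core_id, core InChI, n_members)

    def as_dict(self) -> dict:
        return {
            "mode": self.mode,
            "n_molecules": self.n_molecules,
            "n_cores": self.n_cores,
            "pct_of_molecules": self.pct_of_molecules,
            "n_singletons": self.n_singletons,
            "pct_singleton_molecules": self.pct_singleton_molecules,
            "cum_freq_50": list(self.cum_freq_50),
            "cum_freq_80": list(self.cum_freq_80),
            "top_k": [list(t) for t in self.top_k],
        }


def _cum_freq(sorted_counts: list[int], n_molecules: int, pct: float) -> int:
    """Minimum number of cores, largest first, covering ``pct``% of molecules."""
    target = pct / 100.0 * n_molecules
    total = 0
    for i, c in enumerate(sorted_counts, start=1):
        total += c
        if total >= target:
            return i
    return len(sorted_counts)


def scaffold_report(
    store: MoleculeStore,
    scope: Scope = None,
    mode: str = "scaffold",
    k: int = 20,
) -> ScaffoldReport:
    if mode not in ("scaffold", "framework"):
        raise ValueError("mode must be 'scaffold' or 'framework'")
    mol_ids = store.resolve_scope(scope)
    if not mol_ids:
        raise ValueError("empty scope")
    partition = store.core_partition(mode, mol_ids)
    counts = {cid: len(members) for cid, members in partition.items()}
    n_mol, n_cores = len(mol_ids), len(counts)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    sorted_counts = [c for _, c in ordered]
    n50 = _cum_freq(sorted_counts, n_mol, 50.0)
    n80 = _cum_freq(sorted_counts, n_mol, 80.0)
    n_singletons = sum(1 for c in sorted_counts if c == 1)
    top = [
        (cid, store.core(cid)[1], c) for cid, c in ordered[: max(k, 0)]
    ]
    return ScaffoldReport(
        mode=mode,
        n_molecules=n_mol,
        n_cores=n_cores,
        pct_of_molecules=100.0 * n_cores / n_mol,
        n_singletons=n_singletons,
        pct_singleton_molecules=100.0 * n_singletons / n_mol,
        cum_freq_50=(n50, 100.0 * n50 / n_cores),
        cum_freq_80=(n80, 100.0 * n80 / n_cores),
        top_k=top,
    )


def molecules_of_core(store: MoleculeStore, core_id: int) -> list[MoleculeRecord]:
    """All member molecules of a scaffold/framework core, usable as a library
    source."""
    return [store.get_record(m) for m in store.core_members(core_id)]
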