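"""Synthetic SDF fixture generation with construction-time ground truth.

Structures are built by decorating a pool of ring cores with saturated
substituents, so each family shares one scaffold by construction; acyclic
molecules, liability-bearing molecules (grafted reactive / warhead / PAINS
substructures, verified against the loaded pattern sets at build time),
stereo pairs, atom-order-shuffled duplicates and corrupt records are added
on demand.  The generator returns a manifest holding the expected unique
count, scaffold/framework partition and flag counts, making every fixture
its own oracle.  Generation is byte-deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from rdkit import Chem

from .chem import inchi_for_mol, mol_from_smiles
from .flags import SMARTS_FLAGS, load_flag_definitions, match_flag
from . import sdf as sdfio

#: (core SMILES, hand-derived framework SMILES).  Cores open with a ring atom
#: so a substituent prefix attaches by plain SMILES concatenation.
CORES: list[tuple[str, str]] = [
    ("c1ccccc1", "c1ccccc1"),
    ("c1ccncc1", "c1ccccc1"),
    ("C1CCCCC1", "C1CCCCC1"),
    ("C1CCNCC1", "C1CCCCC1"),
    ("c1ccc2ccccc2c1", "c1ccc2ccccc2c1"),
    ("c1ccc(-c2ccccc2)cc1", "c1ccc(-c2ccccc2)cc1"),
    ("c1ccoc1", "C1CCCC1"),
    ("c1ccsc1", "C1CCCC1"),
    ("c1ccc2c(c1)cc[nH]2", "C1Cc2ccccc2C1"),
    ("C1CCOC1", "C1CCCC1"),
]

#: Saturated substituent prefixes; the last written atom bonds to the core.
SUBSTITUENTS = [
    "", "C", "CC", "CCC", "CCCC", "CCCCC", "CC(C)", "CC(C)C",
    "OCC", "OCCC", "COCC", "NCC", "NCCC", "CNCC", "OC(C)C", "CCOCC",
    "NC(C)C", "CCCCCC", "CC(C)CC", "COCCC", "NCCCC", "OCCCC",
    "CCC(C)C", "CCNCC",
]

ACYCLIC = [
    "CCCCCC", "CCCCCCC", "CCCCCCCC", "CCOCCC", "CCCCO",
    "CCNCCC", "CCCCCO", "CCOCCO", "CCCCNC", "CCCCCN",
]

#: flag -> [(SMILES, scaffold SMILES, framework SMILES)], each verified to
#: match its flag when the fixture is built.
FLAGGED_TEMPLATES: dict[str, list[tuple[str, str, str]]] = {
    "Reactive": [
        ("O=C(CCl)c1ccccc1", "c1ccccc1", "c1ccccc1"),
        ("O=C(Cl)c1ccccc1", "c1ccccc1", "c1ccccc1"),
        ("ClCC(=O)CCCC", "C", "C"),
    ],
    "Warhead": [
        ("C=CS(=O)(=O)c1ccccc1", "c1ccccc1", "c1ccccc1"),
        ("O=C1C=CC(=O)N1C", "O=C1C=CC(=O)N1", "C1CCCC1"),
    ],
    "PAINS_lt15": [
        ("CCC=S", "C", "C"),
    ],
    "PAINS_lt150": [
        ("Oc1ccccc1O", "c1ccccc1", "c1ccccc1"),
        ("O=C1CSC(=S)N1", "O=C1CSC(=S)N1", "C1CCCC1"),
    ],
    "PAINS_gt150": [
        ("O=C1C=CC(=O)C=C1", "O=C1C=CC(=O)C=C1", "C1CCCCC1"),
    ],
}

#: chiral template for stereo pairs: ethyl / H / hydroxyl / phenyl centre.
_STEREO = ("{chain}CC[C@@H](O)c1ccccc1", "{chain}CC[C@H](O)c1ccccc1")


@dataclass
class FixtureSpec:
    n_scaffold_families: int = 3
    members_per_family: Union[int, Sequence[int]] = 4
    n_acyclic: int = 0
    n_flagged: dict[str, int] = field(default_factory=dict)
    n_duplicates: int = 0
    n_stereo_pairs: int = 0
    n_corrupt: int = 0
    seed: int = 0
    #: first core used; lets two fixtures draw disjoint scaffold families.
    family_offset: int = 0

    def family_sizes(self) -> list[int]:
        if isinstance(self.members_per_family, int):
            return [self.members_per_family] * self.n_scaffold_families
        sizes = list(self.members_per_family)
        if len(sizes) != self.n_scaffold_families:
            raise ValueError("members_per_family length != n_scaffold_families")
        return sizes

    def validate(self) -> None:
        sizes = self.family_sizes()
        if self.family_offset < 0:
            raise ValueError("family_offset must be >= 0")
        if self.family_offset + self.n_scaffold_families > len(CORES):
            raise ValueError(f"at most {len(CORES)} scaffold families available")
        if any(s < 1 for s in sizes):
            raise ValueError("family sizes must be >= 1")
        if max(sizes, default=1) > len(SUBSTITUENTS):
            raise ValueError(f"at most {len(SUBSTITUENTS)} members per family")
        if self.n_acyclic > len(ACYCLIC):
            raise ValueError(f"at most {len(ACYCLIC)} acyclic molecules")
        for flag, n in self.n_flagged.items():
            if flag not in FLAGGED_TEMPLATES:
                raise ValueError(f"no flagged templates for {flag!r}")
            if n > len(FLAGGED_TEMPLATES[flag]):
                raise ValueError(
                    f"at most {len(FLAGGED_TEMPLATES[flag])} {flag} molecules"
                )
        if any(v < 0 for v in (
            self.n_acyclic, self.n_duplicates, self.n_stereo_pairs, self.n_corrupt
        )):
            raise ValueError("counts must be >= 0")


@dataclass
class _Structure:
    name: str
    smiles: str
    scaffold_smiles: str
    framework_smiles: str
    mol: Chem.Mol = None
    inchi: str = ""


def _build_structures(spec: FixtureSpec) -> list[_Structure]:
    structures: list[_Structure] = []

    def add(smiles: str, scaffold: str, framework: str) -> None:
        structures.append(
            _Structure(f"mol_{len(structures) + 1:04d}", smiles, scaffold, framework)
        )

    for fam, size in enumerate(spec.family_sizes()):
        core, framework = CORES[spec.family_offset + fam]
        for i in range(size):
            add(SUBSTITUENTS[i] + core, core, framework)
    for i in range(spec.n_acyclic):
        add(ACYCLIC[i], "C", "C")
    for flag in sorted(spec.n_flagged):
        for i in range(spec.n_flagged[flag]):
            add(*FLAGGED_TEMPLATES[flag][i])
    for i in range(spec.n_stereo_pairs):
        chain = "C" * i
        for template in _STEREO:
            add(template.format(chain=chain), "c1ccccc1", "c1ccccc1")

    seen: dict[str, str] = {}
    for s in structures:
        s.mol = mol_from_smiles(s.smiles)
        s.inchi, _ = inchi_for_mol(s.mol)
        if s.inchi in seen:
            raise ValueError(
                f"fixture collision: {s.smiles} duplicates {seen[s.inchi]}"
            )
        seen[s.inchi] = s.smiles
    return structures


_CORRUPT_RECORD = (
    "corrupt_{i}\n     fixture\n\n"
    "  5  4  0  0  0  0  0  0  0  0999 V2000\n"
    "    0.0000    0.0000    0.0000 C   0  0\n"
    "    1.0000    ???        gibberish\n"
    "M  END\n"
)


def generate_fixture(
    spec: FixtureSpec,
    path: Union[str, Path],
    manifest_path: Optional[Union[str, Path]] = None,
) -> dict:
    """Write the SDF described by ``spec``; return (and optionally write) the
    ground-truth manifest."""
    spec.validate()
    structures = _build_structures(spec)
    if spec.n_duplicates > len(structures):
        raise ValueError("more duplicates requested than structures generated")
    rng = np.random.default_rng(spec.seed)

    flag_defs = {
        d.name: d for d in load_flag_definitions() if d.kind == "smarts-set"
    }
    for flag, n in spec.n_flagged.items():
        for smiles, _, _ in FLAGGED_TEMPLATES[flag][:n]:
            if not match_flag(mol_from_smiles(smiles), flag_defs[flag]):
                raise ValueError(
                    f"template {smiles!r} no longer matches the {flag} set"
                )
    structure_flags = {
        s.name: [
            flag
            for flag in SMARTS_FLAGS
            if flag_defs[flag].patterns and match_flag(s.mol, flag_defs[flag])
        ]
        for s in structures
    }
    flag_counts = {
        flag: sum(1 for fl in structure_flags.values() if flag in fl)
        for flag in SMARTS_FLAGS
        if flag_defs[flag].patterns
    }
    undesired = ("Reactive", "Warhead", "PAINS_lt15", "PAINS_lt150", "PAINS_gt150")
    n_undesired = sum(
        1 for fl in structure_flags.values() if any(f in undesired for f in fl)
    )

    records: list[tuple[str, dict[str, str]]] = []
    for s in structures:
        records.append((_named_molblock(s.mol, s.name), {"NAME": s.name}))
    dup_idx = sorted(
        rng.choice(len(structures), size=spec.n_duplicates, replace=False).tolist()
    )
    for i in dup_idx:
        s = structures[i]
        perm = rng.permutation(s.mol.GetNumAtoms()).tolist()
        shuffled = Chem.RenumberAtoms(s.mol, perm)
        records.append(
            (_named_molblock(shuffled, f"dup_of_{s.name}"), {"NAME": f"dup_of_{s.name}"})
        )
    for i in range(spec.n_corrupt):
        records.append((_CORRUPT_RECORD.format(i=i + 1), {}))

    order = rng.permutation(len(records)).tolist()
    path = Path(path)
    with path.open("w") as fh:
        for i in order:
            molblock, props = records[i]
            sdfio.write_record(fh, molblock, props)

    scaffold_inchis = {
        inchi_for_mol(mol_from_smiles(s.scaffold_smiles))[0] for s in structures
    }
    framework_inchis = {
        inchi_for_mol(mol_from_smiles(s.framework_smiles))[0] for s in structures
    }
    manifest = {
        "n_records": len(records),
        "n_structures": len(structures),
        "n_duplicate_records": spec.n_duplicates,
        "n_corrupt": spec.n_corrupt,
        "expected_unique": len(structures),
        "expected_scaffolds": len(scaffold_inchis),
        "expected_frameworks": len(framework_inchis),
        "expected_flag_counts": flag_counts,
        "n_undesired": n_undesired,
        "families": [
            {"core": CORES[spec.family_offset + f][0], "n_members": size}
            for f, size in enumerate(spec.family_sizes())
        ],
        "structures": [
            {
                "name": s.name,
                "smiles": s.smiles,
                "inchi": s.inchi,
                "scaffold": s.scaffold_smiles,
                "framework": s.framework_smiles,
                "flags": structure_flags[s.name],
            }
            for s in structures
        ],
        "spec": {**asdict(spec), "members_per_family": spec.family_sizes()},
    }
    if manifest_path is not None:
        Path(manifest_path).write_text(json.dumps(manifest, indent=2))
    return manifest


def _named_molblock(mol: Chem.Mol, name: str) -> str:
    mol = Chem.Mol(mol)
    mol.SetProp("_Name", name)
    return Chem.MolToMolBlock(mol)
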