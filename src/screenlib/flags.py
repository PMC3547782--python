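"""HTS-liability flags: SMARTS-set flags and descriptor-rule flags.

Five SMARTS-set flags ship with the package — Reactive (15 patterns),
Warhead (20), and the three PAINS hit-frequency tiers (409 / 55 / 16
patterns) — plus an initially empty User set.  A molecule's flag is 1 iff it
matches at least one *active* pattern of the set; patterns can be added,
deactivated or deleted in the store and all values recomputed at any time.

Four rule flags complement them: RO5 (Lipinski fail, >=2 violations by
default), RO3 (fragment rule-of-3 pass), Exotic (element outside the typed
set) and Salt (disconnected structure).

The PAINS SMARTS are the public transcription of the original filter
families, read from the host toolkit's data directory and assigned to tiers
by the screening hit count embedded in each pattern's registry name
(<15 / 15-150 / >150 hits).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

from rdkit import Chem
from rdkit.Chem import RDConfig

from .chem import (
    DescriptorSet,
    MoleculeError,
    compile_smarts,
    mol_from_molblock,
    n_fragments,
)
from .store import MoleculeStore, Scope

SMARTS_FLAGS = ("Reactive", "Warhead", "PAINS_lt15", "PAINS_lt150", "PAINS_gt150", "User")
RULE_FLAGS = ("RO5", "RO3", "Exotic", "Salt")
ALL_FLAGS = SMARTS_FLAGS + RULE_FLAGS

#: Elements the handler is considered to type reliably; anything else raises
#: the Exotic flag.  Overridable via RuleConfig.
DEFAULT_ELEMENTS = frozenset("H B C N O F Si P S Cl Se Br I".split())

_PAINS_REGID = re.compile(r"<regId=(?P<name>.+?)\((?P<hits>\d+)\)>")


@dataclass(frozen=True)
class SmartsPattern:
    name: str
    smarts: str
    active: bool = True


@dataclass
class FlagDefinition:
    """A named flag: either a set of SMARTS patterns or a descriptor rule."""

    name: str
    kind: str  # 'smarts-set' | 'rule'
    patterns: list[SmartsPattern] = field(default_factory=list)

    def __post_init__(self):
        for p in self.patterns:
            compile_smarts(p.smarts)  # raises on an unparseable pattern


@dataclass(frozen=True)
class RuleConfig:
    """Tunables of the rule flags.

    ``ro5_violations`` is the number of Lipinski violations that makes a
    molecule fail the rule of 5 (classic criterion: 2; set to 1 for the
    stricter reading).
    """

    ro5_violations: int = 2
    allowed_elements: frozenset[str] = DEFAULT_ELEMENTS


def _read_flag_file(path: Path, flag: str) -> list[SmartsPattern]:
    patterns = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path.name}:{lineno}: expected name<TAB>SMARTS")
        name, smarts = parts[0], parts[1]
        active = parts[2].strip() not in ("0", "false", "") if len(parts) > 2 else True
        if Chem.MolFromSmarts(smarts, mergeHs=True) is None:
            raise ValueError(
                f"{path.name}:{lineno}: unparseable SMARTS for {flag}/{name}: {smarts!r}"
            )
        patterns.append(SmartsPattern(name, smarts, active))
    return patterns


def _load_pains() -> dict[str, list[SmartsPattern]]:
    tiers: dict[str, list[SmartsPattern]] = {
        "PAINS_lt15": [], "PAINS_lt150": [], "PAINS_gt150": []
    }
    pains_file = Path(RDConfig.RDDataDir) / "Pains" / "wehi_pains.csv"
    with pains_file.open() as fh:
        for smarts, regid in csv.reader(fh):
            m = _PAINS_REGID.search(regid)
            if not m:
                raise ValueError(f"unrecognised PAINS registry id: {regid!r}")
            hits = int(m.group("hits"))
            tier = "PAINS_gt150" if hits >= 150 else "PAINS_lt150" if hits >= 15 else "PAINS_lt15"
            tiers[tier].append(SmartsPattern(m.group("name"), smarts, True))
    return tiers


def load_flag_definitions(resource_dir: Optional[Path] = None) -> list[FlagDefinition]:
    """Load the bundled flag sets (Reactive, Warhead, PAINS tiers, User).

    ``resource_dir`` overrides the packaged Reactive/Warhead/User files, for
    user-maintained pattern sets.
    """
    if resource_dir is None:
        resource_dir = Path(str(resources.files("screenlib").joinpath("data")))
    defs = []
    for flag, fname in (("Reactive", "reactive.smarts"), ("Warhead", "warhead.smarts")):
        defs.append(FlagDefinition(flag, "smarts-set", _read_flag_file(resource_dir / fname, flag)))
    pains = _load_pains()
    for tier in ("PAINS_lt15", "PAINS_lt150", "PAINS_gt150"):
        defs.append(FlagDefinition(tier, "smarts-set", pains[tier]))
    user_file = resource_dir / "user.smarts"
    user = _read_flag_file(user_file, "User") if user_file.exists() else []
    defs.append(FlagDefinition("User", "smarts-set", user))
    for rule in RULE_FLAGS:
        defs.append(FlagDefinition(rule, "rule"))
    return defs


def seed_flag_patterns(store: MoleculeStore, resource_dir: Optional[Path] = None) -> None:
    """Copy the bundled pattern sets into the store's editable pattern table
    (no-op if the table is already populated)."""
    n = store.conn.execute("SELECT COUNT(*) FROM flag_patterns").fetchone()[0]
    if n:
        return
    with store.conn:
        for d in load_flag_definitions(resource_dir):
            if d.kind != "smarts-set":
                continue
            store.conn.executemany(
                "INSERT INTO flag_patterns (flag, name, smarts, active) VALUES (?,?,?,?)",
                [(d.name, p.name, p.smarts, int(p.active)) for p in d.patterns],
            )


def stored_definitions(store: MoleculeStore) -> dict[str, FlagDefinition]:
    defs: dict[str, FlagDefinition] = {
        f: FlagDefinition(f, "smarts-set") for f in SMARTS_FLAGS
    }
    for flag, name, smarts, active in store.conn.execute(
        "SELECT flag, name, smarts, active FROM flag_patterns ORDER BY rowid"
    ):
        defs.setdefault(flag, FlagDefinition(flag, "smarts-set")).patterns.append(
            SmartsPattern(name, smarts, bool(active))
        )
    return defs


def add_user_pattern(store: MoleculeStore, smarts: str, name: Optional[str] = None) -> None:
    compile_smarts(smarts)
    if name is None:
        n = store.conn.execute(
            "SELECT COUNT(*) FROM flag_patterns WHERE flag = 'User'"
        ).fetchone()[0]
        name = f"user_{n + 1}"
    with store.conn:
        store.conn.execute(
            "INSERT INTO flag_patterns (flag, name, smarts, active) VALUES ('User',?,?,1)",
            (name, smarts),
        )


def set_pattern_active(store: MoleculeStore, flag: str, name: str, active: bool) -> None:
    with store.conn:
        cur = store.conn.execute(
            "UPDATE flag_patterns SET active = ? WHERE flag = ? AND name = ?",
            (int(active), flag, name),
        )
    if cur.rowcount == 0:
        raise KeyError(f"no pattern {name!r} in flag {flag!r}")


def match_flag(molblock_or_mol, flag: FlagDefinition) -> bool:
    """1 iff the molecule matches any *active* SMARTS of the set."""
    if flag.kind != "smarts-set":
        raise ValueError(f"{flag.name} is not a SMARTS-set flag")
    mol = (
        molblock_or_mol
        if isinstance(molblock_or_mol, Chem.Mol)
        else mol_from_molblock(molblock_or_mol)
    )
    for p in flag.patterns:
        if p.active and mol.HasSubstructMatch(compile_smarts(p.smarts)):
            return True
    return False


def rule_flags(
    descriptors: DescriptorSet,
    molblock_or_mol,
    config: RuleConfig = RuleConfig(),
) -> dict[str, bool]:
    """Evaluate the four descriptor/structure rules.

    RO5 is a *fail* flag (1 = violates Lipinski), RO3 a *pass* flag
    (1 = fragment-like).
    """
    mol = (
        molblock_or_mol
        if isinstance(molblock_or_mol, Chem.Mol)
        else mol_from_molblock(molblock_or_mol)
    )
    d = descriptors
    violations = sum(
        (d.weight > 500, d.logp > 5, d.hba > 10, d.hbd > 5)
    )
    ro3 = (
        d.weight < 300 and d.logp <= 3 and d.hbd <= 3 and d.hba <= 3
        and d.rot_bonds <= 3
    )
    exotic = any(
        a.GetSymbol() not in config.allowed_elements for a in mol.GetAtoms()
    )
    return {
        "RO5": violations >= config.ro5_violations,
        "RO3": ro3,
        "Exotic": exotic,
        "Salt": n_fragments(mol) > 1,
    }


class _CompiledSets:
    """Active patterns of every SMARTS flag, compiled once per recompute."""

    def __init__(self, defs: dict[str, FlagDefinition]):
        self.queries: dict[str, list[Chem.Mol]] = {}
        for flag, d in defs.items():
            self.queries[flag] = [
                compile_smarts(p.smarts) for p in d.patterns if p.active
            ]

    def evaluate(self, mol: Chem.Mol) -> dict[str, bool]:
        return {
            flag: any(mol.HasSubstructMatch(q) for q in qs)
            for flag, qs in self.queries.items()
        }


def compute_all_flags(
    mol: Chem.Mol,
    descriptors: DescriptorSet,
    compiled: _CompiledSets,
    config: RuleConfig = RuleConfig(),
) -> dict[str, bool]:
    out = compiled.evaluate(mol)
    out.update(rule_flags(descriptors, mol, config))
    return out


def recompute_flags(
    store: MoleculeStore,
    scope: Scope = None,
    config: RuleConfig = RuleConfig(),
) -> int:
    """Re-evaluate every flag for every molecule in scope; returns the count
    of molecules processed."""
    compiled = _CompiledSets(stored_definitions(store))
    mol_ids = store.resolve_scope(scope)
    with store.conn:
        for mol_id in mol_ids:
            rec = store.get_record(mol_id)
            try:
                mol = mol_from_molblock(rec.molblock)
            except MoleculeError:
                continue  # stored molblocks parse by construction
            for flag, value in compute_all_flags(mol, rec.descriptors, compiled, config).items():
                store.set_flag(mol_id, flag, value)
    return len(mol_ids)
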