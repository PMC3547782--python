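"""Embedded, indexed molecule store.

A single-file SQLite database holds the unique-molecule table plus scaffold
and framework cores, providers, libraries, flag values and editable SMARTS
pattern sets, and named property/fingerprint tables.  Each import batch runs
inside one transaction, so a failed batch leaves the store untouched.  The
``inchikey`` column and the three substructure-prescreen descriptors
(heavy atoms, SSSR ring count, halogens) are indexed.

The store records which molecular handler perceived its molecules; a store
is bound to its handler for life, since descriptors, flags and cores are
only comparable within one perception model.
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import rdkit

from .chem import HANDLER_NAME, DescriptorSet

_SCHEMA = """
CREATE TABLE IF NOT EXISTS metadata (
    key TEXT PRIMARY KEY, value TEXT NOT NULL);
CREATE TABLE IF NOT EXISTS molecules (
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    molblock TEXT NOT NULL,
    inchi TEXT NOT NULL UNIQUE,
    inchikey TEXT NOT NULL,
    names TEXT NOT NULL DEFAULT '[]',
    cas TEXT,
    weight REAL, logp REAL, heavy_atoms INTEGER, hba INTEGER, hbd INTEGER,
    halogens INTEGER, rot_bonds INTEGER, ring_count INTEGER,
    max_ring_size INTEGER,
    scaffold_id INTEGER REFERENCES cores(id),
    framework_id INTEGER REFERENCES cores(id),
    subfp TEXT NOT NULL DEFAULT '');
CREATE INDEX IF NOT EXISTS ix_mol_inchikey ON molecules(inchikey);
CREATE INDEX IF NOT EXISTS ix_mol_heavy ON molecules(heavy_atoms);
CREATE INDEX IF NOT EXISTS ix_mol_rings ON molecules(ring_count);
CREATE INDEX IF NOT EXISTS ix_mol_halogens ON molecules(halogens);
CREATE TABLE IF NOT EXISTS cores (
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    kind TEXT NOT NULL CHECK (kind IN ('scaffold', 'framework')),
    inchi TEXT NOT NULL,
    molblock TEXT NOT NULL,
    UNIQUE (kind, inchi));
CREATE TABLE IF NOT EXISTS providers (
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    name TEXT NOT NULL UNIQUE);
CREATE TABLE IF NOT EXISTS provider_molecules (
    provider_id INTEGER NOT NULL REFERENCES providers(id),
    mol_id INTEGER NOT NULL REFERENCES molecules(id),
    UNIQUE (provider_id, mol_id));
CREATE TABLE IF NOT EXISTS libraries (
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    name TEXT NOT NULL UNIQUE);
CREATE TABLE IF NOT EXISTS library_members (
    library_id INTEGER NOT NULL REFERENCES libraries(id),
    mol_id INTEGER NOT NULL REFERENCES molecules(id),
    UNIQUE (library_id, mol_id));
CREATE TABLE IF NOT EXISTS flag_values (
    mol_id INTEGER NOT NULL REFERENCES molecules(id),
    flag TEXT NOT NULL,
    value INTEGER NOT NULL,
    UNIQUE (mol_id, flag));
CREATE TABLE IF NOT EXISTS flag_patterns (
    flag TEXT NOT NULL,
    name TEXT NOT NULL,
    smarts TEXT NOT NULL,
    active INTEGER NOT NULL DEFAULT 1,
    UNIQUE (flag, name));
CREATE TABLE IF NOT EXISTS properties (
    tbl TEXT NOT NULL,
    mol_id INTEGER NOT NULL REFERENCES molecules(id),
    key TEXT NOT NULL,
    value TEXT,
    UNIQUE (tbl, mol_id, key));
CREATE TABLE IF NOT EXISTS fingerprints (
    tbl TEXT NOT NULL,
    mol_id INTEGER NOT NULL REFERENCES molecules(id),
    n_bits INTEGER NOT NULL,
    bits TEXT NOT NULL,
    UNIQUE (tbl, mol_id));
"""


@dataclass
class MoleculeRecord:
    """One unique structure with its identifiers and computed annotations."""

    internal_id: int
    molblock: str
    inchi: str
    inchikey: str
    names: list[str]
    cas: Optional[str]
    descriptors: DescriptorSet
    scaffold_id: Optional[int]
    framework_id: Optional[int]
    provider_ids: set[int] = field(default_factory=set)
    flags: dict[str, int] = field(default_factory=dict)


Scope = Union[None, str, int, Iterable[int]]


class StoreError(RuntimeError):
    pass


class MoleculeStore:
    """Connection wrapper exposing the persistence operations of the toolkit."""

    def __init__(self, path: Union[str, Path] = ":memory:"):
        self.path = str(path)
        self.conn = sqlite3.connect(self.path)
        self.conn.execute("PRAGMA foreign_keys = ON")
        with self.conn:
            self.conn.executescript(_SCHEMA)
            if self.get_metadata("handler") is None:
                self.set_metadata("handler", HANDLER_NAME)
                self.set_metadata("handler_version", rdkit.__version__)
                self.set_metadata("logp_method", "crippen-atom-contribution")
                self.set_metadata("inchi_options", "standard,stereo")

    def close(self) -> None:
        self.conn.close()

    # -- metadata -----------------------------------------------------------
    def set_metadata(self, key: str, value: str) -> None:
        self.conn.execute(
            "INSERT INTO metadata (key, value) VALUES (?, ?) "
            "ON CONFLICT(key) DO UPDATE SET value = excluded.value",
            (key, value),
        )

    def get_metadata(self, key: str) -> Optional[str]:
        row = self.conn.execute(
            "SELECT value FROM metadata WHERE key = ?", (key,)
        ).fetchone()
        return row[0] if row else None

    # -- molecules ----------------------------------------------------------
    def add_molecule(
        self,
        molblock: str,
        inchi: str,
        inchikey: str,
        names: Sequence[str],
        cas: Optional[str],
        descriptors: DescriptorSet,
        scaffold_id: int,
        framework_id: int,
        subfp_bits: Sequence[int],
    ) -> int:
        cur = self.conn.execute(
            "INSERT INTO molecules (molblock, inchi, inchikey, names, cas, "
            "weight, logp, heavy_atoms, hba, hbd, halogens, rot_bonds, "
            "ring_count, max_ring_size, scaffold_id, framework_id, subfp) "
            "VALUES (?,?,?,?,?,?,?,?,?,?,?,?,?,?,?,?,?)",
            (
                molblock, inchi, inchikey, json.dumps(list(names)), cas,
                descriptors.weight, descriptors.logp, descriptors.heavy_atoms,
                descriptors.hba, descriptors.hbd, descriptors.halogens,
                descriptors.rot_bonds, descriptors.ring_count,
                descriptors.max_ring_size, scaffold_id, framework_id,
                " ".join(str(b) for b in subfp_bits),
            ),
        )
        return cur.lastrowid

    def find_by_inchi(self, inchi: str) -> Optional[int]:
        row = self.conn.execute(
            "SELECT id FROM molecules WHERE inchi = ?", (inchi,)
        ).fetchone()
        return row[0] if row else None

    def merge_identifiers(
        self, mol_id: int, names: Sequence[str], cas: Optional[str]
    ) -> None:
        """Append-merge names (and fill a missing CAS) on a duplicate import."""
        row = self.conn.execute(
            "SELECT names, cas FROM molecules WHERE id = ?", (mol_id,)
        ).fetchone()
        if row is None:
            raise StoreError(f"no molecule with id {mol_id}")
        merged = list(json.loads(row[0]))
        merged.extend(n for n in names if n and n not in merged)
        self.conn.execute(
            "UPDATE molecules SET names = ?, cas = COALESCE(cas, ?) WHERE id = ?",
            (json.dumps(merged), cas, mol_id),
        )

    def get_record(self, mol_id: int) -> MoleculeRecord:
        row = self.conn.execute(
            "SELECT id, molblock, inchi, inchikey, names, cas, weight, logp, "
            "heavy_atoms, hba, hbd, halogens, rot_bonds, ring_count, "
            "max_ring_size, scaffold_id, framework_id "
            "FROM molecules WHERE id = ?",
            (mol_id,),
        ).fetchone()
        if row is None:
            raise StoreError(f"no molecule with id {mol_id}")
        providers = {
            r[0]
            for r in self.conn.execute(
                "SELECT provider_id FROM provider_molecules WHERE mol_id = ?",
                (mol_id,),
            )
        }
        flags = dict(
            self.conn.execute(
                "SELECT flag, value FROM flag_values WHERE mol_id = ?", (mol_id,)
            )
        )
        return MoleculeRecord(
            internal_id=row[0],
            molblock=row[1],
            inchi=row[2],
            inchikey=row[3],
            names=json.loads(row[4]),
            cas=row[5],
            descriptors=DescriptorSet(*row[6:15]),
            scaffold_id=row[15],
            framework_id=row[16],
            provider_ids=providers,
            flags=flags,
        )

    def molblock(self, mol_id: int) -> str:
        row = self.conn.execute(
            "SELECT molblock FROM molecules WHERE id = ?", (mol_id,)
        ).fetchone()
        if row is None:
            raise StoreError(f"no molecule with id {mol_id}")
        return row[0]

    def n_molecules(self) -> int:
        return self.conn.execute("SELECT COUNT(*) FROM molecules").fetchone()[0]

    def all_inchis(self) -> set[str]:
        return {r[0] for r in self.conn.execute("SELECT inchi FROM molecules")}

    def resolve_scope(self, scope: Scope) -> list[int]:
        """Turn a scope (None = whole store, library name/id, or explicit id
        list) into a sorted list of molecule ids."""
        if scope is None:
            rows = self.conn.execute("SELECT id FROM molecules ORDER BY id")
            return [r[0] for r in rows]
        if isinstance(scope, str):
            scope = self.library_id(scope)
        if isinstance(scope, int):
            rows = self.conn.execute(
                "SELECT mol_id FROM library_members WHERE library_id = ? "
                "ORDER BY mol_id",
                (scope,),
            )
            return [r[0] for r in rows]
        return sorted(set(scope))

    def subfp_bits(self, mol_id: int) -> list[int]:
        row = self.conn.execute(
            "SELECT subfp FROM molecules WHERE id = ?", (mol_id,)
        ).fetchone()
        if row is None:
            raise StoreError(f"no molecule with id {mol_id}")
        return [int(b) for b in row[0].split()] if row[0] else []

    def prescreen_candidates(
        self, heavy_atoms: int, ring_count: int, halogens: int
    ) -> list[int]:
        """Indexed descriptor filter: stored molecules at least as large as the
        query on each of the three prescreen counts."""
        rows = self.conn.execute(
            "SELECT id FROM molecules WHERE heavy_atoms >= ? AND "
            "ring_count >= ? AND halogens >= ? ORDER BY id",
            (heavy_atoms, ring_count, halogens),
        )
        return [r[0] for r in rows]

    # -- cores --------------------------------------------------------------
    def get_or_create_core(self, kind: str, inchi: str, molblock: str) -> int:
        row = self.conn.execute(
            "SELECT id FROM cores WHERE kind = ? AND inchi = ?", (kind, inchi)
        ).fetchone()
        if row:
            return row[0]
        cur = self.conn.execute(
            "INSERT INTO cores (kind, inchi, molblock) VALUES (?, ?, ?)",
            (kind, inchi, molblock),
        )
        return cur.lastrowid

    def core(self, core_id: int) -> tuple[str, str, str]:
        row = self.conn.execute(
            "SELECT kind, inchi, molblock FROM cores WHERE id = ?", (core_id,)
        ).fetchone()
        if row is None:
            raise StoreError(f"no core with id {core_id}")
        return row

    def core_members(self, core_id: int) -> list[int]:
        kind = self.core(core_id)[0]
        col = "scaffold_id" if kind == "scaffold" else "framework_id"
        rows = self.conn.execute(
            f"SELECT id FROM molecules WHERE {col} = ? ORDER BY id", (core_id,)
        )
        return [r[0] for r in rows]

    def core_partition(self, kind: str, mol_ids: Sequence[int]) -> dict[int, list[int]]:
        """Map core id -> member molecule ids, restricted to ``mol_ids``."""
        col = "scaffold_id" if kind == "scaffold" else "framework_id"
        partition: dict[int, list[int]] = {}
        for mol_id in mol_ids:
            row = self.conn.execute(
                f"SELECT {col} FROM molecules WHERE id = ?", (mol_id,)
            ).fetchone()
            if row is None or row[0] is None:
                raise StoreError(f"molecule {mol_id} has no {kind}")
            partition.setdefault(row[0], []).append(mol_id)
        return partition

    # -- providers ----------------------------------------------------------
    def get_or_create_provider(self, name: str) -> int:
        row = self.conn.execute(
            "SELECT id FROM providers WHERE name = ?", (name,)
        ).fetchone()
        if row:
            return row[0]
        return self.conn.execute(
            "INSERT INTO providers (name) VALUES (?)", (name,)
        ).lastrowid

    def attach_provider(self, provider_id: int, mol_id: int) -> None:
        self.conn.execute(
            "INSERT OR IGNORE INTO provider_molecules (provider_id, mol_id) "
            "VALUES (?, ?)",
            (provider_id, mol_id),
        )

    def providers(self) -> list[tuple[int, str]]:
        return list(self.conn.execute("SELECT id, name FROM providers ORDER BY id"))

    def provider_members(self, provider_id: int) -> list[int]:
        rows = self.conn.execute(
            "SELECT mol_id FROM provider_molecules WHERE provider_id = ? "
            "ORDER BY mol_id",
            (provider_id,),
        )
        return [r[0] for r in rows]

    # -- libraries ----------------------------------------------------------
    def create_library(self, name: str, member_ids: Iterable[int]) -> int:
        with self.conn:
            lib_id = self.conn.execute(
                "INSERT INTO libraries (name) VALUES (?)", (name,)
            ).lastrowid
            self.conn.executemany(
                "INSERT OR IGNORE INTO library_members (library_id, mol_id) "
                "VALUES (?, ?)",
                [(lib_id, m) for m in set(member_ids)],
            )
        return lib_id

    def library_id(self, name: str) -> int:
        row = self.conn.execute(
            "SELECT id FROM libraries WHERE name = ?", (name,)
        ).fetchone()
        if row is None:
            raise StoreError(f"no library named {name!r}")
        return row[0]

    def libraries(self) -> list[tuple[int, str]]:
        return list(self.conn.execute("SELECT id, name FROM libraries ORDER BY id"))

    def library_members(self, library: Union[int, str]) -> list[int]:
        if isinstance(library, str):
            library = self.library_id(library)
        rows = self.conn.execute(
            "SELECT mol_id FROM library_members WHERE library_id = ? "
            "ORDER BY mol_id",
            (library,),
        )
        return [r[0] for r in rows]

    # -- flags --------------------------------------------------------------
    def set_flag(self, mol_id: int, flag: str, value: bool) -> None:
        self.conn.execute(
            "INSERT INTO flag_values (mol_id, flag, value) VALUES (?, ?, ?) "
            "ON CONFLICT(mol_id, flag) DO UPDATE SET value = excluded.value",
            (mol_id, flag, int(value)),
        )

    def flag_value(self, mol_id: int, flag: str) -> int:
        row = self.conn.execute(
            "SELECT value FROM flag_values WHERE mol_id = ? AND flag = ?",
            (mol_id, flag),
        ).fetchone()
        return row[0] if row else 0

    # -- properties ---------------------------------------------------------
    def set_property(self, tbl: str, mol_id: int, key: str, value: str) -> None:
        self.conn.execute(
            "INSERT INTO properties (tbl, mol_id, key, value) VALUES (?,?,?,?) "
            "ON CONFLICT(tbl, mol_id, key) DO UPDATE SET value = excluded.value",
            (tbl, mol_id, key, value),
        )

    def get_property(self, tbl: str, mol_id: int, key: str) -> Optional[str]:
        row = self.conn.execute(
            "SELECT value FROM properties WHERE tbl = ? AND mol_id = ? AND key = ?",
            (tbl, mol_id, key),
        ).fetchone()
        return row[0] if row else None

    # -- fingerprints -------------------------------------------------------
    def set_fingerprint(
        self, tbl: str, mol_id: int, n_bits: int, on_bits: Sequence[int]
    ) -> None:
        self.conn.execute(
            "INSERT INTO fingerprints (tbl, mol_id, n_bits, bits) "
            "VALUES (?,?,?,?) ON CONFLICT(tbl, mol_id) DO UPDATE SET "
            "n_bits = excluded.n_bits, bits = excluded.bits",
            (tbl, mol_id, n_bits, " ".join(str(b) for b in sorted(set(on_bits)))),
        )

    def get_fingerprint(self, tbl: str, mol_id: int) -> Optional[tuple[int, list[int]]]:
        row = self.conn.execute(
            "SELECT n_bits, bits FROM fingerprints WHERE tbl = ? AND mol_id = ?",
            (tbl, mol_id),
        ).fetchone()
        if row is None:
            return None
        return row[0], ([int(b) for b in row[1].split()] if row[1] else [])

    def fingerprint_table(self, tbl: str) -> dict[int, tuple[int, list[int]]]:
        out = {}
        for mol_id, n_bits, bits in self.conn.execute(
            "SELECT mol_id, n_bits, bits FROM fingerprints WHERE tbl = ?", (tbl,)
        ):
            out[mol_id] = (n_bits, [int(b) for b in bits.split()] if bits else [])
        return out
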