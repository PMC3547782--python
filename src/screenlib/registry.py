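"""SDF import pipeline, exports, and property/fingerprint table imports.

Import flow per record: optional standardisation transformers -> handler
perception -> stereo-aware InChI -> deduplicate (a duplicate only gains the
new provider/name/CAS) -> descriptors, flags, scaffold + framework cores,
similarity and prescreen fingerprints -> persist.  Per-record failures are
collected in the :class:`ImportReport`; they never abort the batch, and the
whole batch is one store transaction.

No standardisation is applied by default: salts, charges and stereochemistry
are stored exactly as read.  Transformers are user-registered molblock ->
molblock functions executed in the configured order.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

from .chem import (
    DescriptorSet,
    MoleculeError,
    descriptors_for_mol,
    inchi_for_mol,
    mol_from_molblock,
    mol_to_molblock,
)
from . import sdf as sdfio
from .fingerprints import (
    FINGERPRINT_BITS,
    SUBFP_BITS,
    from_on_bits,
    get_fingerprint_fn,
    substructure_fingerprint,
    to_on_bits,
)
from .flags import RuleConfig, _CompiledSets, compute_all_flags, seed_flag_patterns, stored_definitions
from .scaffolds import assign_cores
from .store import MoleculeStore, Scope

# -- transformers ------------------------------------------------------------

TRANSFORMERS: dict[str, Callable[[str], str]] = {}


def register_transformer(name: str, fn: Callable[[str], str]) -> None:
    if name in TRANSFORMERS:
        raise ValueError(f"transformer {name!r} already registered")
    TRANSFORMERS[name] = fn


def strip_smallest_fragment(molblock: str) -> str:
    """Keep only the largest fragment (by heavy atoms) of a multi-fragment
    structure — the classic desalting transformer."""
    from rdkit import Chem

    mol = mol_from_molblock(molblock)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    largest = max(frags, key=lambda f: (f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)))
    return mol_to_molblock(largest)


register_transformer("strip_smallest_fragment", strip_smallest_fragment)


def standardize(molblock: str, transformers: Sequence[Union[str, Callable]] = ()) -> str:
    """Apply the ordered transformer list; the default (empty) list returns a
    structure with an unchanged InChI."""
    for t in transformers:
        fn = TRANSFORMERS[t] if isinstance(t, str) else t
        molblock = fn(molblock)
    return molblock


# -- import ------------------------------------------------------------------

@dataclass
class ImportOptions:
    transformers: tuple = ()
    #: SD property tags searched for molecule names / CAS numbers.
    name_tags: tuple[str, ...] = ("NAME", "Name", "name", "SA2_NAMES")
    cas_tags: tuple[str, ...] = ("CAS", "cas", "SA2_CAS")
    #: Similarity fingerprints computed (as workers) on each new molecule.
    fingerprints: tuple[str, ...] = ("maccs",)
    rule_config: RuleConfig = field(default_factory=RuleConfig)


@dataclass
class ImportReport:
    n_read: int = 0
    n_imported: int = 0
    n_duplicates: int = 0
    n_errors: int = 0
    error_messages: list[tuple[int, str]] = field(default_factory=list)
    imported_ids: list[int] = field(default_factory=list)

    def record_error(self, index: int, message: str) -> None:
        self.n_errors += 1
        self.error_messages.append((index, message))


def import_sdf(
    store: MoleculeStore,
    path: Union[str, Path],
    provider: str,
    options: ImportOptions = ImportOptions(),
) -> ImportReport:
    """Import an SDF file under a provider; idempotent at structure level."""
    seed_flag_patterns(store)
    compiled = _CompiledSets(stored_definitions(store))
    fp_fns = {name: get_fingerprint_fn(name) for name in options.fingerprints}
    report = ImportReport()
    with store.conn:
        provider_id = store.get_or_create_provider(provider)
        for token in sdfio.parse_sdf(path):
            report.n_read += 1
            if isinstance(token, sdfio.SdfError):
                report.record_error(token.index, token.message)
                continue
            try:
                _import_record(
                    store, token, provider_id, options, compiled, fp_fns, report
                )
            except MoleculeError as exc:
                report.record_error(token.index, str(exc))
    return report


def _identifiers(props: dict[str, str], options: ImportOptions):
    names = [props[t] for t in options.name_tags if props.get(t)]
    cas = next((props[t] for t in options.cas_tags if props.get(t)), None)
    return names, cas


def _import_record(store, token, provider_id, options, compiled, fp_fns, report):
    molblock = standardize(token.molblock, options.transformers)
    mol = mol_from_molblock(molblock)
    inchi, inchikey = inchi_for_mol(mol)
    names, cas = _identifiers(token.properties, options)
    existing = store.find_by_inchi(inchi)
    if existing is not None:
        store.merge_identifiers(existing, names, cas)
        store.attach_provider(provider_id, existing)
        report.n_duplicates += 1
        return
    descriptors = descriptors_for_mol(mol)
    scaffold_id, framework_id = assign_cores(store, mol)
    subfp = to_on_bits(substructure_fingerprint(mol))
    mol_id = store.add_molecule(
        molblock, inchi, inchikey, names, cas, descriptors,
        scaffold_id, framework_id, subfp,
    )
    for flag, value in compute_all_flags(
        mol, descriptors, compiled, options.rule_config
    ).items():
        store.set_flag(mol_id, flag, value)
    for name, fn in fp_fns.items():
        store.set_fingerprint(name, mol_id, FINGERPRINT_BITS[name], to_on_bits(fn(mol)))
    store.attach_provider(provider_id, mol_id)
    report.n_imported += 1
    report.imported_ids.append(mol_id)


# -- export ------------------------------------------------------------------

def export(
    store: MoleculeStore,
    scope: Scope,
    fmt: str,
    path: Union[str, Path],
    delimiter: str = "\t",
) -> int:
    """Export a selection as SDF (with SA2_* and descriptor SD tags) or as a
    delimited text table; returns the number of molecules written."""
    mol_ids = store.resolve_scope(scope)
    if not mol_ids:
        raise ValueError("refusing to export an empty selection")
    path = Path(path)
    if fmt == "sdf":
        with path.open("w") as fh:
            for mol_id in mol_ids:
                rec = store.get_record(mol_id)
                tags = {
                    "SA2_ID": str(rec.internal_id),
                    "SA2_NAMES": ";".join(rec.names),
                }
                if rec.cas:
                    tags["SA2_CAS"] = rec.cas
                tags.update(
                    (k, str(v)) for k, v in rec.descriptors.as_dict().items()
                )
                sdfio.write_record(fh, rec.molblock, tags)
    elif fmt == "text":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh, delimiter=delimiter)
            writer.writerow(("internal_id",) + DescriptorSet.NAMES)
            for mol_id in mol_ids:
                rec = store.get_record(mol_id)
                d = rec.descriptors.as_dict()
                writer.writerow([rec.internal_id] + [d[k] for k in DescriptorSet.NAMES])
    else:
        raise ValueError(f"unknown export format {fmt!r} (expected 'sdf' or 'text')")
    return len(mol_ids)


# -- property / fingerprint tables -------------------------------------------

def _id_resolver(store: MoleculeStore, key: str) -> Callable[[str], Optional[int]]:
    if key == "internal_id":
        ids = {r[0] for r in store.conn.execute("SELECT id FROM molecules")}
        return lambda v: int(v) if v.isdigit() and int(v) in ids else None
    if key == "inchikey":
        by_key = dict(
            store.conn.execute("SELECT inchikey, id FROM molecules")
        )
        return by_key.get
    if key == "name":
        by_name: dict[str, int] = {}
        for mol_id, names in store.conn.execute("SELECT id, names FROM molecules"):
            for n in json.loads(names):
                by_name.setdefault(n, mol_id)
        return by_name.get
    raise ValueError(f"unknown id key {key!r} (internal_id, name or inchikey)")


def import_properties(
    store: MoleculeStore,
    path: Union[str, Path],
    table: str,
    id_key: str = "internal_id",
    delimiter: str = "\t",
) -> tuple[int, list[str]]:
    """Attach columns of a delimited file to stored molecules (upsert).

    Returns (rows applied, warnings for unresolvable ids).
    """
    resolve = _id_resolver(store, id_key)
    warnings: list[str] = []
    count = 0
    with Path(path).open(newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        header = next(reader, None)
        if not header or len(header) < 2:
            raise ValueError("property file needs an ID column plus data columns")
        with store.conn:
            for row in reader:
                if not row:
                    continue
                mol_id = resolve(row[0])
                if mol_id is None:
                    warnings.append(f"unknown id {row[0]!r}")
                    continue
                for key, value in zip(header[1:], row[1:]):
                    store.set_property(table, mol_id, key, value)
                count += 1
    return count, warnings


def parse_fingerprint_field(field_text: str, dialect: str, n_bits: int) -> list[int]:
    """Decode one fingerprint in either supported dialect into set-bit indices.

    ``binary-string``: a 0/1 character string, one character per bit;
    ``index-list``: whitespace-separated indices of the set bits.
    """
    if dialect == "binary-string":
        bits = field_text.strip()
        if set(bits) - {"0", "1"}:
            raise ValueError("binary string may contain only 0/1")
        if len(bits) != n_bits:
            raise ValueError(f"binary string length {len(bits)} != n_bits {n_bits}")
        return [i for i, c in enumerate(bits) if c == "1"]
    if dialect == "index-list":
        on = [int(tok) for tok in field_text.split()]
        if any(i < 0 or i >= n_bits for i in on):
            raise ValueError(f"bit index out of range for {n_bits} bits")
        return sorted(set(on))
    raise ValueError(f"unknown dialect {dialect!r}")


def import_fingerprints(
    store: MoleculeStore,
    path: Union[str, Path],
    table: str,
    dialect: str,
    n_bits: int,
    id_key: str = "internal_id",
    delimiter: str = "\t",
) -> tuple[int, list[str]]:
    """Load a fingerprint table from a delimited id<TAB>fingerprint file.

    Both dialects store identical bit vectors for equivalent input.  Rows
    with out-of-range bits or unknown ids are reported, not fatal.
    """
    if n_bits <= 0:
        raise ValueError("n_bits must be positive")
    resolve = _id_resolver(store, id_key)
    errors: list[str] = []
    count = 0
    with Path(path).open(newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        with store.conn:
            for lineno, row in enumerate(reader, start=1):
                if not row:
                    continue
                mol_id = resolve(row[0])
                if mol_id is None:
                    errors.append(f"line {lineno}: unknown id {row[0]!r}")
                    continue
                try:
                    on_bits = parse_fingerprint_field(row[1], dialect, n_bits)
                except (ValueError, IndexError) as exc:
                    errors.append(f"line {lineno}: {exc}")
                    continue
                store.set_fingerprint(table, mol_id, n_bits, on_bits)
                count += 1
    return count, errors


def stored_fingerprint_vectors(store: MoleculeStore, table: str, mol_ids):
    """Dense 0/1 vectors for ``mol_ids`` from a stored fingerprint table."""
    raw = store.fingerprint_table(table)
    out = {}
    for mol_id in mol_ids:
        if mol_id in raw:
            n_bits, on = raw[mol_id]
            out[mol_id] = from_on_bits(on, n_bits)
    return out
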