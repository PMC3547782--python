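"""Providers, libraries, filtering and the provider composition reports.

A provider records where compounds came from (vendor, project); a library
is a named, persistent subset of the store.  Libraries are id-set snapshots:
creating, merging or filtering libraries never mutates molecule records.

The provider report measures collection originality: compound unicity (CU)
is the percentage of a provider's molecules found in no other provider;
scaffold/framework unicity (SU/FU) count a core as exclusive only when every
member of that core, store-wide, belongs to this provider alone.  The flag
report gives the fragment-like (rule-of-3 pass), non-drug-like (rule-of-5
fail), reactive, PAINS and globally-undesired rates.
"""

from __future__ import annotations

import operator
import re
from dataclasses import dataclass
from typing import Optional, Sequence

from .chem import DescriptorSet
from .flags import ALL_FLAGS
from .store import MoleculeStore, Scope

_COMPARATORS = {
    "<": operator.lt,
    "<=": operator.le,
    "=": operator.eq,
    "==": operator.eq,
    ">=": operator.ge,
    ">": operator.gt,
    "!=": operator.ne,
}

_PRED = re.compile(r"^\s*(?P<field>\w+)\s*(?P<op><=|>=|==|!=|<|>|=)\s*(?P<value>-?[\d.]+)\s*$")

PAINS_FLAGS = ("PAINS_lt15", "PAINS_lt150", "PAINS_gt150")
UNDESIRED_FLAGS = ("Reactive", "Warhead") + PAINS_FLAGS


@dataclass(frozen=True)
class Predicate:
    field: str
    comparator: str
    value: float

    def __post_init__(self):
        if self.comparator not in _COMPARATORS:
            raise ValueError(f"unknown comparator {self.comparator!r}")
        if self.field not in DescriptorSet.NAMES and self.field not in ALL_FLAGS:
            raise ValueError(f"unknown field {self.field!r}")


@dataclass(frozen=True)
class FilterSpec:
    """Conjunction of descriptor/flag predicates."""

    predicates: tuple[Predicate, ...] = ()

    @classmethod
    def parse(cls, text: str) -> "FilterSpec":
        """Parse e.g. ``"weight<=500,RO5=0,Reactive=0"``."""
        preds = []
        for clause in filter(None, (c.strip() for c in text.split(","))):
            m = _PRED.match(clause)
            if not m:
                raise ValueError(f"unparseable filter clause {clause!r}")
            preds.append(
                Predicate(m.group("field"), m.group("op"), float(m.group("value")))
            )
        return cls(tuple(preds))

    def matches(self, descriptors: DescriptorSet, flags: dict[str, int]) -> bool:
        d = descriptors.as_dict()
        for p in self.predicates:
            actual = d[p.field] if p.field in d else flags.get(p.field, 0)
            if not _COMPARATORS[p.comparator](float(actual), p.value):
                return False
        return True


def create_library_filter(
    store: MoleculeStore, name: str, spec: FilterSpec, scope: Scope = None
) -> int:
    """New library = molecules in scope satisfying every predicate.

    An empty result is allowed (contradictory specs yield an empty library).
    Returns the library id.
    """
    members = []
    for mol_id in store.resolve_scope(scope):
        rec = store.get_record(mol_id)
        if spec.matches(rec.descriptors, rec.flags):
            members.append(mol_id)
    return store.create_library(name, members)


def merge_libraries(store: MoleculeStore, name: str, a, b) -> int:
    """New library = union of two libraries (deduplicated by internal id)."""
    members = set(store.library_members(a)) | set(store.library_members(b))
    return store.create_library(name, members)


def save_as_library(store: MoleculeStore, name: str, mol_ids: Sequence[int]) -> int:
    return store.create_library(name, mol_ids)


def _pct(part: int, whole: int) -> float:
    return 100.0 * part / whole if whole else 0.0


def provider_report(store: MoleculeStore, mode: str = "flags") -> dict[str, dict[str, float]]:
    """Per-provider composition report.

    ``mode='scaffold'``/``'framework'`` report unicity and core proportions;
    ``mode='flags'`` reports liability rates.  All values are percentages.
    """
    if mode not in ("scaffold", "framework", "flags"):
        raise ValueError("mode must be scaffold, framework or flags")
    providers = store.providers()
    if not providers:
        raise ValueError("no providers in store")
    out: dict[str, dict[str, float]] = {}
    for provider_id, name in providers:
        mol_ids = store.provider_members(provider_id)
        n = len(mol_ids)
        row: dict[str, float] = {"n_molecules": n}
        records = [store.get_record(m) for m in mol_ids]
        exclusive = sum(1 for r in records if r.provider_ids == {provider_id})
        row["CU"] = _pct(exclusive, n)
        if mode in ("scaffold", "framework"):
            partition = store.core_partition(mode, mol_ids)
            n_cores = len(partition)
            n_excl_cores = 0
            for core_id in partition:
                members = store.core_members(core_id)  # store-wide members
                if all(
                    store.get_record(m).provider_ids == {provider_id}
                    for m in members
                ):
                    n_excl_cores += 1
            key = "S" if mode == "scaffold" else "F"
            row[f"{mode}_proportion"] = _pct(n_cores, n)
            row[f"{key}U"] = _pct(n_excl_cores, n_cores)
        else:
            def rate(pred) -> float:
                return _pct(sum(1 for r in records if pred(r.flags)), n)

            row["fragment_like"] = rate(lambda f: f.get("RO3", 0))
            row["non_drug_like"] = rate(lambda f: f.get("RO5", 0))
            row["reactive"] = rate(lambda f: f.get("Reactive", 0))
            row["pains"] = rate(lambda f: any(f.get(p, 0) for p in PAINS_FLAGS))
            row["undesired"] = rate(
                lambda f: any(f.get(p, 0) for p in UNDESIRED_FLAGS)
            )
        out[name] = row
    return out
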