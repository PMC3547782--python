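"""Plugin registries and batch workers.

Every extensible service kind — similarity metrics, fingerprints,
standardisation transformers, molecule workers and the substructure
fingerprint — is a plain name -> implementation registry.  Third-party
packages can contribute implementations through the ``screenlib.services``
entry-point group: each entry point must resolve to a callable taking no
arguments that performs its own ``register_*`` calls on import.

A *worker* computes something for one molecule and stores it; workers run
either during import or afterwards over any scope, with per-molecule
failure isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import metadata
from typing import Callable

from .chem import mol_from_molblock
from .fingerprints import (
    FINGERPRINT_BITS,
    FINGERPRINTS,
    METRICS,
    get_fingerprint_fn,
    register_fingerprint,
    register_metric,
    substructure_fingerprint,
    to_on_bits,
)
from .registry import TRANSFORMERS, register_transformer
from .store import MoleculeStore, Scope


class Registry:
    """Unique-name lookup for one service kind; unknown names raise with the
    list of available names."""

    def __init__(self, kind: str, mapping: dict):
        self.kind = kind
        self._map = mapping

    def register(self, name: str, impl) -> None:
        if name in self._map:
            raise ValueError(f"{self.kind} {name!r} already registered")
        self._map[name] = impl

    def get(self, name: str):
        try:
            return self._map[name]
        except KeyError:
            raise KeyError(
                f"unknown {self.kind} {name!r}; available: {sorted(self._map)}"
            ) from None

    def names(self) -> list[str]:
        return sorted(self._map)


WORKERS: dict[str, Callable[[MoleculeStore, int], None]] = {}
SUBSTRUCTURE_FPS: dict[str, Callable] = {"pattern1056": substructure_fingerprint}

REGISTRIES: dict[str, Registry] = {
    "metric": Registry("metric", METRICS),
    "fingerprint": Registry("fingerprint", FINGERPRINTS),
    "transformer": Registry("transformer", TRANSFORMERS),
    "worker": Registry("worker", WORKERS),
    "substructure-fp": Registry("substructure-fp", SUBSTRUCTURE_FPS),
}


def _fingerprint_worker(fp_name: str) -> Callable[[MoleculeStore, int], None]:
    def work(store: MoleculeStore, mol_id: int) -> None:
        fn = get_fingerprint_fn(fp_name)
        mol = mol_from_molblock(store.molblock(mol_id))
        store.set_fingerprint(
            fp_name, mol_id, FINGERPRINT_BITS[fp_name], to_on_bits(fn(mol))
        )

    return work


def _subfp_worker(store: MoleculeStore, mol_id: int) -> None:
    mol = mol_from_molblock(store.molblock(mol_id))
    bits = " ".join(str(b) for b in to_on_bits(substructure_fingerprint(mol)))
    store.conn.execute(
        "UPDATE molecules SET subfp = ? WHERE id = ?", (bits, mol_id)
    )


for _fp in ("maccs", "morgan2"):
    WORKERS[f"fingerprint:{_fp}"] = _fingerprint_worker(_fp)
WORKERS["substructure-fp"] = _subfp_worker


@dataclass
class WorkerRun:
    worker: str
    n_processed: int
    n_failed: int
    failures: list[tuple[int, str]]


def run_worker(store: MoleculeStore, worker: str, scope: Scope = None) -> WorkerRun:
    """Apply a worker to every molecule in scope; one molecule's failure
    never touches the others.  Re-running overwrites (idempotent)."""
    fn = REGISTRIES["worker"].get(worker)
    mol_ids = store.resolve_scope(scope)
    n_ok = 0
    failures: list[tuple[int, str]] = []
    with store.conn:
        for mol_id in mol_ids:
            try:
                fn(store, mol_id)
                n_ok += 1
            except Exception as exc:  # noqa: BLE001 — isolation is the contract
                failures.append((mol_id, str(exc)))
    return WorkerRun(worker, n_ok, len(failures), failures)


def load_entry_point_services(group: str = "screenlib.services") -> list[str]:
    """Import and run registration hooks advertised by installed packages."""
    loaded = []
    try:
        eps = metadata.entry_points(group=group)
    except TypeError:  # pragma: no cover — very old importlib.metadata
        eps = metadata.entry_points().get(group, [])
    for ep in eps:
        hook = ep.load()
        hook()
        loaded.append(ep.name)
    return loaded
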