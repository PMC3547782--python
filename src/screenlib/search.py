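"""Exact, similarity, SMARTS and two-stage substructure search.

Exact search compares stereo-aware InChIs, so it is atom-order independent
and distinguishes enantiomers.  Similarity search scans stored fingerprints
with a registered metric (Tanimoto by default) and returns every molecule
at or above the cutoff, best first.  Substructure search runs a prescreen —
the three indexed descriptors (heavy atoms, SSSR count, halogens) must not
exceed the query's, and the query's 1056-bit pattern fingerprint must be a
bit-subset of the molecule's — followed by a full subgraph-isomorphism test
on the candidates.  The prescreen is sound: it never discards a true match.
SMARTS search skips the prescreen, since SMARTS constraints go beyond plain
connectivity, and uses the same matcher as the flag engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .chem import (
    compile_smarts,
    compute_inchi,
    descriptors_for_mol,
    mol_from_molblock,
)
from .fingerprints import (
    BitVector,
    FINGERPRINTS,
    from_on_bits,
    get_metric,
    is_subset,
    substructure_fingerprint,
    SUBFP_BITS,
)
from .store import MoleculeStore, Scope


@dataclass
class SearchResult:
    """Ordered hits: (molecule id, score) for similarity, score None for
    match/no-match searches."""

    query: str
    hits: list[tuple[int, Optional[float]]] = field(default_factory=list)

    @property
    def ids(self) -> list[int]:
        return [h[0] for h in self.hits]

    def __len__(self) -> int:
        return len(self.hits)


def search_exact(store: MoleculeStore, molblock: str) -> SearchResult:
    """At most one hit: the stored molecule with the query's InChI."""
    inchi, _ = compute_inchi(molblock)
    mol_id = store.find_by_inchi(inchi)
    hits = [(mol_id, None)] if mol_id is not None else []
    return SearchResult(query=f"exact:{inchi}", hits=hits)


def search_similarity(
    store: MoleculeStore,
    query: Union[str, BitVector],
    fp_name: str = "maccs",
    metric: str = "tanimoto",
    cutoff: float = 0.7,
    scope: Scope = None,
) -> SearchResult:
    """All molecules in scope with similarity >= cutoff, sorted descending.

    A structure query needs an internally computable fingerprint; querying
    an imported-only (external) fingerprint table requires passing the query
    as a bit vector.
    """
    if isinstance(query, str):
        if fp_name not in FINGERPRINTS:
            raise ValueError(
                f"fingerprint {fp_name!r} is external (import-only); a "
                "structure query needs an internally computable fingerprint"
            )
        qvec = FINGERPRINTS[fp_name](mol_from_molblock(query))
    else:
        qvec = np.asarray(query, dtype=np.uint8)
    sim = get_metric(metric)
    table = store.fingerprint_table(fp_name)
    scored = []
    for mol_id in store.resolve_scope(scope):
        entry = table.get(mol_id)
        if entry is None:
            continue
        n_bits, on = entry
        s = sim(qvec, from_on_bits(on, n_bits))
        if s >= cutoff:
            scored.append((mol_id, s))
    scored.sort(key=lambda h: (-h[1], h[0]))
    return SearchResult(query=f"similarity:{fp_name}/{metric}@{cutoff}", hits=scored)


def substructure_prescreen(store: MoleculeStore, query_molblock: str) -> list[int]:
    """Candidate ids that survive the descriptor + fingerprint screen."""
    qmol = mol_from_molblock(query_molblock)
    qd = descriptors_for_mol(qmol)
    qfp = substructure_fingerprint(qmol)
    candidates = []
    for mol_id in store.prescreen_candidates(qd.heavy_atoms, qd.ring_count, qd.halogens):
        target = from_on_bits(store.subfp_bits(mol_id), SUBFP_BITS)
        if is_subset(qfp, target):
            candidates.append(mol_id)
    return candidates


def search_substructure(
    store: MoleculeStore, query_molblock: str, scope: Scope = None
) -> SearchResult:
    """Two-step substructure search: prescreen, then graph isomorphism."""
    qmol = mol_from_molblock(query_molblock)
    in_scope = set(store.resolve_scope(scope))
    hits = []
    for mol_id in substructure_prescreen(store, query_molblock):
        if mol_id not in in_scope:
            continue
        if mol_from_molblock(store.molblock(mol_id)).HasSubstructMatch(qmol):
            hits.append((mol_id, None))
    return SearchResult(query="substructure", hits=hits)


def search_smarts(
    store: MoleculeStore, smarts: str, scope: Scope = None
) -> SearchResult:
    """Molecules with at least one match of the SMARTS pattern (full scan)."""
    query = compile_smarts(smarts)  # parse error before any scan
    hits = []
    for mol_id in store.resolve_scope(scope):
        if mol_from_molblock(store.molblock(mol_id)).HasSubstructMatch(query):
            hits.append((mol_id, None))
    return SearchResult(query=f"smarts:{smarts}", hits=hits)
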