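"""Scaffold-based min-max diverse subset selection and diversity reporting.

The selector guarantees one molecule per scaffold (or framework) on its
first sweep.  Cores are ordered by decreasing member count (or a seeded
shuffle).  The first pick is the member of the first core most similar to
that core's average fingerprint (per-bit frequency vector, compared with
the continuous Tanimoto sum(min)/sum(max)).  For each following core the
candidate minimising its *maximum* similarity to the selected set is taken,
unless even that minimum exceeds the current similarity cutoff, in which
case the core contributes nothing this sweep.  When a full sweep leaves the
selection short of the target, further sweeps may take additional molecules
per core, and the cutoff is raised by a fixed step whenever the shortfall
was cutoff-induced; once the cutoff reaches 1 every candidate is
acceptable, so any target up to the scope size is reached.

Ties (equal member counts, equal min-max scores) break on the lowest id,
making a fixed configuration byte-reproducible.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .fingerprints import BitVector, continuous_tanimoto, get_metric
from .registry import stored_fingerprint_vectors
from .store import MoleculeStore, Scope


@dataclass
class DiversityConfig:
    n_target: int
    core_mode: str = "scaffold"  # 'scaffold' | 'framework'
    ordering: str = "frequency"  # 'frequency' | 'random'
    fp_name: str = "maccs"
    metric: str = "tanimoto"
    cutoff0: float = 0.6
    cutoff_step: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.cutoff0 <= 1):
            raise ValueError("cutoff0 must be in (0, 1]")
        if self.cutoff_step <= 0:
            raise ValueError("cutoff_step must be positive")
        if self.n_target < 1:
            raise ValueError("n_target must be >= 1")


@dataclass
class DiversityResult:
    selected_ids: list[int]
    runs_used: int
    final_cutoff: float
    per_run_counts: list[int] = field(default_factory=list)


def average_fingerprint(members: Sequence[BitVector]) -> np.ndarray:
    """Per-bit set frequency across the member vectors, in [0, 1]."""
    if not len(members):
        raise ValueError("no member fingerprints")
    return np.mean(np.stack([m.astype(float) for m in members]), axis=0)


def _centroid_pick(member_ids: list[int], vectors: dict[int, BitVector]) -> int:
    avg = average_fingerprint([vectors[m] for m in member_ids])
    # ties break on the lowest internal id (ids are iterated ascending)
    best, best_sim = None, -1.0
    for m in sorted(member_ids):
        s = continuous_tanimoto(vectors[m].astype(float), avg)
        if s > best_sim:
            best, best_sim = m, s
    return best


def select_diverse(
    store: MoleculeStore, cfg: DiversityConfig, scope: Scope = None
) -> DiversityResult:
    mol_ids = store.resolve_scope(scope)
    if not mol_ids:
        raise ValueError("empty scope")
    vectors = stored_fingerprint_vectors(store, cfg.fp_name, mol_ids)
    missing = [m for m in mol_ids if m not in vectors]
    if missing:
        raise ValueError(
            f"{len(missing)} molecules lack the {cfg.fp_name!r} fingerprint"
        )
    sim = get_metric(cfg.metric)
    partition = store.core_partition(cfg.core_mode, mol_ids)
    cores = list(partition)
    if cfg.ordering == "frequency":
        cores.sort(key=lambda c: (-len(partition[c]), c))
    elif cfg.ordering == "random":
        random.Random(cfg.seed).shuffle(cores)
    else:
        raise ValueError("ordering must be 'frequency' or 'random'")

    n_target = min(cfg.n_target, len(mol_ids))
    selected: list[int] = [_centroid_pick(partition[cores[0]], vectors)]
    selected_set = set(selected)
    cutoff = cfg.cutoff0
    runs = 1
    per_run = [1]  # the centroid pick counts toward the first sweep

    while len(selected) < n_target:
        added = 0
        cutoff_rejected = False
        # the first sweep skips the centroid core, already represented
        for core in cores[1:] if runs == 1 else cores:
            if len(selected) >= n_target:
                break
            candidates = [m for m in partition[core] if m not in selected_set]
            if not candidates:
                continue
            best, best_maxsim = None, None
            for m in sorted(candidates):
                maxsim = max(sim(vectors[m], vectors[s]) for s in selected)
                if best_maxsim is None or maxsim < best_maxsim:
                    best, best_maxsim = m, maxsim
            if best_maxsim > cutoff:
                cutoff_rejected = True
                continue
            selected.append(best)
            selected_set.add(best)
            added += 1
        if runs == 1:
            per_run[0] += added
        else:
            per_run.append(added)
        if len(selected) >= n_target:
            break
        if cutoff_rejected and cutoff < 1.0:
            cutoff = min(1.0, cutoff + cfg.cutoff_step)
        runs += 1
    return DiversityResult(
        selected_ids=selected,
        runs_used=runs,
        final_cutoff=cutoff,
        per_run_counts=per_run,
    )


@dataclass
class DiversityReport:
    n_molecules: int
    scaffold_pct: float
    framework_pct: float
    #: per fingerprint name: avg_pairwise, avg_nn, max_sim
    indices: dict[str, dict[str, float]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_molecules": self.n_molecules,
            "scaffold_pct": self.scaffold_pct,
            "framework_pct": self.framework_pct,
            "indices": self.indices,
        }


def similarity_indices(
    vectors: Sequence[BitVector], metric: str = "tanimoto"
) -> dict[str, float]:
    """Average pairwise, average nearest-neighbour and maximum similarity
    over all unordered pairs of a member set."""
    n = len(vectors)
    if n < 2:
        raise ValueError("need at least two members")
    sim = get_metric(metric)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = sim(vectors[i], vectors[j])
    iu = np.triu_indices(n, k=1)
    pair = mat[iu]
    np.fill_diagonal(mat, -np.inf)
    nn = mat.max(axis=1)
    return {
        "avg_pairwise": float(pair.mean()),
        "avg_nn": float(nn.mean()),
        "max_sim": float(pair.max()),
    }


def diversity_report(
    store: MoleculeStore,
    library: Scope,
    fp_names: Sequence[str] = ("maccs",),
    metric: str = "tanimoto",
) -> DiversityReport:
    mol_ids = store.resolve_scope(library)
    if len(mol_ids) < 2:
        raise ValueError("diversity report needs at least two molecules")
    n = len(mol_ids)
    n_scaffolds = len(store.core_partition("scaffold", mol_ids))
    n_frameworks = len(store.core_partition("framework", mol_ids))
    report = DiversityReport(
        n_molecules=n,
        scaffold_pct=100.0 * n_scaffolds / n,
        framework_pct=100.0 * n_frameworks / n,
    )
    for fp_name in fp_names:
        vectors = stored_fingerprint_vectors(store, fp_name, mol_ids)
        if len(vectors) < len(mol_ids):
            raise ValueError(f"missing {fp_name!r} fingerprints in library")
        report.indices[fp_name] = similarity_indices(
            [vectors[m] for m in mol_ids], metric
        )
    return report
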