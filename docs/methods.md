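# Methods

This note documents the conventions, algorithms and numerical choices
behind `screenlib`, and what the synthetic test fixtures do and do not
demonstrate.

## Structure identity and deduplication

All perception goes through one molecular handler (RDKit); the handler
name and version are recorded in the store metadata, and a store is bound
to its handler for life — descriptors, flags and cores are only comparable
within one perception model. Identity is the standard InChI with
stereochemistry layers: atom-order permutations of one structure collapse,
enantiomers stay distinct. No standardisation is applied by default —
salts, charges and stereo are stored as read — because desalting and
charge normalisation are problem-dependent; user transformers (ordered
`molblock -> molblock` functions, e.g. the bundled
`strip_smallest_fragment`) can be enabled per import. V3000 connection
tables are rejected with a clear error; records the handler cannot
sanitize (valence errors, garbled blocks) are counted as per-record errors
and never abort a batch. The import report satisfies
`n_read = n_imported + n_duplicates + n_errors` by construction.

Duplicate imports append-merge names and fill a missing CAS; the original
identifiers are never overwritten. This merge policy is a design choice —
replacement would lose provenance.

## Descriptors and rule flags

Nine descriptors are computed per molecule: molecular weight (g/mol),
Crippen atom-contribution logP, heavy-atom count, Lipinski H-bond
acceptors (N+O) and donors (NH+OH), halogen count (F/Cl/Br/I), rotatable
bonds, SSSR ring count, and largest SSSR ring size. `max_ring_size = 0`
iff `ring_count = 0`.

RO5 is a *fail* flag: ≥ 2 violations of {MW > 500, logP > 5, HBA > 10,
HBD > 5}. The threshold is configurable down to 1 (`RuleConfig`) because
both readings exist in triage practice; 2 is Lipinski's published
criterion and the default. RO3 is a *pass* flag (MW < 300, logP ≤ 3,
HBD ≤ 3, HBA ≤ 3, rotatable ≤ 3). Exotic means an element outside
{H, B, C, N, O, F, Si, P, S, Cl, Se, Br, I} (configurable); Salt means
more than one disconnected fragment.

## SMARTS flag sets

A SMARTS-set flag is 1 iff the molecule matches at least one *active*
pattern; deactivating a pattern can therefore only clear flags, never set
them (tested as a monotonicity property). Patterns are matched with
explicit-hydrogen query atoms merged into their neighbours, so patterns
written with `[#1]` match ordinary implicit-hydrogen molecules.

The Reactive (15) and Warhead (20) sets are curated in-package lists of
standard electrophile / covalent-warhead functional groups, shipped as
editable tab-separated text. The three PAINS tiers are the public SMARTS
transcription of the pan-assay-interference filter families, read at load
time from the handler's data directory and assigned to tiers by the
screening hit count embedded in each pattern's registry name: < 15 hits
(409 patterns), 15–150 (55), > 150 (16). Pattern sets are copied into the
store on first use and edited there (add / deactivate / delete), with
store-wide recomputation available at any time.

## Scaffolds and frameworks

Scaffold (Bemis–Murcko): ring atoms plus linker atoms (found by
iteratively pruning non-ring leaves of the heavy-atom graph), then any
atom attached by a *double* bond to a kept atom is re-added. Retention is
minimal: only the doubly-bonded terminal atom is kept, not chains beyond
it, and the rule applies to linker atoms as well as ring atoms. A vinyl
side chain is lateral (removed); an exocyclic `C=O` or `C=CH2` on a ring
is kept. Fully acyclic molecules map to the single-carbon core, so the
scaffolds partition any molecule set.

Framework: start from ring + linker atoms only (the exocyclic
double-bonded atoms are dropped), replace every atom by carbon, clear
charges/isotopes/stereo, and set every bond to single — except bonds
inside 6-membered aromatic rings, which remain aromatic. Pyridine's
framework is benzene; furan's is cyclopentane (5-membered aromaticity is
not preserved); indole's is 2,3-dihydro-1H-indene. In fused systems only
the bonds of the 6-membered aromatic rings stay aromatic. If carbon
substitution produces an unsanitizable structure the framework falls back
to the all-single-bond skeleton; this is a guard, no such case appears in
the test corpus.

Core identity is the InChI of the core structure, consistent with the
store-wide convention. Frameworks are a coarsening of scaffolds
(`#frameworks ≤ #scaffolds` on every set). The cumulative-frequency
statistic reported is the minimum number of cores, taken in decreasing
member-count order, whose members sum to ≥ X% of the molecules in scope.

## Searches

Similarity search scans a stored fingerprint table with a registered
metric. Tanimoto is `|A∩B| / |A∪B|`, defined as 0 when both vectors are
empty (a convention; the quotient is 0/0). The default similarity
fingerprint is the 166-key structural key set (167 bits with the
toolkit's unused leading bit); a 1024-bit circular fingerprint is also
registered. Fingerprints computable in-package can serve structure
queries; imported-only tables require a bit-vector query.

Substructure search is two-step. The prescreen keeps molecules whose
heavy-atom, SSSR and halogen counts are each ≥ the query's (these three
columns are indexed) and whose 1056-bit pattern fingerprint is a bitwise
superset of the query's. 1056 = 33 × 32 matches the stored width of the
original substructure fingerprint contract; the generator is a registry
entry and can be swapped, after which the stored fingerprints are
regenerated store-wide by a worker. The prescreen is sound (never drops a
true match) because both filters are monotone under subgraph containment;
soundness is verified against a full-isomorphism oracle in the tests. A
maximally generic query (single carbon) passes nearly everything — the
prescreen degrades to a no-op but stays correct. SMARTS search skips the
prescreen entirely, since SMARTS constraints (charge, H-count,
aromaticity) are not captured by the connectivity fingerprint, and uses
the same matcher as the flag engine so a one-pattern search and a
one-pattern flag agree exactly.

## Diverse subset selection

Min-max selection with a one-per-core first sweep:

1. Cores (scaffolds or frameworks) of the scope are ordered by decreasing
   member count, ties by lowest core id; or shuffled with a seeded RNG.
2. The first pick is the member of the first core most similar to that
   core's *average fingerprint* (per-bit frequency vector), using the
   continuous Tanimoto `Σ min / Σ max`, which coincides with the binary
   Tanimoto on 0/1 input.
3. Each subsequent core contributes the member minimising its **maximum**
   similarity to the already-selected set. "Lowest similarity to the
   selected molecules" is interpreted as this min-max aggregate because
   the similarity cutoff is applied to the same quantity. If even the
   best candidate exceeds the current cutoff (default 0.6) the core is
   skipped for this sweep and not revisited within it.
4. If a full sweep leaves the selection short, further sweeps run over
   all cores (now allowing second, third… members per core); the cutoff
   rises by `cutoff_step` (default 0.1) whenever the shortfall was
   cutoff-induced. Once it reaches 1.0 every candidate is acceptable, so
   any target up to the scope size is reached in at most
   `⌈(1−cutoff0)/step⌉` extra cutoff escalations.

All ties (equal member counts, equal min-max scores) break on the lowest
internal id, so a fixed configuration is byte-reproducible. The result
records the number of sweeps, per-sweep pick counts and the final cutoff.

Diversity indices over a member set: average pairwise similarity, average
nearest-neighbour similarity (mean over members of the highest similarity
to another member — the most discriminating of the three), and maximum
pairwise similarity; computed per fingerprint by an O(n²) scan.

## Chemical space

PCA models are fit on autoscaled descriptor columns (zero-variance
columns get unit scale rather than dividing by zero) with two components
retained; loadings are orthonormal and agree with the eigendecomposition
of the correlation matrix to 1e-8 (sign-aligned) in the tests. Projection
applies the stored centring/scaling and loadings, so the training mean
maps to (0,0) and the map is affine in descriptor space. Rows with
missing descriptor values are dropped with a warning.

The dense-region contour marks where the mass of a projected reference
library lives: (1) the `outlier_fraction` most isolated points (ranked by
mean distance to their 5 nearest neighbours) are excluded, default 2%;
(2) the remainder is bootstrap-resampled `n_resamples` times (default
100), each resample's convex hull is taken, and the hulls are averaged
radially about the centroid on a 360-point angular grid; (3) the averaged
polygon is calibrated by a single radial scale factor — the
target-fraction quantile of point-radius / contour-radius ratios — so it
encloses at least `1 − outlier_fraction` of the non-outlier points (an
iterative 0.5% outward nudge absorbs angular-grid discretisation). The
result is star-shaped about the centroid, hence a simple polygon. With
one resample and no outlier exclusion the procedure reduces to the plain
convex hull (to ~2%, the discretisation error of the grid). This
"average convex hull" is one concrete reading of a dense-region
delimitation; it is deliberately softer than the raw hull and is not a
bit-exact reproduction of any external reference implementation.

## Synthetic fixtures: scope and limits

The fixture generator builds SDF files whose ground truth is known by
construction: ring cores decorated with saturated substituents (each
family shares one scaffold), acyclic molecules, liability-bearing
molecules grafted from templates *verified against the loaded pattern
sets at build time*, enantiomer pairs, atom-order-shuffled duplicate
records and structurally corrupt records. The manifest records expected
unique/scaffold/framework/flag counts; flag counts are censused over all
built structures, so incidental matches (e.g. a quinone is both a PAINS
and a Michael acceptor) are counted, not assumed away. Generation is
byte-deterministic per seed.

Fixtures emulate the *bookkeeping* structure of vendor catalogues —
scaffold families of uneven size, duplicates across and within files,
stereo pairs, corrupt entries — not their chemistry. Substituents are
short saturated chains; there are no tautomer traps, no charged species
beyond test salts, no macrocycles, and fingerprint distributions are far
narrower than a real 10⁵-compound catalogue. Passing tests therefore
demonstrate the correctness of the accounting, the search contracts and
the selection algorithm — not descriptor or flag behaviour across real
chemical diversity.

## Problem sizes

The default test run and the acceptance script use: a 500-record import
(271 unique structures) for the deduplication census; a 102-molecule
store and 25 substructure queries (> 2 500 query/molecule trials) for
prescreen soundness; 20 independent ~30-molecule libraries for the
diverse-vs-random comparison (sign test on average nearest-neighbour
similarity, plus mean deltas on all three indices); 500-point uniform-disc
samples for contour enclosure. These sizes keep the whole suite under
half a minute while leaving every statistical check comfortably powered.

## Known limitations

- SMARTS dialect differences between engines can flip a handful of
  matches on exotic PAINS patterns; the pattern *counts* are the stable
  surface, individual match sets are handler-relative.
- The Reactive/Warhead pattern lists are curated here at the published
  cardinalities; they are representative triage sets, not a transcription
  of any specific historical list.
- Exclusive-core unicity (SU/FU) is O(cores × members) in the current
  implementation; fine at desk scale, not tuned for 10⁷-compound stores.
- The store is single-process; concurrent imports are out of scope.
- Scaffold extraction keeps exocyclic double-bonded atoms on linker atoms
  as well as ring atoms; implementations differ on this corner and it is
  flagged as a deliberate convention.
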