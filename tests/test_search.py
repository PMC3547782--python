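"""Search engine: exact identity, similarity vs brute force, metric axioms,
prescreen soundness and SMARTS consistency."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from rdkit import Chem
from rdkit.Chem import MACCSkeys

from screenlib import (
    search_exact,
    search_similarity,
    search_smarts,
    search_substructure,
    substructure_prescreen,
    tanimoto,
)
from screenlib.chem import mol_from_molblock, mol_from_smiles, mol_to_molblock
from screenlib.fingerprints import METRICS, SUBFP_BITS, dice, from_on_bits
from screenlib.flags import stored_definitions

from conftest import mb

bitvec = st.lists(st.integers(0, 1), min_size=1, max_size=64).map(
    lambda l: np.array(l, dtype=np.uint8)
)


class TestExact:
    def test_permuted_atom_order_hits(self, store):
        block = store.molblock(5)
        mol = mol_from_molblock(block)
        shuffled = Chem.RenumberAtoms(mol, list(range(mol.GetNumAtoms()))[::-1])
        res = search_exact(store, mol_to_molblock(shuffled))
        assert res.ids == [5]

    def test_enantiomer_misses(self, store, std_fixture):
        _, manifest = std_fixture
        stereo = next(s for s in manifest["structures"] if "@" in s["smiles"])
        # invert the stereocentre
        flipped = stereo["smiles"].replace("@@", "!!").replace("@", "@@").replace("!!", "@")
        res_orig = search_exact(store, mb(stereo["smiles"]))
        res_flip = search_exact(store, mb(flipped))
        assert len(res_orig) == 1 and len(res_flip) == 1
        assert res_orig.ids != res_flip.ids

    def test_absent_structure_misses(self, store):
        assert len(search_exact(store, mb("C1CC1C1CC1C1CC1"))) == 0


class TestTanimoto:
    @pytest.mark.parametrize(
        "a, b, expected",
        [("1100", "1100", 1.0), ("1100", "0011", 0.0), ("1100", "1010", 1 / 3),
         ("0000", "0000", 0.0)],
    )
    def test_known_values(self, a, b, expected):
        va = np.array([int(c) for c in a], dtype=np.uint8)
        vb = np.array([int(c) for c in b], dtype=np.uint8)
        assert tanimoto(va, vb) == pytest.approx(expected)

    @given(a=bitvec, b=bitvec)
    def test_metric_axioms(self, a, b):
        """Symmetry and unit self-similarity for every registered metric."""
        n = max(len(a), len(b))
        a = np.pad(a, (0, n - len(a)))
        b = np.pad(b, (0, n - len(b)))
        for name, fn in METRICS.items():
            assert fn(a, b) == pytest.approx(fn(b, a))
            assert 0.0 <= fn(a, b) <= 1.0
            if a.any():
                assert fn(a, a) == pytest.approx(1.0)


class TestSimilarity:
    def _oracle(self, store, qvec, cutoff):
        """Independent all-pairs scan: MACCS via the toolkit, plain set ops."""
        hits = []
        for mol_id in store.resolve_scope(None):
            bv = MACCSkeys.GenMACCSKeys(mol_from_molblock(store.molblock(mol_id)))
            on = set(bv.GetOnBits())
            union = len(on | qvec)
            s = len(on & qvec) / union if union else 0.0
            if s >= cutoff:
                hits.append((mol_id, pytest.approx(s)))
        return sorted(hits, key=lambda h: (-h[1].expected, h[0]))

    @pytest.mark.parametrize("cutoff", [0.0, 0.3, 0.5, 0.7, 0.9])
    def test_equals_brute_force_for_all_cutoffs(self, store, cutoff):
        query = "CCc1ccncc1"
        res = search_similarity(store, mb(query), cutoff=cutoff)
        qbits = set(MACCSkeys.GenMACCSKeys(mol_from_smiles(query)).GetOnBits())
        assert res.hits == self._oracle(store, qbits, cutoff)

    def test_cutoff_zero_returns_whole_scope(self, store):
        res = search_similarity(store, mb("CCO"), cutoff=0.0)
        assert len(res) == store.n_molecules()

    def test_identical_query_ranks_first_at_one(self, store):
        block = store.molblock(3)
        res = search_similarity(store, block, cutoff=0.0)
        assert res.hits[0] == (3, pytest.approx(1.0))

    def test_scores_sorted_descending_above_cutoff(self, store):
        res = search_similarity(store, mb("Cc1ccccc1"), cutoff=0.4)
        scores = [s for _, s in res.hits]
        assert scores == sorted(scores, reverse=True)
        assert all(s >= 0.4 for s in scores)

    def test_external_fingerprint_with_structure_query_errors(self, store):
        with pytest.raises(ValueError, match="external"):
            search_similarity(store, mb("CCO"), fp_name="imported_only")

    def test_fingerprint_vector_query_usable(self, store):
        vec = from_on_bits([1, 5, 9], 167)
        res = search_similarity(store, vec, cutoff=0.0)
        assert len(res) == store.n_molecules()


QUERIES = [
    "c1ccccc1", "c1ccncc1", "C1CCCCC1", "CCO", "CCN", "C=O", "c1ccoc1",
    "Cc1ccccc1", "CCCC", "C1CCNCC1", "c1ccc2ccccc2c1", "CCl", "S",
    "CC(C)", "OCC", "c1ccsc1", "CC=S", "O=C1CSC(=S)N1", "CCCCCC", "N",
]


class TestSubstructure:
    def test_prescreen_is_sound_and_search_equals_oracle(self, store):
        """Across query x store trials the prescreen never loses a true
        match, and the two-step search equals a full isomorphism scan."""
        all_ids = store.resolve_scope(None)
        mols = {m: mol_from_molblock(store.molblock(m)) for m in all_ids}
        n_trials = 0
        for q in QUERIES:
            qblock = mb(q)
            qmol = mol_from_molblock(qblock)
            truth = [m for m in all_ids if mols[m].HasSubstructMatch(qmol)]
            candidates = substructure_prescreen(store, qblock)
            assert set(truth) <= set(candidates), q
            assert search_substructure(store, qblock).ids == truth
            n_trials += len(all_ids)
        assert n_trials >= 200

    def test_stored_molecule_is_its_own_candidate(self, store):
        for mol_id in store.resolve_scope(None)[:10]:
            assert mol_id in substructure_prescreen(store, store.molblock(mol_id))

    def test_ring_filter_excludes_acyclic_store(self, empty_store, tmp_path):
        from screenlib import import_sdf
        from screenlib.sdf import write_record

        p = tmp_path / "acyclic.sdf"
        with p.open("w") as fh:
            for s in ("CCCC", "CCO", "CCCCCC"):
                write_record(fh, mb(s), {})
        import_sdf(empty_store, p, "P")
        assert substructure_prescreen(empty_store, mb("c1ccccc1")) == []

    def test_generic_single_carbon_query_matches_all_carbon_molecules(self, store):
        res = search_substructure(store, mb("C"))
        expected = [
            m for m in store.resolve_scope(None)
            if any(a.GetAtomicNum() == 6
                   for a in mol_from_molblock(store.molblock(m)).GetAtoms())
        ]
        assert res.ids == expected


class TestSmarts:
    def test_hydroxyl_pattern(self, empty_store, tmp_path):
        from screenlib import import_sdf
        from screenlib.sdf import write_record

        p = tmp_path / "two.sdf"
        with p.open("w") as fh:
            write_record(fh, mb("CCO"), {})
            write_record(fh, mb("CC"), {})
        import_sdf(empty_store, p, "P")
        assert search_smarts(empty_store, "[OX2H]").ids == [1]

    def test_invalid_smarts_raises_before_scan(self, store):
        from screenlib.chem import MoleculeError

        with pytest.raises(MoleculeError):
            search_smarts(store, "[[[")

    def test_single_pains_pattern_consistent_with_flag_engine(self, store):
        """A SMARTS search with one PAINS pattern returns exactly the
        molecules the flag matcher marks for that pattern."""
        defs = stored_definitions(store)
        pattern = next(
            p for p in defs["PAINS_gt150"].patterns if p.name.startswith("quinone")
        )
        hits = search_smarts(store, pattern.smarts).ids
        from screenlib.chem import compile_smarts

        q = compile_smarts(pattern.smarts)
        expected = [
            m for m in store.resolve_scope(None)
            if mol_from_molblock(store.molblock(m)).HasSubstructMatch(q)
        ]
        assert hits == expected and len(hits) >= 1
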