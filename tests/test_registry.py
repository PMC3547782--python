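"""Import pipeline: standardisation, InChI identity, deduplication,
export round trips, and property/fingerprint table imports."""

import csv

import pytest
from rdkit import Chem

from screenlib import (
    ImportOptions,
    MoleculeStore,
    compute_inchi,
    export,
    import_fingerprints,
    import_properties,
    import_sdf,
    standardize,
)
from screenlib.chem import mol_from_smiles, mol_to_molblock
from screenlib.fixtures import CORES, SUBSTITUENTS, FixtureSpec, generate_fixture
from screenlib.registry import strip_smallest_fragment
from screenlib.sdf import parse_sdf, write_record

from conftest import mb


class TestInChI:
    def test_ethanol_standard_inchi(self):
        inchi, key = compute_inchi(mb("CCO"))
        assert inchi == "InChI=1S/C2H6O/c1-2-3/h3H,2H2,1H3"
        assert len(key) == 27

    def test_atom_ordering_invariance(self):
        mol = mol_from_smiles("c1ccc2c(c1)cc[nH]2")
        perm = list(range(mol.GetNumAtoms()))[::-1]
        shuffled = Chem.RenumberAtoms(mol, perm)
        assert compute_inchi(mol_to_molblock(mol)) == compute_inchi(
            mol_to_molblock(shuffled)
        )

    def test_enantiomers_are_distinct(self):
        r = compute_inchi(mb("C[C@H](O)CC"))
        s = compute_inchi(mb("C[C@@H](O)CC"))
        assert r != s


class TestStandardize:
    def test_empty_registry_preserves_inchi(self):
        block = mb("CC(=O)[O-].[Na+]")
        assert compute_inchi(standardize(block)) == compute_inchi(block)

    def test_strip_smallest_fragment_desalts(self):
        out = standardize(mb("CC(=O)[O-].[Na+]"), ["strip_smallest_fragment"])
        assert Chem.MolToSmiles(Chem.MolFromMolBlock(out)) == "CC(=O)[O-]"

    def test_transformers_compose_in_order(self):
        seen = []
        t_a = lambda b: (seen.append("a"), b)[1]
        t_b = lambda b: (seen.append("b"), b)[1]
        standardize(mb("CCO"), [t_a, t_b])
        assert seen == ["a", "b"]

    def test_desalted_duplicates_collapse_on_import(self, empty_store, tmp_path):
        p = tmp_path / "salts.sdf"
        with p.open("w") as fh:
            write_record(fh, mb("CCN.Cl"), {})
            write_record(fh, mb("CCN"), {})
        rep = import_sdf(
            empty_store, p, "P",
            ImportOptions(transformers=("strip_smallest_fragment",)),
        )
        assert (rep.n_imported, rep.n_duplicates) == (1, 1)


class TestImport:
    def test_report_conservation(self, std_fixture, empty_store):
        sdf, manifest = std_fixture
        rep = import_sdf(empty_store, sdf, "P")
        assert rep.n_read == rep.n_imported + rep.n_duplicates + rep.n_errors
        assert rep.n_read == manifest["n_records"]
        assert rep.n_imported == manifest["expected_unique"]
        assert rep.n_errors == manifest["n_corrupt"]

    def test_idempotent_at_structure_level(self, std_fixture, empty_store):
        sdf, _ = std_fixture
        import_sdf(empty_store, sdf, "P")
        before = (empty_store.n_molecules(), empty_store.all_inchis())
        rep2 = import_sdf(empty_store, sdf, "P")
        assert rep2.n_imported == 0
        assert rep2.n_duplicates == before[0] + 3  # + duplicate records
        assert (empty_store.n_molecules(), empty_store.all_inchis()) == before

    def test_overlapping_providers_share_molecules(self, empty_store, tmp_path):
        p1, p2 = tmp_path / "a.sdf", tmp_path / "b.sdf"
        with p1.open("w") as fh:
            write_record(fh, mb("CCO"), {})
            write_record(fh, mb("CCN"), {})
        with p2.open("w") as fh:
            write_record(fh, mb("CCO"), {})
        import_sdf(empty_store, p1, "A")
        import_sdf(empty_store, p2, "B")
        shared = empty_store.find_by_inchi(compute_inchi(mb("CCO"))[0])
        assert len(empty_store.get_record(shared).provider_ids) == 2

    def test_duplicate_names_append_merge(self, empty_store, tmp_path):
        p = tmp_path / "n.sdf"
        with p.open("w") as fh:
            write_record(fh, mb("CCO"), {"NAME": "ethanol"})
            write_record(fh, mb("CCO"), {"NAME": "EtOH", "CAS": "64-17-5"})
        import_sdf(empty_store, p, "P")
        rec = empty_store.get_record(1)
        assert rec.names == ["ethanol", "EtOH"]
        assert rec.cas == "64-17-5"

    def test_dedup_matches_canonical_smiles_oracle(self, tmp_path, empty_store):
        """Unique count after import equals the number of distinct canonical
        SMILES among the valid records, computed by an independent path."""
        spec = FixtureSpec(
            n_scaffold_families=5, members_per_family=8, n_acyclic=5,
            n_duplicates=20, n_stereo_pairs=3, seed=11,
        )
        sdf = tmp_path / "dedup.sdf"
        generate_fixture(spec, sdf)
        oracle = set()
        for mol in Chem.SDMolSupplier(str(sdf)):
            assert mol is not None
            oracle.add(Chem.MolToSmiles(mol))
        rep = import_sdf(empty_store, sdf, "P")
        assert rep.n_imported == empty_store.n_molecules() == len(oracle)


class TestExport:
    def test_sdf_round_trip_preserves_inchi_set(self, store, tmp_path):
        out = tmp_path / "out.sdf"
        export(store, None, "sdf", out)
        again = MoleculeStore(":memory:")
        rep = import_sdf(again, out, "P2")
        assert rep.n_imported == store.n_molecules()
        assert again.all_inchis() == store.all_inchis()
        rep2 = import_sdf(store, out, "P")  # back into the source store
        assert rep2.n_imported == 0 and rep2.n_duplicates == store.n_molecules()

    def test_sdf_export_carries_id_and_descriptor_tags(self, store, tmp_path):
        out = tmp_path / "tagged.sdf"
        export(store, [1], "sdf", out)
        (rec,) = parse_sdf(out)
        assert rec.properties["SA2_ID"] == "1"
        assert "weight" in rec.properties and "ring_count" in rec.properties

    def test_text_export_shape(self, store, tmp_path):
        out = tmp_path / "table.tsv"
        export(store, [1, 2, 3], "text", out)
        rows = list(csv.reader(out.open(), delimiter="\t"))
        assert len(rows) == 4  # header + 3
        assert len(rows[0]) == 10  # internal_id + 9 descriptors
        assert rows[0][0] == "internal_id"

    def test_empty_selection_refused(self, store, tmp_path):
        store.create_library("empty", [])
        out = tmp_path / "never.sdf"
        with pytest.raises(ValueError):
            export(store, "empty", "sdf", out)
        assert not out.exists()


class TestPropertyTables:
    def _write_table(self, path, rows, header=("id", "ic50", "assay")):
        with path.open("w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(header)
            w.writerows(rows)

    def test_rows_matched_and_stored(self, store, tmp_path):
        p = tmp_path / "props.tsv"
        self._write_table(p, [[1, "5.0", "kin"], [2, "6.1", "kin"], [3, "7.2", "kin"]])
        count, warnings = import_properties(store, p, "assays")
        assert (count, warnings) == (3, [])
        assert store.get_property("assays", 2, "ic50") == "6.1"

    def test_unknown_id_warns_not_fatal(self, store, tmp_path):
        p = tmp_path / "props.tsv"
        self._write_table(p, [[1, "5.0", "x"], [99999, "1.0", "x"], [3, "7.2", "x"]])
        count, warnings = import_properties(store, p, "assays")
        assert count == 2 and len(warnings) == 1

    def test_reimport_overwrites(self, store, tmp_path):
        p = tmp_path / "props.tsv"
        self._write_table(p, [[1, "5.0", "x"]])
        import_properties(store, p, "assays")
        self._write_table(p, [[1, "9.9", "x"]])
        count, _ = import_properties(store, p, "assays")
        assert count == 1
        assert store.get_property("assays", 1, "ic50") == "9.9"


class TestFingerprintTables:
    def _write_fp(self, path, rows):
        with path.open("w", newline="") as fh:
            csv.writer(fh, delimiter="\t").writerows(rows)

    def test_dialects_store_identical_vectors(self, store, tmp_path):
        b, i = tmp_path / "b.tsv", tmp_path / "i.tsv"
        self._write_fp(b, [[1, "10110000"]])
        self._write_fp(i, [[2, "0 2 3"]])
        import_fingerprints(store, b, "ext", "binary-string", 8)
        import_fingerprints(store, i, "ext2", "index-list", 8)
        assert store.get_fingerprint("ext", 1) == store.get_fingerprint("ext2", 2)

    def test_all_zeros_is_empty_bit_set(self, store, tmp_path):
        p = tmp_path / "z.tsv"
        self._write_fp(p, [[1, "00000000"]])
        import_fingerprints(store, p, "ext", "binary-string", 8)
        assert store.get_fingerprint("ext", 1) == (8, [])

    def test_out_of_range_index_is_record_level_error(self, store, tmp_path):
        p = tmp_path / "o.tsv"
        self._write_fp(p, [[1, "9"], [2, "1 2"]])
        count, errors = import_fingerprints(store, p, "ext", "index-list", 8)
        assert count == 1 and len(errors) == 1
        assert store.get_fingerprint("ext", 1) is None
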