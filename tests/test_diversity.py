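"""Min-max diverse selection: one-per-core guarantee, determinism,
termination, centroid seeding, and diversity indices vs brute force."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from screenlib import (
    DiversityConfig,
    MoleculeStore,
    average_fingerprint,
    diversity_report,
    import_sdf,
    select_diverse,
)
from screenlib.diversity import similarity_indices
from screenlib.fingerprints import continuous_tanimoto, from_on_bits, tanimoto
from screenlib.fixtures import FixtureSpec, generate_fixture
from screenlib.registry import stored_fingerprint_vectors


@pytest.fixture(scope="module")
def div_store(tmp_path_factory):
    d = tmp_path_factory.mktemp("div")
    sdf = d / "div.sdf"
    generate_fixture(
        FixtureSpec(n_scaffold_families=6, members_per_family=5, n_acyclic=2, seed=9),
        sdf,
    )
    s = MoleculeStore(":memory:")
    import_sdf(s, sdf, "P")
    return s


class TestAverageFingerprint:
    def test_identical_members_average_is_the_member(self):
        v = from_on_bits([0, 3], 8)
        assert np.allclose(average_fingerprint([v, v, v]), v)

    def test_complementary_vectors_average_half(self):
        a = np.array([1, 1, 0, 0], dtype=np.uint8)
        b = np.array([0, 0, 1, 1], dtype=np.uint8)
        assert np.allclose(average_fingerprint([a, b]), 0.5)

    @given(
        st.lists(st.lists(st.integers(0, 1), min_size=8, max_size=8),
                 min_size=1, max_size=6)
    )
    def test_continuous_tanimoto_matches_independent_oracle(self, rows):
        """sum(min)/sum(max) against a per-element loop oracle."""
        vecs = [np.array(r, dtype=np.uint8) for r in rows]
        avg = average_fingerprint(vecs)
        a = vecs[0].astype(float)
        num = sum(min(x, y) for x, y in zip(a, avg))
        den = sum(max(x, y) for x, y in zip(a, avg))
        expected = num / den if den else 0.0
        assert continuous_tanimoto(a, avg) == pytest.approx(expected)


class TestSelection:
    def test_first_pass_takes_one_molecule_per_core(self, div_store):
        """With the target at most the core count, the selection covers the
        first n_target cores, one member each."""
        partition = div_store.core_partition("scaffold", div_store.resolve_scope(None))
        k = len(partition)
        cfg = DiversityConfig(n_target=k, cutoff0=1.0)
        res = select_diverse(div_store, cfg)
        assert len(res.selected_ids) == k
        chosen_cores = [
            next(c for c, ms in partition.items() if m in ms)
            for m in res.selected_ids
        ]
        assert len(set(chosen_cores)) == k  # one per core

    def test_n_target_one_picks_centroid_of_largest_core(self, div_store):
        partition = div_store.core_partition("scaffold", div_store.resolve_scope(None))
        largest = min(
            (c for c in partition),
            key=lambda c: (-len(partition[c]), c),
        )
        members = sorted(partition[largest])
        vectors = stored_fingerprint_vectors(div_store, "maccs", members)
        avg = average_fingerprint([vectors[m] for m in members])
        best = max(
            members,
            key=lambda m: (continuous_tanimoto(vectors[m].astype(float), avg), -m),
        )
        res = select_diverse(div_store, DiversityConfig(n_target=1))
        assert res.selected_ids == [best]
        assert res.runs_used == 1 and res.per_run_counts == [1]

    def test_fixed_seed_selection_is_reproducible(self, div_store):
        cfg = DiversityConfig(n_target=12, ordering="random", seed=4)
        a = select_diverse(div_store, cfg)
        b = select_diverse(div_store, cfg)
        assert a.selected_ids == b.selected_ids
        assert a.per_run_counts == b.per_run_counts

    @pytest.mark.parametrize("n_target", [1, 5, 17, 10**6])
    def test_terminates_and_reaches_target(self, div_store, n_target):
        scope = div_store.n_molecules()
        cfg = DiversityConfig(n_target=n_target, cutoff0=0.2, cutoff_step=0.1)
        res = select_diverse(div_store, cfg)
        assert len(res.selected_ids) == min(n_target, scope)
        assert len(set(res.selected_ids)) == len(res.selected_ids)
        assert res.final_cutoff <= 1.0

    def test_cutoff_escalates_only_when_needed(self, div_store):
        res = select_diverse(div_store, DiversityConfig(n_target=3))
        assert res.final_cutoff == pytest.approx(0.6)

    def test_diverse_beats_seeded_random_subsets(self, div_store):
        """Monte-Carlo: the selected subset's average nearest-neighbour
        similarity is below the mean of 50 seeded random subsets."""
        n_pick = 10
        res = select_diverse(div_store, DiversityConfig(n_target=n_pick))
        ids = div_store.resolve_scope(None)
        vectors = stored_fingerprint_vectors(div_store, "maccs", ids)

        def avg_nn(members):
            return similarity_indices([vectors[m] for m in members])["avg_nn"]

        rng = np.random.default_rng(123)
        random_scores = [
            avg_nn(rng.choice(ids, size=n_pick, replace=False)) for _ in range(50)
        ]
        assert avg_nn(res.selected_ids) < np.mean(random_scores)

    def test_empty_scope_rejected(self, div_store):
        with pytest.raises(ValueError):
            select_diverse(div_store, DiversityConfig(n_target=5), scope=[])


class TestDiversityReport:
    def test_identical_vectors_all_indices_one(self):
        v = from_on_bits([1, 2, 3], 16)
        idx = similarity_indices([v, v, v, v])
        assert idx == {"avg_pairwise": 1.0, "avg_nn": 1.0, "max_sim": 1.0}

    def test_indices_match_all_pairs_oracle(self, div_store):
        ids = div_store.resolve_scope(None)[:10]
        rep = diversity_report(div_store, ids)
        vectors = stored_fingerprint_vectors(div_store, "maccs", ids)
        sims = [
            tanimoto(vectors[a], vectors[b])
            for i, a in enumerate(ids) for b in ids[i + 1:]
        ]
        nn = [
            max(tanimoto(vectors[a], vectors[b]) for b in ids if b != a)
            for a in ids
        ]
        idx = rep.indices["maccs"]
        assert idx["avg_pairwise"] == pytest.approx(np.mean(sims))
        assert idx["avg_nn"] == pytest.approx(np.mean(nn))
        assert idx["max_sim"] == pytest.approx(max(sims))
        assert idx["avg_pairwise"] <= idx["max_sim"]
        assert idx["avg_nn"] <= idx["max_sim"]

    def test_scaffold_percentages(self, div_store):
        ids = div_store.resolve_scope(None)
        rep = diversity_report(div_store, ids)
        n_scaffolds = len(div_store.core_partition("scaffold", ids))
        assert rep.scaffold_pct == pytest.approx(100.0 * n_scaffolds / len(ids))
        assert rep.framework_pct <= rep.scaffold_pct
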