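import numpy as np
import pytest

from hetphos import (
    Dataset,
    PhosphoSite,
    Protein,
    SynthConfig,
    assemble_vector,
    build_background_pool,
    generate_dataset,
    pairwise_identity,
    run_cv,
    sample_negatives,
    train_final,
)
from hetphos.classify import _fold_assignment
from hetphos.features import extract_window

SMALL = dict(n_background=120, n_substrates=15, protein_length=60)


class TestBackgroundPool:
    def test_known_sites_excluded(self):
        proteome = {"P1": Protein("P1", "MSTA")}
        pool = build_background_pool(proteome, [PhosphoSite("P1", 2, "S", "CDK")])
        assert [(w.protein_id, w.position) for w in pool] == [("P1", 3)]

    def test_no_st_gives_empty_pool(self):
        proteome = {"P1": Protein("P1", "MAGIC".replace("S", "A"))}
        pool = build_background_pool(proteome, [])
        assert pool == []

    def test_count_bookkeeping(self, planted_ds):
        pool = build_background_pool(planted_ds.proteome, planted_ds.sites)
        n_st = sum(
            p.sequence.count("S") + p.sequence.count("T")
            for p in planted_ds.proteome.values()
        )
        assert len(pool) == n_st - len(planted_ds.sites)


@pytest.fixture(scope="module")
def pool():
    ds = generate_dataset(SynthConfig(seed=21, **SMALL))
    return build_background_pool(ds.proteome, ds.sites)


@pytest.fixture(scope="module")
def small_ds():
    return generate_dataset(SynthConfig(seed=31, **SMALL))


@pytest.fixture(scope="module")
def trained_ds():
    return generate_dataset(SynthConfig(seed=41, **SMALL))


class TestSampleNegatives:

    def test_zero_request(self, pool):
        assert sample_negatives(pool, 0) == []

    def test_pairwise_identity_bound(self, pool):
        rng = np.random.default_rng(3)
        sample = sample_negatives(pool, 40, rng=rng)
        for i in range(len(sample)):
            for j in range(i + 1, len(sample)):
                assert pairwise_identity(sample[i], sample[j]) <= 0.7

    def test_seeded_determinism(self, pool):
        a = sample_negatives(pool, 20, rng=np.random.default_rng(5))
        b = sample_negatives(pool, 20, rng=np.random.default_rng(5))
        assert a == b

    def test_exhaustion_error_reports_shortfall(self, pool):
        with pytest.raises(ValueError, match="of 99999"):
            sample_negatives(pool, 99999, rng=np.random.default_rng(1))


class TestAssembleVector:
    def test_sequence_group_length(self, planted_ds):
        w = extract_window(planted_ds.proteome["bg0001"], 10)
        v = assemble_vector(w, "sequence", {}, planted_ds.matrices, planted_ds.structure)
        assert v.size == 252

    def test_group_with_terms_appends_indicators(self, planted_ds):
        w = extract_window(planted_ds.proteome["sub0001"], 10)
        terms = planted_ds.matrices["go_cc"].term_ids[:6]
        v = assemble_vector(
            w, "cc", {"go_cc": terms}, planted_ds.matrices, planted_ds.structure
        )
        assert v.size == 258
        expected = [
            planted_ds.matrices["go_cc"].has_term("sub0001", t) for t in terms
        ]
        assert v[252:].tolist() == expected

    def test_all_group_width_is_sum_of_namespaces(self, planted_ds):
        w = extract_window(planted_ds.proteome["bg0002"], 12)
        selected = {ns: mat.term_ids[:3] for ns, mat in planted_ds.matrices.items()}
        v = assemble_vector(w, "all", selected, planted_ds.matrices, planted_ds.structure)
        assert v.size == 252 + 3 * len(planted_ds.matrices)

    def test_unknown_group_errors(self, planted_ds):
        w = extract_window(planted_ds.proteome["bg0001"], 10)
        with pytest.raises(ValueError, match="group"):
            assemble_vector(w, "bogus", {}, planted_ds.matrices, planted_ds.structure)


class TestFoldAssignment:
    def test_balanced_counts(self):
        rng = np.random.default_rng(0)
        fold = _fold_assignment(rng, 100, 5)
        counts = np.bincount(fold, minlength=5)
        assert counts.tolist() == [20] * 5

    def test_uneven_counts_differ_by_at_most_one(self):
        rng = np.random.default_rng(0)
        counts = np.bincount(_fold_assignment(rng, 23, 5), minlength=5)
        assert counts.max() - counts.min() <= 1


class TestRunCV:
    def test_protein_split_never_leaks_proteins(self, small_ds):
        report = run_cv(
            small_ds,
            "CDK",
            split_mode="protein",
            reps=2,
            groups=("sequence",),
            seed=1,
            record_folds=True,
        )
        assert report.fold_log
        for entry in report.fold_log:
            assert not entry["train_proteins"] & entry["test_proteins"]

    def test_site_split_balanced_classes(self, small_ds):
        report = run_cv(
            small_ds, "CDK", reps=1, groups=("sequence",), seed=2
        )
        assert report.n_pos == report.n_neg

    def test_unknown_family_errors(self, small_ds):
        with pytest.raises(ValueError, match="NOPE"):
            run_cv(small_ds, "NOPE", reps=1)

    def test_minus_column_consistency(self, small_ds):
        report = run_cv(
            small_ds, "CDK", reps=2, groups=("sequence", "all"), seed=3
        )
        assert report.minus == pytest.approx(
            report.accuracy["all"] - report.accuracy["sequence"]
        )
        for acc in report.accuracy.values():
            assert 0.0 <= acc <= 100.0


class TestTrainFinal:
    def test_same_seed_same_selected_features(self, trained_ds):
        a = train_final(trained_ds, "CDK", seed=7)
        b = train_final(trained_ds, "CDK", seed=7)
        assert a.selected == b.selected

    def test_serialization_roundtrip(self, trained_ds, tmp_path):
        from hetphos import TrainedModel

        model = train_final(trained_ds, "CDK", seed=7)
        windows = [
            extract_window(trained_ds.proteome[s.protein_id], s.position) for s in trained_ds.sites[:10]
        ]
        before = model.decision_values(windows, trained_ds)
        model.save(tmp_path / "m.joblib")
        again = TrainedModel.load(tmp_path / "m.joblib")
        after = again.decision_values(windows, trained_ds)
        assert np.array_equal(before, after)

    def test_ranks_true_sites_above_background_windows(self, trained_ds):
        from sklearn.metrics import roc_auc_score

        from hetphos.classify import build_background_pool

        model = train_final(trained_ds, "CDK", seed=9)
        pos = [
            extract_window(trained_ds.proteome[s.protein_id], s.position) for s in trained_ds.sites
        ]
        pool = build_background_pool(trained_ds.proteome, trained_ds.sites)
        rng = np.random.default_rng(9)
        neg = [pool[i] for i in rng.choice(len(pool), size=100, replace=False)]
        d = model.decision_values(pos + neg, trained_ds)
        y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
        assert roc_auc_score(y, d) > 0.8
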