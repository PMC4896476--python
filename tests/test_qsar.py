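import numpy as np
import pytest

from skinsense import (
    LabeledDataset,
    VariantCode,
    assemble_model_dataset,
    parse_molecule,
    select_diverse,
    split,
    train_variant,
    y_randomize,
)
from skinsense.errors import DegenerateInputError, UnknownClassifierError
from skinsense.qsar import (
    CLASSIFIERS,
    RTS_QUOTAS,
    all_variant_codes,
    make_classifier,
)


class TestVariantCode:
    def test_example_code_parses(self):
        code = VariantCode.parse("1D4RF")
        assert (code.model_id, code.split_method, code.set_id,
                code.classifier) == (1, "D", 4, "RF")

    @pytest.mark.parametrize("bad", ["6Z9XX", "1D4XX", "5D4RF", "1E4RF",
                                     "1D0RF", "RF4D1", ""])
    def test_out_of_vocabulary_code_raises(self, bad):
        with pytest.raises(UnknownClassifierError):
            VariantCode.parse(bad)

    def test_round_trip_over_full_grid(self):
        codes = all_variant_codes()
        assert len(codes) == 300
        for code in codes:
            assert VariantCode.parse(str(code)) == code

    def test_every_classifier_family_instantiates(self):
        for name in CLASSIFIERS:
            clf = make_classifier(name, seed=1)
            assert hasattr(clf, "fit")
        rf = make_classifier("RF", seed=1)
        assert rf.n_estimators == 100


class TestModelAssembly:
    def test_totals_follow_class_counts(self, small_benchmark):
        c = small_benchmark.class_counts()
        m2 = assemble_model_dataset(small_benchmark, 2)
        m3 = assemble_model_dataset(small_benchmark, 3)
        m4 = assemble_model_dataset(small_benchmark, 4)
        assert len(m2) == c["X"] + c["St"] + c["S"] + c["N"]
        assert len(m3) == c["M"] + c["N"]
        assert len(m4) == c["W"] + c["N"]

    def test_model1_uses_diverse_nonsensitizer_subset(self, small_benchmark):
        c = small_benchmark.class_counts()
        m1 = assemble_model_dataset(small_benchmark, 1, diverse_nonsens_k=5)
        assert len(m1) == c["X"] + c["St"] + 5
        assert m1.class_counts()["N"] == 5

    def test_missing_required_class_raises(self):
        ds = LabeledDataset(records=[
            parse_molecule("CCO", "a", "S"),
            parse_molecule("CC", "b", "N"),
        ])
        with pytest.raises(ValueError):
            assemble_model_dataset(ds, 3)  # no Moderate sensitizers


class TestSplits:
    def test_direct_split_is_80_20(self, small_benchmark):
        sens = [r.id for r in small_benchmark if r.is_sensitizer][:10]
        nons = [r.id for r in small_benchmark if not r.is_sensitizer][:10]
        ds = small_benchmark.subset(sens + nons)
        sp = split(ds, "D", seed=1)
        assert len(sp.train_ids) == 16 and len(sp.test_ids) == 4
        assert set(sp.train_ids) | set(sp.test_ids) == set(ds.ids)
        assert not set(sp.train_ids) & set(sp.test_ids)

    def test_separation_split_is_per_class(self):
        recs = [parse_molecule(f"C{'C' * i}=O", f"s{i}", "S")
                for i in range(10)]
        recs += [parse_molecule(f"C{'C' * i}O", f"n{i}", "N")
                 for i in range(10)]
        ds = LabeledDataset(records=recs)
        sp = split(ds, "S", seed=2)
        train = ds.subset(sp.train_ids)
        assert train.class_counts() == {"S": 8, "N": 8}

    def test_cross_validation_partitions(self, small_benchmark):
        sp = split(small_benchmark, "C", seed=3, n_folds=10)
        assert sorted(sp.fold_of) == sorted(small_benchmark.ids)
        sizes = [len(te) for _, te in sp.folds()]
        assert sum(sizes) == len(small_benchmark)
        assert max(sizes) - min(sizes) <= 1

    def test_deterministic_under_seed(self, small_benchmark):
        a = split(small_benchmark, "D", seed=7)
        b = split(small_benchmark, "D", seed=7)
        c = split(small_benchmark, "D", seed=8)
        assert a.train_ids == b.train_ids
        assert a.train_ids != c.train_ids

    def test_single_class_raises(self):
        ds = LabeledDataset(records=[
            parse_molecule("CCO", "a", "N"),
            parse_molecule("CC", "b", "N"),
        ])
        with pytest.raises(DegenerateInputError):
            split(ds, "D")


class TestDiverseSelection:
    def test_full_pool_returned_unchanged(self, small_benchmark):
        out = select_diverse(small_benchmark, len(small_benchmark))
        assert out.ids == small_benchmark.ids

    def test_duplicates_lose_to_distinct_molecules(self):
        recs = [parse_molecule("c1ccccc1CCCC", f"dup{i}") for i in range(3)]
        recs.append(parse_molecule("NCCS", "far1"))
        recs.append(parse_molecule("OC(=O)CCl", "far2"))
        pool = LabeledDataset(records=recs)
        out = select_diverse(pool, 2)
        assert set(out.ids) == {"far1", "far2"}

    def test_least_average_similarity_order_invariant(self, small_benchmark):
        fwd = select_diverse(small_benchmark, 10)
        rev_pool = LabeledDataset(
            records=list(reversed(small_benchmark.records)))
        rev = select_diverse(rev_pool, 10)
        assert set(fwd.ids) == set(rev.ids)

    def test_stratified_quotas_met(self, small_benchmark):
        quotas = {"X": 1, "St": 2, "S": 5, "M": 3, "W": 3, "N": 8}
        out = select_diverse(small_benchmark, sum(quotas.values()),
                             mode="stratified-representative", quotas=quotas)
        assert out.class_counts() == quotas

    def test_rts_quotas_total_100(self):
        assert sum(RTS_QUOTAS.values()) == 100
        assert RTS_QUOTAS["N"] == 50

    def test_quota_exceeding_class_raises(self, small_benchmark):
        with pytest.raises(ValueError):
            select_diverse(small_benchmark, 500,
                           mode="stratified-representative",
                           quotas={"X": 500})


class TestTraining:
    def test_separable_clouds_high_heldout_accuracy(self):
        # two Gaussian clouds 5 sd apart, n=200: the tree ensemble must
        # recover the split nearly perfectly
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (100, 5)),
                       rng.normal(5, 1, (100, 5))])
        y = np.array([-1] * 100 + [1] * 100)
        order = rng.permutation(200)
        clf = make_classifier("RF", seed=0)
        clf.fit(X[order[:160]], y[order[:160]])
        acc = (clf.predict(X[order[160:]]) == y[order[160:]]).mean()
        assert acc >= 0.95

    def test_variant_trains_and_predicts_signs(self, small_benchmark,
                                               small_matrix):
        variant = train_variant("2C2RF", small_benchmark, small_matrix,
                                seed=4)
        preds = variant.predict(small_matrix.rows(variant.pool_ids_))
        assert set(np.unique(preds)) <= {-1, 1}
        assert variant.test_accuracy_ > 0.8

    def test_variant_persistence_round_trip(self, small_benchmark,
                                            small_matrix, tmp_path):
        variant = train_variant("2D5J48", small_benchmark, small_matrix,
                                seed=4)
        variant.save(tmp_path / "v")
        loaded = type(variant).load(tmp_path / "v")
        X = small_matrix.rows(variant.pool_ids_)
        assert np.array_equal(variant.predict(X), loaded.predict(X))
        assert str(loaded.code_) == "2D5J48"


class TestYRandomization:
    def test_default_runs_and_null_accuracy(self, small_benchmark,
                                            small_matrix):
        res = y_randomize("2D5J48", small_benchmark, small_matrix, seed=6)
        assert len(res.randomized_accuracies) == 10  # default run count
        null_mean = np.mean(res.randomized_accuracies)
        assert 0.3 < null_mean < 0.8
        assert res.real_accuracy > null_mean
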