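from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from skinsense import (
    DescriptorMatrix,
    build_descriptor_set,
    cfs_merit,
    generate_descriptor_table,
    reduce_best_first,
    select_by_ttest,
)
from skinsense.errors import DegenerateInputError


def make_matrix(values, groups=None):
    values = np.asarray(values, dtype=float)
    names = [f"f{j}" for j in range(values.shape[1])]
    return DescriptorMatrix(
        row_ids=[f"r{i}" for i in range(values.shape[0])],
        feature_names=names,
        values=values,
        feature_group=groups or {},
    )


class TestTTestSelection:
    def test_identical_feature_not_selected(self):
        rng = np.random.default_rng(0)
        shared = rng.normal(size=20)
        m = make_matrix(np.column_stack([shared, shared]))
        y = [-1] * 10 + [1] * 10
        # both columns identical across classes: no class signal
        m.values[:, 1] = m.values[:, 0]
        assert select_by_ttest(m, y) == []

    def test_large_effect_selected_and_matches_welch_oracle(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 20)
        b = rng.normal(10, 1, 20)
        m = make_matrix(np.concatenate([a, b])[:, None])
        y = [-1] * 20 + [1] * 20
        assert select_by_ttest(m, y) == ["f0"]
        p = stats.ttest_ind(a, b, equal_var=False).pvalue
        assert p < 1e-10

    def test_zero_variance_everywhere_excluded(self):
        m = make_matrix(np.ones((10, 3)))
        y = [-1] * 5 + [1] * 5
        assert select_by_ttest(m, y) == []

    def test_single_member_class_raises(self):
        m = make_matrix(np.random.default_rng(2).normal(size=(5, 2)))
        with pytest.raises(DegenerateInputError):
            select_by_ttest(m, [-1, 1, 1, 1, 1])

    def test_invariant_to_label_swap_and_column_order(self):
        m, y = generate_descriptor_table(15, 30, 5, 1.5, seed=3)
        kept = set(select_by_ttest(m, y))
        assert kept == set(select_by_ttest(m, -y))
        rev = list(reversed(m.feature_names))
        assert kept == set(select_by_ttest(m, y, features=rev))


class TestCfsMerit:
    def test_singleton_merit_is_abs_class_correlation(self):
        m, y = generate_descriptor_table(25, 4, 2, 2.0, seed=4)
        for f in m.feature_names:
            col = m.columns([f])[:, 0]
            r = abs(stats.pearsonr(col, (y > 0).astype(float))[0])
            assert cfs_merit([f], m, y) == pytest.approx(r)

    def test_duplicated_feature_never_raises_merit(self):
        # with r_ff = 1 the formula gives k*r/sqrt(k + k(k-1)) = r: a
        # perfect duplicate adds nothing, so the pair cannot beat the
        # singleton and the search keeps one copy
        m, y = generate_descriptor_table(25, 1, 1, 2.0, seed=5)
        dup = DescriptorMatrix(
            row_ids=m.row_ids,
            feature_names=["f", "f_copy"],
            values=np.column_stack([m.values[:, 0], m.values[:, 0]]),
        )
        single = cfs_merit(["f"], dup, y)
        assert cfs_merit(["f", "f_copy"], dup, y) == pytest.approx(single)
        assert reduce_best_first(dup, y, dup.feature_names).features == ["f"]

    def test_pure_noise_merit_near_zero(self):
        m, y = generate_descriptor_table(500, 5, 0, 0.0, seed=6)
        assert cfs_merit(m.feature_names, m, y) < 0.1

    def test_empty_subset_raises(self):
        m, y = generate_descriptor_table(10, 2, 0, 0.0, seed=7)
        with pytest.raises(ValueError):
            cfs_merit([], m, y)


class TestBestFirst:
    def test_single_informative_candidate_returned(self):
        m, y = generate_descriptor_table(25, 1, 1, 3.0, seed=8)
        fs = reduce_best_first(m, y, m.feature_names)
        assert fs.features == m.feature_names

    def test_drops_exact_copy_keeps_informative(self):
        rng = np.random.default_rng(9)
        f = np.concatenate([rng.normal(0, 1, 30), rng.normal(3, 1, 30)])
        g = rng.normal(size=60)
        m = DescriptorMatrix(
            row_ids=[f"r{i}" for i in range(60)],
            feature_names=["a_inf", "b_copy", "c_noise"],
            values=np.column_stack([f, f, g]),
        )
        y = [-1] * 30 + [1] * 30
        fs = reduce_best_first(m, y, m.feature_names)
        assert sum(1 for x in fs.features if x in ("a_inf", "b_copy")) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(2, 9))
        m, y = generate_descriptor_table(
            20, p, int(rng.integers(1, p + 1)),
            float(rng.uniform(0, 2)), seed=seed + 1000,
        )
        best = max(
            cfs_merit(list(sub), m, y)
            for k in range(1, p + 1)
            for sub in combinations(m.feature_names, k)
        )
        got = cfs_merit(reduce_best_first(m, y, m.feature_names).features,
                        m, y)
        assert got == pytest.approx(best, abs=1e-12)

    def test_output_beats_every_singleton(self):
        m, y = generate_descriptor_table(20, 8, 3, 1.0, seed=11)
        fs = reduce_best_first(m, y, m.feature_names)
        merit = cfs_merit(fs.features, m, y)
        for f in m.feature_names:
            assert merit >= cfs_merit([f], m, y) - 1e-12


class TestDescriptorSets:
    @pytest.fixture()
    def abc(self):
        m, y = generate_descriptor_table(25, 9, 4, 2.0, seed=12)
        A = m.feature_names[:4]
        B = m.feature_names[4:7]
        C = m.feature_names[7:9]
        return m, y, A, B, C

    def test_set5_is_plain_union(self, abc):
        m, y, A, B, C = abc
        fs = build_descriptor_set(A, B, C, 5, m, y)
        assert fs.features == A + B + C
        assert len(fs.features) == 9

    def test_set2_retains_all_reactive_fingerprints(self, abc):
        m, y, A, B, C = abc
        fs = build_descriptor_set(A, B, C, 2, m, y)
        assert set(B) <= set(fs.features)

    def test_set3_retains_all_literature_fingerprints(self, abc):
        m, y, A, B, C = abc
        fs = build_descriptor_set(A, B, C, 3, m, y)
        assert set(C) <= set(fs.features)

    def test_set1_and_set4_are_reductions(self, abc):
        m, y, A, B, C = abc
        s1 = build_descriptor_set(A, B, C, 1, m, y)
        s4 = build_descriptor_set(A, B, C, 4, m, y)
        assert set(s1.features) <= set(A) | set(B)
        assert set(s4.features) <= set(A) | set(B)

    def test_bad_set_id_raises(self, abc):
        m, y, A, B, C = abc
        with pytest.raises(ValueError):
            build_descriptor_set(A, B, C, 6, m, y)
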