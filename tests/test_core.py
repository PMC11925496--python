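import numpy as np
import pytest
from scipy import stats

from npmatch import NpmConfig, ValidationError, npm_correct
from npmatch.core import (
    build_paired_matrix,
    center_features,
    condense,
    find_pairs,
    remove_pairing_effects,
    sample_distances,
    select_top_variable,
)

from conftest import make_annotation, make_matrix


class TestSelectTopVariable:
    def test_highest_variance_rows_kept_in_original_order(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(5, 12))
        scales = np.array([2.0, 0.0, 1.0, 1.8, 1.3])  # variances 4, 0, 1, 3.24, 1.69
        m = make_matrix(base * 0 + scales[:, None] * base[0])
        out = select_top_variable(m, 2)
        expected = sorted(
            sorted(range(5), key=lambda i: -m.values[i].var(ddof=1))[:2]
        )
        assert out.feature_ids == [m.feature_ids[i] for i in expected]
        assert out.feature_ids == ["g1", "g4"]

    def test_matches_brute_force_variance_ranking(self):
        rng = np.random.default_rng(4)
        m = make_matrix(rng.normal(size=(30, 8)))
        out = select_top_variable(m, 10)
        variances = [np.var(row, ddof=1) for row in m.values]
        top = sorted(sorted(range(30), key=lambda i: (-variances[i], i))[:10])
        assert out.feature_ids == [m.feature_ids[i] for i in top]

    def test_all_tied_variances_break_by_first_occurrence(self):
        m = make_matrix(np.tile([1.0, 2.0, 3.0], (4, 1)))
        assert select_top_variable(m, 2).feature_ids == ["g1", "g2"]

    def test_n_top_at_least_p_is_identity_with_warning(self):
        m = make_matrix(np.random.default_rng(1).normal(size=(4, 5)))
        assert select_top_variable(m, 4).feature_ids == m.feature_ids
        with pytest.warns(UserWarning, match="exceeds p"):
            out = select_top_variable(m, 10)
        assert np.array_equal(out.values, m.values)


class TestCenterFeatures:
    def test_hand_worked_per_class_centering(self):
        m = make_matrix([[1.0, 3.0, 5.0, 7.0]])
        ann = make_annotation(["A", "A", "B", "B"])
        out = center_features(m, ann)
        assert np.allclose(out.values, [[-1.0, 1.0, -1.0, 1.0]], atol=1e-14)

    def test_idempotent_on_already_centered_rows(self):
        m = make_matrix([[-1.0, 1.0, -2.0, 2.0]])
        ann = make_annotation(["A", "A", "B", "B"])
        out = center_features(m, ann)
        assert np.allclose(out.values, m.values, atol=1e-14)

    def test_per_class_means_are_zero(self):
        rng = np.random.default_rng(7)
        m = make_matrix(rng.normal(5, 2, size=(20, 9)))
        phen = ["A"] * 4 + ["B"] * 3 + ["C"] * 2
        out = center_features(m, make_annotation(phen))
        for cls in "ABC":
            mask = np.asarray(phen) == cls
            assert np.allclose(out.values[:, mask].mean(axis=1), 0.0, atol=1e-12)

    def test_singleton_class_warns_and_zeroes(self):
        m = make_matrix(np.random.default_rng(2).normal(size=(5, 3)))
        with pytest.warns(UserWarning, match="single sample"):
            out = center_features(m, make_annotation(["A", "A", "B"]))
        assert np.allclose(out.values[:, 2], 0.0, atol=1e-12)


class TestSampleDistances:
    def test_identical_profiles_have_zero_distance(self):
        col = np.random.default_rng(3).normal(size=10)
        m = make_matrix(np.column_stack([col, col, col * 1.0 + 0]))
        d = sample_distances(m, "pearson")
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_profiles_are_maximally_distant(self):
        col = np.random.default_rng(3).normal(size=10)
        m = make_matrix(np.column_stack([col, -col]))
        assert sample_distances(m, "pearson")[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_abs_transform_treats_anticorrelation_as_near(self):
        col = np.random.default_rng(3).normal(size=10)
        m = make_matrix(np.column_stack([col, -col]))
        d = sample_distances(m, "pearson", transform="abs")
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("method", ["pearson", "euclidean"])
    def test_matches_pairwise_loop_oracle(self, method):
        rng = np.random.default_rng(12)
        m = make_matrix(rng.normal(size=(15, 4)))
        d = sample_distances(m, method)
        for i in range(4):
            for j in range(4):
                if method == "pearson":
                    expected = 0.0 if i == j else 1.0 - stats.pearsonr(
                        m.values[:, i], m.values[:, j]
                    )[0]
                else:
                    expected = np.sqrt(((m.values[:, i] - m.values[:, j]) ** 2).sum())
                assert d[i, j] == pytest.approx(expected, abs=1e-10)

    def test_symmetry_zero_diagonal_nonnegative(self):
        rng = np.random.default_rng(13)
        d = sample_distances(make_matrix(rng.normal(size=(25, 7))), "pearson")
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert (d >= 0).all()

    def test_zero_variance_sample_named_in_error(self):
        m = make_matrix(np.column_stack([[1.0, 2.0, 3.0], [4.0, 4.0, 4.0]]))
        with pytest.raises(ValidationError, match="s2"):
            sample_distances(m, "pearson")


class TestFindPairs:
    def test_pair_vector_length_is_n_k_c(self):
        rng = np.random.default_rng(14)
        d = sample_distances(make_matrix(rng.normal(size=(30, 4))), "pearson")
        ann = make_annotation(["A", "A", "B", "B"])
        pairs = find_pairs(d, ann, k=1)
        assert len(pairs) == 4 * 1 * 2
        assert len(pairs.flatten()) == 8

    def test_self_always_excluded_even_when_nearest(self):
        # identical duplicate columns: nearest same-class candidate distance 0
        col = np.random.default_rng(15).normal(size=20)
        m = make_matrix(np.column_stack([col, col, col + 5, col + 6]))
        d = sample_distances(m, "euclidean")
        pairs = find_pairs(d, make_annotation(["A", "A", "B", "B"]), k=1)
        for anchor, _, neighbor, _ in pairs.flatten():
            assert neighbor != anchor

    def test_matches_exhaustive_sort_and_take_k_oracle(self):
        rng = np.random.default_rng(16)
        raw = rng.uniform(0.1, 2.0, size=(6, 6))
        d = (raw + raw.T) / 2
        np.fill_diagonal(d, 0.0)
        phen = ["A", "B", "A", "B", "A", "B"]
        ann = make_annotation(phen)
        pairs = find_pairs(d, ann, k=2)
        ids = ann.sample_ids
        for i, anchor in enumerate(ids):
            for cls in ("A", "B"):
                cand = [j for j in range(6) if phen[j] == cls and j != i]
                expected = [ids[j] for j in sorted(cand, key=lambda j: (d[i, j], j))[:2]]
                assert pairs.neighbors[anchor][cls] == expected
                assert pairs.distances[anchor][cls] == sorted(
                    pairs.distances[anchor][cls]
                )

    def test_deterministic_tie_break_by_sample_index(self):
        d = np.zeros((4, 4))  # all distances tie
        ann = make_annotation(["A", "A", "B", "B"])
        pairs = find_pairs(d, ann, k=1)
        assert pairs.neighbors["s1"]["A"] == ["s2"]
        assert pairs.neighbors["s2"]["A"] == ["s1"]
        assert pairs.neighbors["s3"]["B"] == ["s4"]
        assert pairs.neighbors["s1"]["B"] == ["s3"]

    def test_infeasible_k_names_class_and_minimum(self):
        d = np.zeros((4, 4))
        ann = make_annotation(["A", "A", "B", "B"])
        with pytest.raises(ValidationError, match="k=2 infeasible"):
            find_pairs(d, ann, k=2)


class TestPairedMatrix:
    def _setup(self, include_self=False):
        rng = np.random.default_rng(17)
        m = make_matrix(rng.normal(size=(10, 4)))
        ann = make_annotation(["A", "A", "B", "B"])
        d = sample_distances(center_features(m, ann), "pearson")
        pairs = find_pairs(d, ann, k=1)
        paired = build_paired_matrix(m, pairs, ann, include_self_columns=include_self)
        return m, ann, pairs, paired

    def test_columns_are_verbatim_copies(self):
        m, _, _, paired = self._setup()
        assert paired.n_columns == 8  # n·k·c
        pos = {s: i for i, s in enumerate(m.sample_ids)}
        for col in range(paired.n_columns):
            src = paired.column_source[col]
            assert np.array_equal(paired.values[:, col], m.values[:, pos[src]])

    def test_anchor_appears_exactly_kc_times(self):
        _, _, _, paired = self._setup()
        anchors, counts = np.unique(paired.column_anchor, return_counts=True)
        assert len(anchors) == 4
        assert (counts == 2).all()  # k·c = 2 per anchor without self columns

    def test_self_columns_add_one_column_per_anchor(self):
        _, _, _, paired = self._setup(include_self=True)
        assert paired.n_columns == 12  # n·(k·c + 1)
        anchors, counts = np.unique(paired.column_anchor, return_counts=True)
        assert (counts == 3).all()

    def test_column_phenotype_is_the_source_phenotype(self):
        _, ann, _, paired = self._setup(include_self=True)
        lookup = dict(zip(ann.sample_ids, ann.phenotype))
        for col in range(paired.n_columns):
            assert paired.column_phenotype[col] == lookup[paired.column_source[col]]

    def test_condensing_uncorrected_copies_recovers_original(self):
        m, _, _, paired = self._setup(include_self=True)
        back = condense(paired, m.sample_ids)
        assert back.sample_ids == m.sample_ids
        assert np.allclose(back.values, m.values, atol=1e-14)

    def test_condense_averages_duplicate_copies(self):
        m, _, _, paired = self._setup(include_self=True)
        bumped = paired.values.copy()
        mask = paired.column_source == "s1"
        occurrences = int(mask.sum())
        bumped[0, mask] = [1.0, 2.0, 3.0][:occurrences]
        paired.values = bumped
        out = condense(paired, m.sample_ids)
        assert out.values[0, 0] == pytest.approx(
            np.mean([1.0, 2.0, 3.0][:occurrences])
        )

    def test_uncovered_sample_raises_without_self_columns(self):
        # 3-sample class where one sample is far from everything: with k=1
        # it is nobody's neighbor, so source-grouping cannot restore it
        base = np.zeros((5, 6))
        base[:, 1] = 0.1
        base[:, 2] = 50.0  # outlier in class A
        base[:, 3:] = np.array([10.0, 10.2, 30.0])[None, :].repeat(5, 0)
        m = make_matrix(base + np.random.default_rng(8).normal(0, 0.01, (5, 6)))
        ann = make_annotation(["A", "A", "A", "B", "B", "B"])
        d = sample_distances(m, "euclidean")
        pairs = find_pairs(d, ann, k=1)
        paired = build_paired_matrix(m, pairs, ann, include_self_columns=False)
        if "s3" not in set(paired.column_source):
            with pytest.raises(ValidationError, match="nobody's nearest neighbor"):
                condense(paired, m.sample_ids)
        # with self columns the same configuration condenses fine
        paired_self = build_paired_matrix(m, pairs, ann, include_self_columns=True)
        out = condense(paired_self, m.sample_ids)
        assert out.shape == m.shape


class TestRemovePairingEffects:
    def _paired(self, values, anchors, phenos):
        from npmatch.core import PairedMatrix

        return PairedMatrix(
            np.asarray(values, dtype=float),
            [f"g{i}" for i in range(np.asarray(values).shape[0])],
            np.asarray(anchors, dtype=object),
            np.asarray(anchors, dtype=object),  # source unused here
            np.asarray(phenos, dtype=object),
        )

    def test_constant_offset_between_blocks_removed(self):
        # two anchor blocks inside one phenotype, differing by +3
        values = [[1.0, 1.0, 4.0, 4.0]]
        paired = self._paired(values, ["a1", "a1", "a2", "a2"], ["A"] * 4)
        out = remove_pairing_effects(paired)
        assert np.allclose(out.values, [[2.5] * 4], atol=1e-10)

    def test_no_anchor_variation_is_a_null_correction(self):
        rng = np.random.default_rng(19)
        row = rng.normal(size=4)
        values = np.vstack([np.concatenate([row, row]) for _ in range(6)])
        paired = self._paired(
            values, ["a1"] * 4 + ["a2"] * 4, ["A", "A", "B", "B"] * 2
        )
        out = remove_pairing_effects(paired)
        assert np.allclose(out.values, paired.values, atol=1e-10)

    def test_matches_per_feature_ols_oracle(self):
        rng = np.random.default_rng(20)
        n_anchors, kc = 8, 3
        anchors = [f"a{i}" for i in range(n_anchors) for _ in range(kc)]
        phenos = rng.choice(["A", "B"], size=len(anchors))
        values = rng.normal(size=(50, len(anchors)))
        paired = self._paired(values, anchors, phenos)
        out = remove_pairing_effects(paired)

        # independent oracle: per feature, explicit OLS on dummy + deviation
        # coded design, subtract only the anchor-block contribution
        levels = sorted(set(anchors))
        B = np.zeros((len(anchors), len(levels) - 1))
        for j, lev in enumerate(levels[:-1]):
            B[np.asarray(anchors) == lev, j] = 1
            B[np.asarray(anchors) == levels[-1], j] = -1
        P = (phenos == "B").astype(float)[:, None]
        D = np.hstack([np.ones((len(anchors), 1)), P, B])
        for g in range(50):
            beta = np.linalg.pinv(D) @ values[g]
            expected = values[g] - B @ beta[2:]
            assert np.allclose(out.values[g], expected, atol=1e-8)


class TestNpmCorrect:
    def test_output_preserves_shape_and_ids(self):
        rng = np.random.default_rng(22)
        m = make_matrix(rng.normal(6, 1, size=(60, 12)))
        ann = make_annotation(["A"] * 6 + ["B"] * 6)
        out = npm_correct(m, ann, NpmConfig(n_top_features=30))
        assert out.shape == m.shape
        assert out.feature_ids == m.feature_ids
        assert out.sample_ids == m.sample_ids

    def test_bitwise_deterministic(self):
        rng = np.random.default_rng(23)
        m = make_matrix(rng.normal(6, 1, size=(40, 10)))
        ann = make_annotation(["A"] * 5 + ["B"] * 5)
        cfg = NpmConfig(n_top_features=20)
        a = npm_correct(m, ann, cfg)
        b = npm_correct(m, ann, cfg)
        assert np.array_equal(a.values, b.values)

    def test_k_validated_against_smallest_class(self):
        rng = np.random.default_rng(24)
        m = make_matrix(rng.normal(size=(10, 5)))
        ann = make_annotation(["A", "A", "A", "B", "B"])
        with pytest.raises(ValidationError, match="smallest phenotype class"):
            npm_correct(m, ann, NpmConfig(k=2, n_top_features=10))

    def test_annotation_in_any_order_gives_same_result(self):
        rng = np.random.default_rng(25)
        m = make_matrix(rng.normal(6, 1, size=(30, 8)))
        phen = ["A", "B", "A", "B", "A", "B", "A", "B"]
        ann = make_annotation(phen)
        shuffled = make_annotation(
            [phen[i] for i in [3, 1, 0, 2, 7, 5, 4, 6]],
            sample_ids=[ann.sample_ids[i] for i in [3, 1, 0, 2, 7, 5, 4, 6]],
        )
        cfg = NpmConfig(n_top_features=30)
        assert np.array_equal(
            npm_correct(m, ann, cfg).values, npm_correct(m, shuffled, cfg).values
        )
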