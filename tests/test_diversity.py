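import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.spatial import procrustes
from skbio.stats.distance import DistanceMatrix

from gutnet.data_io import CountTable, ValidationError
from gutnet.diversity import (alpha_suite, bray_curtis, pcoa, permanova,
                              shannon, whittaker_beta)


def table_from(counts):
    counts = np.asarray(counts)
    return CountTable([f"s{i}" for i in range(counts.shape[0])],
                      [f"t{j}" for j in range(counts.shape[1])], counts)


class TestShannon:
    @pytest.mark.parametrize("row,expected", [
        ([1, 1, 1, 1], np.log(4)),
        ([10, 0, 0], 0.0),
        ([1, 2, 3], -(1 / 6 * np.log(1 / 6) + 2 / 6 * np.log(2 / 6)
                      + 3 / 6 * np.log(3 / 6))),
    ])
    def test_closed_forms_in_nats(self, row, expected):
        assert shannon(np.array(row)) == pytest.approx(expected, abs=1e-4)

    def test_zero_row_is_error(self):
        with pytest.raises(ValidationError):
            shannon(np.zeros(3))

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(0)
        row = rng.integers(1, 50, 10)
        assert shannon(row) == pytest.approx(shannon(row[::-1].copy()))

    def test_log_base_flag(self):
        assert shannon(np.array([1, 1]), base=2) == pytest.approx(1.0)


@settings(max_examples=50, derandomize=True)
@given(arrays(np.int64, st.integers(2, 20),
              elements=st.integers(0, 1000)).filter(lambda r: r.sum() > 0))
def test_shannon_bounded_by_log_observed_richness(row):
    h = shannon(row)
    s_obs = int((row > 0).sum())
    assert -1e-9 <= h <= np.log(s_obs) + 1e-9


@settings(max_examples=50, derandomize=True)
@given(arrays(np.int64, (4, 8), elements=st.integers(0, 100))
       .filter(lambda m: (m.sum(axis=1) > 0).all()))
def test_bray_curtis_bounds_symmetry_identity(counts):
    dm = bray_curtis(table_from(counts))
    d = dm.data
    assert ((d >= -1e-12) & (d <= 1 + 1e-12)).all()
    np.testing.assert_allclose(d, d.T, atol=1e-12)
    for i in range(4):
        for j in range(4):
            if np.array_equal(counts[i], counts[j]):
                assert d[i, j] == pytest.approx(0.0, abs=1e-12)


class TestAlphaSuite:
    def test_simpson_even_two_taxa(self):
        res = alpha_suite(table_from([[5, 5]]))
        assert res["simpson"].iloc[0] == pytest.approx(0.5)

    def test_chao1_no_singletons_equals_observed_richness(self):
        res = alpha_suite(table_from([[4, 5, 6, 0]]))
        assert res["chao1"].iloc[0] == pytest.approx(3.0)

    def test_chao1_bias_corrected_formula(self):
        # S_obs = 10, F1 = 2, F2 = 1 -> 10 + 2*1/(2*2) = 10.5
        row = [1, 1, 2, 3, 3, 3, 4, 5, 6, 7]
        res = alpha_suite(table_from([row]))
        assert res["chao1"].iloc[0] == pytest.approx(10.5)

    def test_estimators_bounded_below_by_observed_richness(self):
        rng = np.random.default_rng(1)
        table = table_from(rng.integers(0, 8, (6, 30)))
        res = alpha_suite(table)
        s_obs = (table.counts > 0).sum(axis=1)
        assert (res["chao1"].to_numpy() >= s_obs - 1e-9).all()
        assert (res["ace"].to_numpy() >= s_obs - 1e-9).all()

    def test_non_integer_counts_rejected(self):
        t = table_from([[1, 2]])
        t.counts = t.counts.astype(float)
        with pytest.raises(ValidationError):
            alpha_suite(t)


class TestBrayCurtis:
    def test_hand_examples(self):
        dm = bray_curtis(table_from([[2, 2], [2, 0], [0, 2]]))
        assert dm["s0", "s1"] == pytest.approx(1 / 3)
        assert dm["s1", "s2"] == pytest.approx(1.0)   # disjoint supports

    def test_identical_samples_distance_zero(self):
        dm = bray_curtis(table_from([[3, 1, 4], [3, 1, 4]]))
        assert dm["s0", "s1"] == 0.0

    def test_bounds_and_symmetry(self):
        rng = np.random.default_rng(2)
        dm = bray_curtis(table_from(rng.integers(0, 20, (8, 12)) + 1))
        d = dm.data
        assert ((d >= 0) & (d <= 1)).all()
        np.testing.assert_allclose(d, d.T)
        assert np.diag(d).sum() == 0


class TestWhittaker:
    def test_identical_composition_is_zero(self):
        assert whittaker_beta(table_from([[1, 1, 0], [2, 2, 0]])) == \
            pytest.approx(0.0)

    def test_disjoint_equal_richness_is_one(self):
        assert whittaker_beta(table_from([[1, 1, 0, 0], [0, 0, 1, 1]])) == \
            pytest.approx(1.0)

    def test_hand_example_three_samples(self):
        # richness 4, 4, 4; pooled 6 -> 6/4 - 1 = 0.5
        counts = [[1, 1, 1, 1, 0, 0],
                  [0, 0, 1, 1, 1, 1],
                  [1, 1, 0, 0, 1, 1]]
        assert whittaker_beta(table_from(counts)) == pytest.approx(0.5)

    def test_ratio_form_flag(self):
        t = table_from([[1, 1], [1, 1]])
        assert whittaker_beta(t, turnover=False) == pytest.approx(1.0)

    def test_empty_subset_is_error(self):
        with pytest.raises(ValidationError):
            whittaker_beta(table_from([[1, 1]]), sample_ids=[])


class TestPcoa:
    def test_collinear_points_have_one_positive_axis(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        d = np.abs(x[:, None] - x[None, :])
        res = pcoa(DistanceMatrix(d, ids=list("abcd")), n_axes=3)
        eig = np.sort(res.eigenvalues)[::-1]
        assert eig[0] > 1e-6
        assert np.abs(eig[1:]).max() < 1e-8

    def test_recovers_planar_configuration_up_to_rotation(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(10, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res = pcoa(DistanceMatrix(d, ids=[str(i) for i in range(10)]),
                   n_axes=2)
        _, _, disparity = procrustes(pts, res.coordinates.to_numpy())
        assert disparity < 1e-8

    def test_duplicate_samples_get_identical_coordinates(self):
        counts = [[5, 1, 1], [5, 1, 1], [1, 5, 5]]
        dm = bray_curtis(table_from(counts))
        res = pcoa(dm, n_axes=1)
        c = res.coordinates.to_numpy()
        np.testing.assert_allclose(c[0], c[1], atol=1e-10)


class TestPermanova:
    def _separated(self, per_group=6):
        rng = np.random.default_rng(0)
        a = rng.integers(45, 55, (per_group, 4))
        a[:, 1:] = rng.integers(1, 3, (per_group, 3))
        b = rng.integers(45, 55, (per_group, 4))
        b[:, [0, 2, 3]] = rng.integers(1, 3, (per_group, 3))
        return bray_curtis(table_from(np.vstack([a, b])))

    def test_perfect_separation_min_p(self):
        dm = self._separated()
        res = permanova(dm, ["a"] * 6 + ["b"] * 6, n_permutations=99, seed=0)
        assert res.p_value == pytest.approx(1 / 100, abs=0.03)
        assert res.pseudo_F > 10

    def test_sample_order_invariance_of_f(self):
        dm = self._separated()
        labels = np.array(["a"] * 6 + ["b"] * 6)
        res1 = permanova(dm, labels, n_permutations=99, seed=0)
        order = list(np.random.default_rng(1).permutation(12))
        dm2 = dm.filter([dm.ids[i] for i in order])
        res2 = permanova(dm2, labels[order], n_permutations=99, seed=0)
        assert res1.pseudo_F == pytest.approx(res2.pseudo_F)

    def test_p_never_zero_and_r2_in_unit_interval(self):
        dm = self._separated()
        res = permanova(dm, ["a"] * 6 + ["b"] * 6, n_permutations=99, seed=1)
        assert res.p_value >= 1 / 100
        assert 0 <= res.R2 <= 1

    def test_degenerate_grouping_rejected(self):
        dm = self._separated()
        with pytest.raises(ValidationError):
            permanova(dm, ["a"] * 11 + ["b"], n_permutations=99, seed=0)
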