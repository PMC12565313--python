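import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermobreast import FEATURE_NAMES, extract_features, statistical_features
from thermobreast.features import (
    Glcm,
    compute_glcm,
    entropy,
    features_table,
    glcm_features,
    quantize,
)
from conftest import make_breast_sample


class TestStatisticalFeatures:
    def test_direct_arithmetic_oracle(self, sample_factory):
        s = sample_factory([[1.0, 2.0], [3.0, 4.0]])
        f = statistical_features(s)
        assert f["mean"] == pytest.approx(2.5)
        assert f["std"] == pytest.approx(1.118034, abs=1e-6)  # population form
        assert f["variance"] == pytest.approx(1.25)
        assert f["skewness"] == pytest.approx(0.0)  # median 2.5
        assert f["min"] == 1.0 and f["max"] == 4.0
        assert f["cv"] == pytest.approx(44.7214, abs=1e-4)
        assert f["energy"] == pytest.approx(10.0)

    def test_constant_sample_degenerate(self, sample_factory):
        s = sample_factory(np.full((2, 2), 25.0))
        with pytest.warns(UserWarning, match="undefined-constant"):
            f = statistical_features(s)
        assert f["mean"] == 25.0 and f["std"] == 0.0
        assert f["min"] == f["max"] == 25.0
        assert f["cv"] == 0.0 and f["energy"] == 100.0
        assert np.isnan(f["skewness"]) and np.isnan(f["kurtosis"])

    def test_two_point_distribution_closed_form(self, sample_factory):
        # {-1,+1} shifted to {27,29}: symmetric two-point law has
        # skewness 0 and kurtosis E(x-mu)^4/sigma^4 = 1
        s = sample_factory([[27.0, 29.0]])
        f = statistical_features(s)
        assert f["skewness"] == pytest.approx(0.0)
        assert f["kurtosis"] == pytest.approx(1.0)

    def test_variance_is_std_squared(self, sample_factory):
        rng = np.random.default_rng(0)
        s = sample_factory(rng.uniform(20, 36, (7, 5)))
        f = statistical_features(s)
        assert f["variance"] == pytest.approx(f["std"] ** 2, rel=1e-9)

    def test_nonpositive_mean_rejected(self, sample_factory):
        with pytest.raises(ValueError, match="positive"):
            statistical_features(make_breast_sample([[-1.0, 1.0]]))

    def test_single_pixel_rejected(self, sample_factory):
        with pytest.raises(ValueError, match="at least 2"):
            statistical_features(sample_factory([[25.0]]))


class TestQuantize:
    def test_endpoints(self, sample_factory):
        s = sample_factory([[0.0, 10.0]])
        q = quantize(s, G=256, calibration=(0.0, 10.0))
        assert q.levels[0, 0] == 0
        assert q.levels[0, 1] == 255

    def test_floor_rule(self, sample_factory):
        s = sample_factory([[4.9, 5.0]])
        q = quantize(s, G=2, calibration=(0.0, 10.0))
        assert q.levels[0, 0] == 0 and q.levels[0, 1] == 1

    def test_default_calibration_is_sample_min_max(self, sample_factory):
        s = sample_factory([[21.0, 30.0, 26.0]])
        q = quantize(s, G=8)
        assert q.calibration == (21.0, 30.0)
        assert q.levels[0, 0] == 0 and q.levels[0, 1] == 7

    def test_constant_sample_all_zero_with_warning(self, sample_factory):
        s = sample_factory(np.full((2, 3), 25.0))
        with pytest.warns(UserWarning, match="constant"):
            q = quantize(s, G=16)
        assert np.all(q.levels == 0)

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(20.0, 36.0, allow_nan=False), min_size=2, max_size=12),
        st.integers(2, 64),
    )
    def test_quantization_monotone(self, values, G):
        s = make_breast_sample([values])
        q = quantize(s, G=G, calibration=(20.0, 36.0))
        order = np.argsort(values)
        assert np.all(np.diff(q.levels[0, order]) >= 0)


class TestGlcm:
    def test_hand_enumerated_2x2(self, sample_factory):
        q = quantize(sample_factory([[0.0, 0.0], [1.0, 1.0]]), G=2, calibration=(0, 1))
        g = compute_glcm(q)
        assert g.P[0, 0] == pytest.approx(1 / 6)
        assert g.P[1, 1] == pytest.approx(1 / 6)
        assert g.P[0, 1] == pytest.approx(1 / 3)
        assert g.P[1, 0] == pytest.approx(1 / 3)

    def test_constant_image(self, sample_factory):
        s = sample_factory(np.full((3, 3), 25.0))
        with pytest.warns(UserWarning):
            q = quantize(s, G=4)
        g = compute_glcm(q)
        assert g.P[0, 0] == 1.0
        assert g.P.sum() == pytest.approx(1.0)

    def test_normalized_and_symmetric(self, sample_factory):
        rng = np.random.default_rng(5)
        grid = rng.uniform(20, 36, (6, 7))
        mask = rng.random(grid.shape) < 0.8
        mask[0, :2] = True
        s = make_breast_sample(grid, mask)
        g = compute_glcm(quantize(s, G=8))
        assert g.P.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(g.P, g.P.T)

    def test_zero_valid_pairs_errors(self):
        # isolated in-mask pixels: no co-occurring pair
        grid = np.full((3, 3), 25.0)
        mask = np.zeros((3, 3), dtype=bool)
        mask[0, 0] = mask[2, 2] = True
        grid[0, 0] = 20.0
        s = make_breast_sample(grid, mask)
        with pytest.raises(ValueError, match="no valid"):
            compute_glcm(quantize(s, G=4))

    def test_matches_brute_force_oracle(self, glcm_oracle):
        rng = np.random.default_rng(6)
        for _ in range(50):
            h, w = rng.integers(2, 9, 2)
            G = int(rng.integers(2, 9))
            levels = rng.integers(0, G, (h, w))
            mask = rng.random((h, w)) < 0.75
            counts = glcm_oracle(levels, mask, G)
            if counts.sum() == 0:
                continue
            from thermobreast.features import QuantizedSample

            q = QuantizedSample(levels=levels, mask=mask, G=G, calibration=(0.0, 1.0))
            g = compute_glcm(q)
            assert np.array_equal(g.P, counts / counts.sum())


class TestGlcmFeatures:
    def test_closed_form_from_enumerated_matrix(self, sample_factory):
        q = quantize(sample_factory([[0.0, 0.0], [1.0, 1.0]]), G=2, calibration=(0, 1))
        hom, con, cor = glcm_features(compute_glcm(q))
        assert hom == pytest.approx(2 / 3)
        assert con == pytest.approx(2 / 3)
        assert cor == pytest.approx(-1 / 3)

    def test_constant_image_degenerate(self, sample_factory):
        s = sample_factory(np.full((3, 3), 25.0))
        with pytest.warns(UserWarning):
            q = quantize(s, G=4)
            hom, con, cor = glcm_features(compute_glcm(q))
        assert hom == 1.0 and con == 0.0 and cor == 1.0

    def test_identity_diagonal_glcm(self):
        G = 5
        g = Glcm(P=np.eye(G) / G, G=G)
        hom, con, cor = glcm_features(g)
        assert con == 0.0
        assert cor == pytest.approx(1.0)
        assert hom == pytest.approx(1.0)

    def test_homogeneity_bounded_by_one(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            G = int(rng.integers(2, 10))
            M = rng.random((G, G))
            M = M + M.T
            g = Glcm(P=M / M.sum(), G=G)
            hom, con, _ = glcm_features(g)
            assert hom <= 1.0 + 1e-12
            # equality iff all off-diagonal mass (hence contrast) is zero
            assert (hom == pytest.approx(1.0)) == (con == pytest.approx(0.0))


class TestEntropy:
    def test_constant_zero(self, sample_factory):
        with pytest.warns(UserWarning):
            q = quantize(sample_factory(np.full((2, 2), 25.0)), G=8)
        assert entropy(q) == 0.0

    def test_two_equiprobable_levels_one_bit(self, sample_factory):
        q = quantize(sample_factory([[0.0, 10.0]]), G=2, calibration=(0, 10))
        assert entropy(q) == pytest.approx(1.0)

    def test_uniform_256_levels_eight_bits(self, sample_factory):
        vals = np.arange(256, dtype=float).reshape(16, 16)
        q = quantize(sample_factory(vals + 1), G=256, calibration=(1.0, 256.0))
        assert entropy(q) == pytest.approx(8.0)

    def test_permutation_invariant(self, sample_factory):
        rng = np.random.default_rng(8)
        vals = rng.uniform(20, 36, 24)
        q1 = quantize(make_breast_sample([vals]), G=16, calibration=(20, 36))
        q2 = quantize(make_breast_sample([rng.permutation(vals)]), G=16, calibration=(20, 36))
        assert entropy(q1) == pytest.approx(entropy(q2), abs=1e-12)


class TestExtractFeatures:
    def test_schema_names_fixed_and_ordered(self, sample_factory):
        rng = np.random.default_rng(9)
        s = sample_factory(rng.uniform(25, 30, (6, 6)))
        fv = extract_features(s)
        assert list(fv.as_dict()) == list(FEATURE_NAMES)
        assert len(FEATURE_NAMES) == 13
        fv14 = extract_features(s, include_glcm_energy=True)
        assert list(fv14.as_dict()) == list(FEATURE_NAMES) + ["glcm_energy"]
        assert len(fv14.as_dict()) == 14

    def test_case_report_columns_available(self, sample_factory):
        # the per-breast report row: mean, entropy, min, max, homogeneity,
        # contrast, correlation
        rng = np.random.default_rng(10)
        fv = extract_features(sample_factory(rng.uniform(25, 30, (6, 6))))
        d = fv.as_dict()
        for col in ("mean", "entropy", "min", "max", "homogeneity", "contrast", "correlation"):
            assert col in d

    def test_pair_path_equals_matrix_path(self, sample_factory):
        rng = np.random.default_rng(11)
        for _ in range(30):
            h, w = rng.integers(3, 9, 2)
            grid = rng.uniform(20, 36, (h, w))
            mask = rng.random((h, w)) < 0.7
            if mask.sum() < 4:
                continue
            s = make_breast_sample(grid, mask)
            G = int(rng.integers(2, 12))
            try:
                fv = extract_features(s, G=G)
            except ValueError:
                continue
            hom, con, cor = glcm_features(compute_glcm(quantize(s, G=G)))
            assert fv.homogeneity == pytest.approx(hom, abs=1e-12)
            assert fv.contrast == pytest.approx(con, abs=1e-12)
            assert fv.correlation == pytest.approx(cor, abs=1e-9)

    def test_shift_property(self, sample_factory):
        rng = np.random.default_rng(12)
        grid = rng.uniform(24, 30, (8, 8))
        c = 3.0
        s1 = sample_factory(grid)
        s2 = sample_factory(grid + c)
        f1 = extract_features(s1, calibration=(20.0, 36.0))
        f2 = extract_features(s2, calibration=(20.0 + c, 36.0 + c))
        assert f2.mean == pytest.approx(f1.mean + c)
        assert f2.min == pytest.approx(f1.min + c)
        assert f2.max == pytest.approx(f1.max + c)
        assert f2.energy == pytest.approx(f1.energy + c * grid.size)
        for name in ("std", "skewness", "kurtosis", "homogeneity", "contrast", "correlation", "entropy"):
            assert getattr(f2, name) == pytest.approx(getattr(f1, name), abs=1e-9), name

    def test_synthetic_control_breast_mean_near_baseline(self):
        from thermobreast import CohortConfig, generate_breast_field
        from thermobreast.synthetic import breast_masks

        cfg = CohortConfig(grid_height=48, grid_width=64, noise_sd=0.2, baseline_temp=28.0)
        field = generate_breast_field(cfg, "left", False, np.random.default_rng(1))
        _, left_m, _ = breast_masks(48, 64)
        s = make_breast_sample(field, left_m)
        fv = extract_features(s)
        assert 27.0 <= fv.mean <= 29.0 + cfg.lateral_gradient

    def test_features_table_columns(self):
        from thermobreast import CohortConfig, generate_cohort
        from thermobreast.pipeline import cases_to_samples

        cfg = CohortConfig(n_control_subjects=1, n_cancer_subjects=0,
                           grid_height=36, grid_width=48)
        table = features_table(cases_to_samples(generate_cohort(cfg)))
        assert list(table.columns) == ["subject_id", "side", "label"] + list(FEATURE_NAMES)
        assert len(table) == 2
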