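import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from hsretina import (ContrastScorer, ContrastSpectrum, CubeMeta, HyperCube,
                      SpectrumMatrix, WavelengthGrid, aggregate_scores,
                      contrast_spectrum, fit_and_score, normalize_anchor,
                      mask_outliers, score_pixels, stack_spectra)
from tests.conftest import random_matrix


def contrast_oracle(X, labels):
    """Explicit two-loop per-band mean-difference, independent of the package."""
    bands = X.shape[1]
    d = np.zeros(bands)
    for b in range(bands):
        s_ad = n_ad = s_co = n_co = 0
        for i in range(X.shape[0]):
            if labels[i] == "AD":
                s_ad += X[i, b]
                n_ad += 1
            else:
                s_co += X[i, b]
                n_co += 1
        d[b] = s_ad / n_ad - s_co / n_co
    return d


def make_matrix(X, labels, mice=None, fields=None):
    X = np.asarray(X, dtype=float)
    n, b = X.shape
    grid = WavelengthGrid(np.linspace(471, 691, b))
    labels = np.asarray(labels, dtype=object)
    mice = np.asarray(mice if mice is not None else labels, dtype=object)
    fields = np.asarray(fields if fields is not None else np.ones(n, int))
    return SpectrumMatrix(X, labels, mice, fields, grid)


class TestContrastSpectrum:
    def test_hand_computed_two_band_example(self):
        m = make_matrix([[1, 0], [1, 2], [0, 0], [0, 2]],
                        ["AD", "AD", "CO", "CO"])
        d = contrast_spectrum(m).d
        np.testing.assert_allclose(d, [1.0, 0.0], atol=1e-15)

    def test_identical_classes_give_zero_contrast(self, rng):
        X = rng.normal(size=(4, 6))
        m = make_matrix(np.vstack([X, X]), ["AD"] * 4 + ["CO"] * 4)
        np.testing.assert_allclose(contrast_spectrum(m).d, 0.0, atol=1e-15)

    def test_relabeling_negates_contrast(self, rng):
        m = random_matrix(rng, 10, 7)
        swapped = make_matrix(m.X, np.where(m.labels == "AD", "CO", "AD"))
        np.testing.assert_allclose(contrast_spectrum(m).d,
                                   -contrast_spectrum(swapped).d, atol=1e-12)

    def test_matches_two_loop_oracle(self, rng):
        for _ in range(5):
            m = random_matrix(rng, int(rng.integers(2, 40)),
                              int(rng.integers(2, 40)), bands=7)
            np.testing.assert_allclose(contrast_spectrum(m).d,
                                       contrast_oracle(m.X, m.labels),
                                       atol=1e-12)

    def test_single_class_names_missing_class(self, rng):
        m = make_matrix(rng.normal(size=(3, 4)), ["AD"] * 3)
        with pytest.raises(ValueError, match="CO"):
            contrast_spectrum(m)

    def test_balanced_mouse_weighting(self):
        # AD: mouse a contributes 3 pixels at 0, mouse b one pixel at 3.
        X = np.array([[0.0], [0.0], [0.0], [3.0], [0.0]])
        nm_grid = WavelengthGrid([550.0])
        m = SpectrumMatrix(X, np.array(["AD"] * 4 + ["CO"], object),
                           np.array(["a", "a", "a", "b", "c"], object),
                           np.ones(5, int), nm_grid)
        pooled = contrast_spectrum(m, balance_mice=False).d[0]
        balanced = contrast_spectrum(m, balance_mice=True).d[0]
        assert pooled == pytest.approx(3.0 / 4)
        assert balanced == pytest.approx(1.5)  # mean of mouse means (0, 3)


class TestScorePixels:
    def test_dot_product_example(self):
        m = make_matrix([[1.0, 2.0]], ["AD"])
        c = ContrastSpectrum(np.array([3.0, -1.0]), m.grid, 1, 1)
        assert score_pixels(m, c)[0] == pytest.approx(1.0)

    def test_zero_contrast_gives_zero_scores(self, rng):
        m = random_matrix(rng, 4, 4)
        c = ContrastSpectrum(np.zeros(5), m.grid, 4, 4)
        np.testing.assert_array_equal(score_pixels(m, c), 0.0)

    def test_linearity(self, rng):
        m1 = random_matrix(rng, 6, 6)
        X2 = rng.normal(size=m1.X.shape)
        c = contrast_spectrum(m1)
        a, b = 2.5, -1.25
        combo = SpectrumMatrix(a * m1.X + b * X2, m1.labels, m1.mouse_ids,
                               m1.field_ids, m1.grid)
        np.testing.assert_allclose(
            score_pixels(combo, c),
            a * score_pixels(m1, c) + b * (X2 @ c.d), atol=1e-9)

    def test_shift_by_contrast_adds_norm_sq(self, rng):
        m = random_matrix(rng, 5, 5)
        c = contrast_spectrum(m)
        shifted = SpectrumMatrix(m.X + c.d, m.labels, m.mouse_ids,
                                 m.field_ids, m.grid)
        np.testing.assert_allclose(
            score_pixels(shifted, c) - score_pixels(m, c),
            c.norm_sq(), atol=1e-9)

    def test_grid_mismatch_rejected(self, rng):
        m = random_matrix(rng, 3, 3)
        other = ContrastSpectrum(np.zeros(5),
                                 WavelengthGrid(np.linspace(500, 600, 5)), 1, 1)
        with pytest.raises(ValueError):
            score_pixels(m, other)


class TestAggregateScores:
    def test_mouse_score_is_mean_of_pixels(self):
        m = make_matrix(np.zeros((3, 2)), ["AD"] * 3, mice=["m1"] * 3)
        c = ContrastSpectrum(np.zeros(2), m.grid, 3, 1)
        ss = aggregate_scores(np.array([1.0, 2.0, 3.0]), m, c)
        assert ss.mouse_scores.mouse_score.iloc[0] == pytest.approx(2.0)

    def test_mouse_pools_pixels_not_field_means(self):
        # field A: pixels {0, 0}; field B: {3, 3, 3, 3}
        m = make_matrix(np.zeros((6, 2)), ["AD"] * 6, mice=["m1"] * 6,
                        fields=[1, 1, 2, 2, 2, 2])
        c = ContrastSpectrum(np.zeros(2), m.grid, 6, 1)
        ss = aggregate_scores(np.array([0, 0, 3, 3, 3, 3.0]), m, c)
        row = ss.mouse_scores.iloc[0]
        assert row.mouse_score == pytest.approx(2.0)
        assert row.mean_of_field_means == pytest.approx(1.5)

    def test_field_scores_annotated_with_eccentricity(self, rng):
        m = random_matrix(rng, 6, 6)
        ss = fit_and_score(m)
        assert set(ss.field_scores.eccentricity) <= {"central", "peripheral"}
        even = ss.field_scores[ss.field_scores.field_id % 2 == 0]
        assert (even.eccentricity == "peripheral").all()

    def test_in_sample_class_gap_equals_contrast_norm_sq(self, rng):
        for _ in range(5):
            m = random_matrix(rng, int(rng.integers(3, 30)),
                              int(rng.integers(3, 30)))
            c = contrast_spectrum(m)
            s = score_pixels(m, c)
            gap = s[m.labels == "AD"].mean() - s[m.labels == "CO"].mean()
            assert gap == pytest.approx(c.norm_sq(), abs=1e-9)


class TestFitAndScore:
    def test_in_sample_equals_manual_composition(self, rng):
        m = random_matrix(rng, 8, 8)
        ss = fit_and_score(m, mode="in_sample")
        c = contrast_spectrum(m)
        manual = aggregate_scores(score_pixels(m, c), m, c)
        np.testing.assert_array_equal(ss.pixel_scores, manual.pixel_scores)
        pd.testing.assert_frame_equal(ss.mouse_scores, manual.mouse_scores)

    def test_lomo_requires_two_mice_per_class(self, rng):
        X = rng.normal(size=(6, 5))
        m = make_matrix(X, ["AD"] * 3 + ["CO"] * 3,
                        mice=["a1"] * 3 + ["c1", "c2", "c2"])
        with pytest.raises(ValueError, match="AD"):
            fit_and_score(m, mode="leave_one_mouse_out")

    def test_lomo_scores_exclude_own_mouse(self, rng):
        m = random_matrix(rng, 12, 12, n_mice=3)
        ss = fit_and_score(m, mode="leave_one_mouse_out")
        mouse = m.mouse_ids[0]
        held = m.mouse_ids == mouse
        rest = m.subset(~held)
        expected = m.X[held] @ contrast_spectrum(rest).d
        np.testing.assert_allclose(ss.pixel_scores[held], expected, atol=1e-12)

    def test_unknown_mode_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_and_score(random_matrix(rng, 4, 4), mode="bootstrap")


class TestStackSpectra:
    def _normalized(self, data, grid, meta):
        norm = normalize_anchor(HyperCube(data, grid, meta), n_anchor=1)
        norm.mask = mask_outliers(norm, hi=100.0, lo=-100.0)
        return norm

    def test_counts_without_masking(self, grid3):
        cubes = [self._normalized(np.ones((2, 2, 3)), grid3,
                                  CubeMeta(m, c, 18.0, 1))
                 for m, c in (("a", "AD"), ("b", "CO"))]
        m = stack_spectra(cubes)
        assert m.X.shape == (8, 3)
        assert (m.labels == "AD").sum() == 4

    def test_masked_pixels_excluded(self, grid3):
        data = np.ones((2, 2, 3))
        data[0, 0, 0] = -5.0  # out of range after unit-anchor normalization
        norm = normalize_anchor(HyperCube(data, grid3,
                                          CubeMeta("a", "AD", 3.0, 1)),
                                n_anchor=1)
        norm.mask = mask_outliers(norm)
        norm2 = self._normalized(np.ones((1, 1, 3)), grid3,
                                 CubeMeta("b", "CO", 3.0, 1))
        m = stack_spectra([norm, norm2])
        assert m.X.shape[0] == 4  # 3 retained + 1

    def test_mismatched_grids_rejected(self, grid3):
        other = WavelengthGrid([500.0, 601.0, 700.0])
        cubes = [self._normalized(np.ones((1, 1, 3)), grid3,
                                  CubeMeta("a", "AD", 3.0, 1)),
                 self._normalized(np.ones((1, 1, 3)), other,
                                  CubeMeta("b", "CO", 3.0, 1))]
        with pytest.raises(ValueError):
            stack_spectra(cubes)

    def test_row_order_follows_manifest(self, grid3, two_mouse_manifest):
        cubes = []
        for mouse, cls in (("CO01", "CO"), ("AD01", "AD")):  # reversed order
            for f in range(1, 9):
                cubes.append(self._normalized(
                    np.ones((1, 1, 3)), grid3, CubeMeta(mouse, cls, 18.0, f)))
        m = stack_spectra(cubes, two_mouse_manifest)
        assert list(m.mouse_ids[:8]) == ["AD01"] * 8  # manifest lists AD first


class TestContrastScorerEstimator:
    def test_sklearn_params_and_clone(self):
        scorer = ContrastScorer(balance_mice=True)
        assert scorer.get_params()["balance_mice"] is True
        assert clone(scorer).get_params() == scorer.get_params()

    def test_unfitted_decision_function_raises(self, rng):
        from sklearn.exceptions import NotFittedError
        with pytest.raises(NotFittedError):
            ContrastScorer().decision_function(rng.normal(size=(2, 3)))

    def test_works_inside_sklearn_pipeline(self, rng):
        from sklearn.pipeline import Pipeline
        X = rng.normal(size=(20, 6))
        y = np.array(["AD"] * 10 + ["CO"] * 10, object)
        pipe = Pipeline([("score", ContrastScorer())])
        out = pipe.fit_transform(X, y)
        np.testing.assert_allclose(out[:, 0],
                                   X @ (X[:10].mean(0) - X[10:].mean(0)),
                                   atol=1e-12)

    def test_band_count_mismatch_rejected(self, rng):
        scorer = ContrastScorer().fit(rng.normal(size=(6, 4)),
                                      ["AD"] * 3 + ["CO"] * 3)
        with pytest.raises(ValueError):
            scorer.decision_function(rng.normal(size=(2, 5)))
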