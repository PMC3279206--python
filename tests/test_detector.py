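"""Dictionary assembly, residual-ratio classification, hole filling."""

import numpy as np
import pytest
from scipy import ndimage

from mhsidetect import (ConfigurationError, ConsistencyError, DetectionMap,
                        LabelMask, SolverConfig, SpectralCube,
                        SpectralDictionary, build_dictionary, classify_cube,
                        classify_pixel, fill_holes)


def _spectra(rng, n, b=6):
    return 0.2 + 0.6 * rng.random((n, b))


class TestBuildDictionary:
    def test_shapes_and_blocks(self, rng):
        d = build_dictionary(_spectra(rng, 1, 3), _spectra(rng, 1, 3))
        assert d.atoms.shape == (3, 2)
        assert d.n_noncancerous == 1 and d.n_cancerous == 1

    def test_unit_column_norms(self, rng):
        d = build_dictionary(_spectra(rng, 4), _spectra(rng, 3))
        assert np.allclose(np.linalg.norm(d.atoms, axis=0), 1.0, atol=1e-12)

    def test_empty_class_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            build_dictionary(np.empty((0, 6)), _spectra(rng, 3))

    def test_zero_spectrum_rejected_when_normalizing(self, rng):
        normal = _spectra(rng, 2)
        normal[0] = 0.0
        with pytest.raises(ConfigurationError):
            build_dictionary(normal, _spectra(rng, 2))

    def test_within_class_permutation_leaves_scores_unchanged(self, rng):
        # residuals are subspace properties under an exact convex solver
        normal, cancer = _spectra(rng, 4), _spectra(rng, 3)
        d1 = build_dictionary(normal, cancer)
        d2 = build_dictionary(normal[[2, 0, 3, 1]], cancer[[1, 2, 0]])
        cfg = SolverConfig(method="basis_pursuit", eps=1e-8)
        for _ in range(20):
            x = 0.2 + 0.6 * rng.random(6)
            s1 = classify_pixel(x, d1, cfg)
            s2 = classify_pixel(x, d2, cfg)
            assert s1.score == pytest.approx(s2.score, abs=1e-6)


class TestClassifyPixel:
    @pytest.fixture()
    def dictionary(self, rng):
        return build_dictionary(_spectra(rng, 3), _spectra(rng, 3))

    def test_cancer_atom_labeled_cancerous(self, dictionary):
        x = dictionary.cancerous[:, 0]
        code = classify_pixel(x, dictionary, SolverConfig(eps=0.0))
        assert code.r_c < 1e-10
        assert code.score > 0
        assert code.label == "cancerous"

    def test_normal_atom_labeled_noncancerous(self, dictionary):
        x = dictionary.noncancerous[:, 1]
        code = classify_pixel(x, dictionary, SolverConfig(eps=0.0))
        assert code.score < 0
        assert code.label == "noncancerous"

    def test_tied_residuals_fall_to_noncancerous(self, rng):
        # mirrored dictionary makes both class residuals exactly equal
        atom = rng.random(4)
        atom /= np.linalg.norm(atom)
        d = SpectralDictionary(np.column_stack([atom, atom]),
                               np.array([0, 1]))
        ortho = rng.standard_normal(4)
        ortho -= (ortho @ atom) * atom
        code = classify_pixel(ortho, d, SolverConfig(eps=0.0, max_atoms=1))
        assert code.r_nc == pytest.approx(code.r_c)
        assert code.score == 0.0
        assert code.label == "noncancerous"

    def test_scores_always_finite(self, dictionary, rng):
        # exact atom matches drive a residual to 0; the floor keeps
        # the log-ratio finite
        for j in range(dictionary.atoms.shape[1]):
            code = classify_pixel(dictionary.atoms[:, j], dictionary,
                                  SolverConfig(eps=0.0))
            assert np.isfinite(code.score)

    def test_block_swap_negates_scores(self, rng):
        normal, cancer = _spectra(rng, 3), _spectra(rng, 4)
        fwd = build_dictionary(normal, cancer)
        rev = build_dictionary(cancer, normal)
        cfg = SolverConfig(method="basis_pursuit", eps=1e-8)
        for _ in range(10):
            x = 0.2 + 0.6 * rng.random(6)
            assert classify_pixel(x, fwd, cfg).score == pytest.approx(
                -classify_pixel(x, rev, cfg).score, abs=1e-6)

    def test_band_mismatch_rejected(self, dictionary):
        with pytest.raises(ConsistencyError):
            classify_pixel(np.ones(7), dictionary)


class TestClassifyCube:
    def _cube_of(self, columns, h, w):
        b = columns.shape[0]
        data = np.empty((h, w, b))
        data[:] = columns.T[np.arange(h * w) % columns.shape[1]].reshape(h, w, b)
        return SpectralCube(data, 600 + 5.0 * np.arange(b))

    def test_cube_of_cancer_atoms_all_detected(self, rng):
        d = build_dictionary(_spectra(rng, 3), _spectra(rng, 3))
        cube = self._cube_of(d.cancerous, 2, 2)
        out = classify_cube(cube, d, SolverConfig(eps=0.0))
        assert out.raw_mask.all()
        assert np.array_equal(out.raw_mask, out.final_mask)

    def test_cube_of_normal_atoms_none_detected(self, rng):
        d = build_dictionary(_spectra(rng, 3), _spectra(rng, 3))
        out = classify_cube(self._cube_of(d.noncancerous, 2, 2), d,
                            SolverConfig(eps=0.0))
        assert not out.raw_mask.any()

    def test_matches_independent_per_pixel_runs(self, rng, small_scene):
        cfg, scene = small_scene
        d = build_dictionary(_spectra(rng, 4, b=cfg.n_bands),
                             _spectra(rng, 4, b=cfg.n_bands))
        solver = SolverConfig()
        out = classify_cube(scene.true_reflectance, d, solver)
        for i, j in [(0, 0), (5, 7), (12, 12), (23, 23)]:
            expected = classify_pixel(scene.true_reflectance.data[i, j], d,
                                      solver).score
            assert out.scores[i, j] == expected
        assert np.array_equal(out.raw_mask, out.scores > 0)

    def test_mask_of_interest_limits_classification(self, rng):
        d = build_dictionary(_spectra(rng, 3), _spectra(rng, 3))
        cube = self._cube_of(d.cancerous, 3, 3)
        interest = np.full((3, 3), 255, dtype=np.uint8)
        interest[0, 0] = 1
        out = classify_cube(cube, d, SolverConfig(eps=0.0),
                            mask_of_interest=LabelMask(interest))
        assert out.raw_mask[0, 0]
        assert out.raw_mask.sum() == 1  # skipped pixels default noncancerous

    def test_raw_cube_rejected(self, rng):
        d = build_dictionary(_spectra(rng, 2), _spectra(rng, 2))
        raw = SpectralCube(np.ones((2, 2, 6)), 600 + 5.0 * np.arange(6),
                           kind="raw")
        with pytest.raises(ConsistencyError):
            classify_cube(raw, d)


def _fill_oracle(mask, connectivity):
    """Independent flood fill: background labeled from the border survives,
    every other background pixel is filled."""
    structure = ndimage.generate_binary_structure(2, 1 if connectivity == 4
                                                  else 2)
    labels, n = ndimage.label(~mask, structure=structure)
    border = set(labels[0, :]) | set(labels[-1, :]) | \
        set(labels[:, 0]) | set(labels[:, -1])
    border.discard(0)
    filled = mask.copy()
    for lab in range(1, n + 1):
        if lab not in border:
            filled[labels == lab] = True
    return filled


class TestFillHoles:
    def _map(self, mask):
        mask = np.asarray(mask, dtype=bool)
        scores = np.where(mask, 1.0, -1.0)
        return DetectionMap(scores, mask, mask.copy())

    def test_enclosed_hole_filled(self):
        ring = np.ones((5, 5), dtype=bool)
        ring[2, 2] = False
        out = fill_holes(self._map(ring))
        assert out.final_mask[2, 2]
        assert out.final_mask.all()

    def test_border_background_untouched(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        out = fill_holes(self._map(mask))
        assert np.array_equal(out.final_mask, mask)

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle_on_random_blobs(self, connectivity):
        rng = np.random.default_rng(99)
        for _ in range(50):
            blob = ndimage.binary_dilation(rng.random((16, 16)) < 0.2,
                                           iterations=2)
            out = fill_holes(self._map(blob), connectivity)
            assert np.array_equal(out.final_mask,
                                  _fill_oracle(blob, connectivity))

    def test_monotone_growth_and_border_components(self, rng):
        structure = ndimage.generate_binary_structure(2, 1)
        for _ in range(20):
            blob = rng.random((12, 12)) < 0.4
            out = fill_holes(self._map(blob))
            assert np.all(out.final_mask | ~out.raw_mask)  # raw subset final
            # border-connected background components survive filling
            before = _border_components(~blob, structure)
            after = _border_components(~out.final_mask, structure)
            assert before == after


def _border_components(bg, structure):
    labels, _ = ndimage.label(bg, structure=structure)
    border = set(labels[0, :]) | set(labels[-1, :]) | \
        set(labels[:, 0]) | set(labels[:, -1])
    border.discard(0)
    return len(border)
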