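"""Structure tensor, anisotropy measures and tissue classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nscmigrate.field import (ImageVolume, angle_2d, classify_tissue,
                              coherence_2d, fractional_anisotropy,
                              sample_field_at, structure_tensor,
                              tensor_field_from_tensors)


def _closed_form_eig2(a, b, c):
    """Independent 2x2 symmetric eigenvalues from the quadratic formula."""
    mean = 0.5 * (a + c)
    disc = np.sqrt((0.5 * (a - c)) ** 2 + b * b)
    return mean + disc, mean - disc


class TestStructureTensor:
    def test_constant_image_gives_zero_tensors(self):
        tf = structure_tensor(ImageVolume(np.full((12, 12), 3.7)), 2.0)
        assert np.all(tf.tensors == 0)
        assert np.all(tf.eigenvalues == 0)

    def test_ramp_image_gradient_axis(self):
        # I(x, y) = x: gradient (1, 0), tensor [[1,0],[0,0]]
        img = ImageVolume(np.add.outer(np.arange(16.0), np.zeros(16)))
        tf = structure_tensor(img, 0.0)
        assert np.allclose(tf.tensors[..., 0, 0], 1.0)
        assert np.allclose(tf.tensors[..., 1, 1], 0.0)
        assert np.allclose(np.abs(tf.principal_evec[..., 0]), 1.0)
        assert np.allclose(tf.eigenvalues[..., 1], 0.0)

    @pytest.mark.parametrize("theta", [0.0, 0.3, np.pi / 4, 1.2, 2.9])
    def test_rotated_ramp_aligns_with_gradient(self, theta):
        x, y = np.meshgrid(np.arange(24.0), np.arange(24.0), indexing="ij")
        img = ImageVolume(np.cos(theta) * x + np.sin(theta) * y)
        tf = structure_tensor(img, 0.0)
        g = np.array([np.cos(theta), np.sin(theta)])
        align = np.abs(tf.principal_evec @ g)
        assert np.all(align > 1 - 1e-6)

    def test_random_image_matches_closed_form_eigensolution(self, rng):
        img = ImageVolume(rng.random((8, 8)))
        tf = structure_tensor(img, 0.0)
        lam1, lam2 = _closed_form_eig2(tf.tensors[..., 0, 0],
                                       tf.tensors[..., 0, 1],
                                       tf.tensors[..., 1, 1])
        assert np.max(np.abs(tf.eigenvalues[..., 0] - lam1)) < 1e-10
        assert np.max(np.abs(tf.eigenvalues[..., 1] - np.maximum(lam2, 0))) < 1e-10

    def test_3d_eigensystem_consistency(self, rng):
        # eigenpairs must reproduce T e = lambda e, trace and determinant
        img = ImageVolume(rng.random((6, 7, 5)))
        tf = structure_tensor(img, 1.0)
        T = tf.tensors
        lam1 = tf.eigenvalues[..., 0]
        resid = np.einsum("...ij,...j->...i", T, tf.principal_evec) \
            - lam1[..., None] * tf.principal_evec
        assert np.max(np.abs(resid)) < 1e-10
        assert np.allclose(tf.eigenvalues.sum(axis=-1), np.trace(T, axis1=-2, axis2=-1))
        assert np.allclose(np.prod(np.clip(tf.eigenvalues, 0, None), axis=-1),
                           np.linalg.det(T), atol=1e-9)
        assert np.all(np.diff(tf.eigenvalues, axis=-1) <= 1e-12)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError, match="2-D or 3-D"):
            ImageVolume(np.zeros(8))
        with pytest.raises(ValueError, match="finite"):
            structure_tensor(ImageVolume(np.full((4, 4), np.nan)))
        with pytest.raises(ValueError, match="smoothing_sigma"):
            structure_tensor(ImageVolume(np.zeros((4, 4))), -1.0)


class TestAnisotropyMeasures:
    @pytest.mark.parametrize("lam, expected", [
        ((1.0, 1.0), 0.0),
        ((1.0, 0.0), 1.0),
        ((3.0, 1.0), 0.25),
        ((0.0, 0.0), 0.0),  # flat region convention
    ])
    def test_coherence_examples(self, lam, expected):
        assert coherence_2d(*lam) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("lam, expected", [
        ((1.0, 1.0, 1.0), 0.0),
        ((1.0, 0.0, 0.0), 1.0),
        ((2.0, 1.0, 1.0), 0.408248290463863),
        ((0.0, 0.0, 0.0), 0.0),
    ])
    def test_fa_examples(self, lam, expected):
        assert fractional_anisotropy(*lam) == pytest.approx(expected, abs=1e-12)

    @given(st.lists(st.floats(0, 1e6), min_size=3, max_size=3),
           st.floats(1e-6, 1e6))
    @settings(max_examples=200, deadline=None)
    def test_bounds_and_scale_invariance(self, lams, scale):
        l1, l2, l3 = sorted(lams, reverse=True)
        fa = fractional_anisotropy(l1, l2, l3)
        assert 0.0 <= fa <= 1.0
        assert 0.0 <= coherence_2d(l1, l2) <= 1.0
        assert fractional_anisotropy(scale * l1, scale * l2, scale * l3) \
            == pytest.approx(fa, abs=1e-9)

    def test_sorted_precondition_enforced(self):
        with pytest.raises(ValueError):
            coherence_2d(1.0, 2.0)
        with pytest.raises(ValueError):
            fractional_anisotropy(1.0, 2.0, 0.0)


class TestAngle:
    @pytest.mark.parametrize("evec, expected", [
        ((1.0, 0.0), 0.0),
        ((0.0, 1.0), np.pi),          # vertical convention
        ((0.0, -1.0), np.pi),
        (np.array([1.0, 1.0]) / np.sqrt(2), np.pi / 4),
    ])
    def test_examples(self, evec, expected):
        assert angle_2d(evec) == pytest.approx(expected, abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero vector"):
            angle_2d((0.0, 0.0))


class TestClassify:
    def _uniform_tensor_field(self, lam1, lam2, shape=(4, 4)):
        t = np.zeros(shape + (2, 2))
        t[..., 0, 0] = lam1
        t[..., 1, 1] = lam2
        return tensor_field_from_tensors(t)

    def test_threshold_is_inclusive(self):
        tf = self._uniform_tensor_field(3.0, 1.0)  # coherence exactly 0.25
        wm = classify_tissue(tf, epsilon_M=0.25).wm_mask
        assert np.all(wm)
        grey = classify_tissue(tf, epsilon_M=0.2500001).wm_mask
        assert not np.any(grey)

    def test_direction_is_unit_principal_evec(self):
        tf = self._uniform_tensor_field(3.0, 1.0)
        tissue = classify_tissue(tf, 0.25)
        assert np.allclose(np.abs(tissue.direction[..., 0]), 1.0)
        assert np.allclose(np.linalg.norm(tissue.direction, axis=-1), 1.0)

    def test_epsilon_out_of_range(self):
        tf = self._uniform_tensor_field(1.0, 0.0)
        with pytest.raises(ValueError):
            classify_tissue(tf, epsilon_M=1.5)


class TestSampling:
    def test_voxel_center_and_rounding(self, straight_phantom):
        _, _, tissue = straight_phantom
        i, j = 80, 80
        is_w, direction, inb = sample_field_at(tissue, (float(i), float(j)))
        assert inb and is_w == tissue.wm_mask[i, j]
        # nearest-neighbour rule: (i + 0.4, j) still reads voxel (i, j)
        is_w2, d2, _ = sample_field_at(tissue, (i + 0.4, float(j)))
        assert is_w2 == is_w
        assert np.allclose(d2, direction)

    def test_outside_grid_and_mask(self, straight_phantom):
        _, _, tissue = straight_phantom
        assert sample_field_at(tissue, (-30.0, 5.0))[2] is False
        assert sample_field_at(tissue, (2.0, 2.0))[2] is False  # corner, off-brain

    def test_linear_interp_renormalizes(self, straight_phantom):
        _, _, tissue = straight_phantom
        _, d, _ = sample_field_at(tissue, (80.3, 79.6), interp="linear")
        assert np.linalg.norm(d) == pytest.approx(1.0, abs=1e-9)
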