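"""FRC-QE per-slice scoring, the quality profile, and the two baseline metrics."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

import frcqe
from frcqe import (
    ImageStack,
    QEParams,
    dct_shannon_entropy,
    frc_curve,
    frc_qe_profile,
    frc_qe_slice,
    mean_intensity,
    relative_frc_curve,
    scoreable_z_range,
)

from conftest import seeded_image


def noise_stack(depth, shape, seed, loc=100.0, scale=20.0):
    rng = np.random.default_rng(seed)
    return ImageStack(rng.normal(loc, scale, size=(depth,) + shape))


class TestRelativeCurve:
    def test_identical_slices_give_zero_curve(self):
        img = seeded_image((24, 24), seed=1)
        stack = ImageStack(np.broadcast_to(img, (9,) + img.shape).copy())
        rel = relative_frc_curve(stack, 3, QEParams(dz_distant=3))
        np.testing.assert_allclose(rel.value[rel.defined], 0.0, atol=1e-9)
        assert rel.kind == "relative"

    def test_independent_noise_slices_near_zero(self):
        """Mutually independent noise slices: relative curve fluctuates around 0
        with per-ring amplitude set by the ring's sample count."""
        stack = noise_stack(7, (64, 64), seed=2)
        rel = relative_frc_curve(stack, 3, QEParams(dz_distant=3, block="full"))
        m = rel.defined & (rel.n_samples >= 2)
        assert np.all(np.abs(rel.value[m]) <= 6.0 / np.sqrt(rel.n_samples[m]))
        assert abs(np.mean(rel.value[m])) < 0.1

    def test_matches_hand_composed_curves(self):
        """dz_distant=2, z=2 in a 5-slice stack == adj curve minus mean of both distant."""
        stack = noise_stack(5, (32, 32), seed=3)
        params = QEParams(dz_distant=2, block="full")
        rel = relative_frc_curve(stack, 2, params)
        s = stack.voxels
        adj = frc_curve(s[2], s[3])
        lo = frc_curve(s[2], s[0])
        hi = frc_curve(s[2], s[4])
        expected = adj.value - 0.5 * (lo.value + hi.value)
        np.testing.assert_allclose(rel.value, expected, atol=1e-12)

    def test_out_of_range_z_names_valid_interval(self):
        stack = noise_stack(8, (16, 16), seed=4)
        with pytest.raises(frcqe.DepthError, match=r"valid z interval"):
            relative_frc_curve(stack, 7, QEParams(dz_distant=3))

    def test_one_sided_fallback_at_boundary(self):
        stack = noise_stack(8, (32, 32), seed=5)
        # z=0 has only the +dz distant partner under one_sided
        rel = relative_frc_curve(stack, 0, QEParams(dz_distant=3, block="full"))
        s = stack.voxels
        expected = frc_curve(s[0], s[1]).value - frc_curve(s[0], s[3]).value
        np.testing.assert_allclose(rel.value, expected, atol=1e-12)
        with pytest.raises(frcqe.DepthError):
            relative_frc_curve(stack, 0, QEParams(dz_distant=3, boundary="two_sided"))


class TestSliceScore:
    def test_identical_slices_score_zero(self):
        img = seeded_image((24, 24), seed=6)
        stack = ImageStack(np.broadcast_to(img, (9,) + img.shape).copy())
        assert frc_qe_slice(stack, 4, QEParams(dz_distant=3)) == pytest.approx(0.0, abs=1e-9)

    def test_matches_hand_smoothing_and_trapezoid(self):
        stack = noise_stack(7, (32, 32), seed=7)
        params = QEParams(dz_distant=3, smooth_window=5, block="full")
        rel = relative_frc_curve(stack, 3, params)
        v = rel.value[rel.defined]
        r = rel.radius[rel.defined]
        sm = np.empty_like(v)
        for i in range(len(v)):
            half = min(2, i, len(v) - 1 - i)
            sm[i] = v[i - half:i + half + 1].mean()
        expected = np.trapezoid(sm, r)
        assert frc_qe_slice(stack, 3, params) == pytest.approx(expected, abs=1e-12)

    def test_integrate_rule_variants_differ_consistently(self):
        stack = noise_stack(7, (32, 32), seed=8)
        scores = {rule: frc_qe_slice(stack, 3, QEParams(dz_distant=3, integrate=rule))
                  for rule in ("trapz", "mean", "clip")}
        # clipping negatives can only raise the integral
        assert scores["clip"] >= scores["trapz"]

    def test_sharp_beats_blurred_at_every_interior_slice(self):
        """Optical blur before read noise suppresses adjacent-slice high-frequency
        correlation, so the sharp stack outscores its blurred copy slice by slice.
        dz_distant is large relative to the nucleus axial extent so the distant
        normalization slices are structurally decorrelated."""
        spec = frcqe.SyntheticSpec(shape=(16, 96, 96), organoid_radius=40, n_nuclei=120,
                                   degradation_mode="well_cleared", noise_sigma=0.0, seed=3)
        clean = frcqe.generate_organoid_stack(spec).voxels
        noise = np.random.default_rng(99).normal(0, 2.0, clean.shape)
        params = QEParams(dz_distant=4)
        sharp = ImageStack(np.maximum(clean + noise, 0))
        blurred = ImageStack(np.maximum(
            np.stack([gaussian_filter(s, 3.0) for s in clean]) + noise, 0))
        for z in range(params.dz_distant, 16 - params.dz_distant):
            assert frc_qe_slice(sharp, z, params) > frc_qe_slice(blurred, z, params)

    def test_constant_stack_has_undefined_score(self):
        stack = ImageStack(np.full((7, 16, 16), 9.0))
        with pytest.raises(frcqe.UndefinedScoreError):
            frc_qe_slice(stack, 3, QEParams(dz_distant=3))


class TestProfile:
    def test_scoreable_rows_25_slices_one_sided(self):
        stack = noise_stack(25, (16, 16), seed=9)
        prof = frc_qe_profile(stack, QEParams(dz_distant=5))
        np.testing.assert_array_equal(prof.z_index, np.arange(24))

    def test_two_sided_boundary_shrinks_range(self):
        assert scoreable_z_range(25, QEParams(dz_distant=5, boundary="two_sided")) == \
            list(range(5, 19 + 1))

    def test_determinism_bit_identical(self, small_structured_stack):
        params = QEParams(dz_distant=3)
        p1 = frc_qe_profile(small_structured_stack, params)
        p2 = frc_qe_profile(small_structured_stack, params)
        assert np.array_equal(p1.frc_qe, p2.frc_qe)
        assert np.array_equal(p1.dct_entropy, p2.dct_entropy)
        assert np.array_equal(p1.mean_intensity, p2.mean_intensity)
        assert p1.params == p2.params

    def test_block_and_dz_change_absolute_scores(self, small_structured_stack):
        """Scores are parameter-dependent; comparisons require identical params."""
        base = frc_qe_profile(small_structured_stack, QEParams(dz_distant=3))
        other_block = frc_qe_profile(small_structured_stack,
                                     QEParams(dz_distant=3, block=(8, 8, 32, 32)))
        other_dz = frc_qe_profile(small_structured_stack, QEParams(dz_distant=4))
        assert not np.allclose(base.frc_qe, other_block.frc_qe)
        common = np.intersect1d(base.z_index, other_dz.z_index)
        sel = np.isin(base.z_index, common)
        sel2 = np.isin(other_dz.z_index, common)
        assert not np.allclose(base.frc_qe[sel], other_dz.frc_qe[sel2])

    def test_metric_subset_leaves_others_nan(self, small_structured_stack):
        prof = frc_qe_profile(small_structured_stack, QEParams(dz_distant=3),
                              metrics=("mean_intensity",))
        assert np.all(np.isnan(prof.frc_qe))
        assert np.all(np.isfinite(prof.mean_intensity))

    def test_too_shallow_stack_is_explicit_error(self):
        stack = noise_stack(3, (16, 16), seed=10)
        with pytest.raises(frcqe.DepthError, match=r"slices required"):
            frc_qe_profile(stack, QEParams(dz_distant=10))

    def test_dataframe_view_matches_arrays(self, small_structured_stack):
        prof = frc_qe_profile(small_structured_stack, QEParams(dz_distant=3))
        df = prof.to_dataframe()
        assert list(df.columns) == ["z_index", "frc_qe", "dct_entropy",
                                    "mean_intensity", "n_undefined_rings"]
        np.testing.assert_array_equal(df["frc_qe"].to_numpy(), prof.frc_qe)


@pytest.mark.parametrize("bad,field", [
    (dict(dz_adjacent=0), "dz_adjacent"),
    (dict(dz_distant=1), "dz_distant"),
    (dict(ring_width=0.0), "ring_width"),
    (dict(smooth_window=4), "smooth_window"),
    (dict(integrate="median"), "integrate"),
    (dict(boundary="none"), "boundary"),
    (dict(block=(0, 0, 1, 1)), "block"),
    (dict(block=(10, 10, 20, 20)), "block"),
])
def test_param_validation_names_offending_field(bad, field):
    with pytest.raises(frcqe.InvalidParameterError, match=field):
        QEParams(**bad).validate(slice_shape=(16, 16))


class TestBaselines:
    def test_entropy_constant_image_is_zero(self):
        assert dct_shannon_entropy(np.full((8, 8), 7.0)) == 0.0
        assert dct_shannon_entropy(np.zeros((8, 8))) == 0.0

    def test_entropy_bounded_by_log2_pixels(self):
        img = seeded_image((16, 12), seed=11)
        assert 0.0 <= dct_shannon_entropy(img) <= np.log2(16 * 12)

    def test_entropy_scale_invariant(self):
        img = seeded_image((16, 16), seed=12)
        assert dct_shannon_entropy(img) == pytest.approx(
            dct_shannon_entropy(3.5 * img), abs=1e-9)

    def test_entropy_drops_under_blur(self):
        img = seeded_image((64, 64), seed=13)
        assert dct_shannon_entropy(img) > dct_shannon_entropy(gaussian_filter(img, 3.0))

    def test_mean_intensity_values(self):
        assert mean_intensity(np.full((8, 8), 4.25)) == 4.25
        checker = np.indices((8, 8)).sum(axis=0) % 2
        assert mean_intensity(checker) == 0.5
        img = seeded_image((9, 13), seed=14)
        total = 0.0
        for row in img:
            for v in row:
                total += v
        assert mean_intensity(img) == pytest.approx(total / img.size, abs=1e-12)
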