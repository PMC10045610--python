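"""Reference checks for bilinear sampling, deformable conv and RoI pooling.

Every operator is compared against a brute-force twin that evaluates the
defining sums literally (double loops over taps and integer positions).
"""

import numpy as np
import pytest

from lesionnas.autodiff import Tensor
from lesionnas.deform_ops import (
    BinOffsetField,
    ConvLayer,
    ConvWeights,
    FeatureMap,
    OffsetField,
    RoIBox,
    SamplingGrid,
    bilinear_kernel,
    bilinear_sample,
    deformable_conv,
    deformable_roi_pool,
    predict_offsets,
    roi_average_pool,
    standard_conv,
)

from conftest import finite_difference_gradcheck

GRID3 = SamplingGrid.centered(3)
CENTER_TAP = SamplingGrid(((0, 0),))


def brute_force_sample(values: np.ndarray, p) -> np.ndarray:
    """Literal evaluation of x(p) = sum_q G(q, p) x(q) over ALL integer q."""
    C, H, W = values.shape
    out = np.zeros(C)
    for r in range(H):
        for c in range(W):
            out += bilinear_kernel((r, c), p) * values[:, r, c]
    return out


def brute_force_deform_conv(values, kernel, taps, offsets):
    """Triple loop over output positions, taps and channels."""
    O, C, K = kernel.shape[0], kernel.shape[1], len(taps)
    _, H, W = values.shape
    out = np.zeros((O, H, W))
    flat = kernel.reshape(O, C, K)
    for r in range(H):
        for c in range(W):
            for k, (dr, dc) in enumerate(taps):
                p = (r + dr + offsets[2 * k, r, c], c + dc + offsets[2 * k + 1, r, c])
                sample = brute_force_sample(values, p)
                for o in range(O):
                    out[o, r, c] += flat[o, :, k] @ sample
    return out


def brute_force_roi_pool(values, roi, bins_h, bins_w, bin_offsets=None):
    C = values.shape[0]
    out = np.zeros((C, bins_h, bins_w))
    ye = roi.y_min + (roi.y_max - roi.y_min) * np.arange(bins_h + 1) / bins_h
    xe = roi.x_min + (roi.x_max - roi.x_min) * np.arange(bins_w + 1) / bins_w
    for i in range(bins_h):
        for j in range(bins_w):
            off = (0.0, 0.0) if bin_offsets is None else tuple(bin_offsets[:, i, j])
            rows = np.arange(np.ceil(ye[i]), np.ceil(ye[i + 1]))
            cols = np.arange(np.ceil(xe[j]), np.ceil(xe[j + 1]))
            if rows.size and cols.size:
                acc = np.zeros(C)
                for r in rows:
                    for c in cols:
                        acc += brute_force_sample(values, (r + off[0], c + off[1]))
                out[:, i, j] = acc / (rows.size * cols.size)
            else:
                center = ((ye[i] + ye[i + 1]) / 2 + off[0], (xe[j] + xe[j + 1]) / 2 + off[1])
                out[:, i, j] = brute_force_sample(values, center)
    return out


class TestBilinearKernel:
    @pytest.mark.parametrize(
        "q,p,expected",
        [
            ((2, 2), (2.0, 2.0), 1.0),
            ((0, 0), (0.0, 1.0), 0.0),
            ((0, 0), (0.25, 0.5), 0.375),
        ],
    )
    def test_printed_values(self, q, p, expected):
        assert bilinear_kernel(q, p) == pytest.approx(expected)

    def test_compact_support_and_partition_of_unity(self, rng):
        p = rng.uniform(1.0, 2.0, size=2)
        total = 0.0
        for r in range(-2, 6):
            for c in range(-2, 6):
                w = bilinear_kernel((r, c), p)
                if max(abs(r - p[0]), abs(c - p[1])) >= 1:
                    assert w == 0.0
                total += w
        assert total == pytest.approx(1.0)


class TestBilinearSample:
    @pytest.mark.parametrize(
        "p,expected", [((0.5, 0.5), 2.5), ((1, 1), 4.0), ((0, 0.5), 1.5)]
    )
    def test_two_by_two_map(self, p, expected):
        fm = FeatureMap([[[1.0, 2.0], [3.0, 4.0]]])
        assert bilinear_sample(fm, p)[0] == pytest.approx(expected)

    def test_matches_brute_force_everywhere(self, rng):
        values = rng.normal(size=(3, 5, 4))
        fm = FeatureMap(values)
        for _ in range(20):
            p = rng.uniform(0, [4, 3])
            assert np.allclose(bilinear_sample(fm, p), brute_force_sample(values, p))

    def test_rejects_non_finite_position(self):
        with pytest.raises(ValueError):
            bilinear_sample(FeatureMap(np.zeros((1, 2, 2))), (np.nan, 0))


class TestStandardConv:
    def test_constant_map_all_ones_kernel(self):
        fm = FeatureMap(np.full((1, 5, 5), 3.0))
        out = standard_conv(fm, ConvWeights(np.ones((1, 1, 3, 3))), GRID3)
        assert out.array[0, 2, 2] == pytest.approx(27.0)

    def test_identity_kernel(self, rng):
        kernel = np.zeros((1, 1, 3, 3))
        kernel[0, 0, 1, 1] = 1.0
        fm = FeatureMap(rng.normal(size=(1, 6, 6)))
        out = standard_conv(fm, ConvWeights(kernel), GRID3)
        assert np.allclose(out.array, fm.array)

    def test_matches_double_loop_oracle(self, rng):
        values = rng.normal(size=(1, 5, 5))
        kernel = rng.normal(size=(1, 1, 3, 3))
        out = standard_conv(FeatureMap(values), ConvWeights(kernel), GRID3)
        oracle = brute_force_deform_conv(
            values, kernel, GRID3.taps, np.zeros((18, 5, 5))
        )
        assert np.allclose(out.array, oracle)

    def test_channel_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            standard_conv(
                FeatureMap(rng.normal(size=(2, 4, 4))),
                ConvWeights(rng.normal(size=(1, 3, 3, 3))),
                GRID3,
            )

    def test_linear_in_input(self, rng):
        values = rng.normal(size=(2, 4, 4))
        w = ConvWeights(rng.normal(size=(2, 2, 3, 3)))
        a = standard_conv(FeatureMap(values), w, GRID3).array
        b = standard_conv(FeatureMap(2.5 * values), w, GRID3).array
        assert np.allclose(b, 2.5 * a)


class TestDeformableConv:
    def test_zero_offsets_reduce_to_standard(self, rng):
        for _ in range(10):
            values = rng.normal(size=(2, 5, 5))
            w = ConvWeights(rng.normal(size=(3, 2, 3, 3)), rng.normal(size=3))
            off = OffsetField(np.zeros((18, 5, 5)))
            a = standard_conv(FeatureMap(values), w, GRID3).array
            b = deformable_conv(FeatureMap(values), w, GRID3, off).array
            assert np.allclose(a, b, rtol=1e-6)

    def test_half_cell_offset_equals_bilinear_sample(self):
        fm = FeatureMap([[[1.0, 2.0], [3.0, 4.0]]])
        w = ConvWeights(np.ones((1, 1, 1, 1)))
        off = OffsetField(np.full((2, 2, 2), 0.5))
        out = deformable_conv(fm, w, CENTER_TAP, off)
        assert out.array[0, 0, 0] == pytest.approx(2.5)

    def test_integer_offset_shifts_with_zero_fill(self):
        fm = FeatureMap([[[1.0, 2.0], [3.0, 4.0]]])
        w = ConvWeights(np.ones((1, 1, 1, 1)))
        offsets = np.zeros((2, 2, 2))
        offsets[0] = 1.0  # one row down in source coordinates
        out = deformable_conv(fm, w, CENTER_TAP, OffsetField(offsets))
        assert np.allclose(out.array[0], [[3.0, 4.0], [0.0, 0.0]])

    def test_matches_brute_force_oracle(self, rng):
        values = rng.normal(size=(3, 4, 4))
        kernel = rng.normal(size=(2, 3, 3, 3))
        offsets = rng.uniform(-0.8, 0.8, size=(18, 4, 4))
        out = deformable_conv(
            FeatureMap(values), ConvWeights(kernel), GRID3, OffsetField(offsets)
        )
        oracle = brute_force_deform_conv(values, kernel, GRID3.taps, offsets)
        assert np.allclose(out.array, oracle)

    def test_offset_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            deformable_conv(
                FeatureMap(rng.normal(size=(1, 4, 4))),
                ConvWeights(rng.normal(size=(1, 1, 3, 3))),
                GRID3,
                OffsetField(np.zeros((18, 3, 3))),
            )


class TestPredictOffsets:
    def test_zero_weights_give_plain_convolution(self, rng):
        fm = FeatureMap(rng.normal(size=(2, 5, 5)))
        ow = ConvWeights(np.zeros((18, 2, 3, 3)), np.zeros(18))
        off = predict_offsets(fm, ow)
        assert np.all(off.offsets.data == 0)
        w = ConvWeights(rng.normal(size=(2, 2, 3, 3)))
        assert np.allclose(
            deformable_conv(fm, w, GRID3, off).array,
            standard_conv(fm, w, GRID3).array,
        )

    def test_output_shape_and_linearity(self, rng):
        fm = FeatureMap(rng.normal(size=(3, 6, 7)))
        kernel = rng.normal(size=(18, 3, 3, 3))
        off1 = predict_offsets(fm, ConvWeights(kernel)).offsets.data
        off2 = predict_offsets(fm, ConvWeights(2 * kernel)).offsets.data
        assert off1.shape == (18, 6, 7)
        assert np.allclose(off2, 2 * off1)

    def test_odd_channel_count_rejected(self, rng):
        with pytest.raises(ValueError):
            predict_offsets(
                FeatureMap(rng.normal(size=(1, 4, 4))),
                ConvWeights(rng.normal(size=(17, 1, 3, 3))),
            )


class TestRoIPooling:
    def test_constant_map_pools_to_constant(self):
        fm = FeatureMap(np.full((2, 6, 6), 1.7))
        out = roi_average_pool(fm, RoIBox(0.5, 0.5, 5.2, 4.8), 3, 2)
        assert np.allclose(out.array, 1.7)
        assert np.all(out.counts >= 1)

    @pytest.mark.parametrize(
        "bins,expected",
        [((1, 1), [[2.5]]), ((1, 2), [[2.0, 3.0]])],
    )
    def test_enumerated_means(self, bins, expected):
        fm = FeatureMap([[[1.0, 2.0], [3.0, 4.0]]])
        out = roi_average_pool(fm, RoIBox(0, 0, 2, 2), *bins)
        assert np.allclose(out.array[0], expected)

    def test_degenerate_roi_raises(self):
        with pytest.raises(ValueError):
            RoIBox(1.0, 0.0, 1.0, 2.0)

    def test_matches_brute_force_oracle(self, rng):
        values = rng.normal(size=(2, 8, 8))
        roi = RoIBox(0.7, 1.2, 6.3, 7.9)
        out = roi_average_pool(FeatureMap(values), roi, 3, 3)
        assert np.allclose(out.array, brute_force_roi_pool(values, roi, 3, 3))


class TestDeformableRoIPooling:
    def test_zero_offsets_reproduce_plain_pooling(self, rng):
        values = rng.normal(size=(2, 6, 6))
        roi = RoIBox(0.3, 0.9, 5.1, 5.7)
        plain = roi_average_pool(FeatureMap(values), roi, 2, 3)
        deform = deformable_roi_pool(
            FeatureMap(values), roi, 2, 3, BinOffsetField(np.zeros((2, 2, 3)))
        )
        assert np.allclose(plain.array, deform.array)

    def test_row_ramp_shift_adds_one(self):
        # map whose row r has constant value r: shifting a bin one row
        # down in source coordinates raises its mean by exactly 1
        values = np.tile(np.arange(6.0)[None, :, None], (1, 1, 6))
        offsets = np.zeros((2, 2, 2))
        offsets[0, 0, 0] = 1.0
        roi = RoIBox(0, 0, 6, 4)
        plain = roi_average_pool(FeatureMap(values), roi, 2, 2)
        shifted = deformable_roi_pool(
            FeatureMap(values), roi, 2, 2, BinOffsetField(offsets)
        )
        delta = shifted.array - plain.array
        assert delta[0, 0, 0] == pytest.approx(1.0)
        assert np.allclose(delta.ravel()[1:], 0.0)

    def test_fractional_offset_matches_bilinear_oracle(self, rng):
        values = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        offsets = np.zeros((2, 1, 1))
        offsets[0] = 0.5
        out = deformable_roi_pool(
            FeatureMap(values), RoIBox(0, 0, 2, 2), 1, 1, BinOffsetField(offsets)
        )
        oracle = brute_force_roi_pool(
            values, RoIBox(0, 0, 2, 2), 1, 1, bin_offsets=offsets
        )
        assert np.allclose(out.array, oracle)

    def test_matches_brute_force_on_random_inputs(self, rng):
        values = rng.normal(size=(3, 8, 8))
        roi = RoIBox(1.1, 0.4, 7.6, 6.9)
        offsets = rng.uniform(-0.7, 0.7, size=(2, 2, 2))
        out = deformable_roi_pool(
            FeatureMap(values), roi, 2, 2, BinOffsetField(offsets)
        )
        oracle = brute_force_roi_pool(values, roi, 2, 2, bin_offsets=offsets)
        assert np.allclose(out.array, oracle)

    def test_offset_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            deformable_roi_pool(
                FeatureMap(rng.normal(size=(1, 4, 4))),
                RoIBox(0, 0, 3, 3),
                2,
                2,
                BinOffsetField(np.zeros((2, 3, 2))),
            )


class TestDifferentiability:
    def test_deformable_conv_gradcheck(self, rng):
        x = Tensor(rng.normal(size=(1, 3, 3)), requires_grad=True)
        layer_w = Tensor(rng.normal(size=(1, 1, 3, 3)), requires_grad=True)
        off = Tensor(rng.uniform(0.1, 0.4, size=(18, 3, 3)), requires_grad=True)
        proj = rng.normal(size=(1, 3, 3))

        def f():
            out = deformable_conv(
                FeatureMap(x), ConvWeights(layer_w), GRID3, OffsetField(off)
            )
            return (out.values * Tensor(proj)).sum()

        finite_difference_gradcheck(f, [x, layer_w, off])

    def test_deformable_roi_pool_gradcheck(self, rng):
        x = Tensor(rng.normal(size=(1, 3, 3)), requires_grad=True)
        off = Tensor(rng.uniform(0.1, 0.3, size=(2, 2, 2)), requires_grad=True)
        proj = rng.normal(size=(1, 2, 2))

        def f():
            out = deformable_roi_pool(
                FeatureMap(x), RoIBox(0.2, 0.3, 2.5, 2.6), 2, 2, BinOffsetField(off)
            )
            return (out.pooled * Tensor(proj)).sum()

        finite_difference_gradcheck(f, [x, off])


def test_conv_layer_zero_offset_start(rng):
    """A freshly initialised deformable layer equals its plain-conv twin."""
    layer = ConvLayer(2, 3, rng, deformable=True)
    fm = FeatureMap(rng.normal(size=(2, 6, 6)))
    deform_out = layer(fm).array
    plain_out = standard_conv(fm, layer.weights, layer.grid).array
    assert np.allclose(deform_out, plain_out)


def test_deformable_offset_predictor_flag_matches_plain_at_init(rng):
    """Either offset-predictor flavour starts in the plain-conv regime."""
    fm = FeatureMap(rng.normal(size=(2, 5, 5)))
    plain = ConvLayer(2, 2, rng, deformable=True)
    fancy = ConvLayer(2, 2, rng, deformable=True,
                      deformable_offset_predictor=True)
    fancy.weights.kernel.data[:] = plain.weights.kernel.data
    fancy.weights.bias.data[:] = plain.weights.bias.data
    assert np.allclose(plain(fm).array, fancy(fm).array)
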