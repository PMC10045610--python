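"""Deformable convolution and deformable RoI pooling.

Reference implementations of the sampling primitives used throughout the
detector.  The convention everywhere is (row, col) 0-based coordinates,
half-open boxes in continuous coordinates, and (drow, dcol) offsets.  A
standard convolution samples its input on a regular integer grid of taps
R; the deformable variant adds a learned fractional displacement to every
tap at every output position, resolved by bilinear interpolation

    x(p) = sum_q G(q, p) x(q),   G(q, p) = g(q_r, p_r) g(q_c, p_c),
    g(a, b) = max(0, 1 - |a - b|),

so only the (at most four) integer neighbours of p contribute.  Reads
outside the map contribute zero, consistent with zero-padded convolution.

Deformable RoI pooling averages the integer-position samples inside each
of bins_h x bins_w equal sub-rectangles of an RoI, after shifting every
bin's sample positions by that bin's learned (drow, dcol) offset.  An
empty bin (no integer positions) falls back to one bilinear sample at the
bin centre, which keeps the output finite and differentiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import (
    Tensor,
    as_tensor,
    bilinear_gather,
    conv2d,
    deform_conv2d,
    index_rows,
)

__all__ = [
    "FeatureMap",
    "SamplingGrid",
    "OffsetField",
    "ConvWeights",
    "RoIBox",
    "BinGrid",
    "BinOffsetField",
    "bilinear_kernel",
    "bilinear_sample",
    "standard_conv",
    "deformable_conv",
    "predict_offsets",
    "roi_average_pool",
    "deformable_roi_pool",
    "ConvLayer",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class FeatureMap:
    """A [channels, height, width] map plus its stride w.r.t. the input image."""

    values: Tensor
    stride: int = 1

    def __post_init__(self):
        if not isinstance(self.values, Tensor):
            self.values = as_tensor(np.asarray(self.values, dtype=np.float64))
        if self.values.ndim != 3:
            raise ValueError("FeatureMap expects [channels, height, width]")
        if self.height < 1 or self.width < 1:
            raise ValueError("FeatureMap spatial dims must be >= 1")

    @property
    def array(self) -> np.ndarray:
        return self.values.data

    @property
    def channels(self) -> int:
        return self.values.shape[0]

    @property
    def height(self) -> int:
        return self.values.shape[1]

    @property
    def width(self) -> int:
        return self.values.shape[2]


@dataclass(frozen=True)
class SamplingGrid:
    """Ordered integer (row, col) tap displacements of a convolution."""

    taps: tuple

    def __post_init__(self):
        taps = tuple((int(r), int(c)) for r, c in self.taps)
        if len(set(taps)) != len(taps):
            raise ValueError("sampling grid taps must be distinct")
        object.__setattr__(self, "taps", taps)

    def __len__(self) -> int:
        return len(self.taps)

    @classmethod
    def centered(cls, size: int = 3) -> "SamplingGrid":
        """The regular k x k grid R, e.g. {(-1,-1), ..., (1,1)} for k=3."""
        half = size // 2
        return cls(
            tuple(
                (r, c)
                for r in range(-half, size - half)
                for c in range(-half, size - half)
            )
        )


@dataclass
class OffsetField:
    """Per-tap (drow, dcol) displacements, shape [2K, height, width]."""

    offsets: Tensor

    def __post_init__(self):
        if not isinstance(self.offsets, Tensor):
            self.offsets = as_tensor(np.asarray(self.offsets, dtype=np.float64))
        if self.offsets.ndim != 3 or self.offsets.shape[0] % 2:
            raise ValueError("OffsetField expects [2K, height, width]")


@dataclass
class ConvWeights:
    """Kernel [out, in, k_h, k_w] and bias [out] of one convolution."""

    kernel: Tensor
    bias: Tensor | None = None

    def __post_init__(self):
        if not isinstance(self.kernel, Tensor):
            self.kernel = as_tensor(np.asarray(self.kernel, dtype=np.float64))
        if self.kernel.ndim != 4:
            raise ValueError("kernel must be [out, in, k_h, k_w]")
        if self.bias is not None and not isinstance(self.bias, Tensor):
            self.bias = as_tensor(np.asarray(self.bias, dtype=np.float64))

    @property
    def out_channels(self) -> int:
        return self.kernel.shape[0]

    @property
    def in_channels(self) -> int:
        return self.kernel.shape[1]

    def flat(self) -> Tensor:
        """Kernel reshaped to [out, in, K] with taps in row-major order."""
        o, c, kh, kw = self.kernel.shape
        return self.kernel.reshape(o, c, kh * kw)


@dataclass(frozen=True)
class RoIBox:
    """A region of interest in feature-map cell coordinates (half-open)."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self):
        vals = (self.x_min, self.y_min, self.x_max, self.y_max)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("RoIBox coordinates must be finite")
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError("degenerate RoIBox")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min


@dataclass
class BinGrid:
    """Pooled values [channels, bins_h, bins_w] and per-bin sample counts."""

    pooled: Tensor
    counts: np.ndarray

    @property
    def array(self) -> np.ndarray:
        return self.pooled.data


@dataclass
class BinOffsetField:
    """One (drow, dcol) displacement per pooling bin: shape [2, bins_h, bins_w]."""

    offsets: Tensor

    def __post_init__(self):
        if not isinstance(self.offsets, Tensor):
            self.offsets = as_tensor(np.asarray(self.offsets, dtype=np.float64))
        if self.offsets.ndim != 3 or self.offsets.shape[0] != 2:
            raise ValueError("BinOffsetField expects [2, bins_h, bins_w]")
        if not np.all(np.isfinite(self.offsets.data)):
            raise ValueError("bin offsets must be finite")


# ---------------------------------------------------------------------------
# Bilinear interpolation kernel
# ---------------------------------------------------------------------------


def bilinear_kernel(q, p) -> float:
    """G(q, p) = g(q_r, p_r) g(q_c, p_c) with g(a, b) = max(0, 1 - |a - b|)."""
    qr, qc = float(q[0]), float(q[1])
    pr, pc = float(p[0]), float(p[1])
    g = lambda a, b: max(0.0, 1.0 - abs(a - b))
    return g(qr, pr) * g(qc, pc)


def bilinear_sample(fmap: FeatureMap, p) -> np.ndarray:
    """Per-channel bilinear sample of the map at fractional (row, col) p.

    Out-of-map integer neighbours contribute zero.
    """
    p = np.asarray(p, dtype=np.float64)
    if not np.all(np.isfinite(p)):
        raise ValueError("non-finite sampling position")
    out = bilinear_gather(fmap.values.detach(), p.reshape(1, 2))
    return out.data[:, 0].copy()


# ---------------------------------------------------------------------------
# Convolutions
# ---------------------------------------------------------------------------


def standard_conv(
    fmap: FeatureMap, weights: ConvWeights, grid: SamplingGrid | None = None
) -> FeatureMap:
    """'Same'-padded stride-1 convolution: y(p0) = sum_n w(p_n) x(p0 + p_n)."""
    if grid is None:
        grid = SamplingGrid.centered(weights.kernel.shape[2])
    _check_grid(weights, grid)
    if weights.in_channels != fmap.channels:
        raise ValueError(
            f"channel mismatch: map {fmap.channels}, weights {weights.in_channels}"
        )
    out = conv2d(fmap.values, weights.flat(), weights.bias, grid.taps)
    return FeatureMap(out, stride=fmap.stride)


def deformable_conv(
    fmap: FeatureMap,
    weights: ConvWeights,
    grid: SamplingGrid,
    offsets: OffsetField,
) -> FeatureMap:
    """Convolution with per-position learned tap displacements.

    y(p0) = sum_n w(p_n) x(p0 + p_n + dp_n), fractional positions resolved
    bilinearly.  With a zero offset field this reduces exactly to
    :func:`standard_conv`.
    """
    _check_grid(weights, grid)
    if weights.in_channels != fmap.channels:
        raise ValueError(
            f"channel mismatch: map {fmap.channels}, weights {weights.in_channels}"
        )
    expected = (2 * len(grid), fmap.height, fmap.width)
    if offsets.offsets.shape != expected:
        raise ValueError(
            f"offset field shape {offsets.offsets.shape}, expected {expected}"
        )
    out = deform_conv2d(
        fmap.values, weights.flat(), weights.bias, grid.taps, offsets.offsets
    )
    return FeatureMap(out, stride=fmap.stride)


def predict_offsets(fmap: FeatureMap, offset_weights: ConvWeights) -> OffsetField:
    """Predict a tap offset field from the feature map itself.

    A standard convolution with 2K output channels; with zero weights the
    offsets are zero and the paired deformable convolution degenerates to
    a plain one, which is also how training is initialised.
    """
    if offset_weights.out_channels % 2:
        raise ValueError("offset predictor needs an even number of output channels")
    grid = SamplingGrid.centered(offset_weights.kernel.shape[2])
    out = standard_conv(fmap, offset_weights, grid)
    return OffsetField(out.values)


def _check_grid(weights: ConvWeights, grid: SamplingGrid) -> None:
    kh, kw = weights.kernel.shape[2], weights.kernel.shape[3]
    if kh * kw != len(grid):
        raise ValueError(f"kernel has {kh * kw} taps but grid has {len(grid)}")


# ---------------------------------------------------------------------------
# RoI pooling
# ---------------------------------------------------------------------------


def _bin_edges(lo: float, hi: float, nbins: int) -> np.ndarray:
    return lo + (hi - lo) * np.arange(nbins + 1) / nbins


def _bin_positions(roi: RoIBox, bins_h: int, bins_w: int):
    """Integer sample positions and bin ids inside each sub-rectangle.

    Returns (positions [M,2] float, bin_ids [M], counts [bins_h, bins_w]).
    Empty bins contribute one position at the bin centre.
    """
    ye = _bin_edges(roi.y_min, roi.y_max, bins_h)
    xe = _bin_edges(roi.x_min, roi.x_max, bins_w)
    positions, bin_ids = [], []
    counts = np.zeros((bins_h, bins_w), dtype=np.int64)
    for i in range(bins_h):
        rows = np.arange(np.ceil(ye[i]), np.ceil(ye[i + 1]), dtype=np.float64)
        for j in range(bins_w):
            cols = np.arange(np.ceil(xe[j]), np.ceil(xe[j + 1]), dtype=np.float64)
            bid = i * bins_w + j
            if rows.size and cols.size:
                rr, cc = np.meshgrid(rows, cols, indexing="ij")
                pts = np.stack([rr.ravel(), cc.ravel()], axis=1)
            else:  # empty bin: one bilinear sample at the bin centre
                pts = np.array(
                    [[(ye[i] + ye[i + 1]) / 2.0, (xe[j] + xe[j + 1]) / 2.0]]
                )
            positions.append(pts)
            bin_ids.append(np.full(len(pts), bid, dtype=np.int64))
            counts[i, j] = max(1, rows.size * cols.size)
    return np.concatenate(positions), np.concatenate(bin_ids), counts


def _validate_roi(fmap: FeatureMap, roi: RoIBox, bins_h: int, bins_w: int) -> None:
    if bins_h < 1 or bins_w < 1:
        raise ValueError("bins_h and bins_w must be >= 1")
    if (
        roi.x_max <= 0
        or roi.y_max <= 0
        or roi.x_min >= fmap.width
        or roi.y_min >= fmap.height
    ):
        raise ValueError("RoI does not intersect the feature map")


def roi_average_pool(
    fmap: FeatureMap, roi: RoIBox, bins_h: int, bins_w: int
) -> BinGrid:
    """Average pooling over a bins_h x bins_w partition of the RoI.

    y(i, j) = sum_{p in bin(i,j)} x(p0 + p) / n_ij over integer positions.
    """
    _validate_roi(fmap, roi, bins_h, bins_w)
    pos, bin_ids, counts = _bin_positions(roi, bins_h, bins_w)
    return _pool(fmap, pos, bin_ids, counts, bins_h, bins_w)


def deformable_roi_pool(
    fmap: FeatureMap,
    roi: RoIBox,
    bins_h: int,
    bins_w: int,
    bin_offsets: BinOffsetField,
) -> BinGrid:
    """RoI pooling with each bin's sample positions shifted by its dp_ij.

    y(i, j) = sum_{p in bin(i,j)} x(p0 + p + dp_ij) / n_ij, resolved
    bilinearly.  Zero offsets reproduce :func:`roi_average_pool` exactly.
    """
    _validate_roi(fmap, roi, bins_h, bins_w)
    if bin_offsets.offsets.shape != (2, bins_h, bins_w):
        raise ValueError(
            f"bin offset shape {bin_offsets.offsets.shape}, "
            f"expected {(2, bins_h, bins_w)}"
        )
    pos, bin_ids, counts = _bin_positions(roi, bins_h, bins_w)
    # per-position offset = that position's bin offset; differentiable
    off_rc = bin_offsets.offsets.reshape(2, bins_h * bins_w).transpose(1, 0)
    shifted = as_tensor(pos) + index_rows(off_rc, bin_ids)
    return _pool(fmap, shifted, bin_ids, counts, bins_h, bins_w)


def _pool(fmap, positions, bin_ids, counts, bins_h, bins_w) -> BinGrid:
    gathered = bilinear_gather(fmap.values, positions)  # [C, M]
    nbins = bins_h * bins_w
    averaging = np.zeros((len(bin_ids), nbins))
    averaging[np.arange(len(bin_ids)), bin_ids] = 1.0 / counts.ravel()[bin_ids]
    pooled = (gathered @ averaging).reshape(fmap.channels, bins_h, bins_w)
    return BinGrid(pooled=pooled, counts=counts)


# ---------------------------------------------------------------------------
# Trainable convolution layer (regular or deformable)
# ---------------------------------------------------------------------------


class ConvLayer:
    """A trainable 'same' convolution, optionally deformable.

    Deformable layers own a zero-initialised offset-predictor convolution,
    so training starts in the plain-convolution regime and learns where to
    displace the taps.  The predictor is a plain convolution by default;
    with ``deformable_offset_predictor=True`` it is itself a deformable
    convolution carrying a fixed zero offset field.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        rng: np.random.Generator,
        kernel_size: int = 3,
        deformable: bool = False,
        bias: bool = True,
        deformable_offset_predictor: bool = False,
    ):
        k = kernel_size
        scale = np.sqrt(2.0 / (in_channels * k * k))
        self.grid = SamplingGrid.centered(k)
        self.weights = ConvWeights(
            kernel=Tensor(
                rng.normal(0.0, scale, size=(out_channels, in_channels, k, k)),
                requires_grad=True,
            ),
            bias=Tensor(np.zeros(out_channels), requires_grad=True) if bias else None,
        )
        self.deformable = deformable
        self.deformable_offset_predictor = deformable_offset_predictor
        if deformable:
            ktaps = 2 * len(self.grid)
            self.offset_weights = ConvWeights(
                kernel=Tensor(
                    np.zeros((ktaps, in_channels, k, k)), requires_grad=True
                ),
                bias=Tensor(np.zeros(ktaps), requires_grad=True),
            )
        else:
            self.offset_weights = None

    def __call__(self, fmap: FeatureMap) -> FeatureMap:
        if not self.deformable:
            return standard_conv(fmap, self.weights, self.grid)
        if self.deformable_offset_predictor:
            zero = OffsetField(
                np.zeros((2 * len(self.grid), fmap.height, fmap.width))
            )
            raw = deformable_conv(fmap, self.offset_weights, self.grid, zero)
            offsets = OffsetField(raw.values)
        else:
            offsets = predict_offsets(fmap, self.offset_weights)
        return deformable_conv(fmap, self.weights, self.grid, offsets)

    def parameters(self) -> list[Tensor]:
        params = [self.weights.kernel]
        if self.weights.bias is not None:
            params.append(self.weights.bias)
        if self.offset_weights is not None:
            params.extend([self.offset_weights.kernel, self.offset_weights.bias])
        return params

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())
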