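"""The six information paths of the searchable FPN neck.

Each path maps a 4-level feature pyramid (levels 2..5 at strides 4/8/16/32,
shared channel width C) to a pyramid of identical shape:

* top-down      F_i = W_i (*) (U(F_{i+1}) + P_i), built i = 5..2 — the
  classical FPN flow of semantics into high resolution levels;
* bottom-up     F_i = W_i (*) (D(F_{i-1}) + P_i), built i = 2..5;
* scale-balanced F_i = U(W_1 (*) P_{i+1}) + W_0 (*) P_i + D(W_-1 (*) P_{i-1}),
  the pyramid convolution coupling each level to its neighbours (the
  lower-level term is downsampled so shapes agree; missing neighbours at
  the boundary levels are dropped);
* fuse-split    two-step fusion of the upper pair (alpha_s = P_4 + U(P_5))
  and lower pair (alpha_l = D(P_2) + P_3) followed by cross-scale mixing
  through channel concatenation and a split back to four levels;
* null          the additive identity (zero pyramid), which lets the
  architecture search prune redundant edges;
* skip          the identity mapping, parameter-free.

U is nearest-neighbour x2 upsampling and D is 2x2 max pooling — both
parameter-free, so a path's parameter count is exactly its convolution
content.  Per-level convolutions are deformable on levels 3-5 and regular
on level 2; the convolutions the scale-balanced and fuse-split paths share
across levels are deformable.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .autodiff import Tensor, concatenate, maxpool2, upsample2
from .deform_ops import ConvLayer, FeatureMap

__all__ = [
    "LEVELS",
    "LEVEL_STRIDES",
    "FeaturePyramid",
    "PathKind",
    "PathParams",
    "upsample",
    "downsample",
    "top_down_path",
    "bottom_up_path",
    "scale_balanced_path",
    "fuse_split_path",
    "null_path",
    "skip_path",
    "apply_path",
]

LEVELS = (2, 3, 4, 5)
LEVEL_STRIDES = {2: 4, 3: 8, 4: 16, 5: 32}


@dataclass
class FeaturePyramid:
    """Levels P2..P5 at strides 4/8/16/32 with a shared channel width."""

    levels: dict

    def __post_init__(self):
        if sorted(self.levels) != list(LEVELS):
            raise ValueError(f"pyramid must have levels {LEVELS}")
        chans = {fm.channels for fm in self.levels.values()}
        if len(chans) != 1:
            raise ValueError(f"levels disagree on channel width: {chans}")
        for i in LEVELS[:-1]:
            a, b = self.levels[i], self.levels[i + 1]
            if a.height != 2 * b.height or a.width != 2 * b.width:
                raise ValueError(
                    f"level {i} ({a.height}x{a.width}) is not 2x level "
                    f"{i + 1} ({b.height}x{b.width})"
                )

    def __getitem__(self, i: int) -> FeatureMap:
        return self.levels[i]

    @property
    def channels(self) -> int:
        return self.levels[2].channels

    def shapes(self) -> dict:
        return {i: self.levels[i].values.shape for i in LEVELS}

    def zeros_like(self) -> "FeaturePyramid":
        return FeaturePyramid(
            {
                i: FeatureMap(np.zeros(fm.values.shape), stride=fm.stride)
                for i, fm in self.levels.items()
            }
        )

    def __add__(self, other: "FeaturePyramid") -> "FeaturePyramid":
        return FeaturePyramid(
            {
                i: FeatureMap(
                    self.levels[i].values + other.levels[i].values,
                    stride=self.levels[i].stride,
                )
                for i in LEVELS
            }
        )

    @classmethod
    def from_arrays(cls, arrays: dict) -> "FeaturePyramid":
        return cls(
            {
                i: FeatureMap(arrays[i], stride=LEVEL_STRIDES[i])
                for i in LEVELS
            }
        )


class PathKind(Enum):
    TOP_DOWN = "top_down"
    BOTTOM_UP = "bottom_up"
    SCALE_BALANCED = "scale_balanced"
    FUSE_SPLIT = "fuse_split"
    NULL = "null"
    SKIP = "skip"


PARAMETERIZED_KINDS = (
    PathKind.TOP_DOWN,
    PathKind.BOTTOM_UP,
    PathKind.SCALE_BALANCED,
    PathKind.FUSE_SPLIT,
)


class PathParams:
    """The convolution weights of one parameterized information path."""

    def __init__(self, kind: PathKind, channels: int, rng: np.random.Generator):
        if kind not in PARAMETERIZED_KINDS:
            raise ValueError(f"{kind} carries no parameters")
        self.kind = kind
        self.channels = channels
        if kind in (PathKind.TOP_DOWN, PathKind.BOTTOM_UP):
            # one conv per level; deformable on 3..5, regular on level 2
            self.convs = {
                i: ConvLayer(channels, channels, rng, deformable=(i != 2))
                for i in LEVELS
            }
        elif kind is PathKind.SCALE_BALANCED:
            self.convs = {
                name: ConvLayer(channels, channels, rng, deformable=True)
                for name in ("up", "same", "down")
            }
        else:  # FUSE_SPLIT: 2C -> C fusion convs
            self.convs = {
                name: ConvLayer(2 * channels, channels, rng, deformable=True)
                for name in ("small", "large")
            }

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for conv in self.convs.values():
            out.extend(conv.parameters())
        return out

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------


def upsample(fmap: FeatureMap) -> FeatureMap:
    """Nearest-neighbour x2 upsampling."""
    return FeatureMap(upsample2(fmap.values), stride=max(1, fmap.stride // 2))


def downsample(fmap: FeatureMap) -> FeatureMap:
    """2x2 max pooling with stride 2; spatial dims must be even."""
    return FeatureMap(maxpool2(fmap.values), stride=fmap.stride * 2)


def _fm(values, level: int) -> FeatureMap:
    return FeatureMap(values, stride=LEVEL_STRIDES[level])


# ---------------------------------------------------------------------------
# Parameterized paths
# ---------------------------------------------------------------------------


def _check_channels(pyr: FeaturePyramid, params: PathParams) -> None:
    if pyr.channels != params.channels:
        raise ValueError(
            f"pyramid has {pyr.channels} channels, params expect {params.channels}"
        )


def top_down_path(pyr: FeaturePyramid, params: PathParams) -> FeaturePyramid:
    """F_i = W_i (*) (U(F_{i+1}) + P_i), seeded by F_5 = W_5 (*) P_5."""
    _check_channels(pyr, params)
    out: dict = {}
    out[5] = params.convs[5](pyr[5])
    for i in (4, 3, 2):
        summed = _fm(upsample(out[i + 1]).values + pyr[i].values, i)
        out[i] = params.convs[i](summed)
    return FeaturePyramid(out)


def bottom_up_path(pyr: FeaturePyramid, params: PathParams) -> FeaturePyramid:
    """F_i = W_i (*) (D(F_{i-1}) + P_i), seeded by F_2 = W_2 (*) P_2."""
    _check_channels(pyr, params)
    out: dict = {}
    out[2] = params.convs[2](pyr[2])
    for i in (3, 4, 5):
        summed = _fm(downsample(out[i - 1]).values + pyr[i].values, i)
        out[i] = params.convs[i](summed)
    return FeaturePyramid(out)


def scale_balanced_path(pyr: FeaturePyramid, params: PathParams) -> FeaturePyramid:
    """F_i = U(W_up (*) P_{i+1}) + W_same (*) P_i + D(W_down (*) P_{i-1}).

    The three convolutions are shared across levels; missing neighbours at
    levels 2 and 5 drop their term.
    """
    _check_channels(pyr, params)
    out: dict = {}
    for i in LEVELS:
        acc = params.convs["same"](pyr[i]).values
        if i + 1 in pyr.levels:
            acc = acc + upsample(params.convs["up"](pyr[i + 1])).values
        if i - 1 in pyr.levels:
            acc = acc + downsample(params.convs["down"](pyr[i - 1])).values
        out[i] = _fm(acc, i)
    return FeaturePyramid(out)


def fuse_split_path(pyr: FeaturePyramid, params: PathParams) -> FeaturePyramid:
    """Two-step fuse of the upper/lower level pairs, then split to 4 levels.

    alpha_s = P_4 + U(P_5) (small scale), alpha_l = D(P_2) + P_3 (large
    scale); each fusion conv sees the channel concatenation of the two
    resolution-aligned aggregates, and the four outputs are resampled
    copies of the fused maps.
    """
    _check_channels(pyr, params)
    alpha_s = _fm(pyr[4].values + upsample(pyr[5]).values, 4)
    alpha_l = _fm(downsample(pyr[2]).values + pyr[3].values, 3)
    cat_s = _fm(
        concatenate([alpha_s.values, downsample(alpha_l).values], axis=0), 4
    )
    cat_l = _fm(concatenate([upsample(alpha_s).values, alpha_l.values], axis=0), 3)
    beta_s = params.convs["small"](cat_s)
    beta_l = params.convs["large"](cat_l)
    return FeaturePyramid(
        {
            2: _fm(upsample(beta_l).values, 2),
            3: _fm(beta_l.values, 3),
            4: _fm(beta_s.values, 4),
            5: _fm(downsample(beta_s).values, 5),
        }
    )


# ---------------------------------------------------------------------------
# Parameter-free paths and dispatch
# ---------------------------------------------------------------------------


def null_path(pyr: FeaturePyramid) -> FeaturePyramid:
    """The additive identity: a zero pyramid of the same shape."""
    return pyr.zeros_like()


def skip_path(pyr: FeaturePyramid) -> FeaturePyramid:
    """The identity mapping; carries no parameters."""
    return FeaturePyramid(dict(pyr.levels))


_PARAM_PATHS = {
    PathKind.TOP_DOWN: top_down_path,
    PathKind.BOTTOM_UP: bottom_up_path,
    PathKind.SCALE_BALANCED: scale_balanced_path,
    PathKind.FUSE_SPLIT: fuse_split_path,
}


def apply_path(
    kind: PathKind, pyr: FeaturePyramid, params: PathParams | None = None
) -> FeaturePyramid:
    """Dispatch a pyramid through the information path of the given kind."""
    if kind in _PARAM_PATHS:
        if params is None:
            raise ValueError(f"{kind} requires parameters")
        if params.kind is not kind:
            raise ValueError(f"params are for {params.kind}, not {kind}")
        return _PARAM_PATHS[kind](pyr, params)
    if params is not None:
        raise ValueError(f"{kind} carries no parameters")
    return null_path(pyr) if kind is PathKind.NULL else skip_path(pyr)
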