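"""Two-stage lesion detector with a deformable backbone and searched neck.

Assembly, in forward order: a convolutional backbone (a small 4-stage CNN
for desk-scale work, or a ResNet-50-shaped variant) whose stages 3-5 use
deformable convolutions; 1x1 lateral projections to a 4-level feature
pyramid; the searchable neck (a supernet DAG of information paths) whose
output is superimposed element-wise back onto the projected backbone
pyramid; a region proposal network (3 scales x 3 aspect ratios per
level); deformable RoI pooling to a 7x7 grid, with per-bin offsets
predicted from a plainly pooled copy of the RoI; and a fully connected
head producing class scores and box deltas.

The total training objective is

    L = sum(L_cls + L_loc) + mu * L1,

where L_cls is cross-entropy (RPN objectness and head classification),
L_loc is smooth-L1 on box deltas of positive matches (both stages), and
L1 is the mean absolute value of the regularised weight set (the neck by
default), weighted by mu = 0.11.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
import numpy as np
import yaml

from .autodiff import (
    SGD,
    Tensor,
    conv2d,
    smooth_l1,
    softmax_cross_entropy,
)
from .deform_ops import (
    BinOffsetField,
    ConvLayer,
    FeatureMap,
    RoIBox,
    SamplingGrid,
    deformable_roi_pool,
    roi_average_pool,
)
from .fpn_paths import LEVELS, LEVEL_STRIDES, FeaturePyramid
from .supernet import SubnetCode, SupernetDAG, forward_subnet
from . import eval_metrics, synthetic_data

__all__ = [
    "DetectorConfig",
    "DetectionRecord",
    "LossBreakdown",
    "Detector",
    "build_detector",
    "compute_loss",
    "train",
    "nms",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class DetectorConfig:
    backbone: str = "tiny"  # "tiny" | "resnet50"
    backbone_channels: int = 16  # tiny backbone width
    deformable_stages: tuple = (3, 4, 5)
    fpn_channels: int = 112
    head_channels: int = 112
    fc_dim: int = 1024
    roi_bins: tuple = (7, 7)
    n_nodes: int = 5
    mu: float = 0.11
    lr: float = 0.001
    batch_size: int = 4
    epochs: int = 30
    num_classes: int = 1  # foreground classes (background is implicit)
    l1_scope: str = "neck"  # "neck" | "all"
    anchor_scales: tuple = (4.0, 5.04, 6.35)  # x stride
    anchor_ratios: tuple = (0.5, 1.0, 2.0)
    rpn_pos_iou: float = 0.7
    rpn_neg_iou: float = 0.3
    rpn_batch: int = 32
    pre_nms_proposals: int = 200
    post_nms_proposals: int = 20
    roi_pos_iou: float = 0.45  # fg cutoff; accepts near-miss proposals
    roi_batch: int = 24
    gt_jitter: int = 2  # jittered gt copies appended to training proposals
    loc_beta: float = 1.0 / 9.0  # smooth-L1 transition (Faster-RCNN RPN value)
    seed: int = 0

    def __post_init__(self):
        if self.backbone not in ("tiny", "resnet50"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.l1_scope not in ("neck", "all"):
            raise ValueError(f"unknown l1_scope {self.l1_scope!r}")
        for name in ("fpn_channels", "head_channels", "fc_dim", "n_nodes",
                     "lr", "batch_size", "epochs", "num_classes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def tiny(cls, **overrides) -> "DetectorConfig":
        """A desk-scale configuration that trains on one CPU in minutes."""
        defaults = dict(
            backbone="tiny",
            backbone_channels=16,
            fpn_channels=16,
            head_channels=16,
            fc_dim=128,
            n_nodes=1,
            # smaller anchors: desk-scale images carry 6-18 px lesions
            anchor_scales=(2.0, 3.17, 5.04),
        )
        defaults.update(overrides)
        return cls(**defaults)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "DetectorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("deformable_stages", "roi_bins", "anchor_scales", "anchor_ratios"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class DetectionRecord:
    """One predicted box in image pixels, with confidence and class label."""

    box: tuple  # (x_min, y_min, x_max, y_max)
    score: float
    label: int = 1

    def __post_init__(self):
        x0, y0, x1, y1 = self.box
        if not (x0 < x1 and y0 < y1):
            raise ValueError(f"degenerate detection box {self.box}")


@dataclass
class LossBreakdown:
    """The decomposed training objective: total = l_cls + l_loc + mu*l1_reg."""

    l_cls: float
    l_loc: float
    l1_reg: float
    mu: float
    total: float
    total_tensor: Tensor | None = None


def compute_loss(
    cls_terms, loc_terms, mu: float, l1_params, term_scale: float = 1.0,
    loc_beta: float = 1.0 / 9.0,
) -> LossBreakdown:
    """Assemble the detector objective from matched predictions.

    ``cls_terms``: list of (logits Tensor [N,K], integer labels [N]);
    ``loc_terms``: list of (predicted deltas Tensor, target deltas array);
    ``l1_params``: the weight tensors under L1 regularisation (their mean
    absolute value is the penalty).  Terms are summed across stages and
    images, each weighted by ``term_scale`` (1/batch for a batch mean).
    ``loc_beta`` is the smooth-L1 transition point; the small default
    keeps the loss in its linear regime for all but near-exact deltas.
    """
    l_cls_t = Tensor(0.0)
    for logits, labels in cls_terms:
        l_cls_t = l_cls_t + term_scale * softmax_cross_entropy(logits, labels)
    l_loc_t = Tensor(0.0)
    for pred, target in loc_terms:
        l_loc_t = l_loc_t + term_scale * smooth_l1(pred, target, beta=loc_beta)
    l1_params = list(l1_params)
    count = sum(p.data.size for p in l1_params)
    if count:
        acc = Tensor(0.0)
        for p in l1_params:
            acc = acc + p.abs().sum()
        l1_t = acc / count
    else:
        l1_t = Tensor(0.0)
    total_t = l_cls_t + l_loc_t + mu * l1_t
    l_cls, l_loc, l1 = l_cls_t.item(), l_loc_t.item(), l1_t.item()
    return LossBreakdown(
        l_cls=l_cls,
        l_loc=l_loc,
        l1_reg=l1,
        mu=mu,
        total=l_cls + l_loc + mu * l1,
        total_tensor=total_t,
    )


# ---------------------------------------------------------------------------
# Box arithmetic (numpy, non-differentiable side of the two-stage pipeline)
# ---------------------------------------------------------------------------


def box_iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of two [N,4] / [M,4] corner-box arrays."""
    if len(a) == 0 or len(b) == 0:
        return np.zeros((len(a), len(b)))
    ix = np.maximum(
        0.0,
        np.minimum(a[:, None, 2], b[None, :, 2])
        - np.maximum(a[:, None, 0], b[None, :, 0]),
    )
    iy = np.maximum(
        0.0,
        np.minimum(a[:, None, 3], b[None, :, 3])
        - np.maximum(a[:, None, 1], b[None, :, 1]),
    )
    inter = ix * iy
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    return inter / (area_a[:, None] + area_b[None, :] - inter)


def encode_boxes(anchors: np.ndarray, gts: np.ndarray) -> np.ndarray:
    """Standard (dx, dy, dw, dh) regression targets of gts w.r.t. anchors."""
    aw, ah = anchors[:, 2] - anchors[:, 0], anchors[:, 3] - anchors[:, 1]
    ax, ay = anchors[:, 0] + aw / 2, anchors[:, 1] + ah / 2
    gw, gh = gts[:, 2] - gts[:, 0], gts[:, 3] - gts[:, 1]
    gx, gy = gts[:, 0] + gw / 2, gts[:, 1] + gh / 2
    return np.stack(
        [(gx - ax) / aw, (gy - ay) / ah, np.log(gw / aw), np.log(gh / ah)], axis=1
    )


def decode_boxes(anchors: np.ndarray, deltas: np.ndarray) -> np.ndarray:
    """Invert :func:`encode_boxes`; log-scale deltas are clamped to +-4."""
    aw, ah = anchors[:, 2] - anchors[:, 0], anchors[:, 3] - anchors[:, 1]
    ax, ay = anchors[:, 0] + aw / 2, anchors[:, 1] + ah / 2
    d = np.clip(deltas, -4.0, 4.0)
    cx, cy = ax + d[:, 0] * aw, ay + d[:, 1] * ah
    w, h = aw * np.exp(d[:, 2]), ah * np.exp(d[:, 3])
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float) -> list:
    """Greedy non-maximum suppression; returns kept indices, score order."""
    order = np.argsort(-scores, kind="stable")
    keep: list[int] = []
    while len(order):
        i = order[0]
        keep.append(int(i))
        if len(order) == 1:
            break
        rest = order[1:]
        ious = box_iou_matrix(boxes[i : i + 1], boxes[rest])[0]
        order = rest[ious <= iou_threshold]
    return keep


# ---------------------------------------------------------------------------
# Small trainable building blocks
# ---------------------------------------------------------------------------


class Linear:
    def __init__(self, n_in: int, n_out: int, rng, zero_init: bool = False):
        scale = 0.0 if zero_init else np.sqrt(2.0 / n_in)
        self.w = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b

    def parameters(self):
        return [self.w, self.b]


class StridedConv:
    """Plain 'same' convolution with an output stride (used for downsizing)."""

    def __init__(self, n_in: int, n_out: int, rng, stride: int = 2, kernel: int = 3):
        scale = np.sqrt(2.0 / (n_in * kernel * kernel))
        self.taps = SamplingGrid.centered(kernel).taps
        self.w = Tensor(
            rng.normal(0.0, scale, size=(n_out, n_in, kernel * kernel)),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(n_out), requires_grad=True)
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, self.taps, stride=self.stride)

    def parameters(self):
        return [self.w, self.b]


class TinyBackbone:
    """4-stage small CNN producing feature maps at strides 4/8/16/32.

    Stages 3-5 optionally use deformable convolutions, mirroring the
    full-scale backbone's conv3-conv5 placement.
    """

    def __init__(self, cfg: DetectorConfig, rng):
        c = cfg.backbone_channels
        self.stem = StridedConv(1, c, rng, stride=2)
        self.stages = {}
        for stage in (2, 3, 4, 5):
            deform = stage in cfg.deformable_stages
            self.stages[stage] = (
                StridedConv(c, c, rng, stride=2),
                ConvLayer(c, c, rng, deformable=deform),
            )
        self.out_channels = {i: c for i in LEVELS}

    def __call__(self, image: Tensor) -> dict:
        x = self.stem(image).leaky_relu()
        feats = {}
        for stage in (2, 3, 4, 5):
            down, refine = self.stages[stage]
            x = down(x).leaky_relu()
            x = refine(FeatureMap(x, stride=2 ** stage)).values.leaky_relu()
            feats[stage] = x
        return feats

    def parameters(self):
        out = self.stem.parameters()
        for down, refine in self.stages.values():
            out += down.parameters() + refine.parameters()
        return out


class Bottleneck:
    """1x1 -> 3x3 (optionally deformable) -> 1x1 residual block."""

    def __init__(self, n_in, mid, n_out, rng, stride=1, deformable=False):
        self.reduce = StridedConv(n_in, mid, rng, stride=stride, kernel=1)
        self.conv3 = ConvLayer(mid, mid, rng, deformable=deformable)
        self.expand = StridedConv(mid, n_out, rng, stride=1, kernel=1)
        self.project = (
            StridedConv(n_in, n_out, rng, stride=stride, kernel=1)
            if (stride != 1 or n_in != n_out)
            else None
        )
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        y = self.reduce(x).leaky_relu()
        y = self.conv3(FeatureMap(y)).values.leaky_relu()
        y = self.expand(y)
        skip = self.project(x) if self.project is not None else x
        return (y + skip).leaky_relu()

    def parameters(self):
        out = self.reduce.parameters() + self.conv3.parameters() + self.expand.parameters()
        if self.project is not None:
            out += self.project.parameters()
        return out


class ResNet50Backbone:
    """ResNet-50-shaped backbone (bottleneck counts 3/4/6/3), random init.

    Reproduces the full-scale architecture's stage layout and channel
    widths, with deformable 3x3 convolutions in the configured stages.
    """

    BLOCKS = {2: 3, 3: 4, 4: 6, 5: 3}
    MID = {2: 64, 3: 128, 4: 256, 5: 512}
    OUT = {2: 256, 3: 512, 4: 1024, 5: 2048}

    def __init__(self, cfg: DetectorConfig, rng):
        self.stem = StridedConv(1, 64, rng, stride=2, kernel=7)
        self.stages = {}
        n_in = 64
        for stage in (2, 3, 4, 5):
            deform = stage in cfg.deformable_stages
            blocks = []
            for b in range(self.BLOCKS[stage]):
                stride = 2 if (b == 0 and stage != 2) else 1
                blocks.append(
                    Bottleneck(
                        n_in, self.MID[stage], self.OUT[stage], rng,
                        stride=stride, deformable=deform,
                    )
                )
                n_in = self.OUT[stage]
            self.stages[stage] = blocks
        self.out_channels = dict(self.OUT)

    def __call__(self, image: Tensor) -> dict:
        from .autodiff import maxpool2

        x = maxpool2(self.stem(image).leaky_relu())  # stride 4
        feats = {}
        for stage in (2, 3, 4, 5):
            for block in self.stages[stage]:
                x = block(x)
            feats[stage] = x
        return feats

    def parameters(self):
        out = self.stem.parameters()
        for blocks in self.stages.values():
            for b in blocks:
                out += b.parameters()
        return out


# ---------------------------------------------------------------------------
# The detector
# ---------------------------------------------------------------------------


class Detector:
    """Backbone + searched neck + RPN + deformable-RoI head."""

    def __init__(self, config: DetectorConfig, code: SubnetCode | str = "supernet"):
        self.config = config
        rng = np.random.default_rng(config.seed)
        if config.backbone == "tiny":
            self.backbone = TinyBackbone(config, rng)
        else:
            self.backbone = ResNet50Backbone(config, rng)
        self.laterals = {
            i: StridedConv(
                self.backbone.out_channels[i], config.fpn_channels, rng,
                stride=1, kernel=1,
            )
            for i in LEVELS
        }
        self.dag = SupernetDAG(config.n_nodes, config.fpn_channels, rng)
        if code != "supernet" and not isinstance(code, SubnetCode):
            raise ValueError("code must be a SubnetCode or the string 'supernet'")
        if isinstance(code, SubnetCode):
            if set(code.edges) != set(self.dag.edges):
                raise ValueError("subnet code does not match the supernet edge set")
            if not code.is_valid():
                raise ValueError("invalid subnet code")
        self.code = code
        # RPN, shared across levels
        a = len(config.anchor_scales) * len(config.anchor_ratios)
        self.n_anchors = a
        self.rpn_conv = StridedConv(config.fpn_channels, config.head_channels, rng, stride=1)
        self.rpn_cls = StridedConv(config.head_channels, 2 * a, rng, stride=1, kernel=1)
        self.rpn_reg = StridedConv(config.head_channels, 4 * a, rng, stride=1, kernel=1)
        # RoI head
        bh, bw = config.roi_bins
        pooled_dim = config.fpn_channels * bh * bw
        self.roi_offset_fc = Linear(pooled_dim, 2 * bh * bw, rng, zero_init=True)
        self.fc1 = Linear(pooled_dim, config.fc_dim, rng)
        self.cls_fc = Linear(config.fc_dim, config.num_classes + 1, rng)
        self.reg_fc = Linear(config.fc_dim, 4, rng)

    # -- parameter bookkeeping -------------------------------------------

    def neck_parameters(self, code: SubnetCode | None = None):
        code = self._resolve_code(code, allow_none=True)
        out = []
        for lat in self.laterals.values():
            out += lat.parameters()
        out += self.dag.parameters(code)
        return out

    def parameters(self, code: SubnetCode | None = None):
        out = self.backbone.parameters()
        out += self.neck_parameters(code)
        out += self.rpn_conv.parameters() + self.rpn_cls.parameters()
        out += self.rpn_reg.parameters()
        out += self.roi_offset_fc.parameters() + self.fc1.parameters()
        out += self.cls_fc.parameters() + self.reg_fc.parameters()
        return out

    def _resolve_code(self, code, allow_none=False):
        if code is None:
            if isinstance(self.code, SubnetCode):
                return self.code
            if allow_none:
                return None
            raise ValueError("supernet-mode detector needs an explicit code")
        return code

    # -- forward ----------------------------------------------------------

    def pyramid(self, image: np.ndarray, code: SubnetCode | None = None) -> FeaturePyramid:
        """Backbone features, lateral projection, neck and superposition."""
        code = self._resolve_code(code)
        img = np.asarray(image, dtype=np.float64)
        if img.ndim == 2:
            img = img[None]
        h, w = img.shape[1:]
        if h % 32 or w % 32:
            raise ValueError(f"image sides must be divisible by 32, got {h}x{w}")
        feats = self.backbone(Tensor(img))
        base = FeaturePyramid(
            {
                i: FeatureMap(self.laterals[i](feats[i]), stride=LEVEL_STRIDES[i])
                for i in LEVELS
            }
        )
        neck_out = forward_subnet(self.dag, code, base)
        return base + neck_out  # residual superposition onto backbone features

    def _rpn_maps(self, pyr: FeaturePyramid):
        cls_maps, reg_maps = {}, {}
        for i in LEVELS:
            h = self.rpn_conv(pyr[i].values).leaky_relu()
            cls_maps[i] = self.rpn_cls(h)
            reg_maps[i] = self.rpn_reg(h)
        return cls_maps, reg_maps

    def level_anchors(self, level: int, shape) -> np.ndarray:
        """Anchor corner boxes for one pyramid level, [h*w*A, 4] pixels."""
        stride = LEVEL_STRIDES[level]
        hh, ww = shape
        sizes = np.array(self.config.anchor_scales) * stride
        ratios = np.array(self.config.anchor_ratios)
        heights = (sizes[:, None] * np.sqrt(ratios)[None]).ravel()
        widths = (sizes[:, None] / np.sqrt(ratios)[None]).ravel()
        cy = (np.arange(hh) + 0.5) * stride
        cx = (np.arange(ww) + 0.5) * stride
        cyg, cxg = np.meshgrid(cy, cx, indexing="ij")
        boxes = np.empty((hh, ww, len(heights), 4))
        boxes[..., 0] = cxg[..., None] - widths / 2
        boxes[..., 1] = cyg[..., None] - heights / 2
        boxes[..., 2] = cxg[..., None] + widths / 2
        boxes[..., 3] = cyg[..., None] + heights / 2
        return boxes.reshape(-1, 4)

    def _flatten_rpn(self, cls_maps, reg_maps):
        """Per-level maps -> pooled [N,2] logits, [N,4] deltas, [N,4] anchors."""
        logits, deltas, anchors = [], [], []
        a = self.n_anchors
        for i in LEVELS:
            cm, rm = cls_maps[i], reg_maps[i]
            hh, ww = cm.shape[1], cm.shape[2]
            logits.append(
                cm.reshape(a, 2, hh, ww).transpose(2, 3, 0, 1).reshape(-1, 2)
            )
            deltas.append(
                rm.reshape(a, 4, hh, ww).transpose(2, 3, 0, 1).reshape(-1, 4)
            )
            anchors.append(self.level_anchors(i, (hh, ww)))
        from .autodiff import concatenate

        return (
            concatenate(logits, axis=0),
            concatenate(deltas, axis=0),
            np.concatenate(anchors, axis=0),
        )

    def _proposals(self, logits, deltas, anchors, image_shape, gt_boxes=None):
        """Decode, clip, NMS.  Non-differentiable (numpy on detached data)."""
        cfg = self.config
        scores = logits.data
        fg = 1.0 / (1.0 + np.exp(np.clip(scores[:, 0] - scores[:, 1], -60, 60)))
        order = np.argsort(-fg, kind="stable")[: cfg.pre_nms_proposals]
        boxes = decode_boxes(anchors[order], deltas.data[order])
        h, w = image_shape
        boxes[:, 0::2] = np.clip(boxes[:, 0::2], 0, w)
        boxes[:, 1::2] = np.clip(boxes[:, 1::2], 0, h)
        ok = (boxes[:, 2] - boxes[:, 0] > 1) & (boxes[:, 3] - boxes[:, 1] > 1)
        boxes, sc = boxes[ok], fg[order][ok]
        keep = nms(boxes, sc, 0.7)[: cfg.post_nms_proposals]
        proposals = boxes[keep]
        if gt_boxes is not None and len(gt_boxes):
            proposals = np.concatenate([proposals, np.asarray(gt_boxes, dtype=np.float64)])
        return proposals

    def _roi_level(self, box) -> int:
        area = max((box[2] - box[0]) * (box[3] - box[1]), 1.0)
        k = 2 + int(np.floor(np.log2(np.sqrt(area) / 16.0)))
        return int(np.clip(k, 2, 5))

    def _roi_features(self, pyr: FeaturePyramid, rois: np.ndarray) -> Tensor:
        """Deformable RoI pooling + flatten, one row per RoI."""
        from .autodiff import concatenate

        bh, bw = self.config.roi_bins
        rows = []
        for box in rois:
            level = self._roi_level(box)
            stride = LEVEL_STRIDES[level]
            fm = pyr[level]
            roi = RoIBox(
                x_min=box[0] / stride,
                y_min=box[1] / stride,
                x_max=max(box[2] / stride, box[0] / stride + 1e-3),
                y_max=max(box[3] / stride, box[1] / stride + 1e-3),
            )
            plain = roi_average_pool(fm, roi, bh, bw).pooled.reshape(1, -1)
            offsets = self.roi_offset_fc(plain).reshape(2, bh, bw)
            pooled = deformable_roi_pool(
                fm, roi, bh, bw, BinOffsetField(offsets)
            ).pooled
            rows.append(pooled.reshape(1, -1))
        return concatenate(rows, axis=0)

    def _head(self, features: Tensor):
        hidden = self.fc1(features).leaky_relu()
        return self.cls_fc(hidden), self.reg_fc(hidden)

    # -- training losses --------------------------------------------------

    def _rpn_targets(self, anchors, gt_boxes, rng):
        cfg = self.config
        n = len(anchors)
        labels = np.full(n, -1, dtype=np.int64)  # -1 = ignored
        if len(gt_boxes):
            gts = np.asarray(gt_boxes, dtype=np.float64)
            ious = box_iou_matrix(anchors, gts)
            best = ious.max(axis=1)
            argbest = ious.argmax(axis=1)
            labels[best < cfg.rpn_neg_iou] = 0
            labels[best >= cfg.rpn_pos_iou] = 1
            # every gt keeps its best anchor positive
            forced = ious.argmax(axis=0)
            labels[forced] = 1
            argbest[forced] = np.arange(len(gts))
        else:
            labels[:] = 0
            argbest = np.zeros(n, dtype=np.int64)
        pos = np.flatnonzero(labels == 1)
        neg = np.flatnonzero(labels == 0)
        n_pos = min(len(pos), cfg.rpn_batch // 2)
        pos = rng.permutation(pos)[:n_pos]
        neg = rng.permutation(neg)[: cfg.rpn_batch - n_pos]
        sampled = np.concatenate([pos, neg])
        cls_labels = (labels[sampled] == 1).astype(np.int64)
        if len(pos) and len(gt_boxes):
            gts = np.asarray(gt_boxes, dtype=np.float64)
            loc_targets = encode_boxes(anchors[pos], gts[argbest[pos]])
        else:
            loc_targets = np.zeros((0, 4))
        return sampled, cls_labels, pos, loc_targets

    def _roi_targets(self, rois, gt_boxes, rng):
        cfg = self.config
        if len(gt_boxes) == 0:
            labels = np.zeros(len(rois), dtype=np.int64)
            sel = rng.permutation(len(rois))[: cfg.roi_batch]
            return sel, labels[sel], np.empty(0, dtype=np.int64), np.zeros((0, 4))
        gts = np.asarray(gt_boxes, dtype=np.float64)
        ious = box_iou_matrix(rois, gts)
        best, argbest = ious.max(axis=1), ious.argmax(axis=1)
        fg = np.flatnonzero(best >= cfg.roi_pos_iou)
        bg = np.flatnonzero(best < cfg.roi_pos_iou)
        n_fg = min(len(fg), cfg.roi_batch // 2)
        fg = rng.permutation(fg)[:n_fg]
        bg = rng.permutation(bg)[: cfg.roi_batch - n_fg]
        sel = np.concatenate([fg, bg])
        labels = np.concatenate(
            [np.ones(len(fg), dtype=np.int64), np.zeros(len(bg), dtype=np.int64)]
        )
        loc_targets = encode_boxes(rois[fg], gts[argbest[fg]]) if len(fg) else np.zeros((0, 4))
        return sel, labels, np.arange(len(fg)), loc_targets

    def loss_on_image(self, image, gt_boxes, rng, code=None) -> tuple:
        """Classification/localisation terms for one image (both stages)."""
        from .autodiff import index_rows

        code = self._resolve_code(code)
        img = np.asarray(image, dtype=np.float64)
        shape = img.shape[-2:]
        pyr = self.pyramid(img, code)
        logits, deltas, anchors = self._flatten_rpn(*self._rpn_maps(pyr))
        sampled, cls_labels, pos, loc_targets = self._rpn_targets(
            anchors, gt_boxes, rng
        )
        cls_terms = [(index_rows(logits, sampled), cls_labels)]
        loc_terms = []
        if len(pos):
            loc_terms.append((index_rows(deltas, pos), loc_targets))
        rois = self._proposals(logits, deltas, anchors, shape, gt_boxes=gt_boxes)
        if len(gt_boxes) and self.config.gt_jitter:
            # jittered gt copies teach the head to accept and refine the
            # imperfect proposals it will actually see at inference
            gts = np.asarray(gt_boxes, dtype=np.float64)
            w = (gts[:, 2] - gts[:, 0])[:, None]
            h = (gts[:, 3] - gts[:, 1])[:, None]
            for _ in range(self.config.gt_jitter):
                noise = rng.uniform(-0.15, 0.15, size=(len(gts), 4))
                jit = gts + noise * np.concatenate([w, h, w, h], axis=1)
                jit[:, 0::2] = np.clip(jit[:, 0::2], 0, shape[1])
                jit[:, 1::2] = np.clip(jit[:, 1::2], 0, shape[0])
                ok = (jit[:, 2] - jit[:, 0] > 1) & (jit[:, 3] - jit[:, 1] > 1)
                rois = np.concatenate([rois, jit[ok]])
        sel, roi_labels, fg_rows, roi_loc = self._roi_targets(rois, gt_boxes, rng)
        if len(sel):
            feats = self._roi_features(pyr, rois[sel])
            cls_logits, reg = self._head(feats)
            cls_terms.append((cls_logits, roi_labels))
            if len(fg_rows):
                loc_terms.append((index_rows(reg, fg_rows), roi_loc))
        return cls_terms, loc_terms

    def loss_on_batch(self, batch, code=None, rng=None) -> LossBreakdown:
        """Mean two-stage loss over (image, gt boxes) pairs plus L1 penalty."""
        if not batch:
            raise ValueError("empty batch")
        code = self._resolve_code(code)
        rng = rng if rng is not None else np.random.default_rng(0)
        cls_terms, loc_terms = [], []
        for image, gt_boxes in batch:
            ct, lt = self.loss_on_image(image, gt_boxes, rng, code)
            cls_terms += ct
            loc_terms += lt
        l1_params = (
            self.neck_parameters(code)
            if self.config.l1_scope == "neck"
            else self.parameters(code)
        )
        return compute_loss(
            cls_terms,
            loc_terms,
            self.config.mu,
            l1_params,
            term_scale=1.0 / len(batch),
            loc_beta=self.config.loc_beta,
        )

    # -- inference --------------------------------------------------------

    def infer(
        self,
        image,
        score_threshold: float = 0.5,
        nms_iou: float = 0.5,
        code=None,
    ) -> list:
        """Detect lesions in one image; boxes clipped, NMS-deduplicated."""
        code = self._resolve_code(code)
        img = np.asarray(image, dtype=np.float64)
        shape = img.shape[-2:]
        pyr = self.pyramid(img, code)
        logits, deltas, anchors = self._flatten_rpn(*self._rpn_maps(pyr))
        rois = self._proposals(logits, deltas, anchors, shape)
        if len(rois) == 0:
            return []
        feats = self._roi_features(pyr, rois)
        cls_logits, reg = self._head(feats)
        z = cls_logits.data - cls_logits.data.max(axis=1, keepdims=True)
        probs = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        scores = probs[:, 1]
        boxes = decode_boxes(rois, reg.data)
        h, w = shape
        boxes[:, 0::2] = np.clip(boxes[:, 0::2], 0, w)
        boxes[:, 1::2] = np.clip(boxes[:, 1::2], 0, h)
        ok = (
            (scores >= score_threshold)
            & (boxes[:, 2] - boxes[:, 0] > 0)
            & (boxes[:, 3] - boxes[:, 1] > 0)
        )
        boxes, scores = boxes[ok], scores[ok]
        keep = nms(boxes, scores, nms_iou)
        return [
            DetectionRecord(box=tuple(boxes[i]), score=float(scores[i]), label=1)
            for i in keep
        ]

    def evaluate(
        self, dataset, score_threshold=0.05, code=None, nms_iou=0.5
    ) -> float:
        """AP50 over (image, gt boxes) pairs."""
        dets, gts = {}, {}
        for idx, (image, gt_boxes) in enumerate(dataset):
            records = self.infer(
                image, score_threshold=score_threshold, nms_iou=nms_iou,
                code=code,
            )
            dets[idx] = [(*r.box, r.score) for r in records]
            gts[idx] = list(gt_boxes)
        return eval_metrics.average_precision_50(dets, gts)

    # -- checkpointing ----------------------------------------------------

    def save_weights(self, path) -> None:
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        np.savez(path, __config__=json.dumps(asdict(self.config)), **arrays)

    def load_weights(self, path) -> None:
        payload = np.load(path, allow_pickle=False)
        params = self.parameters()
        for i, p in enumerate(params):
            p.data[...] = payload[f"p{i}"]


def build_detector(
    config: DetectorConfig, code: SubnetCode | str = "supernet"
) -> Detector:
    """Factory mirroring the assembly order of the full architecture."""
    return Detector(config, code)


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------


def train(
    detector: Detector,
    train_set,
    rng: np.random.Generator,
    steps: int | None = None,
    lr: float | None = None,
    batch_size: int | None = None,
    augment_data: bool = True,
    code: SubnetCode | None = None,
) -> list:
    """SGD training; returns the per-step loss curve (LossBreakdown list).

    ``train_set`` is a list of (image [H,W] float in [0,1], corner gt
    boxes).  Without ``steps``, runs the configured number of epochs.
    Fully reproducible from ``rng``.
    """
    if not train_set:
        raise ValueError("empty training set")
    cfg = detector.config
    bs = batch_size or cfg.batch_size
    total_steps = (
        steps
        if steps is not None
        else cfg.epochs * max(1, len(train_set) // bs)
    )
    params = detector.parameters(code=detector._resolve_code(code, allow_none=True))
    opt = SGD(params, lr=cfg.lr if lr is None else lr, clip_norm=10.0)
    curve: list[LossBreakdown] = []
    order: list[int] = []
    for _step in range(total_steps):
        if len(order) < bs:  # re-shuffle each epoch
            order = list(rng.permutation(len(train_set)))
        idx = [order.pop() for _ in range(min(bs, len(train_set)))]
        batch = []
        for i in idx:
            image, boxes = train_set[i]
            if augment_data:
                image, boxes = synthetic_data.augment(image, boxes, rng)
            batch.append((np.asarray(image, dtype=np.float64) / 255.0
                          if np.asarray(image).dtype == np.uint8 else image, boxes))
        opt.zero_grad()
        loss = detector.loss_on_batch(batch, code=code, rng=rng)
        loss.total_tensor.backward()
        opt.step()
        loss.total_tensor = None  # free the autodiff graph
        curve.append(loss)
    return curve
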