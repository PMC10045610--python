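"""Seeded generator of MRI-like grayscale scenes with bright oedema lesions.

The real study data — fluid-sensitive lumbar MRI slices in which bone
marrow oedema and fatty tissue both appear bright against a grey
background — is private, so this module emulates its geometry: a vertical
stack of medium-intensity rounded rectangles stands in for the vertebral
column, bright ellipses and streaks outside the column play the role of
organ/fat distractors, and each lesion is a bright, rotated ellipse whose
centre lies inside a vertebra.  Every lesion receives one tight
axis-aligned bounding box, and annotations are written in the MS COCO
detection format (bbox as [x, y, w, h], single category "oedema").

Everything is reproducible from (config, seed); the default dataset split
is 416 training and 105 test images.  The augmentations mirror the
training recipe: horizontal mirroring with probability 0.5 and a random
crop to 0.6-1.0 of the original side length (resampled back to the input
size so batch geometry is preserved), with boxes clipped and dropped once
less than a quarter of their area remains visible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "SceneSpec",
    "DatasetConfig",
    "generate_image",
    "generate_dataset",
    "augment",
    "corner_to_coco",
    "coco_to_corner",
]


@dataclass(frozen=True)
class SceneSpec:
    """Geometry and intensity statistics of one synthetic MRI-like scene."""

    image_size: int = 256
    vertebra_count: int = 5
    vertebra_width_frac: float = 0.32  # column width as a fraction of image
    vertebra_intensity: float = 0.42
    background_intensity: float = 0.14
    distractor_count: tuple = (2, 6)
    distractor_intensity: tuple = (0.65, 0.9)
    lesion_count: tuple = (0, 3)
    lesion_axes: tuple = (4.0, 30.0)  # full axis lengths, pixels
    lesion_intensity_margin: float = 0.3  # above the vertebra intensity
    noise_sigma: float = 0.03

    def __post_init__(self):
        if self.lesion_axes[0] < 2 or self.lesion_axes[1] < self.lesion_axes[0]:
            raise ValueError("invalid lesion axis range")
        column_w = self.vertebra_width_frac * self.image_size
        if self.lesion_axes[1] > column_w:
            raise ValueError(
                "infeasible spec: largest lesion axis exceeds the vertebra width"
            )
        if self.lesion_intensity_margin <= 0:
            raise ValueError("lesion intensity margin must be positive")


@dataclass(frozen=True)
class DatasetConfig:
    n_train: int = 416
    n_test: int = 105
    seed: int = 0
    scene: SceneSpec = field(default_factory=SceneSpec)

    def __post_init__(self):
        if self.n_train < 0 or self.n_test < 0:
            raise ValueError("split sizes must be >= 0")


def _ellipse_mask(size: int, center, axes, angle: float) -> np.ndarray:
    rr, cc = np.mgrid[0:size, 0:size]
    dr, dc = rr - center[0], cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dr + sa * dc
    v = -sa * dr + ca * dc
    return (u / (axes[0] / 2.0)) ** 2 + (v / (axes[1] / 2.0)) ** 2 <= 1.0


def _vertebra_layout(spec: SceneSpec):
    """Rounded-rectangle vertebra masks stacked down the image centre."""
    size = spec.image_size
    col_w = spec.vertebra_width_frac * size
    gap = 0.2  # fraction of one vertebra slot left as disc space
    slot = size / spec.vertebra_count
    boxes = []
    for k in range(spec.vertebra_count):
        top = k * slot + gap * slot / 2.0
        bottom = (k + 1) * slot - gap * slot / 2.0
        left = (size - col_w) / 2.0
        boxes.append((top, left, bottom, left + col_w))
    return boxes


def _rounded_rect_mask(size: int, box, radius: float) -> np.ndarray:
    top, left, bottom, right = box
    rr, cc = np.mgrid[0:size, 0:size]
    inner_r = np.clip(rr, top + radius, bottom - radius)
    inner_c = np.clip(cc, left + radius, right - radius)
    return (rr - inner_r) ** 2 + (cc - inner_c) ** 2 <= radius**2


def _mask_bbox(mask: np.ndarray) -> tuple:
    rows, cols = np.where(mask)
    return (
        float(cols.min()),
        float(rows.min()),
        float(cols.max() - cols.min() + 1),
        float(rows.max() - rows.min() + 1),
    )


def _boxes_closer_than(a: tuple, b: tuple, gap: float) -> bool:
    """True if the [x, y, w, h] boxes are not separated by >= gap pixels.

    Distinct lesion foci must keep a strip of normal marrow between them;
    abutting or overlapping ellipses would merge into one visual blob
    carrying two annotations.
    """
    ax0, ay0, aw, ah = a
    bx0, by0, bw, bh = b
    dx = max(ax0, bx0) - min(ax0 + aw, bx0 + bw)
    dy = max(ay0, by0) - min(ay0 + ah, by0 + bh)
    return max(dx, dy) < gap


def generate_image(spec: SceneSpec, rng: np.random.Generator):
    """Render one scene.  Returns (uint8 image [H, W], list of COCO boxes).

    Each lesion gets one tight [x, y, w, h] box around its rasterised
    ellipse; lesions lie fully inside the image and are brighter than the
    vertebra they sit on by at least the configured margin.
    """
    size = spec.image_size
    img = np.full((size, size), spec.background_intensity)
    vert_boxes = _vertebra_layout(spec)
    vert_mask = np.zeros((size, size), dtype=bool)
    for vb in vert_boxes:
        m = _rounded_rect_mask(size, vb, radius=0.15 * (vb[3] - vb[1]))
        vert_mask |= m
    img[vert_mask] = spec.vertebra_intensity

    # distractors: bright ellipses / streaks outside the vertebral column
    n_distract = int(rng.integers(spec.distractor_count[0], spec.distractor_count[1] + 1))
    for _ in range(n_distract):
        side = rng.choice([-1, 1])
        col_edge = (size - spec.vertebra_width_frac * size) / 2.0
        center = (
            rng.uniform(0.1 * size, 0.9 * size),
            col_edge / 2.0 if side < 0 else size - col_edge / 2.0,
        )
        axes = (rng.uniform(6, 0.25 * size), rng.uniform(3, 0.12 * size))
        mask = _ellipse_mask(size, center, axes, rng.uniform(0, np.pi))
        mask &= ~vert_mask
        img[mask] = rng.uniform(*spec.distractor_intensity)

    # lesions: bright ellipses centred inside a vertebra, fully in-image;
    # distinct foci — a placement overlapping an existing lesion is re-drawn
    n_lesions = int(rng.integers(spec.lesion_count[0], spec.lesion_count[1] + 1))
    boxes = []
    for _ in range(n_lesions):
        for _attempt in range(50):
            vb = vert_boxes[rng.integers(len(vert_boxes))]
            axes = tuple(np.sort(rng.uniform(*spec.lesion_axes, size=2))[::-1])
            center = (
                rng.uniform(vb[0] + 2, vb[2] - 2),
                rng.uniform(vb[1] + 2, vb[3] - 2),
            )
            half = max(axes) / 2.0 + 1
            if not (
                half <= center[0] <= size - 1 - half
                and half <= center[1] <= size - 1 - half
            ):
                continue
            mask = _ellipse_mask(size, center, axes, rng.uniform(0, np.pi))
            if mask.sum() < 4:
                continue
            if any(_boxes_closer_than(_mask_bbox(mask), b, gap=3.0) for b in boxes):
                continue
            intensity = spec.vertebra_intensity + rng.uniform(
                spec.lesion_intensity_margin, spec.lesion_intensity_margin + 0.25
            )
            img[mask] = min(intensity, 1.0)
            boxes.append(_mask_bbox(mask))
            break

    img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    return (img * 255).round().astype(np.uint8), boxes


def _coco_payload(records, categories=None) -> dict:
    images, annotations = [], []
    ann_id = 1
    for img_id, (file_name, size, boxes) in enumerate(records, start=1):
        images.append(
            {"id": img_id, "file_name": file_name, "width": size, "height": size}
        )
        for bbox in boxes:
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": img_id,
                    "category_id": 1,
                    "bbox": [round(v, 2) for v in bbox],
                    "area": round(bbox[2] * bbox[3], 2),
                    "iscrowd": 0,
                }
            )
            ann_id += 1
    return {
        "images": images,
        "annotations": annotations,
        "categories": categories or [{"id": 1, "name": "oedema"}],
    }


def generate_dataset(cfg: DatasetConfig, out_dir) -> dict:
    """Write PNG images and per-split COCO JSON under ``out_dir``.

    Layout: ``train/*.png``, ``test/*.png``, ``instances_train.json``,
    ``instances_test.json`` and a ``manifest.json`` recording the config
    and its hash.  Returns the paths plus per-split annotation counts.
    """
    out = Path(out_dir)
    rng = np.random.default_rng(cfg.seed)
    result: dict = {"out_dir": str(out)}
    for split, count in (("train", cfg.n_train), ("test", cfg.n_test)):
        split_dir = out / split
        split_dir.mkdir(parents=True, exist_ok=True)
        records = []
        for i in range(count):
            img, boxes = generate_image(cfg.scene, rng)
            name = f"{split}_{i:05d}.png"
            Image.fromarray(img, mode="L").save(split_dir / name)
            records.append((name, cfg.scene.image_size, boxes))
        payload = _coco_payload(records)
        ann_path = out / f"instances_{split}.json"
        with open(ann_path, "w") as fh:
            json.dump(payload, fh)
        result[split] = {
            "images": count,
            "annotations": len(payload["annotations"]),
            "annotation_file": str(ann_path),
        }
    config_dict = asdict(cfg)
    digest = hashlib.sha256(
        json.dumps(config_dict, sort_keys=True).encode()
    ).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump({"config": config_dict, "config_sha256": digest}, fh, indent=2)
    result["manifest"] = str(out / "manifest.json")
    return result


# ---------------------------------------------------------------------------
# Augmentations
# ---------------------------------------------------------------------------


def corner_to_coco(box) -> tuple:
    x0, y0, x1, y1 = box
    return (x0, y0, x1 - x0, y1 - y0)


def coco_to_corner(box) -> tuple:
    x, y, w, h = box
    return (x, y, x + w, y + h)


def augment(
    image: np.ndarray,
    boxes,
    rng: np.random.Generator,
    flip_p: float = 0.5,
    crop_range: tuple = (0.6, 1.0),
    min_visible: float = 0.25,
):
    """Random horizontal flip and random crop-and-resize.

    ``boxes`` are corner boxes (x_min, y_min, x_max, y_max) in pixels.
    Mirroring maps x_min' = W - x_max.  The crop side length is a uniform
    scale from ``crop_range`` times the original; the crop is resampled
    back to the input size and boxes with less than ``min_visible`` of
    their area remaining are dropped.
    """
    if not (0.0 < crop_range[0] <= crop_range[1] <= 1.0):
        raise ValueError(f"crop_range must lie in (0, 1], got {crop_range}")
    h, w = image.shape[:2]
    boxes = [tuple(float(v) for v in b) for b in boxes]
    if rng.random() < flip_p:
        image = image[:, ::-1].copy()
        boxes = [(w - x1, y0, w - x0, y1) for (x0, y0, x1, y1) in boxes]
    scale = rng.uniform(*crop_range)
    ch, cw = round(h * scale), round(w * scale)
    if (ch, cw) != (h, w):
        top = int(rng.integers(0, h - ch + 1))
        left = int(rng.integers(0, w - cw + 1))
        crop = image[top : top + ch, left : left + cw]
        kept = []
        sx, sy = w / cw, h / ch
        for x0, y0, x1, y1 in boxes:
            nx0, ny0 = max(x0 - left, 0.0), max(y0 - top, 0.0)
            nx1, ny1 = min(x1 - left, float(cw)), min(y1 - top, float(ch))
            if nx1 <= nx0 or ny1 <= ny0:
                continue
            visible = (nx1 - nx0) * (ny1 - ny0)
            if visible < min_visible * (x1 - x0) * (y1 - y0):
                continue
            kept.append((nx0 * sx, ny0 * sy, nx1 * sx, ny1 * sy))
        pil = Image.fromarray(crop)
        image = np.asarray(pil.resize((w, h), resample=Image.BILINEAR))
        boxes = kept
    return image, boxes
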