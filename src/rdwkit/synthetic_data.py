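"""Synthetic pest-scene generator with YOLO labels.

Real pest imagery is cluttered: small, low-saliency targets on textured
vegetation-like backgrounds, many species, and a long-tailed class
distribution where a few classes dominate. This module emulates those
statistics with fully procedural scenes — value-noise backgrounds plus
class-specific colored blob objects (one shape family and base color per
class) — so every box label is exact by construction: each label is the
tight bounding box of the object's rendered mask.

Everything is deterministic: the same :class:`SceneConfig` and seed produce
byte-identical images and label files. Datasets are written in the YOLO
directory convention (``{train,val,test}/{images,labels}``) with a
70:20:10 split under largest-remainder rounding, and a JSON manifest records
the configuration, the split membership and the provenance of every
augmented copy.

Six label-consistent augmentation operators are provided: brightness,
contrast, color saturation, Gaussian blur, rotation (multiples of 90 degrees,
so boxes transform exactly), and detail enhancement (unsharp masking).
Minority classes can be lifted to a target instance floor by cycling these
operators over images that contain them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from PIL import Image, ImageDraw, ImageEnhance, ImageFilter
from scipy import ndimage

from .boxes import BoxXYWH, LabeledBox, read_yolo_labels, write_yolo_labels

__all__ = [
    "SceneConfig",
    "AugSpec",
    "AUG_OPS",
    "DatasetLayout",
    "longtail_counts",
    "split_counts",
    "generate_scene",
    "generate_dataset",
    "augment_image",
    "rebalance_dataset",
]

# one shape family and base RGB color per class, cycled for many classes
_SHAPES = ("ellipse", "rectangle", "triangle", "diamond", "cross")
_PALETTE = (
    (170, 60, 50),
    (60, 70, 160),
    (190, 170, 60),
    (150, 60, 150),
    (60, 150, 150),
    (200, 120, 50),
    (110, 60, 180),
    (90, 140, 60),
)


@dataclass(frozen=True)
class SceneConfig:
    """Study conditions of the generator.

    per_class_counts sets the long-tail shape: object classes are sampled
    with probability proportional to these counts. object_scale_range is the
    object extent as a fraction of the image side; the default range keeps a
    mix of small and medium targets. clutter_level in [0,1] scales the
    background texture amplitude.
    """

    image_size: Tuple[int, int] = (64, 64)
    num_classes: int = 5
    per_class_counts: Optional[Tuple[int, ...]] = None
    object_scale_range: Tuple[float, float] = (0.1, 0.4)
    clutter_level: float = 0.3
    overlap_allowed: bool = False
    objects_per_image: Tuple[int, int] = (1, 3)
    seed: int = 0

    def class_probs(self) -> np.ndarray:
        counts = (
            np.asarray(self.per_class_counts, dtype=float)
            if self.per_class_counts is not None
            else longtail_counts(self.num_classes)
        )
        if len(counts) != self.num_classes:
            raise ValueError("per_class_counts length must equal num_classes")
        return counts / counts.sum()

    def to_dict(self) -> dict:
        return {
            "image_size": list(self.image_size),
            "num_classes": self.num_classes,
            "per_class_counts": None
            if self.per_class_counts is None
            else [int(c) for c in self.per_class_counts],
            "object_scale_range": list(self.object_scale_range),
            "clutter_level": self.clutter_level,
            "overlap_allowed": self.overlap_allowed,
            "objects_per_image": list(self.objects_per_image),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        return cls(
            image_size=tuple(d["image_size"]),
            num_classes=int(d["num_classes"]),
            per_class_counts=None
            if d.get("per_class_counts") is None
            else tuple(d["per_class_counts"]),
            object_scale_range=tuple(d["object_scale_range"]),
            clutter_level=float(d["clutter_level"]),
            overlap_allowed=bool(d["overlap_allowed"]),
            objects_per_image=tuple(d["objects_per_image"]),
            seed=int(d["seed"]),
        )


def longtail_counts(num_classes: int, exponent: float = 1.5, head: int = 100) -> np.ndarray:
    """Zipf-like class counts: count_i = head / (i+1)^exponent, floored at 1."""
    i = np.arange(num_classes, dtype=float)
    return np.maximum(1, np.round(head / (i + 1.0) ** exponent)).astype(int)


# ---------------------------------------------------------------------------
# scene rendering
# ---------------------------------------------------------------------------


def _value_noise(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    """Multi-octave smooth noise in [-1, 1]."""
    acc = np.zeros((h, w))
    for cells, amp in ((4, 1.0), (8, 0.5), (16, 0.25)):
        coarse = rng.normal(0.0, 1.0, (cells, cells))
        zoomed = ndimage.zoom(coarse, (h / cells, w / cells), order=1, mode="nearest")
        acc += amp * zoomed[:h, :w]
    m = np.abs(acc).max()
    return acc / m if m > 0 else acc


def _render_background(rng: np.random.Generator, cfg: SceneConfig) -> np.ndarray:
    h, w = cfg.image_size
    base = np.array([88.0, 110.0, 70.0])  # muted vegetation tone
    img = np.tile(base, (h, w, 1))
    for ch, weight in enumerate((0.8, 1.0, 0.6)):
        img[:, :, ch] += cfg.clutter_level * 90.0 * weight * _value_noise(rng, h, w)
    img += rng.normal(0.0, 4.0 * cfg.clutter_level, (h, w, 3))  # pixel grain
    return np.clip(img, 0, 255)


def _draw_shape(draw: ImageDraw.ImageDraw, shape: str, x1, y1, x2, y2) -> None:
    cx, cy = (x1 + x2) / 2.0, (y1 + y2) / 2.0
    if shape == "ellipse":
        draw.ellipse([x1, y1, x2, y2], fill=255)
    elif shape == "rectangle":
        draw.rectangle([x1, y1, x2, y2], fill=255)
    elif shape == "triangle":
        draw.polygon([(cx, y1), (x2, y2), (x1, y2)], fill=255)
    elif shape == "diamond":
        draw.polygon([(cx, y1), (x2, cy), (cx, y2), (x1, cy)], fill=255)
    elif shape == "cross":
        bw = max(1.0, (x2 - x1) / 3.0)
        bh = max(1.0, (y2 - y1) / 3.0)
        draw.rectangle([x1, cy - bh / 2, x2, cy + bh / 2], fill=255)
        draw.rectangle([cx - bw / 2, y1, cx + bw / 2, y2], fill=255)
    else:  # pragma: no cover - guarded by class mapping
        raise ValueError(f"unknown shape {shape!r}")


def _mask_bbox(mask: np.ndarray) -> Tuple[int, int, int, int]:
    """Tight pixel bbox (x1, y1, x2, y2), right/bottom exclusive."""
    ys, xs = np.nonzero(mask)
    return int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1


def generate_scene(
    cfg: SceneConfig, scene_seed: int = 0, return_masks: bool = False
):
    """Render one scene; returns (H x W x 3 uint8 image, YOLO-normalized labels).

    Each label box is the tight bounding box of the object's rendered mask;
    with ``return_masks=True`` the per-object boolean masks are returned as a
    third element so that fidelity can be verified externally. Objects that
    cannot be placed under the overlap constraint after bounded retries are
    skipped with a warning.
    """
    rng = np.random.default_rng([cfg.seed, int(scene_seed)])
    h, w = cfg.image_size
    img = _render_background(rng, cfg)
    probs = cfg.class_probs()
    lo, hi = cfg.objects_per_image
    n_obj = int(rng.integers(lo, hi + 1))
    labels: List[LabeledBox] = []
    masks: List[np.ndarray] = []
    placed_px: List[Tuple[int, int, int, int]] = []
    for _ in range(n_obj):
        cls = int(rng.choice(cfg.num_classes, p=probs))
        placed = False
        for _try in range(40):
            scale = rng.uniform(*cfg.object_scale_range)
            ow = max(3.0, scale * w * rng.uniform(0.8, 1.2))
            oh = max(3.0, scale * h * rng.uniform(0.8, 1.2))
            x1 = rng.uniform(0, w - ow)
            y1 = rng.uniform(0, h - oh)
            cand = (x1, y1, x1 + ow, y1 + oh)
            if not cfg.overlap_allowed and any(
                _pixel_iou(cand, p) > 0.05 for p in placed_px
            ):
                continue
            mask_img = Image.new("L", (w, h), 0)
            _draw_shape(
                ImageDraw.Draw(mask_img), _SHAPES[cls % len(_SHAPES)], *cand
            )
            mask = np.asarray(mask_img) > 0
            if not mask.any():
                continue
            color = np.array(_PALETTE[cls % len(_PALETTE)], dtype=float)
            color = color + rng.uniform(-15, 15, 3)
            texture = rng.normal(0.0, 6.0, (h, w, 1))
            alpha = 0.9
            obj_layer = np.clip(color[None, None, :] + texture, 0, 255)
            img[mask] = alpha * obj_layer[mask] + (1 - alpha) * img[mask]
            bx1, by1, bx2, by2 = _mask_bbox(mask)
            labels.append(
                (
                    cls,
                    BoxXYWH(
                        cx=(bx1 + bx2) / 2.0 / w,
                        cy=(by1 + by2) / 2.0 / h,
                        w=(bx2 - bx1) / w,
                        h=(by2 - by1) / h,
                    ),
                )
            )
            placed_px.append((bx1, by1, bx2, by2))
            masks.append(mask)
            placed = True
            break
        if not placed:
            warnings.warn("object placement failed under overlap constraint; skipped")
    out_img = np.clip(img, 0, 255).astype(np.uint8)
    if return_masks:
        return out_img, labels, masks
    return out_img, labels


def _pixel_iou(a, b) -> float:
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    ua = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
    return inter / ua if ua > 0 else 0.0


# ---------------------------------------------------------------------------
# dataset layout
# ---------------------------------------------------------------------------

SPLIT_RATIOS: Tuple[float, ...] = (0.7, 0.2, 0.1)
SPLIT_NAMES: Tuple[str, ...] = ("train", "val", "test")


def split_counts(n: int, ratios: Sequence[float] = SPLIT_RATIOS) -> Tuple[int, ...]:
    """Largest-remainder apportionment of n items; remainder ties go earlier.

    Quotas are computed in exact rational arithmetic so remainder ties are
    genuine ties (decided by position) rather than float-noise artifacts.
    """
    from fractions import Fraction

    quotas = [Fraction(str(r)) * n for r in ratios]
    base = [int(q) for q in quotas]
    seats = n - sum(base)
    order = sorted(range(len(ratios)), key=lambda i: (-(quotas[i] - base[i]), i))
    for i in order[:seats]:
        base[i] += 1
    return tuple(base)


@dataclass
class DatasetLayout:
    """A dataset on disk plus its manifest."""

    root: Path
    manifest: dict

    def images_dir(self, split: str) -> Path:
        return self.root / split / "images"

    def labels_dir(self, split: str) -> Path:
        return self.root / split / "labels"

    def image_ids(self, split: str) -> List[str]:
        return list(self.manifest["splits"][split])

    def save_manifest(self) -> None:
        (self.root / "manifest.json").write_text(json.dumps(self.manifest, indent=2))

    @classmethod
    def load(cls, root: str | Path) -> "DatasetLayout":
        root = Path(root)
        return cls(root=root, manifest=json.loads((root / "manifest.json").read_text()))

    def class_instance_counts(self, split: str = "train") -> Dict[int, int]:
        counts: Dict[int, int] = {}
        for image_id in self.image_ids(split):
            for cls, _ in read_yolo_labels(self.labels_dir(split) / f"{image_id}.txt"):
                counts[cls] = counts.get(cls, 0) + 1
        return counts


def generate_dataset(
    cfg: SceneConfig, n_images: int, out_dir: str | Path, force: bool = False
) -> DatasetLayout:
    """Render ``n_images`` scenes into ``out_dir`` with a 70:20:10 split."""
    if n_images < 10:
        raise ValueError(f"need at least 10 images for a 70:20:10 split, got {n_images}")
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()):
        if not force:
            raise FileExistsError(f"output directory {out_dir} is not empty (use force)")
    counts = split_counts(n_images)
    splits: Dict[str, List[str]] = {}
    idx = 0
    for name, count in zip(SPLIT_NAMES, counts):
        (out_dir / name / "images").mkdir(parents=True, exist_ok=True)
        (out_dir / name / "labels").mkdir(parents=True, exist_ok=True)
        ids = []
        for _ in range(count):
            image_id = f"img_{idx:05d}"
            img, labels = generate_scene(cfg, scene_seed=idx)
            Image.fromarray(img).save(out_dir / name / "images" / f"{image_id}.png")
            write_yolo_labels(out_dir / name / "labels" / f"{image_id}.txt", labels)
            ids.append(image_id)
            idx += 1
        splits[name] = ids
    layout = DatasetLayout(
        root=out_dir,
        manifest={
            "config": cfg.to_dict(),
            "n_images": n_images,
            "split_counts": dict(zip(SPLIT_NAMES, counts)),
            "splits": splits,
            "provenance": {},
        },
    )
    layout.save_manifest()
    return layout


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

AUG_OPS = ("brightness", "contrast", "saturation", "gaussian_blur", "rotate", "detail_enhance")

_DEFAULT_MAGNITUDES = {
    "brightness": 1.3,
    "contrast": 1.3,
    "saturation": 1.4,
    "gaussian_blur": 1.0,
    "rotate": 90.0,
    "detail_enhance": 1.5,
}


@dataclass(frozen=True)
class AugSpec:
    """One augmentation: operator name, operator-specific magnitude, seed."""

    op: str
    magnitude: Optional[float] = None
    seed: int = 0

    def __post_init__(self):
        if self.op not in AUG_OPS:
            raise ValueError(f"unknown augmentation op {self.op!r} (choose from {AUG_OPS})")
        if self.magnitude is None:
            object.__setattr__(self, "magnitude", _DEFAULT_MAGNITUDES[self.op])


def _rotate_box_cw(box: BoxXYWH, quarter_turns: int) -> BoxXYWH:
    """Rotate a normalized box by 90-degree clockwise turns."""
    cx, cy, w, h = box.as_tuple()
    for _ in range(quarter_turns % 4):
        cx, cy, w, h = 1.0 - cy, cx, h, w
    return BoxXYWH(cx, cy, w, h)


def augment_image(
    image: np.ndarray, labels: Sequence[LabeledBox], spec: AugSpec
) -> Tuple[np.ndarray, List[LabeledBox]]:
    """Apply one operator; photometric ops leave labels untouched, rotation
    transforms boxes by the exact coordinate map."""
    labels = list(labels)
    if spec.op == "rotate":
        angle = float(spec.magnitude) % 360.0
        if angle % 90.0 != 0.0:
            raise ValueError(f"rotation must be a multiple of 90 degrees, got {spec.magnitude}")
        q = int(angle // 90)
        out = np.rot90(image, k=-q).copy()  # k=-1 is one clockwise quarter turn
        return out, [(cls, _rotate_box_cw(box, q)) for cls, box in labels]
    pil = Image.fromarray(image)
    if spec.op == "brightness":
        pil = ImageEnhance.Brightness(pil).enhance(spec.magnitude)
    elif spec.op == "contrast":
        pil = ImageEnhance.Contrast(pil).enhance(spec.magnitude)
    elif spec.op == "saturation":
        pil = ImageEnhance.Color(pil).enhance(spec.magnitude)
    elif spec.op == "gaussian_blur":
        pil = pil.filter(ImageFilter.GaussianBlur(radius=spec.magnitude))
    elif spec.op == "detail_enhance":
        # unsharp masking: image + amount * (image - blurred)
        pil = pil.filter(
            ImageFilter.UnsharpMask(radius=2, percent=int(100 * spec.magnitude), threshold=0)
        )
    return np.asarray(pil).copy(), labels


# ---------------------------------------------------------------------------
# long-tail rebalancing
# ---------------------------------------------------------------------------


def rebalance_dataset(
    layout: DatasetLayout,
    min_per_class: int,
    max_multiplier: int = 10,
    split: str = "train",
) -> Tuple[DatasetLayout, dict]:
    """Lift every under-floor class to >= min_per_class training instances.

    Augmented copies of images containing a deficient class are added,
    cycling the six operators with fresh seeds, until the floor is met or
    each source image has been copied ``max_multiplier`` times. Returns the
    updated layout and a report with final counts and any class that could
    not be rebalanced (absent entirely).
    """
    counts = layout.class_instance_counts(split)
    report: dict = {"initial_counts": dict(counts), "added_images": 0, "unbalanceable": []}
    rotate_angles = (90.0, 180.0, 270.0)
    aug_idx = 0
    for cls in range(layout.manifest["config"]["num_classes"]):
        have = counts.get(cls, 0)
        if have >= min_per_class:
            continue
        sources = [
            image_id
            for image_id in layout.image_ids(split)
            if any(
                c == cls
                for c, _ in read_yolo_labels(layout.labels_dir(split) / f"{image_id}.txt")
            )
        ]
        if not sources:
            report["unbalanceable"].append(cls)
            continue
        copies = 0
        budget = max_multiplier * len(sources)
        while counts.get(cls, 0) < min_per_class and copies < budget:
            src = sources[copies % len(sources)]
            op = AUG_OPS[aug_idx % len(AUG_OPS)]
            magnitude = (
                rotate_angles[(aug_idx // len(AUG_OPS)) % 3] if op == "rotate" else None
            )
            spec = AugSpec(op=op, magnitude=magnitude, seed=aug_idx)
            image = np.asarray(
                Image.open(layout.images_dir(split) / f"{src}.png").convert("RGB")
            )
            lbls = read_yolo_labels(layout.labels_dir(split) / f"{src}.txt")
            aug_img, aug_lbls = augment_image(image, lbls, spec)
            new_id = f"{src}_aug{aug_idx:04d}"
            Image.fromarray(aug_img).save(layout.images_dir(split) / f"{new_id}.png")
            write_yolo_labels(layout.labels_dir(split) / f"{new_id}.txt", aug_lbls)
            layout.manifest["splits"][split].append(new_id)
            layout.manifest["provenance"][new_id] = {
                "source": src,
                "op": op,
                "magnitude": spec.magnitude,
                "seed": spec.seed,
            }
            for c, _ in aug_lbls:
                counts[c] = counts.get(c, 0) + 1
            report["added_images"] += 1
            copies += 1
            aug_idx += 1
    layout.save_manifest()
    report["final_counts"] = dict(counts)
    return layout, report
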