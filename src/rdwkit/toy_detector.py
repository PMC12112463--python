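"""A minimal anchor-free detector built from the package's blocks.

The network is deliberately tiny — stem convolution, RDFBlock, DPDown,
RDFBlock, DPDown, 1x1 head — so the interesting components (dilated-fusion
blocks, dual-path downsampling, and the Wasserstein-weighted IoU loss) can
be trained and fused end to end on synthetic scenes in minutes on a CPU.
Two stride-2 stages give a prediction grid at 1/4 resolution; each ground
truth is assigned to the single cell containing its center, and each cell
predicts an objectness logit, per-class logits, and a box as
(dx, dy, log w, log h): the center offset within the cell (through a
sigmoid) and log-sizes in normalized image units, so decoded widths and
heights are always positive.

The loss is binary cross-entropy on objectness over all cells, binary
cross-entropy on class logits at positive cells, and the WWIoU loss on
decoded boxes at positive cells. Box-loss gradients come from the exact
forward-mode gradient of the loss and are chained through the decoding map
analytically.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from PIL import Image

from . import _autodiff as ad
from .boxes import BoxXYWH, LabeledBox, read_yolo_labels
from .dp_down import DPDown, DPDownConfig
from .eval_metrics import Detection, EvalReport, GroundTruth, evaluate
from .geometry_loss import LossConfig, _wwiou_core, iou
from .nn import SGD, Conv2d, Param, ReLU, bce_with_logits, sigmoid
from .rdf_block import BranchSpec, RDFBlock, RDFConfig

__all__ = [
    "ToyDetectorConfig",
    "GridPrediction",
    "ToyDetector",
    "build_toy_detector",
    "encode_box",
    "decode_box",
    "toy_loss",
    "train_toy",
    "predict_image",
    "evaluate_detector",
    "save_checkpoint",
    "load_checkpoint",
]

STRIDE = 4  # two stride-2 stages


@dataclass(frozen=True)
class ToyDetectorConfig:
    input_size: Tuple[int, int] = (64, 64)
    stem_channels: int = 8
    num_classes: int = 5
    head_channels: int = 32
    rdf_K: int = 5
    rdf_branches: Tuple[Tuple[int, int], ...] = ((3, 1), (3, 2))
    loss_cfg: LossConfig = field(default_factory=lambda: LossConfig(c_norm=0.2))
    w_obj: float = 1.0
    w_cls: float = 1.0
    w_box: float = 2.0
    # positive cells are ~1% of the grid; this rebalances the objectness BCE
    obj_pos_weight: float = 64.0

    def __post_init__(self):
        h, w = self.input_size
        if h % STRIDE or w % STRIDE:
            raise ValueError(f"input size must be divisible by {STRIDE}, got {self.input_size}")
        if self.stem_channels % 2:
            raise ValueError("stem_channels must be even (DPDown splits channels)")

    @property
    def grid_size(self) -> Tuple[int, int]:
        return (self.input_size[0] // STRIDE, self.input_size[1] // STRIDE)

    def to_dict(self) -> dict:
        return {
            "input_size": list(self.input_size),
            "stem_channels": self.stem_channels,
            "num_classes": self.num_classes,
            "head_channels": self.head_channels,
            "rdf_K": self.rdf_K,
            "rdf_branches": [list(b) for b in self.rdf_branches],
            "loss_cfg": {
                "r_weight": self.loss_cfg.r_weight,
                "c_norm": self.loss_cfg.c_norm,
                "nwd_exponent": self.loss_cfg.nwd_exponent,
            },
            "w_obj": self.w_obj,
            "w_cls": self.w_cls,
            "w_box": self.w_box,
            "obj_pos_weight": self.obj_pos_weight,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ToyDetectorConfig":
        return cls(
            input_size=tuple(d["input_size"]),
            stem_channels=int(d["stem_channels"]),
            num_classes=int(d["num_classes"]),
            head_channels=int(d["head_channels"]),
            rdf_K=int(d["rdf_K"]),
            rdf_branches=tuple(tuple(b) for b in d["rdf_branches"]),
            loss_cfg=LossConfig(**d["loss_cfg"]),
            w_obj=float(d["w_obj"]),
            w_cls=float(d["w_cls"]),
            w_box=float(d["w_box"]),
            obj_pos_weight=float(d.get("obj_pos_weight", 64.0)),
        )


@dataclass
class GridPrediction:
    """Raw head output split into its three roles (logits, not probabilities)."""

    obj_logit: np.ndarray  # (B, 1, Gh, Gw)
    cls_logit: np.ndarray  # (B, C, Gh, Gw)
    box_raw: np.ndarray  # (B, 4, Gh, Gw): dx, dy, log w, log h

    @property
    def objectness(self) -> np.ndarray:
        return sigmoid(self.obj_logit)

    @property
    def class_scores(self) -> np.ndarray:
        return sigmoid(self.cls_logit)


class ToyDetector:
    """stem conv -> RDFBlock -> DPDown -> RDFBlock -> DPDown -> 1x1 head."""

    def __init__(self, cfg: ToyDetectorConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        s = cfg.stem_channels
        branches = tuple(BranchSpec(k, r) for k, r in cfg.rdf_branches)
        self.cfg = cfg
        self.stem = Conv2d(3, s, 3, padding=1, rng=rng)
        self.stem_act = ReLU()
        self.rdf1 = RDFBlock(RDFConfig(s, s, K=cfg.rdf_K, branches=branches), rng=rng)
        self.down1 = DPDown(DPDownConfig(s, 2 * s), rng=rng)
        self.rdf2 = RDFBlock(RDFConfig(2 * s, 2 * s, K=cfg.rdf_K, branches=branches), rng=rng)
        self.down2 = DPDown(DPDownConfig(2 * s, 4 * s), rng=rng)
        self.head1 = Conv2d(4 * s, cfg.head_channels, 1, rng=rng)
        self.head_act = ReLU()
        self.head2 = Conv2d(cfg.head_channels, 1 + cfg.num_classes + 4, 1, rng=rng)
        self.head2.bias.data[0] = -4.0  # low objectness prior: start near background
        self.deploy = False
        # single precision: the toy net is bandwidth-bound on CPU
        for p in self.params():
            p.astype(np.float32)
        for bn in (self.rdf1.bn, self.rdf2.bn):
            bn.running_mean = bn.running_mean.astype(np.float32)
            bn.running_var = bn.running_var.astype(np.float32)

    # -- forward / backward --------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        bn_mode = "batch_stats" if train else "running_stats"
        y = self.stem_act.forward(self.stem.forward(x))
        if self.deploy:
            y = self.rdf1.forward_deploy(y)
            y = self.down1.forward(y)
            y = self.rdf2.forward_deploy(y)
        else:
            y = self.rdf1.forward_train(y, bn_mode=bn_mode)
            y = self.down1.forward(y)
            y = self.rdf2.forward_train(y, bn_mode=bn_mode)
        y = self.down2.forward(y)
        return self.head2.forward(self.head_act.forward(self.head1.forward(y)))

    def backward(self, dout: np.ndarray) -> None:
        d = self.head1.backward(self.head_act.backward(self.head2.backward(dout)))
        d = self.down2.backward(d)
        d = self.rdf2.backward(d)
        d = self.down1.backward(d)
        d = self.rdf1.backward(d)
        self.stem.backward(self.stem_act.backward(d))

    def params(self) -> List[Param]:
        return (
            self.stem.params()
            + self.rdf1.params()
            + self.down1.params()
            + self.rdf2.params()
            + self.down2.params()
            + self.head1.params()
            + self.head2.params()
        )

    def parameter_count(self) -> int:
        return sum(p.data.size for p in self.params())

    def fuse(self) -> None:
        """Switch both RDF blocks to their single-kernel deploy path."""
        self.rdf1.fuse()
        self.rdf2.fuse()
        self.deploy = True

    def split_prediction(self, raw: np.ndarray) -> GridPrediction:
        c = self.cfg.num_classes
        return GridPrediction(
            obj_logit=raw[:, :1], cls_logit=raw[:, 1 : 1 + c], box_raw=raw[:, 1 + c :]
        )


def build_toy_detector(cfg: ToyDetectorConfig, seed: int = 0) -> ToyDetector:
    return ToyDetector(cfg, seed=seed)


# ---------------------------------------------------------------------------
# box encoding on the prediction grid
# ---------------------------------------------------------------------------

_LOGIT_EPS = 1e-6


def _cell_of(box: BoxXYWH, gh: int, gw: int) -> Tuple[int, int]:
    if not (0.0 <= box.cx <= 1.0 and 0.0 <= box.cy <= 1.0):
        raise ValueError(f"ground-truth center outside the image: ({box.cx}, {box.cy})")
    return min(int(box.cy * gh), gh - 1), min(int(box.cx * gw), gw - 1)


def encode_box(box: BoxXYWH, gh: int, gw: int) -> Tuple[int, int, np.ndarray]:
    """Map a normalized box to its cell (i, j) and raw targets (dx, dy, log w, log h)."""
    i, j = _cell_of(box, gh, gw)
    fx = np.clip(box.cx * gw - j, _LOGIT_EPS, 1 - _LOGIT_EPS)
    fy = np.clip(box.cy * gh - i, _LOGIT_EPS, 1 - _LOGIT_EPS)
    raw = np.array(
        [math.log(fx / (1 - fx)), math.log(fy / (1 - fy)), math.log(box.w), math.log(box.h)]
    )
    return i, j, raw


def decode_box(raw: Sequence[float], i: int, j: int, gh: int, gw: int) -> BoxXYWH:
    """Inverse of :func:`encode_box`; decoded w, h are positive by construction."""
    dx, dy, lw, lh = (float(v) for v in raw)
    return BoxXYWH(
        cx=(j + 1.0 / (1.0 + math.exp(-dx))) / gw,
        cy=(i + 1.0 / (1.0 + math.exp(-dy))) / gh,
        w=math.exp(lw),
        h=math.exp(lh),
    )


def _decode_core(raw, i: int, j: int, gh: int, gw: int):
    """Decode with _autodiff-compatible scalars (for chaining gradients)."""
    dx, dy, lw, lh = raw
    sx = 1.0 / (1.0 + ad.exp(-dx))
    sy = 1.0 / (1.0 + ad.exp(-dy))
    return ((j + sx) / gw, (i + sy) / gh, ad.exp(lw), ad.exp(lh))


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------


def toy_loss(
    raw: np.ndarray,
    gt_lists: Sequence[Sequence[LabeledBox]],
    cfg: ToyDetectorConfig,
) -> Tuple[float, Dict[str, float], np.ndarray]:
    """Total loss, per-term values, and the gradient w.r.t. the raw head output.

    Each ground truth claims the cell containing its center (first one wins
    if two share a cell). Objectness BCE runs over every cell; class BCE and
    the WWIoU box loss run at positive cells only.
    """
    b, ch, gh, gw = raw.shape
    c = cfg.num_classes
    assert ch == 1 + c + 4
    obj_t = np.zeros((b, 1, gh, gw))
    cls_t = np.zeros((b, c, gh, gw))
    positives: List[Tuple[int, int, int, BoxXYWH]] = []
    for bi, labels in enumerate(gt_lists):
        taken = set()
        for cls_id, box in labels:
            i, j = _cell_of(box, gh, gw)
            if (i, j) in taken:
                continue
            taken.add((i, j))
            obj_t[bi, 0, i, j] = 1.0
            cls_t[bi, cls_id, i, j] = 1.0
            positives.append((bi, i, j, box))

    draw = np.zeros_like(raw)
    obj_loss, dobj = bce_with_logits(raw[:, :1], obj_t, pos_weight=cfg.obj_pos_weight)
    draw[:, :1] = dobj

    cls_loss = 0.0
    box_loss = 0.0
    if positives:
        pos_idx = np.array([[p[0], p[1], p[2]] for p in positives])
        bi, ii, jj = pos_idx[:, 0], pos_idx[:, 1], pos_idx[:, 2]
        cls_logits = raw[bi, 1 : 1 + c, ii, jj]
        cls_loss, dcls = bce_with_logits(cls_logits, cls_t[bi, :, ii, jj])
        tmp = np.zeros_like(raw[:, 1 : 1 + c])
        tmp[bi, :, ii, jj] = dcls
        draw[:, 1 : 1 + c] = tmp

        n_pos = len(positives)
        for bi_, i_, j_, gt_box in positives:
            braw = raw[bi_, 1 + c :, i_, j_]
            gt_t = gt_box.as_tuple()

            def f(p):
                return _wwiou_core(_decode_core(p, i_, j_, gh, gw), gt_t, cfg.loss_cfg)

            box_loss += ad.value(f(list(braw))) / n_pos
            draw[bi_, 1 + c :, i_, j_] += cfg.w_box * ad.gradient(f, braw) / n_pos

    total = cfg.w_obj * obj_loss + cfg.w_cls * cls_loss + cfg.w_box * box_loss
    draw[:, :1] *= cfg.w_obj
    draw[:, 1 : 1 + c] *= cfg.w_cls
    terms = {"obj": obj_loss, "cls": cls_loss, "box": box_loss}
    return float(total), terms, draw


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def _nms(dets: List[Detection], iou_threshold: float = 0.5) -> List[Detection]:
    """Greedy per-class non-max suppression."""
    keep: List[Detection] = []
    for cls in sorted({d.class_id for d in dets}):
        pool = sorted((d for d in dets if d.class_id == cls), key=lambda d: -d.confidence)
        while pool:
            best = pool.pop(0)
            keep.append(best)
            pool = [d for d in pool if iou(d.box, best.box) < iou_threshold]
    return keep


def predict_image(
    model: ToyDetector,
    image: np.ndarray,
    image_id: str,
    conf_threshold: float = 0.25,
    nms_iou: float = 0.5,
) -> List[Detection]:
    """Run the detector on one HxWx3 uint8 image and decode detections."""
    x = _to_input(image)[None]
    raw = model.forward(x, train=False)
    pred = model.split_prediction(raw)
    gh, gw = raw.shape[2], raw.shape[3]
    obj = pred.objectness[0, 0]
    cls_scores = pred.class_scores[0]
    dets: List[Detection] = []
    for i in range(gh):
        for j in range(gw):
            best_cls = int(cls_scores[:, i, j].argmax())
            conf = float(obj[i, j] * cls_scores[best_cls, i, j])
            if conf < conf_threshold:
                continue
            box = decode_box(pred.box_raw[0, :, i, j], i, j, gh, gw)
            if not (0.0 <= box.cx <= 1.0 and 0.0 <= box.cy <= 1.0):
                continue
            dets.append(
                Detection(image_id=image_id, class_id=best_cls, box=box, confidence=min(conf, 1.0))
            )
    return _nms(dets, nms_iou)


def _to_input(image: np.ndarray) -> np.ndarray:
    return image.astype(np.float32).transpose(2, 0, 1) / np.float32(255.0) - np.float32(0.5)


def _load_split(dataset_dir: Path, split: str) -> Tuple[List[str], List[np.ndarray], List[List[LabeledBox]]]:
    images_dir = dataset_dir / split / "images"
    labels_dir = dataset_dir / split / "labels"
    ids, images, labels = [], [], []
    for img_path in sorted(images_dir.glob("*.png")):
        ids.append(img_path.stem)
        images.append(np.asarray(Image.open(img_path).convert("RGB")))
        labels.append(read_yolo_labels(labels_dir / f"{img_path.stem}.txt"))
    if not ids:
        raise FileNotFoundError(f"no images under {images_dir}")
    return ids, images, labels


def evaluate_detector(
    model: ToyDetector,
    dataset_dir: str | Path,
    split: str = "val",
    conf_threshold: float = 0.1,
    iou_threshold: float = 0.5,
) -> EvalReport:
    """mAP@0.5 of the detector on one split of a generated dataset."""
    ids, images, labels = _load_split(Path(dataset_dir), split)
    dets: List[Detection] = []
    gts: List[GroundTruth] = []
    for image_id, image, lbls in zip(ids, images, labels):
        dets.extend(predict_image(model, image, image_id, conf_threshold=conf_threshold))
        gts.extend(GroundTruth(image_id, cls, box) for cls, box in lbls)
    return evaluate(dets, gts, iou_threshold=iou_threshold)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def train_toy(
    dataset_dir: str | Path,
    cfg: ToyDetectorConfig,
    epochs: int = 20,
    seed: int = 0,
    lr: float = 0.01,
    momentum: float = 0.937,
    batch_size: int = 8,
    val_conf: float = 0.1,
    log_path: Optional[str | Path] = None,
    checkpoint_path: Optional[str | Path] = None,
    eval_every: int = 1,
) -> Tuple[List[dict], ToyDetector]:
    """Train on the train split; returns the per-epoch log and the model.

    Deterministic given the seed: model init, batch order and every forward
    pass are driven by one generator. Logs epoch-mean loss terms and val
    mAP@0.5; optionally writes a CSV log and a weight-archive checkpoint.
    """
    dataset_dir = Path(dataset_dir)
    model = ToyDetector(cfg, seed=seed)
    _, images, labels = _load_split(dataset_dir, "train")
    xs = np.stack([_to_input(im) for im in images])
    opt = SGD(model.params(), lr=lr, momentum=momentum)
    rng = np.random.default_rng(seed + 1)
    n = len(images)
    log: List[dict] = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        sums = {"loss": 0.0, "obj": 0.0, "cls": 0.0, "box": 0.0}
        n_batches = 0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            raw = model.forward(xs[idx], train=True)
            loss, terms, draw = toy_loss(raw, [labels[i] for i in idx], cfg)
            opt.zero_grad()
            model.backward(draw)
            opt.step()
            sums["loss"] += loss
            for k in ("obj", "cls", "box"):
                sums[k] += terms[k]
            n_batches += 1
        entry = {"epoch": epoch, **{k: v / n_batches for k, v in sums.items()}}
        if eval_every and (epoch % eval_every == 0 or epoch == epochs - 1):
            entry["val_map50"] = evaluate_detector(
                model, dataset_dir, "val", conf_threshold=val_conf
            ).map50
        log.append(entry)
    if log_path is not None:
        fields = ["epoch", "loss", "obj", "cls", "box", "val_map50"]
        with open(log_path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=fields)
            writer.writeheader()
            for entry in log:
                writer.writerow({k: entry.get(k, "") for k in fields})
    if checkpoint_path is not None:
        save_checkpoint(checkpoint_path, model)
    return log, model


# ---------------------------------------------------------------------------
# checkpoints: flat npz + JSON config sidecar, fuse-compatible keys
# ---------------------------------------------------------------------------


def _named_arrays(model: ToyDetector) -> Dict[str, np.ndarray]:
    out: Dict[str, np.ndarray] = {
        "stem_w": model.stem.weight.data,
        "stem_b": model.stem.bias.data,
        "head1_w": model.head1.weight.data,
        "head1_b": model.head1.bias.data,
        "head2_w": model.head2.weight.data,
        "head2_b": model.head2.bias.data,
    }
    for name, blk in (("rdf1", model.rdf1), ("rdf2", model.rdf2)):
        wts = blk.get_weights()
        out[f"{name}_w_std"] = wts.w_std
        for i, w in enumerate(wts.w_dil):
            out[f"{name}_w_dil_{i}"] = w
        out[f"{name}_bn_gamma"] = wts.bn_gamma
        out[f"{name}_bn_beta"] = wts.bn_beta
        out[f"{name}_bn_mean"] = wts.bn_mean
        out[f"{name}_bn_var"] = wts.bn_var
    for name, dp in (("dp1", model.down1), ("dp2", model.down2)):
        out[f"{name}_conv3_w"] = dp.conv3.weight.data
        out[f"{name}_conv3_b"] = dp.conv3.bias.data
        out[f"{name}_conv1_w"] = dp.conv1.weight.data
        out[f"{name}_conv1_b"] = dp.conv1.bias.data
    return out


def save_checkpoint(path: str | Path, model: ToyDetector) -> None:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_name(path.name + ".npz")
    np.savez(path, **_named_arrays(model))
    path.with_suffix(".json").write_text(json.dumps(model.cfg.to_dict(), indent=2))


def load_checkpoint(path: str | Path) -> ToyDetector:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_name(path.name + ".npz")
    cfg = ToyDetectorConfig.from_dict(json.loads(path.with_suffix(".json").read_text()))
    model = ToyDetector(cfg, seed=0)
    with np.load(path) as npz:
        model.stem.weight.data = npz["stem_w"]
        model.stem.bias.data = npz["stem_b"]
        model.head1.weight.data = npz["head1_w"]
        model.head1.bias.data = npz["head1_b"]
        model.head2.weight.data = npz["head2_w"]
        model.head2.bias.data = npz["head2_b"]
        for name, blk in (("rdf1", model.rdf1), ("rdf2", model.rdf2)):
            wts = blk.get_weights()
            wts.w_std = npz[f"{name}_w_std"]
            wts.w_dil = [npz[f"{name}_w_dil_{i}"] for i in range(len(blk.cfg.branches))]
            wts.bn_gamma = npz[f"{name}_bn_gamma"]
            wts.bn_beta = npz[f"{name}_bn_beta"]
            wts.bn_mean = npz[f"{name}_bn_mean"]
            wts.bn_var = npz[f"{name}_bn_var"]
            blk.set_weights(wts)
        for name, dp in (("dp1", model.down1), ("dp2", model.down2)):
            dp.conv3.weight.data = npz[f"{name}_conv3_w"]
            dp.conv3.bias.data = npz[f"{name}_conv3_b"]
            dp.conv1.weight.data = npz[f"{name}_conv1_w"]
            dp.conv1.bias.data = npz[f"{name}_conv1_b"]
    return model
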