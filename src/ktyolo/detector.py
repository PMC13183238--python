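"""Detector wrapper: box decoding, target assignment, losses, NMS inference.

The head is anchor-free: each grid cell at pyramid level *l* (stride ``s``)
predicts, per side, a 16-bin distribution over the distance from the cell
center to the box edge (in stride units, softmax-expectation decoded) plus
independent per-class logits.  Assignment is center-cell: each ground truth
becomes one positive sample at the cell containing its center, on the level
selected by object size; all other cells are negatives.  The classification
loss is BCE, optionally slide-weighted on positives by the IoU between the
decoded box and its assigned ground truth; the box loss is an IoU loss plus
a distribution-focal term on the two bins bracketing each target distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evalmetrics import DetectionRecord, iou_matrix
from .losses import RunningMeanIoU, SlideLossParams, slide_weight
from .netgraph import ModelGraph, build_network
from .nn import SGD, sigmoid

__all__ = ["Detector", "DetLoss", "nms", "dataset_from_scenes"]

# object max-dimension boundaries (pixels) for pyramid level selection
LEVEL_BOUNDS = (96.0, 192.0)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thresh: float) -> list:
    """Greedy non-maximum suppression; returns kept indices, score order."""
    order = np.argsort(-scores, kind="stable")
    keep = []
    while order.size:
        i = order[0]
        keep.append(int(i))
        if order.size == 1:
            break
        ious = iou_matrix(boxes[i : i + 1], boxes[order[1:]])[0]
        order = order[1:][ious <= iou_thresh]
    return keep


def _softmax(z, axis):
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


@dataclass
class DetLoss:
    total: float
    cls: float
    box: float
    dfl: float
    n_pos: int
    mean_pos_iou: float


class Detector:
    """A runnable detector built from a :class:`ModelGraph`."""

    def __init__(self, graph: ModelGraph, seed: int = 0):
        if graph.layers[-1].kind != "detect_head":
            raise ValueError("graph must end in a detect_head layer")
        self.graph = graph
        self.config = graph.config
        rng = np.random.default_rng(seed)
        self.net, self.head = build_network(graph, rng)
        self.strides = graph.head_strides
        self.reg_max = graph.config.reg_max
        self.num_classes = graph.config.num_classes
        self.mu_tracker = RunningMeanIoU()

    # -- parameters ---------------------------------------------------------
    def parameters(self):
        return self.net.parameters() + self.head.parameters()

    def buffers(self):
        return self.net.buffers() + self.head.buffers()

    def state(self):
        return [a.copy() for p in self.parameters() for a in (p.value,)] + \
               [b.copy() for b in self.buffers()]

    def load_state(self, state):
        params = self.parameters()
        for p, v in zip(params, state[: len(params)]):
            p.value[...] = v
        for b, v in zip(self.buffers(), state[len(params) :]):
            b[...] = v

    # -- forward ------------------------------------------------------------
    def forward(self, images: np.ndarray, train: bool = False):
        feats = self.net(images, train=train)
        return self.head(feats, train=train)

    def _cell_centers(self, h, w, stride):
        ys, xs = np.mgrid[0:h, 0:w]
        return (xs + 0.5) * stride, (ys + 0.5) * stride

    def decode_level(self, box_logits: np.ndarray, stride: int):
        """(N, 4*reg_max, H, W) logits -> (boxes_xyxy (N,H,W,4), p, d)."""
        n, _, h, w = box_logits.shape
        r = self.reg_max
        z = box_logits.reshape(n, 4, r, h, w)
        p = _softmax(z, axis=2)
        d = (p * np.arange(r, dtype=np.float32)[None, None, :, None, None]).sum(axis=2)
        cx, cy = self._cell_centers(h, w, stride)
        boxes = np.stack(
            [
                cx[None] - d[:, 0] * stride,
                cy[None] - d[:, 1] * stride,
                cx[None] + d[:, 2] * stride,
                cy[None] + d[:, 3] * stride,
            ],
            axis=-1,
        )
        return boxes, p, d

    # -- inference ----------------------------------------------------------
    def predict(
        self,
        images: np.ndarray,
        image_ids=None,
        score_thresh: float = 0.01,
        nms_iou: float = 0.7,
        max_det: int = 300,
    ) -> list:
        """Run inference; returns per-image lists of DetectionRecords."""
        outs = self.forward(images, train=False)
        n = images.shape[0]
        image_ids = image_ids or [str(i) for i in range(n)]
        all_boxes = [[] for _ in range(n)]
        all_scores = [[] for _ in range(n)]
        all_classes = [[] for _ in range(n)]
        for (box_logits, cls_logits), stride in zip(outs, self.strides):
            boxes, _, _ = self.decode_level(box_logits, stride)
            probs = sigmoid(cls_logits)  # (N, nc, H, W)
            for i in range(n):
                b = boxes[i].reshape(-1, 4)
                s = probs[i].reshape(self.num_classes, -1).T  # (HW, nc)
                cls = s.argmax(axis=1)
                conf = s.max(axis=1)
                m = conf >= score_thresh
                all_boxes[i].append(b[m])
                all_scores[i].append(conf[m])
                all_classes[i].append(cls[m])
        results = []
        h_img, w_img = images.shape[2], images.shape[3]
        for i in range(n):
            b = np.concatenate(all_boxes[i]) if all_boxes[i] else np.zeros((0, 4))
            s = np.concatenate(all_scores[i]) if all_scores[i] else np.zeros(0)
            c = np.concatenate(all_classes[i]) if all_classes[i] else np.zeros(0, int)
            if len(s) > max_det * 4:  # pre-NMS candidate cap
                top = np.argsort(-s, kind="stable")[: max_det * 4]
                b, s, c = b[top], s[top], c[top]
            b[:, 0::2] = np.clip(b[:, 0::2], 0, w_img)
            b[:, 1::2] = np.clip(b[:, 1::2], 0, h_img)
            recs = []
            for cls in np.unique(c):
                m = c == cls
                keep = nms(b[m], s[m], nms_iou)
                idx = np.flatnonzero(m)[keep]
                for j in idx:
                    x1, y1, x2, y2 = b[j]
                    if x2 - x1 < 1e-3 or y2 - y1 < 1e-3:
                        continue
                    recs.append(
                        DetectionRecord(image_ids[i], int(cls), (x1, y1, x2, y2), float(s[j]))
                    )
            recs.sort(key=lambda r: -r.score)
            results.append(recs[:max_det])
        return results

    # -- training -----------------------------------------------------------
    def _assign(self, gts_boxes, gts_classes, level_shapes):
        """Center-cell assignment; larger objects assigned first so that on
        collision the smaller object keeps the cell."""
        targets = [dict() for _ in self.strides]  # (i,j) -> (ltrb_strides, cls)
        areas = (gts_boxes[:, 2] - gts_boxes[:, 0]) * (gts_boxes[:, 3] - gts_boxes[:, 1])
        for g in np.argsort(-areas, kind="stable"):
            x1, y1, x2, y2 = gts_boxes[g]
            m = max(x2 - x1, y2 - y1)
            lvl = 0 if m <= LEVEL_BOUNDS[0] else (1 if m <= LEVEL_BOUNDS[1] else 2)
            s = self.strides[lvl]
            h, w = level_shapes[lvl]
            cx, cy = (x1 + x2) / 2, (y1 + y2) / 2
            j, i = min(int(cx / s), w - 1), min(int(cy / s), h - 1)
            ax, ay = (j + 0.5) * s, (i + 0.5) * s
            ltrb = np.array([ax - x1, ay - y1, x2 - ax, y2 - ay]) / s
            ltrb = np.clip(ltrb, 0.01, self.reg_max - 1.01)
            targets[lvl][(i, j)] = (ltrb, int(gts_classes[g]))
        return targets

    def compute_loss_and_grads(self, outs, batch_gts, cls_loss: str = "bce",
                               slide_params: SlideLossParams | None = None):
        """Loss over a batch plus gradients w.r.t. head outputs.

        ``batch_gts`` is a list (per image) of (boxes (M,4), classes (M,)).
        Returns (DetLoss, grad list aligned with ``outs``, positive IoUs).
        """
        n = outs[0][0].shape[0]
        r = self.reg_max
        level_shapes = [bl.shape[2:] for bl, _ in outs]
        w_cls, w_box, w_dfl = 1.0, 5.0, 1.0

        grads = [(np.zeros_like(bl), np.zeros_like(cl)) for bl, cl in outs]
        cls_sum = box_sum = dfl_sum = 0.0
        n_pos = 0
        pos_ious: list = []

        # precompute decoded distributions per level
        decoded = [self.decode_level(bl, s) for (bl, _), s in zip(outs, self.strides)]

        # classification: start from the all-negative BCE field
        sig = [sigmoid(cl) for _, cl in outs]
        for img in range(n):
            boxes, classes = batch_gts[img]
            targets = (
                self._assign(boxes, classes, level_shapes)
                if len(boxes)
                else [dict() for _ in self.strides]
            )
            for lvl, ((box_logits, cls_logits), stride) in enumerate(zip(outs, self.strides)):
                p_all = sig[lvl][img]  # (nc, H, W)
                t_field = np.zeros_like(p_all)
                w_field = np.ones_like(p_all)
                z = decoded[lvl][1][img]  # softmax probs (4, r, H, W)
                d = decoded[lvl][2][img]  # expected distances (4, H, W)
                for (i, j), (ltrb_t, cls_id) in targets[lvl].items():
                    n_pos += 1
                    d_pred = d[:, i, j]
                    # IoU between decoded and target box (shared anchor point)
                    iw = min(d_pred[0], ltrb_t[0]) + min(d_pred[2], ltrb_t[2])
                    ih = min(d_pred[1], ltrb_t[1]) + min(d_pred[3], ltrb_t[3])
                    inter = max(iw, 0.0) * max(ih, 0.0)
                    area_p = (d_pred[0] + d_pred[2]) * (d_pred[1] + d_pred[3])
                    area_t = (ltrb_t[0] + ltrb_t[2]) * (ltrb_t[1] + ltrb_t[3])
                    union = area_p + area_t - inter + 1e-9
                    iou_val = float(np.clip(inter / union, 0.0, 1.0))
                    pos_ious.append(iou_val)
                    box_sum += 1.0 - iou_val
                    # d(1-IoU)/d(d_pred): subgradients of min() at the box edges
                    if inter > 0:
                        dI = np.array([
                            ih if d_pred[0] <= ltrb_t[0] else 0.0,
                            iw if d_pred[1] <= ltrb_t[1] else 0.0,
                            ih if d_pred[2] <= ltrb_t[2] else 0.0,
                            iw if d_pred[3] <= ltrb_t[3] else 0.0,
                        ])
                    else:
                        dI = np.zeros(4)
                    dA = np.array([
                        d_pred[1] + d_pred[3], d_pred[0] + d_pred[2],
                        d_pred[1] + d_pred[3], d_pred[0] + d_pred[2],
                    ])
                    dIoU_dd = (dI * union - inter * (dA - dI)) / (union * union)
                    dL_dd = -w_box * dIoU_dd  # loss is 1 - IoU
                    # through the softmax expectation: dz_k = p_k (k - d) dL/dd
                    bins = np.arange(r, dtype=np.float64)
                    p_bins = z[:, :, i, j]  # (4, r)
                    dz_box = p_bins * (bins[None, :] - d_pred[:, None]) * dL_dd[:, None]
                    # distribution-focal term on the two bracketing bins
                    lo = np.floor(ltrb_t).astype(int)
                    hi = np.minimum(lo + 1, r - 1)
                    w_hi = ltrb_t - lo
                    w_lo = 1.0 - w_hi
                    eps = 1e-9
                    dfl_sum += float(
                        -(w_lo * np.log(p_bins[np.arange(4), lo] + eps)
                          + w_hi * np.log(p_bins[np.arange(4), hi] + eps)).sum() / 4.0
                    )
                    t_dist = np.zeros((4, r))
                    t_dist[np.arange(4), lo] += w_lo
                    t_dist[np.arange(4), hi] += w_hi
                    dz_box += w_dfl * (p_bins - t_dist) / 4.0
                    grads[lvl][0][img, :, i, j] += dz_box.reshape(-1).astype(np.float32)
                    # classification target and slide weight for this cell
                    t_field[cls_id, i, j] = 1.0
                    if cls_loss == "slide" and slide_params is not None:
                        w_field[:, i, j] = slide_weight(iou_val, slide_params)
                # accumulate classification loss/grad for the whole field
                eps = 1e-9
                bce_field = -(t_field * np.log(p_all + eps) + (1 - t_field) * np.log(1 - p_all + eps))
                cls_sum += float((w_field * bce_field).sum())
                grads[lvl][1][img] += (w_cls * w_field * (p_all - t_field)).astype(np.float32)

        norm = max(n_pos, 1)
        loss = DetLoss(
            total=(w_cls * cls_sum + w_box * box_sum + w_dfl * dfl_sum) / norm,
            cls=cls_sum / norm,
            box=box_sum / norm,
            dfl=dfl_sum / norm,
            n_pos=n_pos,
            mean_pos_iou=float(np.mean(pos_ious)) if pos_ious else 0.0,
        )
        inv = 1.0 / norm
        grads = [(gb * inv, gc * inv) for gb, gc in grads]
        return loss, grads, pos_ious

    def train_step(self, images, batch_gts, optimizer: SGD, cls_loss="bce",
                   slide_params=None):
        outs = self.forward(images, train=True)
        loss, grads, pos_ious = self.compute_loss_and_grads(
            outs, batch_gts, cls_loss=cls_loss, slide_params=slide_params
        )
        if not np.isfinite(loss.total):
            raise FloatingPointError(f"non-finite loss: {loss}")
        optimizer.zero_grad()
        dfeats = self.head.backward(grads)
        self.net.backward(dfeats)
        optimizer.step()
        self.mu_tracker.update(pos_ious)
        return loss


def dataset_from_scenes(scenes) -> list:
    """(image_id, SyntheticScene) pairs -> training samples.

    Each sample: dict with image (3,H,W) float32 in [0,1], boxes (M,4),
    classes (M,), image_id and the capture/season tags.
    """
    samples = []
    for image_id, scene in scenes:
        img = scene.image.astype(np.float32).transpose(2, 0, 1) / 255.0
        boxes = np.array([r.box for r in scene.annotations], dtype=np.float64).reshape(-1, 4)
        classes = np.array([r.class_id for r in scene.annotations], dtype=np.int64)
        samples.append({
            "image": img,
            "boxes": boxes,
            "classes": classes,
            "image_id": image_id,
            "capture_tag": scene.spec.illumination,
            "season_tag": scene.spec.season,
        })
    return samples
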