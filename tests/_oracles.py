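"""Independent reference implementations used as test oracles.

These deliberately avoid the package's vectorized code paths: convolution is
an explicit five-fold loop, AP is an exhaustive sweep over score cutoffs,
and matching is re-derived from the greedy rule step by step.
"""

import numpy as np


def conv2d_ref(x, weight, bias=None, stride=1):
    """Dense same-padded convolution by explicit loops. x: (N,C,H,W)."""
    n, cin, h, w = x.shape
    cout, cin_w, k, _ = weight.shape
    assert cin == cin_w
    p = k // 2
    xp = np.zeros((n, cin, h + 2 * p, w + 2 * p), dtype=np.float64)
    xp[:, :, p : p + h, p : p + w] = x
    ho = (h + 2 * p - k) // stride + 1
    wo = (w + 2 * p - k) // stride + 1
    y = np.zeros((n, cout, ho, wo), dtype=np.float64)
    for b in range(n):
        for co in range(cout):
            for i in range(ho):
                for j in range(wo):
                    acc = 0.0
                    for ci in range(cin):
                        for ki in range(k):
                            for kj in range(k):
                                acc += (
                                    weight[co, ci, ki, kj]
                                    * xp[b, ci, i * stride + ki, j * stride + kj]
                                )
                    y[b, co, i, j] = acc
            if bias is not None:
                y[b, co] += bias[co]
    return y


def silu_ref(x):
    return x / (1.0 + np.exp(-x))


def convbn_ref(module, x, act=True):
    """Recompute a Conv+BN(+SiLU) unit in eval mode from its parameters."""
    y = conv2d_ref(
        np.asarray(x, dtype=np.float64),
        np.asarray(module.conv.weight.value, dtype=np.float64),
        stride=module.conv.stride,
    )
    bn = module.bn
    y = (y - bn.running_mean[None, :, None, None]) / np.sqrt(
        bn.running_var[None, :, None, None] + bn.eps
    )
    y = bn.gamma.value[None, :, None, None] * y + bn.beta.value[None, :, None, None]
    return silu_ref(y) if act else y


def kernel_team_ref(team, work):
    """Straight-line re-implementation of the kernel-team computation."""
    outs, at = [], 0
    for c, branch in zip(team.partition.group_channels, team.branches):
        outs.append(convbn_ref(branch, work[:, at : at + c]))
        at += c
    stacked = np.concatenate(outs, axis=1)
    return convbn_ref(team.fuse, stacked)


def ktf_block_ref(block, x):
    """Composition oracle for the full KTF block."""
    y = convbn_ref(block.entry, x)
    s = block.shortcut_channels
    if s > 0:
        merged = np.concatenate([y[:, :s], kernel_team_ref(block.team, y[:, s:])], axis=1)
    else:
        merged = kernel_team_ref(block.team, y)
    return convbn_ref(block.fuse, merged)


def iou_ref(a, b):
    ix1, iy1 = max(a[0], b[0]), max(a[1], b[1])
    ix2, iy2 = min(a[2], b[2]), min(a[3], b[3])
    if ix2 <= ix1 or iy2 <= iy1:
        return 0.0
    inter = (ix2 - ix1) * (iy2 - iy1)
    ua = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
    return inter / ua


def greedy_match_counts(det_boxes, det_scores, gt_boxes, thresh):
    """Greedy matching re-derived independently; returns (tp, fp, fn)."""
    order = sorted(range(len(det_boxes)), key=lambda i: -det_scores[i])
    taken = set()
    tp = fp = 0
    for i in order:
        cands = [
            (iou_ref(det_boxes[i], gt_boxes[g]), g)
            for g in range(len(gt_boxes))
            if g not in taken
        ]
        cands = [c for c in cands if c[0] >= thresh and c[0] > 0]
        if cands:
            best = max(cands, key=lambda c: c[0])
            taken.add(best[1])
            tp += 1
        else:
            fp += 1
    return tp, fp, len(gt_boxes) - len(taken)


def ap_exhaustive_cutoff(det_records, gt_records, thresh):
    """AP by enumerating every score cutoff and step-summing the enveloped
    precision-recall staircase (no interpolation grid, no cumulative-sum
    shortcut shared with the implementation)."""
    n_gt = len(gt_records)
    if n_gt == 0:
        raise ValueError("undefined")
    scores = sorted({d.score for d in det_records}, reverse=True)
    pr_points = []
    for cutoff in scores:
        kept = [d for d in det_records if d.score >= cutoff]
        # match per image with the greedy rule
        tp = fp = 0
        images = {g.image_id for g in gt_records} | {d.image_id for d in kept}
        for img in images:
            db = [d.box for d in kept if d.image_id == img]
            ds = [d.score for d in kept if d.image_id == img]
            gb = [g.box for g in gt_records if g.image_id == img]
            t, f, _ = greedy_match_counts(db, ds, gb, thresh)
            tp += t
            fp += f
        if tp + fp:
            pr_points.append((tp / n_gt, tp / (tp + fp)))
    pr_points.sort()
    # monotone envelope from the right
    recs = [0.0] + [r for r, _ in pr_points]
    pres = [None] + [p for _, p in pr_points]
    env = []
    best = 0.0
    for r, p in reversed(pr_points):
        best = max(best, p)
        env.append((r, best))
    env.reverse()
    ap = 0.0
    prev_r = 0.0
    for r, p in env:
        ap += (r - prev_r) * p
        prev_r = r
    return ap
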