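"""Independent brute-force oracles used to validate the library's fast paths.

These deliberately use naive per-pixel loops and set arithmetic, sharing no
code with the implementations they check.
"""

from __future__ import annotations

import numpy as np


def edge_oracle(mask: np.ndarray) -> np.ndarray:
    """Double-loop 8-neighbourhood boundary scan; out-of-bounds = background."""
    h, w = mask.shape
    out = np.zeros((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < h and 0 <= cc < w) or not mask[rr, cc]:
                        out[r, c] = True
    return out


def area_oracle(mask: np.ndarray, mm_per_px: float) -> float:
    """Accumulate the physical area pixel by pixel."""
    total = 0.0
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if mask[r, c]:
                total += mm_per_px * mm_per_px
    return total


def seg_metrics_oracle(pred: np.ndarray, gt: np.ndarray, theta: float):
    """Per-pixel mean accuracy / mean IoU and brute-force boundary F1."""
    accs, ious = [], []
    for cls in (0, 1):
        tp = fn = fp = 0
        for r in range(gt.shape[0]):
            for c in range(gt.shape[1]):
                p = int(pred[r, c]) == cls
                g = int(gt[r, c]) == cls
                tp += p and g
                fn += (not p) and g
                fp += p and (not g)
        if tp + fn > 0:
            accs.append(tp / (tp + fn))
        if tp + fn + fp > 0:
            ious.append(tp / (tp + fn + fp))
    mean_acc = float(np.mean(accs)) if accs else 1.0
    mean_iou = float(np.mean(ious)) if ious else 1.0

    bp = [tuple(p) for p in np.argwhere(edge_oracle(pred.astype(bool)))]
    bg = [tuple(p) for p in np.argwhere(edge_oracle(gt.astype(bool)))]
    if not bp and not bg:
        bf1 = 1.0
    elif not bp or not bg:
        bf1 = 0.0
    else:
        def frac_matched(src, dst):
            hits = 0
            for r, c in src:
                if min(np.hypot(r - r2, c - c2) for r2, c2 in dst) <= theta:
                    hits += 1
            return hits / len(src)

        precision = frac_matched(bp, bg)
        recall = frac_matched(bg, bp)
        bf1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return mean_acc, mean_iou, bf1


def ap_oracle(records, n_gt: int) -> float:
    """All-point-interpolated AP from (score, is_tp) records, by enumeration."""
    records = sorted(records, key=lambda t: -t[0])
    points = []
    tp = fp = 0
    for _, is_tp in records:
        tp += is_tp
        fp += not is_tp
        points.append((tp / n_gt, tp / (tp + fp)))
    ap = 0.0
    prev_r = 0.0
    for r, _ in points:
        if r > prev_r:
            p_max = max(p for r2, p in points if r2 >= r)
            ap += (r - prev_r) * p_max
            prev_r = r
    return ap
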