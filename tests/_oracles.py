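"""Independent brute-force oracles used by the test suite.

Everything here is written as plain per-pixel / per-item Python loops,
deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import math


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def naive_gray(image) -> list[list[float]]:
    """BT.601 luma by explicit per-pixel arithmetic."""
    h, w = len(image), len(image[0])
    return [
        [
            0.299 * float(image[i][j][0])
            + 0.587 * float(image[i][j][1])
            + 0.114 * float(image[i][j][2])
            for j in range(w)
        ]
        for i in range(h)
    ]


def _reflect(idx: int, n: int) -> int:
    # (d c b a | a b c d) border convention
    while idx < 0 or idx >= n:
        if idx < 0:
            idx = -idx - 1
        else:
            idx = 2 * n - 1 - idx
    return idx


def gaussian_kernel2d(kernel_size: int, sigma: float) -> list[list[float]]:
    radius = (kernel_size - 1) // 2
    k = [
        [
            math.exp(-(dx * dx + dy * dy) / (2.0 * sigma * sigma))
            for dx in range(-radius, radius + 1)
        ]
        for dy in range(-radius, radius + 1)
    ]
    total = sum(sum(row) for row in k)
    return [[v / total for v in row] for row in k]


def naive_blur(values, kernel_size: int, sigma: float) -> list[list[float]]:
    """Direct 2-D convolution with reflective borders."""
    if kernel_size == 1:
        return [list(row) for row in values]
    h, w = len(values), len(values[0])
    radius = (kernel_size - 1) // 2
    kernel = gaussian_kernel2d(kernel_size, sigma)
    out = [[0.0] * w for _ in range(h)]
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for dy in range(-radius, radius + 1):
                for dx in range(-radius, radius + 1):
                    ii = _reflect(i + dy, h)
                    jj = _reflect(j + dx, w)
                    acc += kernel[dy + radius][dx + radius] * values[ii][jj]
            out[i][j] = acc
    return out


def naive_gray_blur(image, kernel_size: int, sigma: float):
    return naive_blur(naive_gray(image), kernel_size, sigma)


def naive_l3(b_prev, b_k, b_next) -> list[list[float]]:
    h, w = len(b_k), len(b_k[0])
    return [
        [
            abs(b_k[i][j] - b_prev[i][j]) + abs(b_next[i][j] - b_k[i][j])
            for j in range(w)
        ]
        for i in range(h)
    ]


def naive_enhance(i_prev, i_k, i_next, kernel_size: int, sigma: float):
    """Full enhancement pipeline: returns an HxWx3 nested list of ints."""
    blurred = [naive_gray_blur(img, kernel_size, sigma) for img in (i_prev, i_k, i_next)]
    l3 = naive_l3(*blurred)
    h, w = len(l3), len(l3[0])
    out = [[[0, 0, 0] for _ in range(w)] for _ in range(h)]
    for i in range(h):
        for j in range(w):
            out[i][j][0] = min(255, max(0, round_half_up(l3[i][j])))
            out[i][j][1] = int(i_k[i][j][1])
            out[i][j][2] = min(
                255,
                max(0, round_half_up(0.5 * float(i_k[i][j][2]) + 0.5 * float(i_k[i][j][0]))),
            )
    return out


def pixel_iou(a, b, scale: int = 1) -> float:
    """IoU by pixel-set counting at integer resolution (boxes scaled up)."""
    ax0, ay0, ax1, ay1 = (int(round(v * scale)) for v in (a.xmin, a.ymin, a.xmax, a.ymax))
    bx0, by0, bx1, by1 = (int(round(v * scale)) for v in (b.xmin, b.ymin, b.xmax, b.ymax))
    pa = {(x, y) for x in range(ax0, ax1) for y in range(ay0, ay1)}
    pb = {(x, y) for x in range(bx0, bx1) for y in range(by0, by1)}
    union = len(pa | pb)
    return len(pa & pb) / union if union else 0.0


def optimal_tp_count(dets, anns, iou_fn, threshold: float) -> int:
    """Maximum one-to-one matching size over all assignments (exhaustive)."""
    edges = [
        (i, j)
        for i in range(len(dets))
        for j in range(len(anns))
        if iou_fn(dets[i].box, anns[j].box) > threshold
    ]

    best = 0

    def extend(used_d, used_a, count, start):
        nonlocal best
        best = max(best, count)
        for idx in range(start, len(edges)):
            i, j = edges[idx]
            if i not in used_d and j not in used_a:
                extend(used_d | {i}, used_a | {j}, count + 1, idx + 1)

    extend(frozenset(), frozenset(), 0, 0)
    return best


def naive_average_precision(ranked: list[tuple[float, bool]], n_annotations: int) -> float:
    """All-point interpolated AP from its definition, with explicit loops.

    For every rank where a true positive is collected, the recall step
    is weighted by the maximum precision achieved at that recall level
    or any higher one.
    """
    order = sorted(range(len(ranked)), key=lambda i: -ranked[i][0])
    seq = [ranked[i][1] for i in order]
    precisions, recalls = [], []
    tp = 0
    for rank, is_tp in enumerate(seq, start=1):
        if is_tp:
            tp += 1
        precisions.append(tp / rank)
        recalls.append(tp / n_annotations)
    ap = 0.0
    prev_r = 0.0
    for idx, r in enumerate(recalls):
        if r > prev_r:
            best_p = max(p for p, rr in zip(precisions, recalls) if rr >= r)
            ap += (r - prev_r) * best_p
            prev_r = r
    return ap
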