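"""Shared helpers: ground-truth matching and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def match_detections(detections, truth_cells, tol_px=2.0):
    """Greedy one-to-one matching of detections to ground-truth cells.

    Returns (n_matched, n_truth, n_detections).
    """
    used = set()
    hits = 0
    for _, x, y, _r in truth_cells:
        for i, d in enumerate(detections):
            if i in used:
                continue
            if (d.center_x_px - x) ** 2 + (d.center_y_px - y) ** 2 <= tol_px**2:
                hits += 1
                used.add(i)
                break
    return hits, len(truth_cells), len(detections)


def brute_force_circles(image, radius_min, radius_max, edge_threshold=50.0,
                        score_threshold=0.8, min_distance=5.0):
    """Exhaustive correlation search for circles: independent oracle.

    For every center and every integer radius, scores the fraction of the
    rasterised circle perimeter landing on edge pixels (gradient magnitude
    above threshold).  Greedy non-maximum suppression on the best radius per
    center.  O(W*H*R*perimeter) — only for tiny images.
    """
    img = np.asarray(image, dtype=float)
    gx = ndimage.sobel(img, axis=1, mode="reflect") / 8.0
    gy = ndimage.sobel(img, axis=0, mode="reflect") / 8.0
    edge = np.hypot(gx, gy) > edge_threshold
    h, w = img.shape

    rings = {}
    for r in range(radius_min, radius_max + 1):
        ang = np.linspace(0, 2 * np.pi, int(np.ceil(8 * r)), endpoint=False)
        pts = np.unique(
            np.stack([np.rint(r * np.cos(ang)), np.rint(r * np.sin(ang))],
                     axis=1).astype(int), axis=0)
        rings[r] = pts

    best_score = np.zeros((h, w))
    best_r = np.zeros((h, w), dtype=int)
    for r, pts in rings.items():
        for cy in range(r, h - r):
            for cx in range(r, w - r):
                on = edge[cy + pts[:, 1], cx + pts[:, 0]].mean()
                if on > best_score[cy, cx]:
                    best_score[cy, cx] = on
                    best_r[cy, cx] = r

    cand = np.argwhere(best_score > score_threshold)
    order = sorted(
        range(len(cand)),
        key=lambda i: (-best_score[cand[i][0], cand[i][1]],
                       cand[i][0], cand[i][1]),
    )
    kept = []
    for i in order:
        cy, cx = cand[i]
        if all((cx - kx) ** 2 + (cy - ky) ** 2 >= min_distance**2
               for kx, ky, _ in kept):
            kept.append((int(cx), int(cy), int(best_r[cy, cx])))
    return kept


def passing_bablok_brute(x, y):
    """Literal Passing-Bablok enumeration: all pairwise slopes, shifted median.

    Independent of the package implementation; used as the exact oracle.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    slopes = []
    for i in range(n):
        for j in range(i + 1, n):
            if x[j] != x[i]:
                s = (y[j] - y[i]) / (x[j] - x[i])
                if s != -1.0:
                    slopes.append(s)
    slopes.sort()
    big_n = len(slopes)
    k = sum(s < -1.0 for s in slopes)
    if big_n % 2:
        idx = (big_n + 1) // 2 + k
        b = slopes[min(max(idx, 1), big_n) - 1]
    else:
        i1 = min(max(big_n // 2 + k, 1), big_n) - 1
        i2 = min(max(big_n // 2 + 1 + k, 1), big_n) - 1
        b = 0.5 * (slopes[i1] + slopes[i2])
    resid = sorted(yy - b * xx for xx, yy in zip(x, y))
    m = len(resid)
    a = resid[m // 2] if m % 2 else 0.5 * (resid[m // 2 - 1] + resid[m // 2])
    return b, a
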