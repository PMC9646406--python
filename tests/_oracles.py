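"""Independent brute-force oracles used only by the test suite.

Everything here is deliberately naive — nested loops, explicit neighbor
stencils, O(n^2) distance scans — so it shares no code path with the
package implementations it cross-checks.
"""

from __future__ import annotations

import numpy as np

# 18-connectivity: all offsets with Chebyshev distance 1 except the 8 corners.
STENCIL_18 = [(i, j, k)
              for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
              if (i, j, k) != (0, 0, 0) and abs(i) + abs(j) + abs(k) <= 2]

STENCIL_6 = [(i, j, k)
             for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
             if abs(i) + abs(j) + abs(k) == 1]


def flood_fill_components(mask: np.ndarray, stencil=STENCIL_18) -> np.ndarray:
    """Label connected components by explicit flood fill."""
    mask = np.asarray(mask).astype(bool)
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    for seed in zip(*np.nonzero(mask)):
        if labels[seed]:
            continue
        current += 1
        queue = [seed]
        labels[seed] = current
        while queue:
            x, y, z = queue.pop()
            for dx, dy, dz in stencil:
                n = (x + dx, y + dy, z + dz)
                if all(0 <= c < s for c, s in zip(n, mask.shape)) \
                        and mask[n] and not labels[n]:
                    labels[n] = current
                    queue.append(n)
    return labels


def bounding_box(volume: np.ndarray):
    """(lower, upper) half-open box of voxels nonzero in any channel."""
    nz = np.any(np.asarray(volume) != 0, axis=0)
    coords = np.nonzero(nz)
    return (tuple(int(c.min()) for c in coords),
            tuple(int(c.max()) + 1 for c in coords))


def dice_by_loop(g: np.ndarray, y: np.ndarray) -> float:
    g = np.asarray(g).ravel()
    y = np.asarray(y).ravel()
    inter = sg = sy = 0
    for gi, yi in zip(g, y):
        inter += int(gi and yi)
        sg += int(gi)
        sy += int(yi)
    if sg + sy == 0:
        return 1.0
    return 2.0 * inter / (sg + sy)


def surface_voxels(mask: np.ndarray) -> list[tuple[int, int, int]]:
    """Mask voxels with at least one 6-neighbor outside the mask."""
    mask = np.asarray(mask).astype(bool)
    out = []
    for v in zip(*np.nonzero(mask)):
        for d in STENCIL_6:
            n = tuple(c + o for c, o in zip(v, d))
            outside = any(not 0 <= c < s for c, s in zip(n, mask.shape)) \
                or not mask[n]
            if outside:
                out.append(v)
                break
    return out


def hausdorff_by_loop(g: np.ndarray, y: np.ndarray, voxel_size) -> float:
    sp = np.asarray(voxel_size, dtype=float)
    pg = [np.asarray(v) * sp for v in surface_voxels(g)]
    py = [np.asarray(v) * sp for v in surface_voxels(y)]
    d_gy = max(min(np.linalg.norm(a - b) for b in py) for a in pg)
    d_yg = max(min(np.linalg.norm(a - b) for b in pg) for a in py)
    return max(d_gy, d_yg)


def detection_counts_by_loop(g_labels: np.ndarray, y_labels: np.ndarray,
                             overlap_fraction: float) -> tuple[int, int, int]:
    tp = fn = fp = 0
    for lbl in range(1, int(g_labels.max()) + 1):
        sel = g_labels == lbl
        frac = np.logical_and(sel, y_labels > 0).sum() / sel.sum()
        if frac >= overlap_fraction:
            tp += 1
        else:
            fn += 1
    for lbl in range(1, int(y_labels.max()) + 1):
        if not np.logical_and(y_labels == lbl, g_labels > 0).any():
            fp += 1
    return tp, fp, fn


def dice_focal_by_loop(G: np.ndarray, P: np.ndarray, epsilon: float,
                       gamma: float, p_min: float = 1e-7
                       ) -> tuple[float, float]:
    """Scalar-loop soft Dice and focal losses on one (J, N) example."""
    J, N = G.shape
    inter = norm_g = norm_p = 0.0
    focal = 0.0
    for j in range(J):
        for n in range(N):
            inter += G[j, n] * P[j, n]
            norm_g += G[j, n] ** 2
            norm_p += P[j, n] ** 2
            p = min(max(P[j, n], p_min), 1 - p_min)
            focal += G[j, n] * (1 - p) ** gamma * np.log(p)
    dice = 1.0 - (2.0 * inter + epsilon) / (norm_g + norm_p + epsilon)
    return dice, -focal / N
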