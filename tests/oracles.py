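"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately naive (queue-based flood fill, per-pixel loops) and
share no code with the package.
"""

from collections import deque

import numpy as np


def bfs_flood_fill_label(mask, connectivity=8):
    """Breadth-first flood-fill labeling of foreground pixels.

    Returns (label_map, n_objects) with labels 1..n in discovery order.
    """
    mask = np.asarray(mask)
    h, w = mask.shape
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)]
    labels = np.zeros((h, w), dtype=int)
    n = 0
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and not labels[r0, c0]:
                n += 1
                labels[r0, c0] = n
                queue = deque([(r0, c0)])
                while queue:
                    r, c = queue.popleft()
                    for dr, dc in nbrs:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] \
                                and not labels[rr, cc]:
                            labels[rr, cc] = n
                            queue.append((rr, cc))
    return labels, n


def loop_pixel_confusion(predicted, truth):
    """Per-pixel loop confusion counts: (tp, tn, fp, fn)."""
    tp = tn = fp = fn = 0
    for p, t in zip(np.asarray(predicted).ravel(), np.asarray(truth).ravel()):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    return tp, tn, fp, fn


def same_partition(labels_a, labels_b):
    """True if two label maps induce the same partition of the foreground
    (identical up to relabeling)."""
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    fg = (a > 0) | (b > 0)
    if not ((a > 0) == (b > 0)).all():
        return False
    pairs = set(zip(a[fg].tolist(), b[fg].tolist()))
    return len(pairs) == len({p[0] for p in pairs}) == len({p[1] for p in pairs})
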