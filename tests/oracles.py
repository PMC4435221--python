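"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: the Otsu oracle minimises
the pooled within-class variance directly on the raw values, and the
segmentation oracle replays the documented mutual-best-fit rounds with plain
Python dict/set bookkeeping, recomputing every statistic from pixel sets.
"""

from __future__ import annotations

import math

import numpy as np


def otsu_within_class_oracle(values, n_bins: int = 256) -> float:
    """Threshold minimising within-class variance over the same bin boundaries."""
    values = np.asarray(values, dtype=float).ravel()
    values = values[np.isfinite(values)]
    lo, hi = values.min(), values.max()
    edges = np.linspace(lo, hi, n_bins + 1)
    best: float | None = None
    best_ts: list[float] = []
    for t in edges[1:-1]:
        left = values[values < t]
        right = values[values >= t]
        if left.size == 0 or right.size == 0:
            continue
        w = (left.size * left.var() + right.size * right.var()) / values.size
        if best is None or w < best - 1e-12 * max(abs(best), 1.0):
            best, best_ts = w, [t]
        elif abs(w - best) <= 1e-12 * max(abs(best), 1.0):
            best_ts.append(t)
    return (best_ts[0] + best_ts[-1]) / 2.0


# ---------------------------------------------------------------------------
# Region-merging oracle
# ---------------------------------------------------------------------------


def _pop_sd(pixvals: list[float]) -> float:
    n = len(pixvals)
    s = sum(pixvals)
    q = sum(v * v for v in pixvals)
    var = q / n - (s / n) ** 2
    return math.sqrt(max(var, 0.0))


def _perimeter(pixels: set[tuple[int, int]]) -> int:
    per = 0
    for (r, c) in pixels:
        for (dr, dc) in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            if (r + dr, c + dc) not in pixels:
                per += 1
    return per


def _shared_edges(p1: set, p2: set) -> int:
    count = 0
    for (r, c) in p1:
        for (dr, dc) in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            if (r + dr, c + dc) in p2:
                count += 1
    return count


def _merge_cost(p1: set, p2: set, values: np.ndarray, params) -> float:
    n1, n2 = len(p1), len(p2)
    nm = n1 + n2
    nb = values.shape[2]
    d_colour = 0.0
    for b in range(nb):
        v1 = [float(values[r, c, b]) for (r, c) in p1]
        v2 = [float(values[r, c, b]) for (r, c) in p2]
        w_b = params.band_weights[b] if params.band_weights is not None else 1.0
        d_colour += w_b * (nm * _pop_sd(v1 + v2) - n1 * _pop_sd(v1) - n2 * _pop_sd(v2))

    def shape_terms(pix):
        n = len(pix)
        l = _perimeter(pix)
        rs = [r for r, _ in pix]
        cs = [c for _, c in pix]
        b = 2 * ((max(rs) - min(rs) + 1) + (max(cs) - min(cs) + 1))
        return n * (l / math.sqrt(n)), n * (l / b)

    cm, sm = shape_terms(p1 | p2)
    c1, s1 = shape_terms(p1)
    c2, s2 = shape_terms(p2)
    d_shape = params.compactness_weight * (cm - c1 - c2) + params.smoothness_weight * (sm - s1 - s2)
    return params.colour_weight * d_colour + params.shape_weight * d_shape


def oracle_segment(values: np.ndarray, params) -> set[frozenset]:
    """Final partition (as a set of frozensets of (r, c)) by brute force."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 2:
        values = values[:, :, None]
    h, w = values.shape[:2]
    # object key = smallest row-major flat index of its pixels
    objects: dict[int, set] = {r * w + c: {(r, c)} for r in range(h) for c in range(w)}
    threshold = params.scale * params.scale

    while True:
        # adjacency between objects
        owner = {}
        for key, pix in objects.items():
            for p in pix:
                owner[p] = key
        neighbours: dict[int, set[int]] = {k: set() for k in objects}
        for (r, c) in owner:
            for (dr, dc) in ((1, 0), (0, 1)):
                q = (r + dr, c + dc)
                if q in owner and owner[q] != owner[(r, c)]:
                    neighbours[owner[(r, c)]].add(owner[q])
                    neighbours[owner[q]].add(owner[(r, c)])

        best: dict[int, tuple[float, int]] = {}
        for k in objects:
            cands = []
            for nb in neighbours[k]:
                cost = _merge_cost(objects[k], objects[nb], values, params)
                if cost < threshold:
                    cands.append((cost, nb))
            if cands:
                best[k] = min(cands)  # (cost, lowest rep) tie-break

        merges = []
        for k, (_, nb) in best.items():
            if k < nb and nb in best and best[nb][1] == k:
                merges.append((k, nb))
        if not merges:
            break
        for a, b in merges:
            objects[a] = objects[a] | objects[b]
            del objects[b]
    return {frozenset(p) for p in objects.values()}


def labels_to_partition(labels: np.ndarray) -> set[frozenset]:
    out = {}
    h, w = labels.shape
    for r in range(h):
        for c in range(w):
            if labels[r, c] >= 0:
                out.setdefault(int(labels[r, c]), set()).add((r, c))
    return {frozenset(p) for p in out.values()}
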