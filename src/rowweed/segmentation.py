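"""Sub-plot gridding and multiresolution region-merging segmentation.

The image is analysed in square sub-plots (default 5 x 5 m) to absorb the
spatial and spectral variability of a crop field.  Within each sub-plot the
raster is segmented bottom-up: every valid pixel starts as its own object and
adjacent objects merge while the *increase in heterogeneity* caused by the
merge stays below ``scale**2``.

For a candidate merge of objects 1 and 2 into *m* the cost is

    f = w_colour * dh_colour + w_shape * dh_shape
    dh_colour = sum_b w_b * (n_m s_m,b - n_1 s_1,b - n_2 s_2,b)
    dh_shape  = w_cmpct * d(n*l/sqrt(n)) + w_smooth * d(n*l/b)

with ``n`` pixel count, ``s`` per-band population standard deviation, ``l``
perimeter in exposed pixel edges and ``b`` the perimeter of the axis-aligned
bounding box.  Defaults (scale 10, colour 0.9, shape 0.1, smoothness 0.5,
compactness 0.5) suit 8-bit-range band values at centimetre resolutions.

Merging proceeds in deterministic synchronous rounds of *mutual best
fitting*: each object points at its admissible minimum-cost neighbour (ties
broken towards the neighbour whose smallest pixel index is lowest); pairs
that point at each other merge simultaneously.  Rounds repeat until no
admissible mutual pair remains.  Object identity is anchored on the smallest
flat (row-major) pixel index contained in the object, which makes the whole
procedure reproducible and oracle-checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError
from .geometry import FieldImage


@dataclass(frozen=True)
class SegmentationParams:
    """Weights of the region-merging criterion.

    ``colour_weight + shape_weight == 1`` and
    ``smoothness_weight + compactness_weight == 1``.
    """

    scale: float = 10.0
    colour_weight: float = 0.9
    shape_weight: float = 0.1
    smoothness_weight: float = 0.5
    compactness_weight: float = 0.5
    band_weights: tuple[float, ...] | None = None  # defaults to 1 per band

    def __post_init__(self) -> None:
        if self.scale < 0:
            raise InvalidArgumentError("scale must be non-negative")
        if abs(self.colour_weight + self.shape_weight - 1.0) > 1e-9:
            raise InvalidArgumentError("colour_weight + shape_weight must equal 1")
        if abs(self.smoothness_weight + self.compactness_weight - 1.0) > 1e-9:
            raise InvalidArgumentError("smoothness_weight + compactness_weight must equal 1")
        if self.band_weights is not None and any(w < 0 for w in self.band_weights):
            raise InvalidArgumentError("band weights must be non-negative")


# ---------------------------------------------------------------------------
# Sub-plot grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubplotGrid:
    """Rectangular windows (half-open ``(r0, c0, r1, c1)``) tiling the image."""

    windows: tuple[tuple[int, int, int, int], ...]
    nominal_size_m: float
    side_px: int


def grid_subplots(image: FieldImage, size_m: float = 5.0) -> SubplotGrid:
    """Tile the image into square sub-plots of nominal side ``size_m``.

    The window side in pixels is ``round(size_m / gsd_m)``; partial windows
    along the right/bottom edges are retained.
    """
    if size_m <= 0:
        raise InvalidArgumentError("sub-plot size must be positive")
    side = int(round(size_m / image.gsd_m))
    if side < 1:
        raise InvalidArgumentError(
            f"sub-plot size {size_m} m is smaller than one pixel ({image.gsd_m} m)"
        )
    h, w = image.shape
    windows = []
    for r0 in range(0, h, side):
        for c0 in range(0, w, side):
            windows.append((r0, c0, min(r0 + side, h), min(c0 + side, w)))
    return SubplotGrid(windows=tuple(windows), nominal_size_m=size_m, side_px=side)


# ---------------------------------------------------------------------------
# Object map
# ---------------------------------------------------------------------------


@dataclass
class ObjectMap:
    """A partition of a raster into contiguous multi-pixel objects.

    ``labels`` assigns each valid pixel an object id in ``[0, n_objects)``
    (-1 = nodata).  Objects are 4-connected.  Aggregate statistics are kept as
    sums so they combine exactly under merging.
    """

    labels: np.ndarray
    size: np.ndarray  # (n,)
    band_sum: np.ndarray  # (n, B)
    band_sumsq: np.ndarray  # (n, B)
    perimeter: np.ndarray  # (n,) exposed pixel edges
    bbox: np.ndarray  # (n, 4) r0, c0, r1, c1 (half-open)
    centroid_sum: np.ndarray  # (n, 2) sums of (row + .5, col + .5)
    edges: np.ndarray  # (E, 2) unique undirected adjacency pairs, a < b

    @property
    def n_objects(self) -> int:
        return int(self.size.shape[0])

    @property
    def band_mean(self) -> np.ndarray:
        return self.band_sum / self.size[:, None]

    @property
    def band_std(self) -> np.ndarray:
        """Per-band population standard deviation."""
        var = self.band_sumsq / self.size[:, None] - self.band_mean**2
        return np.sqrt(np.maximum(var, 0.0))

    @property
    def centroid_rc(self) -> np.ndarray:
        """Centroid in pixel-centre coordinates (row, col)."""
        return self.centroid_sum / self.size[:, None]

    def centroid_world(self, gsd_m: float, origin: tuple[float, float]) -> np.ndarray:
        """Centroids as world (x, y)."""
        rc = self.centroid_rc
        x = origin[0] + rc[:, 1] * gsd_m
        y = origin[1] - rc[:, 0] * gsd_m
        return np.column_stack([x, y])

    def adjacency_sets(self) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in range(self.n_objects)]
        for a, b in self.edges:
            adj[int(a)].add(int(b))
            adj[int(b)].add(int(a))
        return adj

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_objects))
        g.add_edges_from(map(tuple, self.edges))
        return g

    @staticmethod
    def from_labels(values: np.ndarray, labels: np.ndarray) -> "ObjectMap":
        """Recompute all object statistics and adjacency from a label raster.

        ``values`` is (H, W, B); ``labels`` is (H, W) with -1 for nodata.
        Object ids must already be compact (0..n-1).
        """
        values = np.asarray(values, dtype=np.float64)
        if values.ndim == 2:
            values = values[:, :, None]
        labels = np.asarray(labels)
        h, w = labels.shape
        n = int(labels.max()) + 1 if labels.size and labels.max() >= 0 else 0
        flat = labels.ravel()
        ok = flat >= 0
        lab = flat[ok]
        size = np.bincount(lab, minlength=n).astype(np.int64)
        nb = values.shape[2]
        vals = values.reshape(-1, nb)[ok]
        band_sum = np.zeros((n, nb))
        band_sumsq = np.zeros((n, nb))
        for b in range(nb):
            band_sum[:, b] = np.bincount(lab, weights=vals[:, b], minlength=n)
            band_sumsq[:, b] = np.bincount(lab, weights=vals[:, b] ** 2, minlength=n)
        rr, cc = np.divmod(np.flatnonzero(ok.reshape(h, w).ravel()), w)
        centroid_sum = np.zeros((n, 2))
        centroid_sum[:, 0] = np.bincount(lab, weights=rr + 0.5, minlength=n)
        centroid_sum[:, 1] = np.bincount(lab, weights=cc + 0.5, minlength=n)
        bbox = np.zeros((n, 4), dtype=np.int64)
        if n:
            bbox[:, 0] = h
            bbox[:, 1] = w
            np.minimum.at(bbox[:, 0], lab, rr)
            np.minimum.at(bbox[:, 1], lab, cc)
            np.maximum.at(bbox[:, 2], lab, rr + 1)
            np.maximum.at(bbox[:, 3], lab, cc + 1)

        # perimeter: each pixel side not shared with a same-object pixel
        perimeter = 4 * size.copy()
        pairs = []
        for (la, lb) in (
            (labels[:, :-1].ravel(), labels[:, 1:].ravel()),
            (labels[:-1, :].ravel(), labels[1:, :].ravel()),
        ):
            both = (la >= 0) & (lb >= 0)
            la, lb = la[both], lb[both]
            same = la == lb
            np.subtract.at(perimeter, la[same], 1)
            np.subtract.at(perimeter, lb[same], 1)
            cross = ~same
            if cross.any():
                pairs.append(np.column_stack([la[cross], lb[cross]]))
        if pairs:
            e = np.concatenate(pairs)
            e = np.sort(e, axis=1)
            edges = np.unique(e, axis=0)
        else:
            edges = np.empty((0, 2), dtype=np.int64)
        return ObjectMap(
            labels=labels,
            size=size,
            band_sum=band_sum,
            band_sumsq=band_sumsq,
            perimeter=perimeter.astype(np.int64),
            bbox=bbox,
            centroid_sum=centroid_sum,
            edges=edges,
        )


# ---------------------------------------------------------------------------
# Merge criterion
# ---------------------------------------------------------------------------


def _stats_cost(
    n1, s1, q1, l1, bb1, n2, s2, q2, l2, bb2, shared, params: SegmentationParams, band_w
):
    """Vectorised heterogeneity increase for candidate merges.

    All arguments are arrays over candidate pairs; ``s``/``q`` are per-band
    value sums and sums of squares, ``l`` perimeters, ``bb`` bounding boxes,
    ``shared`` the number of pixel edges shared by the pair.
    """
    nm = n1 + n2
    sm = s1 + s2
    qm = q1 + q2

    def pop_sd(n, s, q):
        mean = s / n[:, None]
        var = q / n[:, None] - mean**2
        return np.sqrt(np.maximum(var, 0.0))

    sd1 = pop_sd(n1, s1, q1)
    sd2 = pop_sd(n2, s2, q2)
    sdm = pop_sd(nm, sm, qm)
    d_colour = np.sum(band_w[None, :] * (nm[:, None] * sdm - n1[:, None] * sd1 - n2[:, None] * sd2), axis=1)

    lm = l1 + l2 - 2 * shared
    r0 = np.minimum(bb1[:, 0], bb2[:, 0])
    c0 = np.minimum(bb1[:, 1], bb2[:, 1])
    r1 = np.maximum(bb1[:, 2], bb2[:, 2])
    c1 = np.maximum(bb1[:, 3], bb2[:, 3])
    bm = 2 * ((r1 - r0) + (c1 - c0))
    b1 = 2 * ((bb1[:, 2] - bb1[:, 0]) + (bb1[:, 3] - bb1[:, 1]))
    b2 = 2 * ((bb2[:, 2] - bb2[:, 0]) + (bb2[:, 3] - bb2[:, 1]))

    d_cmpct = nm * (lm / np.sqrt(nm)) - n1 * (l1 / np.sqrt(n1)) - n2 * (l2 / np.sqrt(n2))
    d_smooth = nm * (lm / bm) - n1 * (l1 / b1) - n2 * (l2 / b2)
    d_shape = params.compactness_weight * d_cmpct + params.smoothness_weight * d_smooth
    return params.colour_weight * d_colour + params.shape_weight * d_shape


def heterogeneity_increase(
    o1: dict, o2: dict, params: SegmentationParams, shared_edges: int = 1
) -> float:
    """Heterogeneity increase for merging two object records.

    Each record is a dict with keys ``n`` (pixel count), ``sum`` and
    ``sumsq`` (per-band value sums), ``l`` (perimeter), ``bbox``
    (r0, c0, r1, c1).  ``shared_edges`` is the length of the common border in
    pixel edges.
    """
    nb = len(np.atleast_1d(o1["sum"]))
    band_w = (
        np.asarray(params.band_weights, dtype=np.float64)
        if params.band_weights is not None
        else np.ones(nb)
    )

    def arr(o, key):
        return np.atleast_2d(np.asarray(o[key], dtype=np.float64))

    out = _stats_cost(
        np.asarray([o1["n"]], dtype=np.float64),
        arr(o1, "sum"),
        arr(o1, "sumsq"),
        np.asarray([o1["l"]], dtype=np.float64),
        np.asarray([o1["bbox"]], dtype=np.float64),
        np.asarray([o2["n"]], dtype=np.float64),
        arr(o2, "sum"),
        arr(o2, "sumsq"),
        np.asarray([o2["l"]], dtype=np.float64),
        np.asarray([o2["bbox"]], dtype=np.float64),
        np.asarray([shared_edges], dtype=np.float64),
        params,
        band_w,
    )
    return float(out[0])


# ---------------------------------------------------------------------------
# Region merging
# ---------------------------------------------------------------------------


def multiresolution_segment(
    values: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
    valid: np.ndarray | None = None,
    max_rounds: int = 10_000,
) -> ObjectMap:
    """Segment a (window of a) raster by mutual-best-fit region merging.

    Parameters
    ----------
    values : (H, W, B) array
        Band values of the window.  The scale parameter is calibrated for an
        8-bit-like dynamic range; callers with reflectance data should scale
        it (the pipeline driver multiplies reflectances by 255).
    valid : (H, W) bool, optional
        False marks nodata pixels, which receive label -1.

    Returns
    -------
    ObjectMap
        Final object partition of the window with compact ids ordered by each
        object's smallest row-major pixel index.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim == 2:
        values = values[:, :, None]
    h, w, nb = values.shape
    if valid is None:
        valid = np.all(np.isfinite(values), axis=2)
    else:
        valid = np.asarray(valid, dtype=bool) & np.all(np.isfinite(values), axis=2)
    band_w = (
        np.asarray(params.band_weights, dtype=np.float64)
        if params.band_weights is not None
        else np.ones(nb)
    )
    if band_w.shape[0] != nb:
        raise InvalidArgumentError("band_weights length does not match band count")

    n_valid = int(valid.sum())
    labels = np.full((h, w), -1, dtype=np.int64)
    if n_valid == 0:
        return ObjectMap(
            labels=labels,
            size=np.zeros(0, dtype=np.int64),
            band_sum=np.zeros((0, nb)),
            band_sumsq=np.zeros((0, nb)),
            perimeter=np.zeros(0, dtype=np.int64),
            bbox=np.zeros((0, 4), dtype=np.int64),
            centroid_sum=np.zeros((0, 2)),
            edges=np.empty((0, 2), dtype=np.int64),
        )

    flat_idx = np.flatnonzero(valid.ravel())
    labels.ravel()[flat_idx] = np.arange(n_valid)

    # object state (index = current object id; ids stay sorted by rep)
    rep = flat_idx.copy()  # smallest row-major pixel index in object
    rr, cc = np.divmod(flat_idx, w)
    size = np.ones(n_valid, dtype=np.float64)
    bsum = values.reshape(-1, nb)[flat_idx].copy()
    bsumsq = bsum**2
    perim = np.full(n_valid, 4.0)
    bbox = np.column_stack([rr, cc, rr + 1, cc + 1]).astype(np.float64)
    csum = np.column_stack([rr + 0.5, cc + 0.5]).astype(np.float64)

    # adjacency edges with shared-border counts
    pair_list = []
    for (la, lb) in (
        (labels[:, :-1].ravel(), labels[:, 1:].ravel()),
        (labels[:-1, :].ravel(), labels[1:, :].ravel()),
    ):
        both = (la >= 0) & (lb >= 0)
        pair_list.append(np.column_stack([la[both], lb[both]]))
    if pair_list and sum(p.shape[0] for p in pair_list):
        e = np.concatenate(pair_list)
        e = np.sort(e, axis=1)
        edges = np.unique(e, axis=0)
        shared = np.ones(edges.shape[0], dtype=np.float64)
    else:
        edges = np.empty((0, 2), dtype=np.int64)
        shared = np.zeros(0)

    threshold = params.scale * params.scale
    owner = np.arange(n_valid)  # union-find-ish map applied per round

    for _ in range(max_rounds):
        if edges.shape[0] == 0:
            break
        a, b = edges[:, 0], edges[:, 1]
        cost = _stats_cost(
            size[a], bsum[a], bsumsq[a], perim[a], bbox[a],
            size[b], bsum[b], bsumsq[b], perim[b], bbox[b],
            shared, params, band_w,
        )
        ok = cost < threshold
        if not ok.any():
            break
        ea, eb, ec = a[ok], b[ok], cost[ok]
        # directed view: each endpoint sees the other as a candidate
        node = np.concatenate([ea, eb])
        nbr = np.concatenate([eb, ea])
        nbr_rep = rep[nbr]
        ccost = np.concatenate([ec, ec])
        # best neighbour per node: min cost, ties -> smaller neighbour rep
        order = np.lexsort((nbr_rep, ccost, node))
        node_o = node[order]
        first = np.ones(node_o.shape[0], dtype=bool)
        first[1:] = node_o[1:] != node_o[:-1]
        best_node = node_o[first]
        best_nbr = nbr[order][first]
        best = np.full(size.shape[0], -1, dtype=np.int64)
        best[best_node] = best_nbr
        # mutual pairs (a matching: every object has exactly one best)
        mutual = (best[best[best_node]] == best_node) & (best_node < best[best_node])
        pa = best_node[mutual]
        pb = best[best_node][mutual]
        if pa.size == 0:
            break

        # shared border length of each merging pair (edges are sorted a<b)
        key_edges = edges[:, 0] * n_valid + edges[:, 1]
        key_pairs = np.minimum(pa, pb) * n_valid + np.maximum(pa, pb)
        pos = np.searchsorted(key_edges, key_pairs)
        pair_shared = shared[pos]

        # merge pb into pa (pa keeps the smaller current id; reps follow)
        size[pa] += size[pb]
        bsum[pa] += bsum[pb]
        bsumsq[pa] += bsumsq[pb]
        perim[pa] += perim[pb] - 2.0 * pair_shared
        bbox[pa, 0] = np.minimum(bbox[pa, 0], bbox[pb, 0])
        bbox[pa, 1] = np.minimum(bbox[pa, 1], bbox[pb, 1])
        bbox[pa, 2] = np.maximum(bbox[pa, 2], bbox[pb, 2])
        bbox[pa, 3] = np.maximum(bbox[pa, 3], bbox[pb, 3])
        csum[pa] += csum[pb]
        rep[pa] = np.minimum(rep[pa], rep[pb])

        owner[:] = np.arange(size.shape[0])
        owner[pb] = pa
        keep = np.ones(size.shape[0], dtype=bool)
        keep[pb] = False
        # compact ids, preserving rep order (pa ids are already rep-minimal
        # within their pair; global order by rep is restored by sorting)
        new_ids = np.cumsum(keep) - 1
        remap = new_ids[owner]

        rep = rep[keep]
        order2 = np.argsort(rep, kind="stable")
        rank = np.empty_like(order2)
        rank[order2] = np.arange(order2.shape[0])
        remap = rank[remap]
        rep = rep[order2]
        size = size[keep][order2]
        bsum = bsum[keep][order2]
        bsumsq = bsumsq[keep][order2]
        perim = perim[keep][order2]
        bbox = bbox[keep][order2]
        csum = csum[keep][order2]
        owner = np.arange(size.shape[0])

        # contract edges
        e2 = remap[edges]
        e2 = np.sort(e2, axis=1)
        live = e2[:, 0] != e2[:, 1]
        e2 = e2[live]
        sh2 = shared[live]
        key = e2[:, 0] * n_valid + e2[:, 1]
        uniq, inv = np.unique(key, return_inverse=True)
        shared = np.zeros(uniq.shape[0])
        np.add.at(shared, inv, sh2)
        edges = np.column_stack([uniq // n_valid, uniq % n_valid])

        lab_flat = labels.ravel()
        lab_flat[flat_idx] = remap[lab_flat[flat_idx]]

    return ObjectMap(
        labels=labels,
        size=size.astype(np.int64),
        band_sum=bsum,
        band_sumsq=bsumsq,
        perimeter=perim.astype(np.int64),
        bbox=bbox.astype(np.int64),
        centroid_sum=csum,
        edges=edges.astype(np.int64),
    )


def segment_subplots(
    image_values: np.ndarray,
    grid: SubplotGrid,
    params: SegmentationParams = SegmentationParams(),
) -> np.ndarray:
    """Segment every sub-plot independently; return a global label raster.

    Objects never straddle sub-plot borders.  Ids are compact over the whole
    image, blocks numbered in grid order.
    """
    values = np.asarray(image_values, dtype=np.float64)
    if values.ndim == 2:
        values = values[:, :, None]
    h, w = values.shape[:2]
    labels = np.full((h, w), -1, dtype=np.int64)
    offset = 0
    for (r0, c0, r1, c1) in grid.windows:
        om = multiresolution_segment(values[r0:r1, c0:c1], params)
        sub = om.labels.copy()
        sub[sub >= 0] += offset
        labels[r0:r1, c0:c1] = sub
        offset += om.n_objects
    return labels
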