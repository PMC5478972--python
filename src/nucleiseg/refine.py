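"""Splitting of touching and overlapping nuclei.

The coarse watershed leaves clumps of overlapping nuclei as single regions.
Each region is refined independently under the assumption that a nucleus is
approximately elliptical:

1. The *gradient-weighted distance transform*
   ``Dg = D * exp(1 - (G - Gmin)/(Gmax - Gmin))`` combines the Euclidean
   distance map ``D`` of the region mask with the gradient image ``G``:
   ``Dg`` is high near object centers and depressed at high-gradient
   internal boundaries, so its regional maxima are candidate nucleus
   centers.  With ``n`` maxima the region holds at most ``n`` nuclei.
2. For every hypothesis ``K = 1..n`` the maxima are grouped into ``K``
   clusters (k-means, deterministic farthest-point initialization), each
   cluster is fused into one connected internal marker by rasterizing its
   Euclidean minimum spanning tree, and a marker-controlled watershed of
   the minima-imposed gradient splits the region into ``K`` sub-regions.
3. An ellipse is fitted to every sub-region by matching second-order
   moments, and the hypothesis is scored by the ellipse-fit objective
   ``xi(K)`` = (pixels inside a fitted ellipse but outside the region)
   + (region pixels outside every fitted ellipse) — the pixel count of the
   symmetric difference between the region and its K-ellipse cover.
4. The ``K`` minimizing ``xi`` (ties -> smaller K) gives the estimated
   nucleus count and the final split for that region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree as _sparse_mst
from scipy.spatial.distance import cdist
from skimage.draw import line as _draw_line
from skimage.measure import label as cc_label
from skimage.morphology import disk, local_maxima
from skimage.morphology import erosion as _binary_erosion

from .config import PipelineConfig
from .segment import (
    FOOTPRINT_8,
    euclidean_distance_map,
    impose_minima,
    marker_watershed,
)

__all__ = [
    "RegionView",
    "MaximaSet",
    "Clustering",
    "Ellipse",
    "SplitCandidate",
    "extract_regions",
    "gradient_weighted_distance",
    "regional_maxima",
    "kmeans_cluster",
    "mst_markers",
    "region_external_marker",
    "split_with_markers",
    "fit_ellipse",
    "ellipse_interior_mask",
    "split_objective",
    "refine_region",
    "refine_all",
]


@dataclass(frozen=True)
class RegionView:
    """One connected region cropped to its padded bounding box.

    ``offset`` is the (row, col) of the crop's (0, 0) pixel in image
    coordinates; crops at the image border are padded (mask with False,
    gradient/hematoxylin with edge values) so morphology near the frame is
    well defined.
    """

    region_id: int
    mask: np.ndarray
    grad_patch: np.ndarray
    hema_patch: np.ndarray
    offset: tuple[int, int]


@dataclass(frozen=True)
class MaximaSet:
    """Representative points of the regional maxima of ``Dg``, one per
    plateau (plateau centroid rounded to the nearest in-plateau pixel),
    with the ``Dg`` value at each point."""

    points: np.ndarray  # (n, 2) int, (row, col)
    values: np.ndarray  # (n,) float

    @property
    def n(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class Clustering:
    k: int
    assignment: np.ndarray  # (n,) int cluster index in [0, k)
    centroids: np.ndarray  # (k, 2) float
    wcss: float


@dataclass(frozen=True)
class Ellipse:
    """Rotated ellipse: center (cx, cy) = (col, row) in pixels, semi-axes
    a >= b > 0, rotation alpha in [0, pi) from the +x (column) axis."""

    cx: float
    cy: float
    a: float
    b: float
    alpha: float

    @property
    def area(self) -> float:
        return float(np.pi * self.a * self.b)

    def contains(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Interior test at pixel centers via the rotated quadratic form."""
        dx = np.asarray(cols, dtype=float) - self.cx
        dy = np.asarray(rows, dtype=float) - self.cy
        c, s = np.cos(self.alpha), np.sin(self.alpha)
        u = dx * c + dy * s
        v = -dx * s + dy * c
        return (u / self.a) ** 2 + (v / self.b) ** 2 <= 1.0


@dataclass(frozen=True)
class SplitCandidate:
    """One K-hypothesis for a region: its sub-label image (crop frame),
    fitted ellipses and objective value."""

    k: int
    sublabels: np.ndarray
    ellipses: tuple[Ellipse, ...]
    xi: float


# ---------------------------------------------------------------------------
# Region extraction


def extract_regions(
    labels: np.ndarray,
    grad: np.ndarray,
    hema: np.ndarray,
    pad: int = 4,
) -> list[RegionView]:
    """Crop every labeled region to its bounding box padded by ``pad``."""
    regions: list[RegionView] = []
    h, w = labels.shape
    for region_id in range(1, int(labels.max()) + 1):
        mask = labels == region_id
        if not mask.any():
            continue
        rows, cols = np.nonzero(mask)
        r0, r1 = rows.min() - pad, rows.max() + pad + 1
        c0, c1 = cols.min() - pad, cols.max() + pad + 1
        sr0, sr1 = max(r0, 0), min(r1, h)
        sc0, sc1 = max(c0, 0), min(c1, w)
        before = (sr0 - r0, sc0 - c0)
        after = (r1 - sr1, c1 - sc1)
        pad_spec = ((before[0], after[0]), (before[1], after[1]))
        m = np.pad(mask[sr0:sr1, sc0:sc1], pad_spec, mode="constant")
        g = np.pad(grad[sr0:sr1, sc0:sc1], pad_spec, mode="edge")
        hm = np.pad(hema[sr0:sr1, sc0:sc1], pad_spec, mode="edge")
        regions.append(
            RegionView(
                region_id=region_id,
                mask=m,
                grad_patch=g,
                hema_patch=hm,
                offset=(r0, c0),
            )
        )
    return regions


# ---------------------------------------------------------------------------
# Maxima detection


def gradient_weighted_distance(region: RegionView) -> np.ndarray:
    """``Dg = D * exp(1 - (G - Gmin)/(Gmax - Gmin))`` on the region mask.

    ``D`` is the Euclidean distance map of the mask and ``G`` the gradient
    patch; ``Gmin``/``Gmax`` are taken over mask pixels.  When the gradient
    is constant on the mask the normalized term is defined as 0 (continuous
    limit), giving ``Dg = D * e``.  Zero outside the mask.
    """
    mask = region.mask
    if not mask.any():
        raise ValueError("region mask is empty")
    d = euclidean_distance_map(mask)
    g = np.asarray(region.grad_patch, dtype=float)
    gmin, gmax = float(g[mask].min()), float(g[mask].max())
    if gmax > gmin:
        norm = (g - gmin) / (gmax - gmin)
    else:
        norm = np.zeros_like(g)
    dg = d * np.exp(1.0 - norm)
    dg[~mask] = 0.0
    return dg


def regional_maxima(dg: np.ndarray, mask: np.ndarray | None = None) -> MaximaSet:
    """Regional maxima of ``Dg`` as one representative point per plateau.

    A regional maximum is an 8-connected plateau strictly greater than all
    neighbors outside it; the representative is the plateau centroid
    rounded to the nearest in-plateau pixel (ties toward smaller
    row, then column).
    """
    dg = np.asarray(dg, dtype=float)
    if mask is None:
        mask = dg > 0
    peaks = local_maxima(dg, footprint=FOOTPRINT_8, allow_borders=True) & mask
    plateaus, n = cc_label(peaks, connectivity=2, return_num=True)
    points = []
    values = []
    for pid in range(1, n + 1):
        rr, cc = np.nonzero(plateaus == pid)
        centroid = np.array([rr.mean(), cc.mean()])
        d2 = (rr - centroid[0]) ** 2 + (cc - centroid[1]) ** 2
        order = np.lexsort((cc, rr, d2))
        best = order[0]
        points.append((int(rr[best]), int(cc[best])))
        values.append(float(dg[rr[best], cc[best]]))
    if not points:
        return MaximaSet(points=np.empty((0, 2), dtype=int), values=np.empty(0))
    return MaximaSet(points=np.asarray(points, dtype=int), values=np.asarray(values))


# ---------------------------------------------------------------------------
# Clustering and markers


#: Point counts up to which the WCSS-optimal clustering is found by exact
#: partition enumeration rather than Lloyd iteration.
EXACT_KMEANS_MAX_N = 9


def _exact_min_wcss(pts: np.ndarray, k: int) -> np.ndarray:
    """Assignment minimizing within-cluster sum of squares, by exhaustive
    enumeration of set partitions (restricted-growth strings) into exactly
    ``k`` blocks.  Deterministic: ties keep the first partition in RGS
    order."""
    n = len(pts)
    best_w = np.inf
    best: np.ndarray | None = None
    assign = np.zeros(n, dtype=int)

    def rec(i: int, used: int) -> None:
        nonlocal best_w, best
        if n - i < k - used:  # cannot reach k blocks any more
            return
        if i == n:
            if used != k:
                return
            w = 0.0
            for j in range(k):
                sub = pts[assign == j]
                w += float(((sub - sub.mean(axis=0)) ** 2).sum())
            if w < best_w - 1e-12:
                best_w = w
                best = assign.copy()
            return
        for j in range(min(used + 1, k)):
            assign[i] = j
            rec(i + 1, max(used, j + 1))

    rec(0, 0)
    assert best is not None
    return best


def kmeans_cluster(
    points: np.ndarray, k: int, start_index: int = 0, max_iter: int = 100
) -> Clustering:
    """Minimum within-cluster-sum-of-squares clustering of maxima
    coordinates, fully deterministic.

    For the tiny point sets that arise per region (n <= 9) the WCSS
    optimum is found exactly by enumerating all set partitions; for larger
    sets Lloyd iteration runs from a farthest-point (k-center greedy)
    initialization seeded at ``start_index`` (the caller passes the
    maximum-``Dg`` point) until the assignment reaches a fixpoint or
    ``max_iter``.  Reported ``wcss`` is the within-cluster sum of squared
    Euclidean distances to cluster means.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")

    if n <= EXACT_KMEANS_MAX_N:
        assignment = _exact_min_wcss(pts, k)
        centroids = np.stack([pts[assignment == j].mean(axis=0) for j in range(k)])
        wcss = float(
            sum(np.sum((pts[assignment == j] - centroids[j]) ** 2) for j in range(k))
        )
        return Clustering(k=k, assignment=assignment, centroids=centroids, wcss=wcss)

    centers = [start_index]
    d2 = np.sum((pts - pts[start_index]) ** 2, axis=1)
    while len(centers) < k:
        nxt = int(np.argmax(d2))  # argmax -> first index on ties
        centers.append(nxt)
        d2 = np.minimum(d2, np.sum((pts - pts[nxt]) ** 2, axis=1))
    centroids = pts[centers].copy()

    assignment = np.full(n, -1, dtype=int)
    for _ in range(max_iter):
        dist2 = cdist(pts, centroids, metric="sqeuclidean")
        new_assignment = np.argmin(dist2, axis=1)
        # Keep every cluster non-empty: give an empty cluster the point
        # farthest from its current assignment's centroid.
        for j in range(k):
            if not np.any(new_assignment == j):
                worst = int(np.argmax(dist2[np.arange(n), new_assignment]))
                new_assignment[worst] = j
        if np.array_equal(new_assignment, assignment):
            break
        assignment = new_assignment
        centroids = np.stack([pts[assignment == j].mean(axis=0) for j in range(k)])

    wcss = float(
        sum(
            np.sum((pts[assignment == j] - centroids[j]) ** 2)
            for j in range(k)
        )
    )
    return Clustering(k=k, assignment=assignment, centroids=centroids, wcss=wcss)


def mst_markers(cluster_points: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Fuse a cluster of maxima into one connected marker via its MST.

    Builds the Euclidean minimum spanning tree of the points and rasterizes
    each tree edge as a Bresenham line segment; the marker is the union of
    the points and the rasterized edges, clipped to the region mask.
    """
    pts = np.asarray(cluster_points, dtype=int)
    if len(pts) == 0:
        raise ValueError("a cluster must contain at least one point")
    marker = np.zeros(mask.shape, dtype=bool)
    marker[pts[:, 0], pts[:, 1]] = True
    if len(pts) > 1:
        w = cdist(pts.astype(float), pts.astype(float))
        tree = _sparse_mst(w).tocoo()
        for i, j in zip(tree.row, tree.col):
            rr, cc = _draw_line(pts[i, 0], pts[i, 1], pts[j, 0], pts[j, 1])
            marker[rr, cc] = True
    return marker & np.asarray(mask, dtype=bool)


def mst_total_weight(cluster_points: np.ndarray) -> float:
    """Total Euclidean weight of the cluster's minimum spanning tree."""
    pts = np.asarray(cluster_points, dtype=float)
    if len(pts) < 2:
        return 0.0
    return float(_sparse_mst(cdist(pts, pts)).sum())


def region_external_marker(region: RegionView, radius: int = 3) -> np.ndarray:
    """External marker of a region: erosion of the mask complement by
    ``disk(radius)``.  Always disjoint from the mask."""
    return _binary_erosion(~np.asarray(region.mask, dtype=bool), disk(radius))


def split_with_markers(
    region: RegionView,
    internal: np.ndarray,
    external: np.ndarray | None = None,
    external_radius: int = 3,
) -> np.ndarray:
    """Marker-controlled watershed of the region's gradient patch.

    ``internal`` may be binary (components labeled by connectivity) or an
    integer label image (markers keep their labels even if adjacent).  The
    gradient patch is minima-imposed with internal + external markers and
    flooded; labels outside the region mask are discarded and the result is
    relabeled 1..K.  A single internal marker component cannot split
    anything, so the region mask itself is returned as one label.
    """
    mask = region.mask
    internal = np.asarray(internal)
    if internal.dtype == bool:
        seeds = cc_label(internal, connectivity=2).astype(np.int32)
    else:
        seeds = internal.astype(np.int32)
    marker_ids = np.unique(seeds[seeds > 0])
    if len(marker_ids) == 0:
        raise ValueError("internal markers are empty")
    if len(marker_ids) == 1:
        return mask.astype(np.int32)

    if external is None:
        external = region_external_marker(region, external_radius)
    imposed = impose_minima(region.grad_patch, (seeds > 0) | external)
    from skimage.segmentation import watershed as _skimage_watershed

    ext_label = int(marker_ids.max()) + 1
    seeds = seeds.copy()
    seeds[external] = ext_label
    # Flooding is confined to the region plus the external ring: the ring
    # (disjoint from the mask by construction) stops basins at the region
    # boundary without stealing boundary pixels.  No explicit ridge line is
    # drawn — basins are distinct labels already — so the positive labels
    # partition the mask exactly and the ellipse objective compares split
    # hypotheses without a per-split boundary penalty.
    labels = _skimage_watershed(
        imposed, markers=seeds, connectivity=1, mask=mask | external, watershed_line=False
    )
    labels = np.where(labels == ext_label, 0, labels)
    labels[~mask] = 0
    # Relabel to consecutive ids, ascending original marker order.
    out = np.zeros_like(labels, dtype=np.int32)
    nxt = 0
    for lab in np.unique(labels[labels > 0]):
        nxt += 1
        out[labels == lab] = nxt
    return out


# ---------------------------------------------------------------------------
# Ellipse fitting and the split objective


def fit_ellipse(component: np.ndarray) -> Ellipse:
    """Moment-matched ellipse of a binary component.

    Center = pixel centroid; semi-axes and rotation come from the ellipse
    with the same normalized second central moments (semi-axis =
    2*sqrt(eigenvalue of the covariance of pixel coordinates)); ``a >= b``
    and ``alpha`` in [0, pi) measured from the +x (column) axis.  Degenerate
    (single-pixel or collinear) components get axes clamped to 0.5 px.
    """
    component = np.asarray(component, dtype=bool)
    rows, cols = np.nonzero(component)
    if len(rows) == 0:
        raise ValueError("cannot fit an ellipse to an empty component")
    cy, cx = rows.mean(), cols.mean()
    dy, dx = rows - cy, cols - cx
    cov = np.array(
        [
            [np.mean(dx * dx), np.mean(dx * dy)],
            [np.mean(dx * dy), np.mean(dy * dy)],
        ]
    )
    evals, evecs = np.linalg.eigh(cov)  # ascending
    a = 2.0 * np.sqrt(max(evals[1], 0.0))
    b = 2.0 * np.sqrt(max(evals[0], 0.0))
    a, b = max(a, 0.5), max(b, 0.5)
    vx, vy = evecs[0, 1], evecs[1, 1]  # eigenvector of the larger eigenvalue
    alpha = float(np.arctan2(vy, vx)) % np.pi
    if np.isclose(evals[0], evals[1]):
        alpha = 0.0  # circular: orientation undefined, fix for determinism
    return Ellipse(cx=float(cx), cy=float(cy), a=float(a), b=float(b), alpha=alpha)


def ellipse_interior_mask(ellipse: Ellipse, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize an ellipse onto a grid: pixel centers passing the interior
    test of :meth:`Ellipse.contains`."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ellipse.contains(rr, cc)


def split_objective(
    sublabels: np.ndarray, ellipses: list[Ellipse] | tuple[Ellipse, ...], mask: np.ndarray
) -> float:
    """Ellipse-fit objective ``xi``: pixel count of the symmetric difference
    between the region mask and the union of fitted ellipses.

    ``xi = |{p in some ellipse, p not in mask}| +
    |{p in mask, p outside every ellipse}|``, with ellipse membership
    evaluated analytically at pixel centers.  The evaluation grid covers the
    crop extended to every ellipse's bounding box, so ellipse area falling
    outside the crop is still counted.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    r0, c0, r1, c1 = 0, 0, h, w
    for e in ellipses:
        reach = e.a + 1.0
        r0 = min(r0, int(np.floor(e.cy - reach)))
        c0 = min(c0, int(np.floor(e.cx - reach)))
        r1 = max(r1, int(np.ceil(e.cy + reach)) + 1)
        c1 = max(c1, int(np.ceil(e.cx + reach)) + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    covered = np.zeros(rr.shape, dtype=bool)
    for e in ellipses:
        covered |= e.contains(rr, cc)
    mask_on_grid = np.zeros(rr.shape, dtype=bool)
    mask_on_grid[-r0 : h - r0, -c0 : w - c0] = mask
    outside = int(np.count_nonzero(covered & ~mask_on_grid))
    uncovered = int(np.count_nonzero(mask_on_grid & ~covered))
    return float(outside + uncovered)


# ---------------------------------------------------------------------------
# Per-region refinement

def _candidate_for_k(
    region: RegionView,
    maxima: MaximaSet,
    k: int,
    external: np.ndarray,
    max_iter: int,
) -> SplitCandidate:
    """Build and score the K-cluster split hypothesis for one region."""
    mask = region.mask
    if k == 1:
        sublabels = mask.astype(np.int32)
        ellipses = (fit_ellipse(mask),)
        return SplitCandidate(
            k=1, sublabels=sublabels, ellipses=ellipses, xi=split_objective(sublabels, ellipses, mask)
        )
    start = int(np.argmax(maxima.values))
    clustering = kmeans_cluster(maxima.points, k, start_index=start, max_iter=max_iter)
    seeds = np.zeros(mask.shape, dtype=np.int32)
    for j in range(k):
        cluster_pts = maxima.points[clustering.assignment == j]
        marker = mst_markers(cluster_pts, mask)
        seeds[marker] = j + 1
    sublabels = split_with_markers(region, seeds, external=external)
    ids = np.unique(sublabels[sublabels > 0])
    ellipses = tuple(fit_ellipse(sublabels == i) for i in ids)
    xi = split_objective(sublabels, ellipses, mask)
    return SplitCandidate(k=k, sublabels=sublabels, ellipses=ellipses, xi=xi)


def refine_region(region: RegionView, config: PipelineConfig | None = None) -> SplitCandidate:
    """Estimate the nucleus count of one region and split it accordingly.

    Detects the regional maxima of the gradient-weighted distance transform
    (capped at ``config.max_n`` by descending ``Dg`` value), evaluates the
    split hypothesis for every K = 1..n and returns the candidate with
    minimal ``xi`` (ties broken toward smaller K).  A region with no maxima
    is returned unsplit with K = 1.
    """
    cfg = config or PipelineConfig()
    dg = gradient_weighted_distance(region)
    maxima = regional_maxima(dg, region.mask)
    if maxima.n == 0:
        mask = region.mask
        ellipses = (fit_ellipse(mask),)
        return SplitCandidate(
            k=1,
            sublabels=mask.astype(np.int32),
            ellipses=ellipses,
            xi=split_objective(mask.astype(np.int32), ellipses, mask),
        )
    if maxima.n > cfg.max_n:
        order = np.lexsort((maxima.points[:, 1], maxima.points[:, 0], -maxima.values))
        keep = np.sort(order[: cfg.max_n])
        maxima = MaximaSet(points=maxima.points[keep], values=maxima.values[keep])

    external = region_external_marker(region, cfg.external_marker_radius)
    best: SplitCandidate | None = None
    for k in range(1, maxima.n + 1):
        cand = _candidate_for_k(region, maxima, k, external, cfg.kmeans_max_iter)
        if best is None or cand.xi < best.xi:  # strict: ties keep smaller k
            best = cand
    return best


def refine_all(
    labels: np.ndarray,
    grad: np.ndarray,
    hema: np.ndarray,
    config: PipelineConfig | None = None,
) -> np.ndarray:
    """Apply :func:`refine_region` to every region of a label image.

    Regions are processed independently in ascending label order and the
    accepted splits are reassembled into a globally, consecutively relabeled
    image.
    """
    cfg = config or PipelineConfig()
    pad = cfg.external_marker_radius + 1
    out = np.zeros_like(labels, dtype=np.int32)
    nxt = 0
    h, w = labels.shape
    for region in extract_regions(labels, grad, hema, pad=pad):
        cand = refine_region(region, cfg)
        r0, c0 = region.offset
        ids = np.unique(cand.sublabels[cand.sublabels > 0])
        for i in ids:
            rr, cc = np.nonzero(cand.sublabels == i)
            rr = rr + r0
            cc = cc + c0
            keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            nxt += 1
            out[rr[keep], cc[keep]] = nxt
    return out
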