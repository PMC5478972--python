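"""Coarse nuclei segmentation of the hematoxylin channel.

The initial label image is produced in four stages:

1. *Morphological smoothing* — opening by reconstruction followed by closing
   by reconstruction (disk structuring element, radius ~7 at 40x) flattens
   chromatin texture inside nuclei while exactly preserving the outline of
   structures larger than the structuring element; hole filling removes
   residual dark spots.
2. *Thresholding* — Otsu's criterion (minimum within-class variance over a
   256-bin histogram) separates the now near-bimodal image into nuclei
   (high hematoxylin) and background.
3. *Marker construction* — internal markers are the H-maxima (h = 3 px) of
   the Euclidean distance transform of the smoothed foreground, which keep
   the shape of each nucleus; the external marker is the morphological
   skeleton of the background, a connected curve threading between nuclei.
4. *Marker-controlled watershed* — regional minima of the Sobel gradient
   image are imposed exactly at the markers (minima imposition by erosion
   reconstruction) and the watershed transform floods from them, so every
   internal marker yields exactly one nucleus and spurious gradient minima
   cannot over-segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import opening as _binary_opening
from skimage.morphology import (
    disk,
    local_maxima,
    local_minima,
    reconstruction,
    skeletonize,
)
from skimage.measure import label as cc_label
from skimage.segmentation import watershed as _skimage_watershed

from .config import PipelineConfig
from .stains import deconvolve_stains, estimate_stain_matrix, extract_hematoxylin, rgb_to_od

__all__ = [
    "reconstruct_open",
    "reconstruct_close",
    "fill_holes",
    "OtsuResult",
    "otsu_threshold",
    "smooth_binary",
    "euclidean_distance_map",
    "internal_markers",
    "external_markers",
    "gradient_magnitude",
    "impose_minima",
    "marker_watershed",
    "coarse_pipeline",
]

# 8-connectivity for components and regional extrema; the watershed itself
# uses 4-connectivity so basins remain separable by 1-pixel ridges.
FOOTPRINT_8 = np.ones((3, 3), dtype=bool)


def _check_radius(radius: int) -> None:
    if radius < 1:
        raise ValueError(f"structuring-element radius must be >= 1, got {radius}")


def reconstruct_open(img: np.ndarray, radius: int = 7) -> np.ndarray:
    """Grayscale opening by reconstruction with a disk structuring element.

    Erosion by ``disk(radius)`` followed by reconstruction by dilation under
    the original image.  Bright structures too small to survive the erosion
    are removed; everything else is restored with its exact original shape.
    Output <= input pointwise.
    """
    _check_radius(radius)
    img = np.asarray(img, dtype=float)
    eroded = ndi.grey_erosion(img, footprint=disk(radius))
    return reconstruction(eroded, img, method="dilation")


def reconstruct_close(img: np.ndarray, radius: int = 7) -> np.ndarray:
    """Grayscale closing by reconstruction (dual of :func:`reconstruct_open`).

    Dilation by ``disk(radius)`` followed by reconstruction by erosion above
    the original; removes dark structures smaller than the disk.  Output >=
    input pointwise.
    """
    _check_radius(radius)
    img = np.asarray(img, dtype=float)
    dilated = ndi.grey_dilation(img, footprint=disk(radius))
    return reconstruction(dilated, img, method="erosion")


def fill_holes(img: np.ndarray) -> np.ndarray:
    """Fill interior holes of a binary mask or grayscale image.

    Binary input: holes are background regions not connected to the image
    border.  Grayscale input: fill-hole by erosion reconstruction from a
    border-seeded marker, which raises every regional minimum not touching
    the border to the level of its surrounding ridge.
    """
    img = np.asarray(img)
    if img.dtype == bool:
        return ndi.binary_fill_holes(img)
    img = img.astype(float)
    seed = np.full_like(img, img.max())
    seed[0, :] = img[0, :]
    seed[-1, :] = img[-1, :]
    seed[:, 0] = img[:, 0]
    seed[:, -1] = img[:, -1]
    return reconstruction(seed, img, method="erosion")


@dataclass(frozen=True)
class OtsuResult:
    """Threshold minimizing within-class variance; foreground = values > T."""

    threshold: float
    degenerate: bool = False  # constant image: no foreground can be defined


def otsu_threshold(img: np.ndarray, n_bins: int = 256) -> OtsuResult:
    """Otsu's threshold: exhaustive minimization of within-class variance.

    The image is histogrammed into ``n_bins`` equal-width bins over its own
    value range.  For every candidate cut the within-class variance
    ``w1*var1 + w2*var2`` is evaluated (an empty class contributes zero) and
    the cut minimizing it is returned; ties are broken toward the smallest
    threshold, and the returned threshold is the upper edge of the last bin
    of the low class.  A constant image is degenerate: its own value is
    returned with ``degenerate=True``.
    """
    img = np.asarray(img, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    if lo == hi:
        return OtsuResult(threshold=lo, degenerate=True)
    counts, edges = np.histogram(img, bins=n_bins, range=(lo, hi))
    p = counts / counts.sum()
    mids = 0.5 * (edges[:-1] + edges[1:])

    w1 = np.cumsum(p)
    w2 = 1.0 - w1
    cum_mean = np.cumsum(p * mids)
    total_mean = cum_mean[-1]
    cum_sq = np.cumsum(p * mids**2)
    total_sq = cum_sq[-1]

    with np.errstate(divide="ignore", invalid="ignore"):
        mu1 = cum_mean / w1
        mu2 = (total_mean - cum_mean) / w2
        var1 = cum_sq / w1 - mu1**2
        var2 = (total_sq - cum_sq) / w2 - mu2**2
    var1 = np.where(w1 > 0, var1, 0.0)
    var2 = np.where(w2 > 0, var2, 0.0)
    within = np.where(w1 > 0, var1 * w1, 0.0) + np.where(w2 > 0, var2 * w2, 0.0)
    # Cuts after the last bin leave class 2 empty; exclude the final index so
    # the foreground (> T) is never forced empty on a non-constant image.
    t = int(np.argmin(within[:-1]))  # argmin takes the first = smallest T on ties
    return OtsuResult(threshold=float(edges[t + 1]), degenerate=False)


def smooth_binary(mask: np.ndarray, radius: int = 3) -> np.ndarray:
    """Binary opening by ``disk(radius)``: smooths boundaries, removes
    protrusions and specks thinner than the disk.  Output is a subset of the
    input."""
    _check_radius(radius)
    return _binary_opening(np.asarray(mask, dtype=bool), disk(radius))


def euclidean_distance_map(mask: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance of each foreground pixel to the nearest
    background pixel; zero on background."""
    return ndi.distance_transform_edt(np.asarray(mask, dtype=bool))


def internal_markers(dist: np.ndarray, h: float = 3.0) -> np.ndarray:
    """Internal (nucleus) markers: H-maxima of the distance map.

    Regional maxima whose dynamic is below ``h`` are suppressed by grayscale
    reconstruction of ``dist - h`` under ``dist``; the markers are the
    regional maxima of the suppressed map, restricted to the foreground
    (``dist > 0``).  Maxima plateaus are kept whole, so markers retain the
    shape of the nucleus core rather than collapsing to points.
    """
    if h <= 0:
        raise ValueError(f"h must be positive, got {h}")
    dist = np.asarray(dist, dtype=float)
    suppressed = reconstruction(dist - h, dist, method="dilation", footprint=FOOTPRINT_8)
    markers = local_maxima(suppressed, footprint=FOOTPRINT_8, allow_borders=True)
    return markers.astype(bool) & (dist > 0)


def external_markers(foreground: np.ndarray) -> np.ndarray:
    """External (background) marker: morphological skeleton of the background.

    Homotopic thinning is used, so the skeleton preserves the connectivity
    of the background: where the background is one connected region, the
    external marker is a single connected curve threading between nuclei.
    The skeleton is always disjoint from the foreground.
    """
    foreground = np.asarray(foreground, dtype=bool)
    background = ~foreground
    if not background.any():
        raise ValueError("background is empty; cannot construct external markers")
    return skeletonize(background)


def gradient_magnitude(img: np.ndarray) -> np.ndarray:
    """Sobel gradient magnitude ``sqrt(gx^2 + gy^2)`` (classic 3x3 kernels,
    reflect boundary)."""
    img = np.asarray(img, dtype=float)
    gr = ndi.sobel(img, axis=0, mode="reflect")
    gc = ndi.sobel(img, axis=1, mode="reflect")
    return np.hypot(gr, gc)


def impose_minima(grad: np.ndarray, markers: np.ndarray) -> np.ndarray:
    """Force the regional minima of ``grad`` to coincide exactly with
    ``markers`` (minima imposition by erosion reconstruction).

    The marker image takes a sentinel below the image minimum on marker
    pixels and a sentinel above the maximum elsewhere; the result is the
    erosion reconstruction of the pointwise minimum of (grad + offset) and
    the marker image, reconstructed from the marker image.  After the
    operation the only regional minima are the marker components.
    """
    grad = np.asarray(grad, dtype=float)
    markers = np.asarray(markers, dtype=bool)
    if not markers.any():
        raise ValueError("markers are empty; minima imposition is undefined")
    lo, hi = float(grad.min()), float(grad.max())
    offset = max((hi - lo) * 1e-3, 1e-6)
    fm = np.where(markers, lo - 1.0, hi + offset + 1.0)
    g = np.minimum(grad + offset, fm)
    return reconstruction(fm, g, method="erosion", footprint=FOOTPRINT_8)


def marker_watershed(
    grad_imposed: np.ndarray,
    internal: np.ndarray,
    external: np.ndarray,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Flood the minima-imposed gradient from the markers.

    Each 8-connected component of ``internal`` seeds exactly one positive
    label; pixels reached from ``external`` and watershed ridge pixels are
    labeled 0.  Basin boundaries use 4-connectivity so a 1-pixel ridge can
    separate two basins.  When ``mask`` is given, flooding is confined to
    it (the external marker should be part of the mask to stay active).
    """
    internal = np.asarray(internal, dtype=bool)
    external = np.asarray(external, dtype=bool)
    seeds, n_internal = cc_label(internal, connectivity=2, return_num=True)
    seeds = seeds.astype(np.int32)
    ext_label = n_internal + 1
    seeds[external] = ext_label
    labels = _skimage_watershed(
        grad_imposed, markers=seeds, connectivity=1, mask=mask, watershed_line=True
    )
    labels = np.where(labels == ext_label, 0, labels).astype(np.int32)
    return labels


def _tidy_labels(labels: np.ndarray, min_area: int) -> np.ndarray:
    """Split labels into 8-connected pieces, drop pieces below ``min_area``
    pixels and relabel consecutively 1..N (ascending original label order).

    Re-labeling per original label (rather than one global connected-
    component pass) keeps watershed-split neighbors separate even where the
    dividing ridge runs diagonally.
    """
    out = np.zeros_like(labels, dtype=np.int32)
    nxt = 0
    for lab in range(1, int(labels.max()) + 1):
        pieces, n = cc_label(labels == lab, connectivity=2, return_num=True)
        for piece_id in range(1, n + 1):
            piece = pieces == piece_id
            if int(piece.sum()) >= min_area:
                nxt += 1
                out[piece] = nxt
    return out


def coarse_pipeline(
    rgb: np.ndarray, config: PipelineConfig | None = None
) -> tuple[np.ndarray, dict]:
    """RGB H&E tile -> initial nuclei label image.

    Chains stain separation, opening/closing by reconstruction, hole
    filling, Otsu thresholding, boundary smoothing, distance-transform
    internal markers, background-skeleton external markers, gradient minima
    imposition and marker-controlled watershed; components smaller than
    ``config.min_area`` are dropped.

    Returns
    -------
    labels : (H, W) int32 ndarray
        0 = background/ridges, 1..N = nuclei.
    stages : dict
        Intermediate images keyed by stage name (hematoxylin, smoothed,
        foreground, distance, internal, external, gradient), for QC overlays
        and diagnostics.
    """
    cfg = config or PipelineConfig()
    od = rgb_to_od(rgb, cfg.background_intensity)
    used_matrix = (
        estimate_stain_matrix(od) if cfg.stain == "auto" else cfg.fixed_stain_matrix()
    )
    conc = deconvolve_stains(od, used_matrix)
    raw_hema = np.clip(conc[..., 0], 0.0, None)
    hema = extract_hematoxylin(conc)

    # A tile with no appreciable hematoxylin absorbance anywhere holds no
    # nuclei; without this guard the [0, 1] rescale amplifies noise and
    # Otsu happily splits it.
    if float(np.percentile(raw_hema, 99)) < cfg.min_hema_od:
        empty = np.zeros(hema.shape, dtype=np.int32)
        stages = {
            "stain_matrix": used_matrix,
            "hematoxylin": hema,
            "smoothed": hema,
            "otsu_threshold": 0.0,
            "foreground": empty.astype(bool),
            "n_objects": 0,
        }
        return empty, stages

    smoothed = reconstruct_open(hema, cfg.se_radius_preproc)
    smoothed = reconstruct_close(smoothed, cfg.se_radius_preproc)
    smoothed = fill_holes(smoothed)

    otsu = otsu_threshold(smoothed, cfg.n_bins)
    if otsu.degenerate:
        foreground = np.zeros(smoothed.shape, dtype=bool)
    else:
        foreground = smoothed > otsu.threshold
    foreground = smooth_binary(foreground, cfg.se_radius_smooth)
    foreground = ndi.binary_fill_holes(foreground)

    stages = {
        "stain_matrix": used_matrix,
        "hematoxylin": hema,
        "smoothed": smoothed,
        "otsu_threshold": otsu.threshold,
        "foreground": foreground,
    }
    if not foreground.any():
        stages.update(n_objects=0)
        return np.zeros(foreground.shape, dtype=np.int32), stages

    dist = euclidean_distance_map(foreground)
    internal = internal_markers(dist, cfg.hmax_h)
    external = external_markers(foreground)
    grad = gradient_magnitude(smoothed)
    # The raw-channel gradient keeps the narrow seams between abutting
    # nuclei that the reconstruction filters flatten; the refinement stage
    # floods this one.
    stages.update(
        distance=dist,
        internal=internal,
        external=external,
        gradient=grad,
        gradient_raw=gradient_magnitude(hema),
    )

    if not internal.any():
        stages.update(n_objects=0)
        return np.zeros(foreground.shape, dtype=np.int32), stages

    imposed = impose_minima(grad, internal | external)
    # The external skeleton (disjoint from the foreground) confines basins
    # to the threshold mask, which the internal basins then partition.
    labels = marker_watershed(imposed, internal, external, mask=foreground | external)
    labels[~foreground] = 0
    labels = _tidy_labels(labels, cfg.min_area)
    stages.update(n_objects=int(labels.max()))
    return labels, stages


def regional_minima_mask(img: np.ndarray) -> np.ndarray:
    """8-connected regional minima of a grayscale image (diagnostic helper,
    used to verify minima imposition)."""
    return local_minima(np.asarray(img, dtype=float), footprint=FOOTPRINT_8).astype(bool)
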