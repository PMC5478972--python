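"""Color deconvolution of H&E-stained RGB images.

Brightfield microscopy of an absorbing stain follows the Lambert–Beer law:
the transmitted intensity is ``I = I0 * exp(-OD)`` where the optical density
OD is linear in the amount of stain in the light path.  With several stains,
per-pixel optical densities mix linearly through a 3x3 stain matrix ``M``
whose unit columns are the OD-space colors of hematoxylin, eosin and a
residual direction.  Inverting that mixture ("color deconvolution") recovers
per-stain concentration maps; nuclei segmentation then operates on the
hematoxylin concentration alone, because hematoxylin is the nuclear dye.

The stain matrix can be supplied (e.g. the published Ruifrok–Johnston H&E
vectors) or estimated from the image itself with the SVD-plane method:
project high-density pixels onto the plane spanned by the top two singular
vectors of the OD cloud and take robust extreme directions as the two stain
vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StainMatrix",
    "RUIFROK_HE",
    "rgb_to_od",
    "od_to_rgb",
    "estimate_stain_matrix",
    "deconvolve_stains",
    "extract_hematoxylin",
    "separate_stains",
]

#: Guard added to intensities before the log so a 0 pixel has finite OD.
DARK_PIXEL_GUARD = 1.0

#: Default background (unstained, fully transmitting) intensity.
BACKGROUND_INTENSITY = 255.0


class InvalidInputError(ValueError):
    """Raised when an image does not satisfy an operation's contract."""


class InvalidStainMatrixError(ValueError):
    """Raised when a stain matrix is singular or malformed."""


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n == 0:
        raise InvalidStainMatrixError("zero-length stain vector")
    return v / n


@dataclass(frozen=True)
class StainMatrix:
    """3x3 matrix whose unit-norm columns are OD-space stain vectors.

    Column order is fixed as (hematoxylin, eosin, residual); hematoxylin is
    the column with the larger red-channel OD component (it absorbs red
    light more strongly than eosin does).

    Parameters
    ----------
    matrix : (3, 3) ndarray
        Columns are stain vectors in OD-RGB space, each of Euclidean norm 1.
    source : {"fixed", "estimated"}
        Whether the matrix is the published fallback or was estimated from
        the image at hand.
    """

    matrix: np.ndarray
    source: str = "fixed"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise InvalidStainMatrixError(f"stain matrix must be 3x3, got {m.shape}")
        norms = np.linalg.norm(m, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise InvalidStainMatrixError(f"stain columns must be unit norm, got {norms}")
        if abs(np.linalg.det(m)) < 1e-12:
            raise InvalidStainMatrixError("stain columns are linearly dependent")
        object.__setattr__(self, "matrix", m)

    @property
    def hematoxylin(self) -> np.ndarray:
        return self.matrix[:, 0]

    @property
    def eosin(self) -> np.ndarray:
        return self.matrix[:, 1]

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)


def _ruifrok_matrix() -> StainMatrix:
    h = _unit(np.array([0.650, 0.704, 0.286]))
    e = _unit(np.array([0.072, 0.990, 0.105]))
    r = _unit(np.cross(h, e))
    return StainMatrix(np.stack([h, e, r], axis=1), source="fixed")


#: Published Ruifrok–Johnston H&E OD vectors (unit-normalized, residual =
#: normalized cross product).  Used as the estimation fallback.
RUIFROK_HE: StainMatrix = _ruifrok_matrix()


def rgb_to_od(
    img: np.ndarray, background_intensity: float = BACKGROUND_INTENSITY
) -> np.ndarray:
    """Convert an 8-bit RGB image to optical density.

    ``OD = -log(max(I, eps) / I0)`` per channel, clamped to >= 0, where
    ``eps`` is a one-intensity-unit guard that keeps the OD of a fully dark
    pixel finite (``-log(eps/I0)``) without perturbing any other intensity.

    Parameters
    ----------
    img : (H, W, 3) array
        Integer intensities in [0, 255].
    background_intensity : float
        Intensity of unstained background, ``I0 > 0``.

    Returns
    -------
    (H, W, 3) float ndarray of non-negative optical densities.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise InvalidInputError(f"expected an HxWx3 RGB image, got shape {img.shape}")
    if background_intensity <= 0:
        raise InvalidInputError("background_intensity must be positive")
    od = -np.log(np.maximum(img.astype(float), DARK_PIXEL_GUARD) / background_intensity)
    return np.maximum(od, 0.0)


def od_to_rgb(
    od: np.ndarray, background_intensity: float = BACKGROUND_INTENSITY
) -> np.ndarray:
    """Inverse of the Lambert–Beer transform: ``I = I0 * exp(-OD)``, as uint8.

    This is the forward imaging model; the synthetic generator uses it to
    render RGB from stain concentration fields.
    """
    od = np.asarray(od, dtype=float)
    rgb = background_intensity * np.exp(-od)
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def estimate_stain_matrix(
    od: np.ndarray,
    od_floor: float = 0.15,
    angle_percentile: float = 1.0,
    min_pixels: int = 100,
) -> StainMatrix:
    """Estimate the H&E stain matrix from the OD cloud (SVD-plane method).

    Pixels with OD magnitude above ``od_floor`` are projected onto the plane
    of the top two right-singular vectors of the OD cloud; the directions at
    the ``angle_percentile`` and ``100 - angle_percentile`` percentiles of
    the in-plane angle are taken as the two stain vectors, and the residual
    column is their normalized cross product.  Hematoxylin is identified as
    the vector with the larger red-channel component.

    Falls back to :data:`RUIFROK_HE` (``source="fixed"``) when the estimate
    is unreliable: fewer than ``min_pixels`` pixels clear the OD floor
    (near-white image), or the OD cloud is effectively one-dimensional
    (second singular value below 10% of the first — a one-stain image,
    where the two-stain mixture model cannot be resolved).
    """
    od = np.asarray(od, dtype=float)
    pixels = od.reshape(-1, 3)
    pixels = pixels[np.linalg.norm(pixels, axis=1) > od_floor]
    if pixels.shape[0] < min_pixels:
        return RUIFROK_HE

    # Plane of maximal OD variance (uncentered, directions through origin).
    _, sv, vt = np.linalg.svd(pixels, full_matrices=False)
    if sv[1] < 0.1 * sv[0]:
        return RUIFROK_HE
    basis = vt[:2]  # (2, 3)
    # Orient the basis so projections land in a consistent half-plane.
    if basis[0].sum() < 0:
        basis = basis.copy()
        basis[0] = -basis[0]
    proj = pixels @ basis.T  # (n, 2)
    angles = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(angles, [angle_percentile, 100.0 - angle_percentile])
    v1 = _unit(np.array([np.cos(lo), np.sin(lo)]) @ basis)
    v2 = _unit(np.array([np.cos(hi), np.sin(hi)]) @ basis)
    # OD vectors are non-negative up to noise; flip into the positive octant.
    if v1.sum() < 0:
        v1 = -v1
    if v2.sum() < 0:
        v2 = -v2
    # Hematoxylin absorbs red more strongly than eosin.
    h, e = (v1, v2) if v1[0] >= v2[0] else (v2, v1)
    r = _unit(np.cross(h, e))
    return StainMatrix(np.stack([h, e, r], axis=1), source="estimated")


def deconvolve_stains(od: np.ndarray, stain_matrix: StainMatrix) -> np.ndarray:
    """Solve the per-pixel linear mixture ``od = M @ conc`` for concentrations.

    Negative concentrations are preserved (no clipping), so the operation is
    an exact linear inverse of the forward mixture; clipping happens in
    :func:`extract_hematoxylin`.

    Returns
    -------
    (H, W, 3) float ndarray; channels ordered (hematoxylin, eosin, residual).
    """
    od = np.asarray(od, dtype=float)
    if od.ndim != 3 or od.shape[2] != 3:
        raise InvalidInputError(f"expected an HxWx3 OD cube, got shape {od.shape}")
    conc = od.reshape(-1, 3) @ stain_matrix.inverse.T
    return conc.reshape(od.shape)


def extract_hematoxylin(conc: np.ndarray) -> np.ndarray:
    """Hematoxylin concentration rescaled to [0, 1] (higher = more stain).

    Takes channel 0 of the concentration cube, clips negatives to zero and
    divides by the image's own maximum; an all-nonpositive channel yields an
    all-zero image.
    """
    conc = np.asarray(conc, dtype=float)
    hema = np.clip(conc[..., 0], 0.0, None)
    peak = hema.max() if hema.size else 0.0
    if peak > 0:
        hema = hema / peak
    return hema


def separate_stains(
    img: np.ndarray,
    stain_matrix: StainMatrix | None = None,
    background_intensity: float = BACKGROUND_INTENSITY,
) -> tuple[np.ndarray, StainMatrix]:
    """RGB image -> ([0, 1] hematoxylin image, stain matrix used).

    Convenience wrapper chaining :func:`rgb_to_od`,
    :func:`estimate_stain_matrix` (when no matrix is given),
    :func:`deconvolve_stains` and :func:`extract_hematoxylin`.
    """
    od = rgb_to_od(img, background_intensity)
    if stain_matrix is None:
        stain_matrix = estimate_stain_matrix(od)
    conc = deconvolve_stains(od, stain_matrix)
    return extract_hematoxylin(conc), stain_matrix
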