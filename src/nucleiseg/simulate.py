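"""Seeded generator of H&E-like tiles with known ground truth.

Tiles emulate 40x (~0.25 um/pixel) H&E histology through the same forward
model the deconvolution inverts: elliptical nuclei contribute a hematoxylin
concentration field (flat core, smooth boundary falloff, low-frequency
within-nucleus texture and per-nucleus intensity jitter), the background
carries an uneven eosin field, optical densities mix through the stain
matrix and ``RGB = I0 * exp(-M @ conc)`` plus sensor noise.  A configurable
fraction of nuclei is laid out in touching pairs/triplets with a controlled
fractional overlap so the clump-splitting stage has realistic work to do.

Every sample carries its ground truth: the label mask (overlap pixels
assigned to the nearest generating center), the generating ellipse of each
nucleus and the clump composition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi

from .refine import Ellipse, RegionView
from .segment import gradient_magnitude
from .stains import RUIFROK_HE, StainMatrix

__all__ = [
    "SyntheticSpec",
    "SyntheticSample",
    "sample_layout",
    "render_he",
    "generate_sample",
    "generate_dataset",
    "make_clump_region",
]


class PlacementError(RuntimeError):
    """Raised when a layout cannot be placed; lower n_nuclei or sizes."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic tile.

    Defaults emulate the tiles the pipeline targets: 350x350 px at 40x with
    ~70 nuclei of 9-16 px semi-axes (4.5-8 um diameter range), 30% of
    nuclei in touching clumps with 10-35% pairwise area overlap.
    """

    width: int = 350
    height: int = 350
    n_nuclei: int = 70
    axis_range: tuple[float, float] = (9.0, 16.0)
    overlap_fraction: float = 0.30
    target_pair_overlap: tuple[float, float] = (0.10, 0.35)
    intensity_jitter: float = 0.15
    texture_sd: float = 0.08
    background_eosin: float = 0.35
    noise_sd: float = 3.0
    stain_matrix: StainMatrix = field(default_factory=lambda: RUIFROK_HE)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.axis_range[0] <= 0 or self.axis_range[0] > self.axis_range[1]:
            raise ValueError(f"invalid axis_range {self.axis_range}")
        if not 0 <= self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        lo, hi = self.target_pair_overlap
        if not 0 < lo <= hi < 1:
            raise ValueError(f"invalid target_pair_overlap {self.target_pair_overlap}")


@dataclass(frozen=True)
class SyntheticSample:
    """A rendered tile with its ground truth."""

    rgb: np.ndarray  # (H, W, 3) uint8
    gt_labels: np.ndarray  # (H, W) int32; label i+1 <-> nuclei[i]
    nuclei: tuple[Ellipse, ...]
    clumps: tuple[tuple[int, ...], ...]  # groups of touching gt labels
    spec: SyntheticSpec


# ---------------------------------------------------------------------------
# Layout


def _raster(e: Ellipse, shape: tuple[int, int]) -> np.ndarray:
    r0 = max(int(e.cy - e.a - 1), 0)
    r1 = min(int(e.cy + e.a + 2), shape[0])
    c0 = max(int(e.cx - e.a - 1), 0)
    c1 = min(int(e.cx + e.a + 2), shape[1])
    out = np.zeros(shape, dtype=bool)
    if r1 > r0 and c1 > c0:
        rr, cc = np.mgrid[r0:r1, c0:c1]
        out[r0:r1, c0:c1] = e.contains(rr, cc)
    return out


def _overlap_fraction(e1: Ellipse, e2: Ellipse, shape) -> float:
    m1, m2 = _raster(e1, shape), _raster(e2, shape)
    inter = int(np.count_nonzero(m1 & m2))
    smaller = min(int(m1.sum()), int(m2.sum()))
    return inter / smaller if smaller else 0.0


def _sample_ellipse(rng: np.random.Generator, spec: SyntheticSpec, cy, cx) -> Ellipse:
    lo, hi = spec.axis_range
    a = rng.uniform(lo, hi)
    b = rng.uniform(lo, a) if a > lo else lo
    return Ellipse(cx=float(cx), cy=float(cy), a=float(a), b=float(b), alpha=float(rng.uniform(0, np.pi)))


def _place_clump(
    rng: np.random.Generator, spec: SyntheticSpec, size: int
) -> list[Ellipse]:
    """A chain of ``size`` ellipses with controlled pairwise overlap,
    positioned around the local origin (centers later translated)."""
    shape = (
        int(8 * spec.axis_range[1] + 8),
        int(8 * spec.axis_range[1] + 8),
    )
    mid = (shape[0] / 2, shape[1] / 2)
    members = [_sample_ellipse(rng, spec, *mid)]
    f_lo, f_hi = spec.target_pair_overlap
    prev_theta: float | None = None
    for _ in range(size - 1):
        prev = members[-1]
        target = rng.uniform(f_lo, f_hi)
        if prev_theta is None:
            theta = rng.uniform(0, 2 * np.pi)
        else:
            # Chains extend; a sharp bend would fold the chain into a
            # compact cluster instead.
            theta = prev_theta + rng.uniform(-np.pi / 3, np.pi / 3)
        prev_theta = theta
        nxt = _sample_ellipse(rng, spec, prev.cy, prev.cx)
        # Bisection on center distance along theta to hit the target overlap.
        d_lo, d_hi = 0.5, float(prev.a + nxt.a + 2)
        placed = None
        for _ in range(40):
            d = 0.5 * (d_lo + d_hi)
            cand = replace(
                nxt,
                cy=prev.cy + d * np.sin(theta),
                cx=prev.cx + d * np.cos(theta),
            )
            f = _overlap_fraction(prev, cand, shape)
            if f_lo <= f <= f_hi:
                placed = cand
                break
            if f > f_hi:
                d_lo = d
            else:
                d_hi = d
        if placed is None:
            raise PlacementError("could not reach target pair overlap")
        # A chain overlaps only between consecutive members; folding back
        # onto an earlier member would make a cluster, not a chain.
        for other in members[:-1]:
            if _overlap_fraction(other, placed, shape) > 0:
                raise PlacementError("clump chain folded onto itself")
        members.append(placed)
    return members


def sample_layout(
    spec: SyntheticSpec, rng: np.random.Generator | None = None, max_attempts: int = 300
) -> tuple[list[Ellipse], list[tuple[int, ...]]]:
    """Rejection-sample a full tile layout.

    Nuclei designated for clumps are placed as pairs (one triplet when the
    clump budget is odd) with pairwise overlap inside
    ``spec.target_pair_overlap``; singles are pairwise disjoint with >= 2 px
    clearance from everything else; every ellipse lies fully inside the
    frame.  Returns the ellipses (index i -> gt label i+1) and the clump
    groups as label tuples.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)
    n_clumped = int(round(spec.overlap_fraction * spec.n_nuclei))
    if n_clumped == 1:
        n_clumped = 0
    sizes: list[int] = []
    remaining = n_clumped
    while remaining >= 2:
        if remaining == 3:
            sizes.append(3)
            remaining = 0
        else:
            sizes.append(2)
            remaining -= 2
    n_singles = spec.n_nuclei - sum(sizes)

    occupied = np.zeros(shape, dtype=bool)
    clearance = np.zeros(shape, dtype=bool)  # occupied dilated by the gap
    gap = np.ones((5, 5), dtype=bool)  # >= 2 px separation between entities
    ellipses: list[Ellipse] = []
    clumps: list[tuple[int, ...]] = []
    margin = 2.0

    def commit(group: list[Ellipse]) -> None:
        nonlocal occupied, clearance
        start = len(ellipses)
        mask = np.zeros(shape, dtype=bool)
        for e in group:
            mask |= _raster(e, shape)
        occupied |= mask
        clearance |= ndi.binary_dilation(mask, structure=gap)
        ellipses.extend(group)
        if len(group) > 1:
            clumps.append(tuple(range(start + 1, start + len(group) + 1)))

    def try_place(group: list[Ellipse]) -> bool:
        """Translate a locally-built group to a random in-frame position."""
        a_max = max(e.a for e in group)
        for _ in range(max_attempts):
            dy = rng.uniform(margin + a_max, spec.height - margin - a_max)
            dx = rng.uniform(margin + a_max, spec.width - margin - a_max)
            ref = group[0]
            moved = [
                replace(e, cy=e.cy - ref.cy + dy, cx=e.cx - ref.cx + dx) for e in group
            ]
            ok = True
            for e in moved:
                if (
                    e.cy - e.a < margin
                    or e.cy + e.a > spec.height - margin
                    or e.cx - e.a < margin
                    or e.cx + e.a > spec.width - margin
                ):
                    ok = False
                    break
                if clearance[_raster(e, shape)].any():
                    ok = False
                    break
            if ok:
                commit(moved)
                return True
        return False

    for size in sizes:
        placed = False
        for _ in range(max_attempts):
            try:
                group = _place_clump(rng, spec, size)
            except PlacementError:
                continue
            if try_place(group):
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place a {size}-nucleus clump; lower n_nuclei or axis sizes"
            )
    for _ in range(n_singles):
        single = [_sample_ellipse(rng, spec, 0.0, 0.0)]
        if not try_place(single):
            raise PlacementError("could not place a nucleus; lower n_nuclei or axis sizes")
    return ellipses, clumps


# ---------------------------------------------------------------------------
# Rendering


def _ellipse_radius_sq(e: Ellipse, rr: np.ndarray, cc: np.ndarray) -> np.ndarray:
    dx = cc - e.cx
    dy = rr - e.cy
    c, s = np.cos(e.alpha), np.sin(e.alpha)
    u = dx * c + dy * s
    v = -dx * s + dy * c
    return (u / e.a) ** 2 + (v / e.b) ** 2


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Zero-mean, unit-sd low-frequency Gaussian field."""
    f = ndi.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = f.std()
    return f / sd if sd > 0 else f


def render_he(
    layout: tuple[list[Ellipse], list[tuple[int, ...]]], spec: SyntheticSpec
) -> SyntheticSample:
    """Render a layout through the Lambert-Beer forward model.

    Nuclei are opaque, abutting objects: each covered pixel belongs to the
    nucleus with the nearest center (the same convention as the ground
    truth) and carries that nucleus's concentration ``c_i * p(r)``, where
    ``r`` is the normalized elliptical radius and ``p`` is 1 in the core
    (r <= 0.9) with a cosine falloff to 0 at r = 1.  Along the junction
    between touching nuclei the concentration is raised by a narrow
    chromatin-rim term (stacked nuclear envelopes and condensed peripheral
    chromatin make the interface between real abutting nuclei visibly
    darker), so clumps carry a gradient ridge at the true interface just as
    real H&E clumps do.  Within-nucleus texture multiplies the field by
    ``exp(texture_sd * smooth noise)``; the eosin background is
    ``background_eosin`` modulated by a low-frequency field.  RGB =
    ``255 * exp(-M @ conc)`` with additive Gaussian noise, clipped to
    [0, 255].
    """
    ellipses, clumps = layout
    rng = np.random.default_rng(spec.seed + 1)  # rendering stream
    shape = (spec.height, spec.width)
    rr, cc = np.mgrid[0 : spec.height, 0 : spec.width]

    hema = np.zeros(shape, dtype=float)
    gt = np.zeros(shape, dtype=np.int32)
    best_d = np.full(shape, np.inf)  # distance to owner's center
    second_d = np.full(shape, np.inf)  # distance to the runner-up's center
    amplitudes = []
    for i, e in enumerate(ellipses):
        c_i = max(1.0 + spec.intensity_jitter * rng.standard_normal(), 0.2)
        amplitudes.append(c_i)
        r2 = _ellipse_radius_sq(e, rr, cc)
        inside = r2 <= 1.0
        d = np.sqrt((rr - e.cy) ** 2 + (cc - e.cx) ** 2)
        d = np.where(inside, d, np.inf)
        closer = d < best_d
        second_d = np.where(closer, best_d, np.minimum(second_d, d))
        best_d = np.where(closer, d, best_d)
        gt[closer] = i + 1
    for i, e in enumerate(ellipses):
        own = gt == i + 1
        if not own.any():
            continue
        r = np.sqrt(np.maximum(_ellipse_radius_sq(e, rr, cc), 0.0))
        profile = np.where(
            r <= 0.9, 1.0, np.where(r <= 1.0, 0.5 * (1 + np.cos(np.pi * (r - 0.9) / 0.1)), 0.0)
        )
        hema[own] = amplitudes[i] * profile[own]
    # Chromatin rim along junctions: pixels nearly equidistant between two
    # covering nuclei (the ownership boundary inside a clump).
    junction = np.isfinite(second_d) & (gt > 0)
    if junction.any():
        gap = np.full(shape, np.inf)
        gap[junction] = 0.5 * (second_d[junction] - best_d[junction])
        hema = hema * (1.0 + 0.5 * np.exp(-((gap / 1.5) ** 2)))

    if spec.texture_sd > 0:
        hema *= np.exp(spec.texture_sd * _smooth_field(rng, shape, sigma=3.0))
    eosin = spec.background_eosin * np.clip(
        1.0 + 0.4 * _smooth_field(rng, shape, sigma=40.0), 0.3, 2.0
    )

    m = spec.stain_matrix.matrix
    od = (
        hema[..., None] * m[:, 0][None, None, :]
        + eosin[..., None] * m[:, 1][None, None, :]
    )
    rgb = 255.0 * np.exp(-od)
    if spec.noise_sd > 0:
        rgb = rgb + rng.normal(0.0, spec.noise_sd, rgb.shape)
    rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
    return SyntheticSample(
        rgb=rgb,
        gt_labels=gt,
        nuclei=tuple(ellipses),
        clumps=tuple(clumps),
        spec=spec,
    )


def generate_sample(spec: SyntheticSpec) -> SyntheticSample:
    """Layout + render with the spec's seed (byte-deterministic)."""
    return render_he(sample_layout(spec), spec)


def generate_dataset(specs: list[SyntheticSpec], out_dir) -> dict:
    """Write image/ground-truth/CSV triples plus a manifest.

    Per spec: ``tile_<seed>.png`` (RGB), ``tile_<seed>_gt.tif`` (16-bit
    labels) and ``tile_<seed>_nuclei.csv`` (one row per nucleus: label,
    center, semi-axes, rotation, clump id or -1).  The manifest
    (``manifest.json``) lists every spec so any tile can be regenerated
    byte-identically from its seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for spec in specs:
        sample = generate_sample(spec)
        stem = f"tile_{spec.seed:05d}"
        iio.imwrite(out / f"{stem}.png", sample.rgb)
        tifffile.imwrite(out / f"{stem}_gt.tif", sample.gt_labels.astype(np.uint16))
        clump_of = {}
        for ci, group in enumerate(sample.clumps):
            for lab in group:
                clump_of[lab] = ci
        rows = [
            {
                "label": i + 1,
                "row": e.cy,
                "col": e.cx,
                "semi_major": e.a,
                "semi_minor": e.b,
                "alpha": e.alpha,
                "clump": clump_of.get(i + 1, -1),
            }
            for i, e in enumerate(sample.nuclei)
        ]
        pd.DataFrame(rows).to_csv(out / f"{stem}_nuclei.csv", index=False)
        entry = {k: v for k, v in spec.__dict__.items() if k != "stain_matrix"}
        entry["image"] = f"{stem}.png"
        entry["gt"] = f"{stem}_gt.tif"
        entry["nuclei"] = f"{stem}_nuclei.csv"
        entry["n_clumps"] = len(sample.clumps)
        entries.append(entry)
    manifest = {"tiles": entries}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=list)
    return manifest


# ---------------------------------------------------------------------------
# Region-level fixtures for the refinement stage


def make_clump_region(
    seed: int,
    n_nuclei: int = 2,
    overlap: tuple[float, float] = (0.10, 0.35),
    axis_range: tuple[float, float] = (9.0, 16.0),
    frame: int = 128,
    texture_sd: float = 0.08,
    noise_sd: float = 3.0,
) -> tuple[RegionView, np.ndarray, tuple[Ellipse, ...]]:
    """Render one isolated clump (or single nucleus) and package it as a
    :class:`RegionView` for :func:`~nucleiseg.refine.refine_region`.

    The region mask is the union of the generating ellipses (single
    connected component by construction) and the gradient patch is the
    Sobel magnitude of the rendered hematoxylin field, exactly what the
    refinement stage sees in the full pipeline.  Returns the region, the
    ground-truth label crop and the generating ellipses.
    """
    spec = SyntheticSpec(
        width=frame,
        height=frame,
        n_nuclei=n_nuclei,
        overlap_fraction=1.0 if n_nuclei > 1 else 0.0,
        target_pair_overlap=overlap,
        axis_range=axis_range,
        texture_sd=texture_sd,
        noise_sd=noise_sd,
        seed=seed,
    )
    sample = generate_sample(spec)
    from .stains import separate_stains

    hema, _ = separate_stains(sample.rgb, stain_matrix=spec.stain_matrix)
    # The refinement stage operates on the gradient of the raw hematoxylin
    # channel (not the reconstruction-filtered one): the filters flatten the
    # narrow high-gradient seam between abutting nuclei, which is precisely
    # the cue the splitting watershed needs.  Same input as refine_all gets
    # in the full pipeline.
    mask = sample.gt_labels > 0
    region = RegionView(
        region_id=1,
        mask=mask,
        grad_patch=gradient_magnitude(hema),
        hema_patch=hema,
        offset=(0, 0),
    )
    return region, sample.gt_labels, sample.nuclei
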