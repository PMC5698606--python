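"""Center-proliferation segmentation (CPS) of nucleus patches.

Nuclei in an H&E pathology tile are dark (hematoxylin) blobs on a brighter
background.  CPS proceeds in four steps: (1) coarse binarisation at a
suitable threshold (Otsu by default, dark pixels = foreground), (2)
circularity filtering of connected regions (4*pi*A/P^2 > 0.85 keeps
round, isolated nuclei), (3) nucleus-center localisation at the region
centroids, and (4) extraction of a fixed-size patch around each center,
resized to the canonical 100x100 one-nucleus-per-patch format.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from skimage import measure
from skimage.color import rgb2gray
from skimage.filters import threshold_otsu
from skimage.transform import resize

from .synthetic import NucleusPatch

__all__ = [
    "LabeledRegion",
    "binarize",
    "circularity",
    "label_regions",
    "filter_regions",
    "extract_patches",
    "segment_image",
]


@dataclass(frozen=True, eq=False)  # identity equality: coords is an ndarray
class LabeledRegion:
    """One connected foreground region of the coarse segmentation."""

    coords: np.ndarray  # (n, 2) int pixel coordinates (row, col)
    area_px: int
    perimeter_px: float
    centroid: tuple[float, float]  # (row, col)


def _to_gray(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim == 3:
        # luma weights; keep the original intensity scale
        scale = 255.0 if image.dtype == np.uint8 else 1.0
        return rgb2gray(image) * scale
    return image.astype(float)


def binarize(image: np.ndarray, threshold: float | str = "auto") -> np.ndarray:
    """Coarse binary segmentation: dark (nucleus) pixels map to True.

    ``threshold="auto"`` uses Otsu's method on the intensity channel; a
    scalar threshold is used as-is.  A constant image (Otsu undefined)
    yields an all-false mask with a warning.
    """
    gray = _to_gray(image)
    if isinstance(threshold, str):
        if threshold != "auto":
            raise ValueError("threshold must be a scalar or 'auto'")
        if np.ptp(gray) == 0:
            warnings.warn("constant image: empty foreground", stacklevel=2)
            return np.zeros(gray.shape, dtype=bool)
        threshold = threshold_otsu(gray)
    mask = gray < threshold
    if not mask.any():
        warnings.warn("binarization produced an empty foreground", stacklevel=2)
    return mask


def circularity(region: LabeledRegion) -> float:
    """Roundness measure ``4*pi*area / perimeter^2``.

    ~1 for a disk, pi/4 for a square, small for elongated regions.  The
    perimeter is the larger of the chain-code (boundary-following) and
    Crofton estimates: the chain-code length collapses for one-pixel-wide
    structures (it walks an open curve), which would make degenerate lines
    look round.  A single-pixel region is defined to have circularity 1.0.
    """
    if region.perimeter_px == 0 or region.area_px == 1:
        return 1.0
    return 4.0 * math.pi * region.area_px / region.perimeter_px**2


def label_regions(mask: np.ndarray) -> list[LabeledRegion]:
    """Connected components (8-connectivity) of a binary mask."""
    labels = measure.label(np.asarray(mask, dtype=bool), connectivity=2)
    out = []
    for rp in measure.regionprops(labels):
        out.append(LabeledRegion(
            coords=rp.coords,
            area_px=int(rp.area),
            perimeter_px=float(max(rp.perimeter, rp.perimeter_crofton)),
            centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
        ))
    return out


def filter_regions(regions: list[LabeledRegion],
                   min_circularity: float = 0.85,
                   min_area: int = 0) -> list[LabeledRegion]:
    """Keep regions with circularity strictly above ``min_circularity``
    (and at least ``min_area`` pixels), preserving input order."""
    if not 0 <= min_circularity <= 1:
        raise ValueError("min_circularity must be in [0, 1]")
    return [r for r in regions
            if r.area_px >= min_area and circularity(r) > min_circularity]


def _crop_padded(image: np.ndarray, center: tuple[int, int], n: int,
                 fill) -> np.ndarray:
    """n x n crop with rows [c - n//2, c - n//2 + n - 1], padded with
    ``fill`` outside the image."""
    r0 = int(center[0]) - n // 2
    c0 = int(center[1]) - n // 2
    out = np.full((n, n), fill, dtype=image.dtype)
    rs, re = max(r0, 0), min(r0 + n, image.shape[0])
    cs, ce = max(c0, 0), min(c0 + n, image.shape[1])
    if rs < re and cs < ce:
        out[rs - r0:re - r0, cs - c0:ce - c0] = image[rs:re, cs:ce]
    return out


def extract_patches(
    image: np.ndarray,
    centers: list[tuple[float, float]],
    n: int = 50,
    patch_size: int = 100,
    threshold: float | str = "auto",
    label: str = "unknown",
) -> list[NucleusPatch]:
    """Cut an ``n x n`` patch around each center and resize to
    ``patch_size``.

    The binary mask is obtained from the coarse segmentation of the patch;
    only the connected component at (or nearest to) the patch center is
    kept, so every patch holds exactly one nucleus.  Masks are resized with
    nearest-neighbour interpolation to preserve binarity.
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    gray = _to_gray(image)
    for (r, c) in centers:
        if not (0 <= r < gray.shape[0] and 0 <= c < gray.shape[1]):
            raise ValueError(f"center ({r}, {c}) lies outside the image")
    full_mask = binarize(gray, threshold=threshold)
    patches = []
    for (r, c) in centers:
        sub = _crop_padded(full_mask, (int(round(r)), int(round(c))), n, False)
        labels = measure.label(sub, connectivity=2)
        if labels.max() == 0:
            raise ValueError(f"no foreground found around center ({r}, {c})")
        # keep the component containing (or nearest to) the patch center
        mid = n // 2
        lab = labels[mid, mid]
        if lab == 0:
            cand = np.argwhere(labels > 0)
            d = ((cand - np.array([mid, mid])) ** 2).sum(axis=1)
            lab = labels[tuple(cand[d.argmin()])]
        single = labels == lab
        big = resize(single.astype(float), (patch_size, patch_size),
                     order=0, preserve_range=True, anti_aliasing=False) > 0.5
        patches.append(NucleusPatch(mask=big,
                                    source_center=(float(r), float(c)),
                                    label=label))
    return patches


def segment_image(
    image: np.ndarray,
    n: int = 50,
    patch_size: int = 100,
    min_circularity: float = 0.85,
    min_area: int = 60,
    threshold: float | str = "auto",
) -> tuple[list[NucleusPatch], list[tuple[float, float]]]:
    """Full CPS pipeline: binarise, filter regions, locate centers,
    extract one-nucleus patches.

    Returns ``(patches, centers)``; ``centers`` are region centroids in
    source-image coordinates.  ``min_area`` suppresses speckle regions
    that would pass the circularity filter trivially.
    """
    mask = binarize(image, threshold=threshold)
    regions = filter_regions(label_regions(mask), min_circularity, min_area)
    centers = [r.centroid for r in regions]
    if not centers:
        return [], []
    patches = extract_patches(image, centers, n=n, patch_size=patch_size,
                              threshold=threshold)
    return patches, centers
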