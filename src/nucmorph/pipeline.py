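"""End-to-end feature extraction: masks -> feature table.

Ties the stages together the way the recognition method prescribes:

* shape-similarity features are computed on fully aligned masks (center,
  area ~1000 px, horizontal principal axis) against an aligned library;
* boundary-similarity features are computed on pose-aligned masks (center
  and direction only — the ellipse semi-axes come from the original
  nucleus scale).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .alignment import align
from .boundary_features import (boundary_feature_points, ellipse_template,
                                extract_boundary, triangle_features)
from .classify import FeatureTable
from .shape_features import ShapeLibrary, build_library, shape_feature_vector
from .synthetic import NucleusPatch

__all__ = ["align_masks", "library_from_patches", "extract_features"]


def align_masks(masks, target_area: float = 1000.0) -> list[np.ndarray]:
    """Fully align a list of masks into the uniform standard space."""
    return [align(np.asarray(m, dtype=bool), target_area=target_area)[0]
            for m in masks]


def library_from_patches(patches: list[NucleusPatch], n_per_class: int = 80,
                         seed: int = 0, target_area: float = 1000.0,
                         selection="random") -> ShapeLibrary:
    """Align candidate patches and build the shape library from them."""
    aligned = align_masks([p.mask for p in patches], target_area)
    labels = [p.label for p in patches]
    return build_library(aligned, labels, n_per_class=n_per_class,
                         selection=selection, seed=seed,
                         target_area=target_area)


def boundary_feature_vector(mask: np.ndarray, k: int = 12,
                            mode: str = "paper",
                            boundary_method: str = "gradient") -> pd.Series:
    """Triangle features of one mask after pose-only alignment."""
    posed, _ = align(np.asarray(mask, dtype=bool), scale=False)
    boundary = extract_boundary(posed, method=boundary_method)
    template = ellipse_template(posed, k=k)
    landmarks = boundary_feature_points(boundary, template)
    return triangle_features(landmarks, mode=mode).values


def extract_features(
    patches: list[NucleusPatch],
    library: ShapeLibrary | None = None,
    metrics: tuple[str, ...] = ("JI",),
    include_boundary: bool = True,
    k: int = 12,
    mode: str = "paper",
    target_area: float = 1000.0,
) -> FeatureTable:
    """Feature table for a list of nucleus patches.

    ``metrics`` selects the shape-similarity families (subset of DI, JI,
    P, R; empty tuple or ``library=None`` skips them);
    ``include_boundary`` appends the triangle features.  The JI + BF
    default is the combination found most discriminative.
    """
    rows = []
    for p in patches:
        parts = []
        if library is not None and metrics:
            aligned, _ = align(p.mask, target_area=target_area)
            parts.append(shape_feature_vector(aligned, library, metrics))
        if include_boundary:
            parts.append(boundary_feature_vector(p.mask, k=k, mode=mode))
        if not parts:
            raise ValueError("no feature families requested")
        rows.append(pd.concat(parts))
    features = pd.DataFrame(rows).reset_index(drop=True)
    labels = np.array([p.label for p in patches])
    return FeatureTable(features, labels)
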