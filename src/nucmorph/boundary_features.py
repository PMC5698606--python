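"""Triangle-based boundary-similarity features.

The boundary of a (center- and direction-aligned, but not rescaled)
nucleus is reduced to ``k`` ordered landmarks: an ellipse template with the
nucleus' second-moment semi-axes ``(a, b)`` is sampled at equal polar-angle
intervals (pi/6 for the default k = 12, anticlockwise from the positive
horizontal axis), and each template point is matched to its nearest
boundary pixel.  Every landmark triple ``(i, j, k)`` forms a triangle whose
shape is captured by interior-angle cosines; with 12 landmarks there are
C(12,3) = 220 triangles.  Angles are scale-free, so these features carry
boundary-irregularity information independent of nucleus size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import feature as skfeature
from skimage import measure

__all__ = [
    "EllipseTemplate",
    "LandmarkSet",
    "TriangleFeatures",
    "extract_boundary",
    "ellipse_template",
    "boundary_feature_points",
    "triangle_features",
]

_EDGE_STRUCT = np.ones((3, 3), dtype=bool)  # 8-connected inner boundary


def extract_boundary(mask: np.ndarray, method: str = "gradient") -> np.ndarray:
    """Closed one-pixel boundary of the single foreground component.

    Holes are filled first (the outer boundary is the shape's boundary).
    ``method="gradient"`` (default) uses the morphological gradient
    ``mask & ~erosion(mask)`` — deterministic and parameter-free;
    ``method="canny"`` runs a Canny edge detector on the mask instead.

    Returns an ``(n, 2)`` integer array of (row, col) boundary pixels in
    lexicographic order.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    n_comp = measure.label(mask, connectivity=2).max()
    if n_comp > 1:
        raise ValueError(f"mask has {n_comp} connected components, expected 1")
    filled = ndimage.binary_fill_holes(mask)
    if method == "gradient":
        edge = filled & ~ndimage.binary_erosion(filled, structure=_EDGE_STRUCT)
    elif method == "canny":
        edge = skfeature.canny(filled.astype(float), sigma=1.0)
        if not edge.any():  # tiny shapes: fall back to the gradient
            edge = filled & ~ndimage.binary_erosion(filled, structure=_EDGE_STRUCT)
    else:
        raise ValueError("method must be 'gradient' or 'canny'")
    pts = np.argwhere(edge)
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    return pts[order]


@dataclass(frozen=True)
class EllipseTemplate:
    """Ellipse with the nucleus' semi-axes, sampled at k equal polar angles."""

    a: float  # semi-major axis, px
    b: float  # semi-minor axis, px
    center: tuple[float, float]  # (row, col)
    angles: np.ndarray  # k polar angles (radians)
    points: np.ndarray  # (k, 2) template points, (row, col)


def ellipse_template(mask: np.ndarray, k: int = 12,
                     initial_angle: float = 0.0) -> EllipseTemplate:
    """Ellipse template of a direction-aligned nucleus.

    Semi-axes are derived from the second central moments (an ellipse with
    semi-axes A, B has coordinate variances A^2/4 and B^2/4 along its
    principal directions).  Template points sit at polar angles
    ``initial_angle + j * 2*pi/k``, anticlockwise on screen, starting on
    the positive horizontal axis; the interval is pi/6 for k = 12.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    rows, cols = np.nonzero(mask)
    x = cols.astype(float)
    y = -rows.astype(float)  # y-up
    dx, dy = x - x.mean(), y - y.mean()
    var_x, var_y = (dx * dx).mean(), (dy * dy).mean()
    a = 2.0 * math.sqrt(max(var_x, var_y))
    b = 2.0 * math.sqrt(min(var_x, var_y))
    if b < 0.5:
        raise ValueError("degenerate mask: minor axis collapses (b < 0.5 px)")
    cr, cc = rows.mean(), cols.mean()
    angles = initial_angle + np.arange(k) * (2.0 * math.pi / k)
    prow = cr - b * np.sin(angles)
    pcol = cc + a * np.cos(angles)
    return EllipseTemplate(a=a, b=b, center=(cr, cc), angles=angles,
                           points=np.stack([prow, pcol], axis=1))


@dataclass(frozen=True)
class LandmarkSet:
    """k ordered boundary feature points (row, col) and their template."""

    points: np.ndarray  # (k, 2) float, each an actual boundary pixel
    template: EllipseTemplate

    def __len__(self) -> int:
        return len(self.points)


def boundary_feature_points(boundary: np.ndarray,
                            template: EllipseTemplate) -> LandmarkSet:
    """Match each template point to its nearest boundary pixel.

    Ties in Euclidean distance are broken by the smallest (row, col) in
    lexicographic order; ``boundary`` as returned by ``extract_boundary``
    is already lexicographically sorted, so the first minimiser wins.
    """
    boundary = np.asarray(boundary, dtype=float)
    if boundary.ndim != 2 or boundary.shape[0] == 0:
        raise ValueError("boundary must be a non-empty (n, 2) array")
    order = np.lexsort((boundary[:, 1], boundary[:, 0]))
    boundary = boundary[order]
    d2 = ((boundary[None, :, :] - template.points[:, None, :]) ** 2).sum(axis=2)
    idx = d2.argmin(axis=1)  # first occurrence = lexicographic tie-break
    return LandmarkSet(points=boundary[idx].copy(), template=template)


@dataclass(frozen=True)
class TriangleFeatures:
    """Interior-angle cosines of all C(k,3) landmark triangles."""

    values: pd.Series  # named bf.i.j.k (mode=paper) or bf.i.j.k.{j,k}
    triples: tuple[tuple[int, int, int], ...]
    n_degenerate: int
    mode: str


def _triangle_cosines(p_i, p_j, p_k):
    """cos of the angles at vertices j and k, by the law of cosines."""
    d_ij2 = float(((p_i - p_j) ** 2).sum())
    d_jk2 = float(((p_j - p_k) ** 2).sum())
    d_ik2 = float(((p_i - p_k) ** 2).sum())
    if d_ij2 == 0.0 or d_jk2 == 0.0 or d_ik2 == 0.0:
        return 1.0, 1.0, True  # coincident vertices: zero-angle limit
    cos_j = (d_ij2 + d_jk2 - d_ik2) / (2.0 * math.sqrt(d_ij2 * d_jk2))
    cos_k = (d_ik2 + d_jk2 - d_ij2) / (2.0 * math.sqrt(d_ik2 * d_jk2))
    cos_j = min(1.0, max(-1.0, cos_j))
    cos_k = min(1.0, max(-1.0, cos_k))
    degen = abs(cos_j) >= 1.0 - 1e-12 or abs(cos_k) >= 1.0 - 1e-12
    return cos_j, cos_k, degen


def triangle_features(landmarks: LandmarkSet | np.ndarray,
                      mode: str = "paper") -> TriangleFeatures:
    """Boundary-similarity feature vector from landmark triangles.

    All C(k,3) vertex triples are enumerated in lexicographic order of
    (i, j, k).  ``mode="paper"`` stores one cosine per triangle (the angle
    at the middle vertex j), giving 220 dimensions for k = 12;
    ``mode="full"`` stores the cosines at both j and k (440 dimensions).
    Degenerate (collinear or coincident) triples get the limiting cosine
    values and are counted in ``n_degenerate``.
    """
    if mode not in ("paper", "full"):
        raise ValueError("mode must be 'paper' or 'full'")
    pts = landmarks.points if isinstance(landmarks, LandmarkSet) else np.asarray(
        landmarks, dtype=float)
    k = len(pts)
    if k < 3:
        raise ValueError("need at least 3 landmarks")
    values, names, triples = [], [], []
    n_degen = 0
    for i, j, l in combinations(range(k), 3):
        cos_j, cos_l, degen = _triangle_cosines(pts[i], pts[j], pts[l])
        n_degen += degen
        triples.append((i, j, l))
        if mode == "paper":
            values.append(cos_j)
            names.append(f"bf.{i}.{j}.{l}")
        else:
            values.extend([cos_j, cos_l])
            names.extend([f"bf.{i}.{j}.{l}.j", f"bf.{i}.{j}.{l}.k"])
    return TriangleFeatures(
        values=pd.Series(values, index=names, dtype=float),
        triples=tuple(triples),
        n_degenerate=n_degen,
        mode=mode,
    )
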