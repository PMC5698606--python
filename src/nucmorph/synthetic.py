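"""Synthetic binary nucleus masks of two morphological classes.

The generator emulates the one-nucleus-per-100x100-patch regime of H&E
liver-pathology patches: each nucleus is a star-shaped region whose boundary
is an ellipse modulated by a small number of random radial harmonics,

    r(t) = r_ellipse(t) * (1 + sum_h eps_h * cos(h*t + psi_h)),

rasterised and filled.  The two class archetypes encode the qualitative
pathology contrast the recognition task relies on: normal hepatocyte nuclei
are small, near-elliptical and smooth, while HCC (hepatocellular carcinoma)
nuclei are enlarged, more elongated and have irregular boundaries.

``generate_pathology_image`` additionally composes many nuclei into a single
intensity image (dark nuclei on a bright, lightly textured background) with
ground-truth centers, as a test bed for the segmentation stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import polygon
from skimage.filters import gaussian

__all__ = [
    "NucleusModel",
    "ClassParams",
    "DEFAULT_CLASS_PARAMS",
    "NucleusPatch",
    "generate_mask",
    "sample_model",
    "generate_dataset",
    "generate_pathology_image",
    "interpolate_class_params",
]

NORMAL = "normal"
HCC = "HCC"


@dataclass(frozen=True)
class NucleusModel:
    """Parametric description of one synthetic nucleus.

    ``epsilon`` is the total radial perturbation amplitude as a fraction of
    the local ellipse radius (sum of harmonic amplitudes); ``n_harmonics``
    random cosine harmonics (orders 2..n+1) share it.
    """

    semi_axis_a: float
    semi_axis_b: float
    epsilon: float = 0.0
    n_harmonics: int = 6
    orientation: float = 0.0
    label: str = NORMAL

    def __post_init__(self):
        if not (self.semi_axis_a >= self.semi_axis_b > 0):
            raise ValueError("require a >= b > 0")
        if not (0 <= self.epsilon < 0.5):
            raise ValueError("epsilon must be in [0, 0.5)")


@dataclass(frozen=True)
class NucleusPatch:
    """One nucleus mask in a fixed-size patch."""

    mask: np.ndarray
    source_center: tuple[float, float] = (0.0, 0.0)  # (row, col) in source image
    label: str = "unknown"


@dataclass(frozen=True)
class ClassParams:
    """Sampling ranges for one morphological class (uniform draws)."""

    area: tuple[float, float]
    aspect: tuple[float, float]
    epsilon: tuple[float, float]
    n_harmonics: int = 6


# Class archetypes: normal = near-elliptical and smooth; HCC = enlarged,
# more elongated, rough-boundaried, with higher size variance.
DEFAULT_CLASS_PARAMS: dict[str, ClassParams] = {
    NORMAL: ClassParams(area=(600.0, 1200.0), aspect=(1.0, 1.4), epsilon=(0.0, 0.05)),
    HCC: ClassParams(area=(800.0, 2600.0), aspect=(1.0, 2.2), epsilon=(0.1, 0.3)),
}


def interpolate_class_params(contrast: float) -> dict[str, ClassParams]:
    """Class archetypes with the HCC-vs-normal contrast scaled by
    ``contrast`` in [0, 1]: 0 makes the two classes identical (the normal
    archetype), 1 restores the defaults.  Used to verify that classifier
    accuracy degrades to chance as the morphological contrast vanishes.
    """
    if not 0 <= contrast <= 1:
        raise ValueError("contrast must be in [0, 1]")
    n = DEFAULT_CLASS_PARAMS[NORMAL]
    h = DEFAULT_CLASS_PARAMS[HCC]

    def lerp(lo, hi):
        return tuple(a + contrast * (b - a) for a, b in zip(lo, hi))

    return {
        NORMAL: n,
        HCC: ClassParams(area=lerp(n.area, h.area),
                         aspect=lerp(n.aspect, h.aspect),
                         epsilon=lerp(n.epsilon, h.epsilon),
                         n_harmonics=h.n_harmonics),
    }


def _boundary_radius(model: NucleusModel, t: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    a, b = model.semi_axis_a, model.semi_axis_b
    tt = t - model.orientation
    r_ell = a * b / np.hypot(b * np.cos(tt), a * np.sin(tt))
    if model.epsilon > 0 and model.n_harmonics > 0:
        amps = rng.uniform(0.3, 1.0, model.n_harmonics)
        amps *= model.epsilon / amps.sum()
        phases = rng.uniform(0, 2 * math.pi, model.n_harmonics)
        orders = np.arange(2, model.n_harmonics + 2)
        mod = 1.0 + (amps[None, :] * np.cos(orders[None, :] * t[:, None]
                                            + phases[None, :])).sum(axis=1)
        r_ell = r_ell * mod
    return r_ell


def generate_mask(model: NucleusModel, patch_size: int = 100,
                  seed: int | np.random.Generator = 0) -> NucleusPatch:
    """Rasterise one nucleus into a ``patch_size`` square patch.

    Deterministic for a given ``(model, seed)``.  Raises ``ValueError`` if
    the nucleus does not fit the patch at its scale.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.linspace(0, 2 * math.pi, 1024, endpoint=False)
    r = _boundary_radius(model, t, rng)
    if r.max() >= patch_size / 2 - 1:
        raise ValueError(
            f"nucleus radius {r.max():.1f} px exceeds patch of size {patch_size}"
        )
    c = (patch_size - 1) / 2.0
    # y-up convention: anticlockwise boundary on screen
    cols = c + r * np.cos(t)
    rows = c - r * np.sin(t)
    rr, cc = polygon(rows, cols, shape=(patch_size, patch_size))
    mask = np.zeros((patch_size, patch_size), dtype=bool)
    mask[rr, cc] = True
    mask = ndimage.binary_fill_holes(mask)
    return NucleusPatch(mask=mask, source_center=(c, c), label=model.label)


def sample_model(params: ClassParams, label: str,
                 rng: np.random.Generator) -> NucleusModel:
    """Draw one nucleus model from a class archetype."""
    area = rng.uniform(*params.area)
    aspect = rng.uniform(*params.aspect)
    eps = rng.uniform(*params.epsilon)
    # area of the base ellipse is pi*a*b; aspect = a/b
    b = math.sqrt(area / (math.pi * aspect))
    a = aspect * b
    return NucleusModel(
        semi_axis_a=a, semi_axis_b=b, epsilon=eps,
        n_harmonics=params.n_harmonics,
        orientation=rng.uniform(0, math.pi), label=label,
    )


def generate_dataset(
    n_per_class: int,
    class_params: dict[str, ClassParams] | None = None,
    seed: int = 0,
    patch_size: int = 100,
) -> tuple[list[NucleusPatch], pd.DataFrame]:
    """Balanced two-class mask dataset with a manifest.

    Returns ``(patches, manifest)`` where the manifest has one row per patch
    (id, label) in generation order: all normal first, then all HCC.  A
    single global seed fans out to per-nucleus substreams, so datasets are
    reproducible and extensible.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    params = class_params or DEFAULT_CLASS_PARAMS
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * n_per_class)
    patches: list[NucleusPatch] = []
    rows = []
    i = 0
    for label in (NORMAL, HCC):
        for j in range(n_per_class):
            rng = np.random.default_rng(children[i])
            # redraw models whose extreme size/aspect/roughness combination
            # would overflow the patch
            for _ in range(50):
                model = sample_model(params[label], label, rng)
                try:
                    patch = generate_mask(model, patch_size=patch_size, seed=rng)
                    break
                except ValueError:
                    continue
            else:
                raise ValueError(
                    f"no nucleus of class '{label}' fits a "
                    f"{patch_size}x{patch_size} patch under the given params"
                )
            patches.append(patch)
            rows.append({"id": f"{label}_{j:05d}", "label": label})
            i += 1
    return patches, pd.DataFrame(rows)


def generate_pathology_image(
    n_nuclei: int,
    image_size: int = 512,
    seed: int = 0,
    max_retries: int = 2000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Compose non-overlapping nuclei into one intensity image.

    Nuclei are round-ish and smooth (they must survive the circularity
    filter of the segmentation stage).  Returns ``(image, centers, labels)``
    where ``image`` is a uint8 grayscale raster (dark nuclei ~ intensity 60
    on a bright ~200 textured background), ``centers`` is an ``(n, 2)``
    array of ground-truth (row, col) centers, and ``labels`` the full-size
    integer label image of the planted masks (0 = background).
    """
    rng = np.random.default_rng(seed)
    label_img = np.zeros((image_size, image_size), dtype=int)
    centers = []
    placed_disks: list[tuple[float, float, float]] = []
    tries = 0
    k = 0
    while k < n_nuclei:
        if tries >= max_retries:
            raise RuntimeError(
                f"could not place {n_nuclei} non-overlapping nuclei in a "
                f"{image_size}x{image_size} image; try fewer nuclei"
            )
        tries += 1
        radius = rng.uniform(12, 20)
        aspect = rng.uniform(1.0, 1.25)
        b = radius / math.sqrt(aspect)
        a = radius * math.sqrt(aspect)
        margin = a + 3
        cr = rng.uniform(margin, image_size - margin)
        cc = rng.uniform(margin, image_size - margin)
        if any(math.hypot(cr - r0, cc - c0) < a + a0 + 4
               for r0, c0, a0 in placed_disks):
            continue
        model = NucleusModel(semi_axis_a=a, semi_axis_b=b,
                             epsilon=rng.uniform(0.0, 0.04), n_harmonics=4,
                             orientation=rng.uniform(0, math.pi))
        t = np.linspace(0, 2 * math.pi, 720, endpoint=False)
        r = _boundary_radius(model, t, rng)
        rows = cr - r * np.sin(t)
        cols = cc + r * np.cos(t)
        rr, cc_idx = polygon(rows, cols, shape=label_img.shape)
        if label_img[rr, cc_idx].any():
            continue
        k += 1
        label_img[rr, cc_idx] = k
        centers.append((float(np.mean(rr)), float(np.mean(cc_idx))))
        placed_disks.append((cr, cc, a))

    image = rng.normal(200.0, 6.0, (image_size, image_size))
    nuc = label_img > 0
    image[nuc] = rng.normal(60.0, 6.0, int(nuc.sum()))
    image = gaussian(image, sigma=1.0, preserve_range=True)
    image = np.clip(image, 0, 255).astype(np.uint8)
    return image, np.array(centers, dtype=float).reshape(-1, 2), label_img
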