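"""Shape-similarity features against a nucleus shape library.

A query nucleus, once aligned into the uniform standard space, is compared
against every entry of a reference library of aligned nucleus masks (by
default 80 normal + 80 HCC) using four set-overlap coefficients on the
foreground pixel sets: Dice (DI), Jaccard (JI), precision (P) and recall
(R).  One value per metric per library entry yields, at the default library
size of 160, feature vectors of 160 dimensions per metric and 640 in total.

Convention: the query mask plays the role of the segmentation region (SR)
and the library mask the reference region (TR); this fixes which of P and R
is which.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import principal_angle

__all__ = [
    "OverlapScores",
    "ShapeLibrary",
    "overlap_metrics",
    "build_library",
    "shape_feature_vector",
    "METRICS",
]

METRICS = ("DI", "JI", "P", "R")


@dataclass(frozen=True)
class OverlapScores:
    dice: float
    jaccard: float
    precision: float
    recall: float

    def as_dict(self) -> dict[str, float]:
        return {"DI": self.dice, "JI": self.jaccard,
                "P": self.precision, "R": self.recall}


def overlap_metrics(sr: np.ndarray, tr: np.ndarray) -> OverlapScores:
    """Dice, Jaccard, precision and recall between two binary masks.

    ``sr`` is the query/segmentation region, ``tr`` the reference region.
    ``tr`` must be non-empty; an empty ``sr`` yields all-zero scores
    (precision 0/0 is defined as 0 by convention).
    """
    sr = np.asarray(sr, dtype=bool)
    tr = np.asarray(tr, dtype=bool)
    if sr.shape != tr.shape:
        raise ValueError(f"mask shapes differ: {sr.shape} vs {tr.shape}")
    n_sr = int(sr.sum())
    n_tr = int(tr.sum())
    if n_tr == 0:
        raise ValueError("reference mask (TR) is empty" +
                         ("; both masks empty (0/0)" if n_sr == 0 else ""))
    inter = int((sr & tr).sum())
    union = n_sr + n_tr - inter
    return OverlapScores(
        dice=2.0 * inter / (n_sr + n_tr),
        jaccard=inter / union,
        precision=(inter / n_sr) if n_sr else 0.0,
        recall=inter / n_tr,
    )


def _check_aligned(mask: np.ndarray, target_area: float, area_tol: float,
                   what: str) -> None:
    area = int(np.asarray(mask, dtype=bool).sum())
    if abs(area - target_area) > area_tol * target_area:
        raise ValueError(
            f"{what} has foreground area {area}, outside "
            f"{target_area}±{100 * area_tol:.0f}%: align it first"
        )


@dataclass(frozen=True)
class ShapeLibrary:
    """Ordered reference set of aligned nucleus masks with class labels.

    The entry order is fixed: feature columns are indexed by it, so the
    library must be persisted (see ``nucmorph.io``) and reused unchanged
    across training and prediction.
    """

    masks: tuple[np.ndarray, ...]
    labels: tuple[str, ...]
    ids: tuple[str, ...]
    target_area: float = 1000.0

    def __post_init__(self):
        if not (len(self.masks) == len(self.labels) == len(self.ids)):
            raise ValueError("masks, labels and ids must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("library ids must be unique")

    def __len__(self) -> int:
        return len(self.masks)

    @property
    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for lab in self.labels:
            counts[lab] = counts.get(lab, 0) + 1
        return counts


def build_library(
    masks: list[np.ndarray],
    labels: list[str],
    n_per_class: int = 80,
    selection: str | list[int] = "random",
    seed: int = 0,
    ids: list[str] | None = None,
    target_area: float = 1000.0,
    validate: bool = True,
) -> ShapeLibrary:
    """Assemble the nucleus shape library (default 80 per class).

    ``selection`` is either ``"random"`` (a seeded uniform draw without
    replacement, per class) or an explicit list of indices into ``masks``
    standing in for the pathologists' manual pick.  All entries must already
    be aligned (area within 5% of ``target_area``); principal angles are
    checked to be near-horizontal.
    """
    if ids is None:
        ids = [f"lib_{i:04d}" for i in range(len(masks))]
    labels = list(labels)

    if isinstance(selection, str):
        if selection != "random":
            raise ValueError("selection must be 'random' or an index list")
        rng = np.random.default_rng(seed)
        chosen: list[int] = []
        for cls in dict.fromkeys(labels):  # preserves first-seen class order
            pool = [i for i, lab in enumerate(labels) if lab == cls]
            if len(pool) < n_per_class:
                raise ValueError(
                    f"class '{cls}' has only {len(pool)} masks, "
                    f"need {n_per_class}"
                )
            chosen.extend(sorted(rng.choice(pool, n_per_class, replace=False)))
    else:
        chosen = list(selection)

    sel_masks, sel_labels, sel_ids = [], [], []
    for i in chosen:
        m = np.asarray(masks[i], dtype=bool)
        if validate:
            _check_aligned(m, target_area, 0.05, f"library mask {ids[i]}")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if abs(principal_angle(m)) > 0.03:
                    raise ValueError(
                        f"library mask {ids[i]} is not direction-aligned"
                    )
        sel_masks.append(m)
        sel_labels.append(labels[i])
        sel_ids.append(ids[i])
    return ShapeLibrary(tuple(sel_masks), tuple(sel_labels), tuple(sel_ids),
                        target_area=target_area)


def shape_feature_vector(
    mask: np.ndarray,
    library: ShapeLibrary,
    metrics: tuple[str, ...] = METRICS,
) -> pd.Series:
    """Similarity feature vector of one aligned query mask.

    For each requested metric, one value per library entry in library
    order; with all four metrics and a 160-entry library the vector has
    640 dimensions.  Columns are named ``metric.library_id``.
    """
    bad = [m for m in metrics if m not in METRICS]
    if bad:
        raise ValueError(f"unknown metrics {bad}; choose from {METRICS}")
    if len(library) == 0:
        raise ValueError("library is empty")
    _check_aligned(mask, library.target_area, 0.05, "query mask")

    scores = [overlap_metrics(mask, lm).as_dict() for lm in library.masks]
    values, names = [], []
    for metric in metrics:
        for s, lid in zip(scores, library.ids):
            values.append(s[metric])
            names.append(f"{metric}.{lid}")
    return pd.Series(values, index=names, dtype=float)
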