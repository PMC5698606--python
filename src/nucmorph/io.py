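"""Mask and manifest I/O.

Masks travel as 0/255 single-channel PNGs, one nucleus per fixed-size
patch; datasets are described by a CSV manifest with one row per patch
(patch_path, source_image, center_row, center_col, label).  The shape
library is persisted the same way so that feature-column order is stable
across runs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .shape_features import ShapeLibrary
from .synthetic import NucleusPatch

__all__ = [
    "save_mask", "load_mask", "save_patches", "load_patches",
    "save_library", "load_library",
]


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    arr = (np.asarray(mask, dtype=bool) * np.uint8(255))
    Image.fromarray(arr, mode="L").save(path)


def load_mask(path: str | Path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    return arr > 127


def save_patches(patches: list[NucleusPatch], out_dir: str | Path,
                 source_image: str = "", prefix: str = "patch") -> pd.DataFrame:
    """Write patch masks + manifest CSV; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, p in enumerate(patches):
        name = f"{prefix}_{i:05d}.png"
        save_mask(p.mask, out_dir / name)
        rows.append({
            "patch_path": name,
            "source_image": source_image,
            "center_row": p.source_center[0],
            "center_col": p.source_center[1],
            "label": p.label,
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_patches(manifest_path: str | Path) -> list[NucleusPatch]:
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    patches = []
    for _, row in manifest.iterrows():
        patches.append(NucleusPatch(
            mask=load_mask(base / row["patch_path"]),
            source_center=(float(row["center_row"]), float(row["center_col"])),
            label=str(row["label"]),
        ))
    return patches


def save_library(library: ShapeLibrary, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for mask, label, lid in zip(library.masks, library.labels, library.ids):
        name = f"{lid}.png"
        save_mask(mask, out_dir / name)
        rows.append({"id": lid, "mask_path": name, "label": label})
    pd.DataFrame(rows).to_csv(out_dir / "library.csv", index=False)


def load_library(manifest_path: str | Path,
                 target_area: float = 1000.0) -> ShapeLibrary:
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    masks = tuple(load_mask(base / p) for p in df["mask_path"])
    return ShapeLibrary(masks=masks, labels=tuple(df["label"].astype(str)),
                        ids=tuple(df["id"].astype(str)),
                        target_area=target_area)
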