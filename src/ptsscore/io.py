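"""File I/O: paired PNG tiles, label maps, cohort CSVs, YAML specs, overlays."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .tissue import BACKGROUND, TissueClass

__all__ = [
    "save_rgb", "load_rgb", "save_labelmap", "load_labelmap",
    "save_tile_pairs", "load_tile_pairs",
    "save_cohort", "load_cohort",
    "read_yaml", "write_yaml", "write_json",
    "pts_overlay",
]


def save_rgb(path, array: np.ndarray) -> None:
    Image.fromarray(np.asarray(array, dtype=np.uint8), mode="RGB").save(path)


def load_rgb(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def save_labelmap(path, labels: np.ndarray) -> None:
    labels = np.asarray(labels, dtype=np.uint8)
    if str(path).lower().endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(path, labels)
    else:
        Image.fromarray(labels, mode="L").save(path)


def load_labelmap(path) -> np.ndarray:
    if str(path).lower().endswith((".tif", ".tiff")):
        import tifffile

        return np.asarray(tifffile.imread(path))
    return np.asarray(Image.open(path).convert("L"))


def save_tile_pairs(directory, pairs: list, prefix: str = "tile") -> pd.DataFrame:
    """Write (tile, labels) pairs as paired PNGs plus a manifest CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (tile, labels) in enumerate(pairs):
        img = f"{prefix}_{i:05d}.png"
        lab = f"{prefix}_{i:05d}_labels.png"
        save_rgb(directory / img, tile)
        save_labelmap(directory / lab, labels)
        rows.append({"image": img, "labels": lab})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(directory / "manifest.csv", index=False)
    return manifest


def load_tile_pairs(directory) -> list:
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    return [
        (load_rgb(directory / r.image), load_labelmap(directory / r.labels))
        for r in manifest.itertuples()
    ]


def save_cohort(path, cohort: pd.DataFrame) -> None:
    """Cohort CSV with NA encoded as an empty field."""
    cohort.to_csv(path, index=False, na_rep="")


def load_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"li": object, "pi": object, "vi": object})
    if "lnm" in df.columns:
        df["lnm"] = df["lnm"].astype(bool)
    return df


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(path, data: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def write_json(path, data: dict) -> None:
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def pts_overlay(labels: np.ndarray, region: np.ndarray) -> np.ndarray:
    """Three-color overlay: tumor purple, PTS green, everything else gray."""
    h, w = labels.shape
    out = np.full((h, w, 3), 210, dtype=np.uint8)
    tumor = labels == int(TissueClass.TUMOR)
    pts = (labels == int(TissueClass.STROMA)) & np.asarray(region, dtype=bool)
    out[labels == BACKGROUND] = (255, 255, 255)
    out[tumor] = (128, 0, 128)
    out[pts] = (0, 160, 0)
    return out
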