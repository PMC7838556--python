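"""Binary morphological image processing for tumor-region delineation.

The peri-tumoral stroma (PTS) score of a slide is computed from its tissue
label map in three steps:

1. the binary tumor mask (pixels labeled as cancer epithelium) is
   morphologically *closed* — dilated then eroded with the same structuring
   element (SE) — which fills intra-tumoral gaps narrower than the SE and
   yields the tumor *region*;
2. the PTS area is the number of stroma pixels lying inside that region;
3. PTS score = PTS area / tumor area, where the tumor area is the raw count
   of cancer-epithelium pixels (not the closed region).

The score is a dimensionless ratio, non-negative, and may exceed 1 on
stroma-rich slides.

Dilation and erosion are computed by FFT convolution against the SE
footprint and exact integer thresholding; the operations agree exactly with
the set-theoretic definitions (see the brute-force oracles in the test
suite).  Pixels outside the image are treated as background (false), and
:func:`compute_pts` pads the label map by the SE radius before closing so
image borders never truncate the tumor region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .tissue import BACKGROUND, TissueClass, validate_labelmap

__all__ = [
    "StructuringElement",
    "PtsResult",
    "dilate",
    "erode",
    "close_tumor_region",
    "compute_pts",
    "remove_small_objects",
]


@dataclass(frozen=True)
class StructuringElement:
    """Binary footprint probing the image during morphological operations.

    Parameters
    ----------
    footprint
        2-D boolean matrix with at least one true cell.
    origin
        (row, col) of the anchor cell within the footprint.  Defaults to the
        central cell.
    name
        Human-readable descriptor recorded in results.
    """

    footprint: np.ndarray
    origin: tuple[int, int] = field(default=None)  # type: ignore[assignment]
    name: str = "custom"

    def __post_init__(self) -> None:
        fp = np.asarray(self.footprint, dtype=bool)
        if fp.ndim != 2:
            raise ValueError("structuring element footprint must be 2-D")
        if not fp.any():
            raise ValueError("structuring element must contain at least one true cell")
        object.__setattr__(self, "footprint", fp)
        origin = self.origin
        if origin is None:
            origin = (fp.shape[0] // 2, fp.shape[1] // 2)
        oy, ox = origin
        if not (0 <= oy < fp.shape[0] and 0 <= ox < fp.shape[1]):
            raise ValueError(f"origin {origin} outside footprint bounds {fp.shape}")
        object.__setattr__(self, "origin", (int(oy), int(ox)))

    @classmethod
    def disk(cls, radius: int) -> "StructuringElement":
        """Disk of the given radius in pixels (Euclidean, inclusive)."""
        if radius < 0:
            raise ValueError("radius must be >= 0")
        yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
        fp = yy * yy + xx * xx <= radius * radius
        return cls(fp, (radius, radius), name=f"disk(r={radius})")

    @classmethod
    def square(cls, side: int) -> "StructuringElement":
        """Filled square of the given side length in pixels."""
        if side < 1:
            raise ValueError("side must be >= 1")
        fp = np.ones((side, side), dtype=bool)
        return cls(fp, (side // 2, side // 2), name=f"square({side})")

    @property
    def radius(self) -> int:
        """Maximal reach of the footprint from its origin, in pixels."""
        oy, ox = self.origin
        h, w = self.footprint.shape
        return int(max(oy, h - 1 - oy, ox, w - 1 - ox))


@dataclass(frozen=True)
class PtsResult:
    """Areas and score produced by :func:`compute_pts`.

    ``tumor_area`` and ``pts_area`` are pixel counts at the processed
    resolution; ``score = pts_area / tumor_area`` is scale-free.
    """

    tumor_area: int
    pts_area: int
    score: float
    se_name: str

    def to_dict(self) -> dict:
        return {
            "tumor_area": int(self.tumor_area),
            "pts_area": int(self.pts_area),
            "score": float(self.score),
            "structuring_element": self.se_name,
        }


def _conv_counts(mask: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Full convolution of a binary mask with a binary kernel, exact ints."""
    c = fftconvolve(mask.astype(np.float64), kernel.astype(np.float64), mode="full")
    return np.rint(c).astype(np.int64)


def dilate(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Binary dilation: true where the reflected SE placed there hits the mask.

    Outside-image pixels are treated as false, so dilation never wraps.
    """
    mask = np.asarray(mask, dtype=bool)
    oy, ox = se.origin
    h, w = mask.shape
    full = _conv_counts(mask, se.footprint)
    return full[oy : oy + h, ox : ox + w] >= 1


def erode(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Binary erosion: true where the SE placed there fits inside the mask.

    Outside-image pixels are false, so erosion shrinks the mask at borders.
    """
    mask = np.asarray(mask, dtype=bool)
    fp = se.footprint
    oy, ox = se.origin
    h, w = mask.shape
    kh, kw = fp.shape
    # correlation(mask, fp)[p] = sum_d mask[p + d] fp[origin + d]
    # expressed through the full convolution with the flipped footprint
    full = _conv_counts(mask, fp[::-1, ::-1])
    sy, sx = kh - 1 - oy, kw - 1 - ox
    counts = full[sy : sy + h, sx : sx + w]
    return counts >= int(fp.sum())


def close_tumor_region(tumor_mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Morphological closing: dilation followed by erosion with the same SE.

    Extensive (result contains the input for origin-containing SEs) and
    idempotent; fills gaps and holes narrower than the SE.  The mask is
    padded by the SE radius before closing so the dilation is not clipped at
    the array boundary, and cropped back afterwards.
    """
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    r = se.radius
    padded = np.pad(tumor_mask, r, mode="constant", constant_values=False)
    closed = erode(dilate(padded, se), se)
    if r:
        closed = closed[r:-r, r:-r]
    return closed


def remove_small_objects(mask: np.ndarray, min_size: int) -> np.ndarray:
    """Drop connected components smaller than ``min_size`` pixels (8-connected)."""
    from scipy import ndimage

    mask = np.asarray(mask, dtype=bool)
    if min_size <= 1:
        return mask
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_size
    keep[0] = False
    return keep[labels]


def compute_pts(
    labels: np.ndarray,
    se: StructuringElement,
    *,
    min_object_size: int = 0,
) -> PtsResult:
    """Compute the PTS score of a tissue label map.

    Parameters
    ----------
    labels
        2-D integer label map over the tissue classes plus background.
    se
        Structuring element used for the closing; its size controls how wide
        an intra-tumoral gap still counts as inside the tumor region.
    min_object_size
        Optional pre-filter removing tumor-mask components smaller than this
        many pixels before closing (0 disables, the default).

    Raises
    ------
    ValueError
        If the map contains no tumor pixels ("no tumor in slide").
    """
    labels = validate_labelmap(labels)
    tumor_mask = labels == int(TissueClass.TUMOR)
    tumor_area = int(tumor_mask.sum())
    if tumor_area == 0:
        raise ValueError("no tumor in slide: label map contains zero tumor pixels")
    if min_object_size > 1:
        filtered = remove_small_objects(tumor_mask, min_object_size)
        if filtered.any():  # never discard the entire tumor
            tumor_mask = filtered
            tumor_area = int(tumor_mask.sum())
    region = close_tumor_region(tumor_mask, se)
    stroma = labels == int(TissueClass.STROMA)
    pts_area = int((stroma & region).sum())
    return PtsResult(
        tumor_area=tumor_area,
        pts_area=pts_area,
        score=pts_area / tumor_area,
        se_name=se.name,
    )
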