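"""H&E stain normalization.

Two preprocessing steps are applied to every tile before segmentation:

1. **Macenko normalization** — estimate the slide's two stain vectors
   (hematoxylin and eosin) in optical-density space via the top-2 singular
   plane of the tissue-pixel OD cloud, solve per-pixel stain concentrations
   by non-negative least squares, rescale each stain's robust concentration
   maximum to a reference, and recompose with the reference stain matrix;
2. **histogram normalization** — per-channel affine rescale so intensities
   span the full 0–255 range.

The pipeline order is Macenko first, then histogram normalization.

Beer–Lambert convention: ``OD = -log10(I / 255)`` with a small intensity
floor so white pixels map to OD 0 and the transform is invertible above the
floor.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np

__all__ = [
    "StainModel",
    "InsufficientTissueError",
    "rgb_to_od",
    "od_to_rgb",
    "estimate_stain_model",
    "stain_concentrations",
    "normalize_macenko",
    "histogram_normalize",
    "DEFAULT_TARGET",
]

#: Macenko reference defaults: OD threshold, angular percentile, intensity floor.
DEFAULT_BETA = 0.15
DEFAULT_ALPHA = 1.0
DEFAULT_FLOOR = 1.0 / 255.0
MIN_TISSUE_PIXELS = 100


class InsufficientTissueError(ValueError):
    """Raised when a tile has too few tissue pixels to estimate stains."""


@dataclass(frozen=True)
class StainModel:
    """Two unit-norm H&E stain vectors in OD space plus robust maxima.

    ``stain_matrix`` is 3x2 (columns: H then E); ``max_concentrations`` are
    the per-stain robust (99th percentile) concentration maxima.
    """

    stain_matrix: np.ndarray
    max_concentrations: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.stain_matrix, dtype=np.float64)
        c = np.asarray(self.max_concentrations, dtype=np.float64)
        if m.shape != (3, 2):
            raise ValueError(f"stain matrix must be 3x2, got {m.shape}")
        norms = np.linalg.norm(m, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("stain vectors must have unit Euclidean norm")
        if c.shape != (2,) or np.any(c <= 0):
            raise ValueError("max_concentrations must be two positive scalars")
        object.__setattr__(self, "stain_matrix", m)
        object.__setattr__(self, "max_concentrations", c)

    def to_dict(self) -> dict:
        return {
            "stain_matrix": self.stain_matrix.tolist(),
            "max_concentrations": self.max_concentrations.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StainModel":
        return cls(np.asarray(d["stain_matrix"]), np.asarray(d["max_concentrations"]))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "StainModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


#: Standard H&E reference basis (Ruifrok-style OD vectors, unit-normalized).
def _default_target() -> StainModel:
    m = np.array([[0.65, 0.07], [0.70, 0.99], [0.29, 0.11]], dtype=np.float64)
    m /= np.linalg.norm(m, axis=0, keepdims=True)
    return StainModel(m, np.array([1.9705, 1.0308]))


DEFAULT_TARGET = _default_target()


def rgb_to_od(tile: np.ndarray, floor: float = DEFAULT_FLOOR) -> np.ndarray:
    """Optical density per channel: ``-log10(max(I/255, floor))``.

    Monotone decreasing in intensity; a pure-white pixel has OD 0.
    """
    if not 0 < floor <= 1:
        raise ValueError("floor must lie in (0, 1]")
    intensity = np.asarray(tile, dtype=np.float64) / 255.0
    return -np.log10(np.maximum(intensity, floor))


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_od` (continuous; no quantization)."""
    return 255.0 * np.power(10.0, -np.asarray(od, dtype=np.float64))


def _order_he(vectors: np.ndarray) -> np.ndarray:
    """Column order convention: hematoxylin has the larger red-OD component."""
    if vectors[0, 0] >= vectors[0, 1]:
        return vectors
    return vectors[:, ::-1]


def estimate_stain_model(
    od: np.ndarray,
    beta: float = DEFAULT_BETA,
    alpha: float = DEFAULT_ALPHA,
    min_pixels: int = MIN_TISSUE_PIXELS,
) -> StainModel:
    """Macenko stain-vector estimation from an OD image or pixel list.

    Pixels with OD norm <= ``beta`` (near-white background) are discarded;
    the remaining cloud is projected onto its top-2 singular plane and the
    stain vectors are taken at the ``alpha`` and ``100 - alpha`` percentile
    angles within that plane, signs fixed so components are non-negative.

    Raises
    ------
    InsufficientTissueError
        If fewer than ``min_pixels`` tissue pixels survive the threshold.
    """
    pixels = np.asarray(od, dtype=np.float64).reshape(-1, 3)
    tissue = pixels[np.linalg.norm(pixels, axis=1) > beta]
    if tissue.shape[0] < min_pixels:
        raise InsufficientTissueError(
            f"insufficient tissue: {tissue.shape[0]} pixels above OD {beta} "
            f"(minimum {min_pixels})"
        )
    # plane of maximal variance through the origin (uncentered SVD)
    _, _, vt = np.linalg.svd(tissue, full_matrices=False)
    plane = vt[:2].T  # 3x2
    # fix plane basis signs so projections are predominantly positive
    for k in range(2):
        if plane[:, k].sum() < 0:
            plane[:, k] = -plane[:, k]
    proj = tissue @ plane  # N x 2
    angles = np.arctan2(proj[:, 1], proj[:, 0])
    # inverted-CDF percentiles: invariant under pixel duplication
    lo, hi = np.percentile(angles, [alpha, 100.0 - alpha], method="inverted_cdf")
    v1 = plane @ np.array([np.cos(lo), np.sin(lo)])
    v2 = plane @ np.array([np.cos(hi), np.sin(hi)])
    vectors = np.stack([v1, v2], axis=1)
    vectors = np.where(vectors.sum(axis=0, keepdims=True) < 0, -vectors, vectors)
    vectors = np.clip(vectors, 0.0, None)
    vectors /= np.linalg.norm(vectors, axis=0, keepdims=True)
    vectors = _order_he(vectors)
    conc = stain_concentrations(pixels, vectors)
    max_c = np.percentile(conc, 99.0, axis=0, method="inverted_cdf")
    max_c = np.maximum(max_c, 1e-6)
    return StainModel(vectors, max_c)


def stain_concentrations(od_pixels: np.ndarray, stain_matrix: np.ndarray) -> np.ndarray:
    """Exact 2-variable non-negative least squares, vectorized over pixels.

    Solves ``min ||S c - od||`` s.t. ``c >= 0`` for each pixel.  With two
    columns the active-set solution is closed-form: take the unconstrained
    solution; if a coefficient is negative, clamp it to zero and solve the
    remaining single-stain problem.
    """
    S = np.asarray(stain_matrix, dtype=np.float64)
    od = np.asarray(od_pixels, dtype=np.float64).reshape(-1, 3)
    gram = S.T @ S
    rhs = od @ S  # N x 2
    c = rhs @ np.linalg.inv(gram).T  # unconstrained solution
    s_sq = np.diag(gram)
    single = np.maximum(rhs / s_sq, 0.0)  # per-stain-alone solutions

    neg0, neg1 = c[:, 0] < 0, c[:, 1] < 0
    c[neg0, 0], c[neg0, 1] = 0.0, single[neg0, 1]
    c[neg1, 1], c[neg1, 0] = 0.0, single[neg1, 0]
    return np.maximum(c, 0.0)


def normalize_macenko(
    tile: np.ndarray,
    target: StainModel = DEFAULT_TARGET,
    beta: float = DEFAULT_BETA,
    alpha: float = DEFAULT_ALPHA,
    floor: float = DEFAULT_FLOOR,
) -> np.ndarray:
    """Map a tile's stains onto the target stain basis.

    Concentrations are solved against the tile's own estimated stain model,
    scaled so each stain's robust maximum maps to the target's, and
    recomposed with the target stain matrix.  Output is uint8 in [0, 255]
    (round-half-even).
    """
    tile = np.asarray(tile)
    od = rgb_to_od(tile, floor)
    source = estimate_stain_model(od, beta=beta, alpha=alpha)
    conc = stain_concentrations(od, source.stain_matrix)
    conc *= target.max_concentrations / source.max_concentrations
    od_new = conc @ target.stain_matrix.T
    rgb = od_to_rgb(od_new).reshape(tile.shape)
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def histogram_normalize(tile: np.ndarray) -> np.ndarray:
    """Per-channel affine rescale so min maps to 0 and max to 255.

    Constant channels pass through unchanged (rescaling would fabricate
    contrast out of nothing).  Round-half-even quantization.
    """
    tile = np.asarray(tile)
    out = tile.astype(np.float64).copy()
    chans = out.reshape(-1, out.shape[-1]) if out.ndim == 3 else out.reshape(-1, 1)
    for k in range(chans.shape[1]):
        lo, hi = chans[:, k].min(), chans[:, k].max()
        if hi > lo:
            # multiply before dividing: keeps exact halves (e.g. 127.5) exact
            chans[:, k] = (chans[:, k] - lo) * 255.0 / (hi - lo)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)
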