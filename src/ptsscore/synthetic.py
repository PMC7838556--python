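"""Synthetic H&E-like data with exact ground truth.

Every downstream stage of the pipeline is testable without external slide
archives because this module generates:

* **tiles** — small RGB patches whose tissue classes are separable by color,
  paired with pixel-exact label maps (:func:`make_labeled_tiles`);
* **whole-slide label maps** — parameterized tumor/stroma geometry built
  from axis-aligned rectangles, returned together with analytically known
  areas and the expected PTS score (:func:`make_wsi_labelmap`);
* **cohorts** — patient tables in which the log-odds of lymph-node
  metastasis (LNM) is linear in the PTS score with configurable effect
  size, plus invasion flags with controlled missingness
  (:func:`make_cohort`).

All generators are pure functions of (spec, seed): identical inputs yield
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.special import expit

from .tissue import BACKGROUND, FOREGROUND_CLASSES, TissueClass

__all__ = [
    "TileSpec",
    "WsiGeometrySpec",
    "WsiGroundTruth",
    "CohortSpec",
    "DEFAULT_PALETTE",
    "make_labeled_tiles",
    "make_wsi_labelmap",
    "make_cohort",
    "make_exclusion_records",
    "render_slide_rgb",
]


# Per-class base RGB means (0-255).  Loose caricature of H&E appearance:
# tumor dark purple, stroma pink, lymphocytes deep blue, mucus pale yellow,
# adipose near-white, muscle salmon, normal mucosa light violet.
DEFAULT_PALETTE: dict[TissueClass, tuple[int, int, int]] = {
    TissueClass.TUMOR: (120, 60, 150),
    TissueClass.STROMA: (230, 150, 180),
    TissueClass.LYMPHOCYTES: (60, 70, 160),
    TissueClass.MUCUS: (220, 220, 160),
    TissueClass.ADIPOSE: (245, 240, 245),
    TissueClass.MUSCLE: (200, 120, 120),
    TissueClass.NORMAL: (170, 140, 200),
}


# ---------------------------------------------------------------------------
# Tiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TileSpec:
    """Recipe for color-separable labeled tiles.

    ``layout`` is ``"solid"`` (one class per tile) or ``"quadrant"`` (four
    classes in the four quadrants of each tile, making segmentation a real
    localization task).  ``texture_grain`` adds block-wise brightness
    modulation at the given pixel scale (0 disables).
    """

    tile_size: int = 224
    classes: tuple[TissueClass, ...] = FOREGROUND_CLASSES
    palette: dict = dc_field(default_factory=lambda: dict(DEFAULT_PALETTE))
    noise_sd: float = 8.0
    texture_grain: int = 0
    layout: str = "solid"
    separability_margin: float = 20.0

    def __post_init__(self) -> None:
        if self.tile_size <= 0:
            raise ValueError("tile_size must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.layout not in ("solid", "quadrant"):
            raise ValueError(f"unknown layout {self.layout!r}")
        means = [np.asarray(self.palette[c], dtype=float) for c in self.classes]
        for i in range(len(means)):
            for j in range(i + 1, len(means)):
                d = float(np.linalg.norm(means[i] - means[j]))
                if d < self.separability_margin:
                    raise ValueError(
                        f"class colors for {self.classes[i].name} and "
                        f"{self.classes[j].name} are only {d:.1f} apart "
                        f"(< margin {self.separability_margin}); classes would "
                        "not be separable"
                    )


def _render_region(
    rng: np.random.Generator,
    shape: tuple[int, int],
    mean_rgb: np.ndarray,
    noise_sd: float,
    grain: int,
) -> np.ndarray:
    h, w = shape
    img = np.broadcast_to(mean_rgb, (h, w, 3)).astype(np.float64).copy()
    if grain > 0:
        gh, gw = -(-h // grain), -(-w // grain)
        blocks = rng.normal(0.0, max(noise_sd, 1.0), size=(gh, gw, 1))
        img += np.kron(blocks, np.ones((grain, grain, 1)))[:h, :w, :]
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=(h, w, 3))
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def make_labeled_tiles(
    spec: TileSpec, n: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Generate ``n`` (RGB tile, label map) pairs.

    Classes are assigned round-robin so their proportions are approximately
    equal across the set.  Deterministic in (spec, n, seed).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    ts = spec.tile_size
    classes = list(spec.classes)
    out: list[tuple[np.ndarray, np.ndarray]] = []
    for i in range(n):
        if spec.layout == "solid":
            cls = classes[i % len(classes)]
            labels = np.full((ts, ts), int(cls), dtype=np.uint8)
            tile = _render_region(
                rng, (ts, ts), np.asarray(spec.palette[cls], float),
                spec.noise_sd, spec.texture_grain,
            )
        else:  # quadrant
            # rotate the class list so every class leads equally often
            order = classes[i % len(classes):] + classes[: i % len(classes)]
            quad = (order * 4)[:4]
            h2, w2 = ts // 2, ts // 2
            labels = np.zeros((ts, ts), dtype=np.uint8)
            tile = np.zeros((ts, ts, 3), dtype=np.uint8)
            corners = [(0, 0), (0, w2), (h2, 0), (h2, w2)]
            sizes = [(h2, w2), (h2, ts - w2), (ts - h2, w2), (ts - h2, ts - w2)]
            for cls, (y, x), (hh, ww) in zip(quad, corners, sizes):
                labels[y : y + hh, x : x + ww] = int(cls)
                tile[y : y + hh, x : x + ww] = _render_region(
                    rng, (hh, ww), np.asarray(spec.palette[cls], float),
                    spec.noise_sd, spec.texture_grain,
                )
        out.append((tile, labels))
    return out


# ---------------------------------------------------------------------------
# Whole-slide label maps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WsiGeometrySpec:
    """Axis-aligned tumor/stroma geometry for a synthetic slide.

    The tumor is a filled rectangle ``tumor_box = (row, col, height, width)``
    on a background canvas.  ``holes`` are rectangles strictly inside the
    tumor that are carved out and filled with stroma (the peri-tumoral
    stroma a closing with a wide-enough SE will capture).  An optional
    exterior stroma band of ``stroma_band`` pixels surrounds the tumor;
    it lies outside the closed region and must not count toward the score.
    ``filler`` paints leftover background with another class.
    """

    canvas: tuple[int, int] = (256, 256)
    tumor_box: tuple[int, int, int, int] = (64, 64, 128, 128)
    holes: tuple[tuple[int, int, int, int], ...] = ()
    stroma_band: int = 0
    filler: TissueClass | None = None

    def __post_init__(self) -> None:
        ch, cw = self.canvas
        r, c, h, w = self.tumor_box
        if h <= 0 or w <= 0 or r < 0 or c < 0 or r + h > ch or c + w > cw:
            raise ValueError("tumor box must lie within the canvas")
        boxes = []
        for hr, hc, hh, hw in self.holes:
            if hh <= 0 or hw <= 0:
                raise ValueError("hole dimensions must be positive")
            if hh >= h or hw >= w:
                raise ValueError("hole larger than tumor shape")
            if not (hr > r and hc > c and hr + hh < r + h and hc + hw < c + w):
                raise ValueError("holes must lie strictly inside the tumor shape")
            for pr, pc, ph, pw in boxes:
                if hr < pr + ph and pr < hr + hh and hc < pc + pw and pc < hc + hw:
                    raise ValueError("holes must be pairwise disjoint")
            boxes.append((hr, hc, hh, hw))


@dataclass(frozen=True)
class WsiGroundTruth:
    """Exact pixel accounting for a generated slide."""

    tumor_area: int
    hole_areas: tuple[int, ...]
    expected_score: float


def make_wsi_labelmap(spec: WsiGeometrySpec) -> tuple[np.ndarray, WsiGroundTruth]:
    """Build the label map and its analytic ground truth.

    For rectangle-with-rectangular-holes geometry, any SE that can bridge
    the widest hole fills it completely during closing, so the expected PTS
    score is exactly ``sum(hole areas) / tumor area`` (integer pixel
    counts).  The exterior stroma band contributes nothing.
    """
    ch, cw = spec.canvas
    labels = np.full((ch, cw), BACKGROUND, dtype=np.uint8)
    if spec.filler is not None:
        labels[:, :] = int(spec.filler)
    r, c, h, w = spec.tumor_box
    if spec.stroma_band > 0:
        b = spec.stroma_band
        labels[max(r - b, 0) : min(r + h + b, ch), max(c - b, 0) : min(c + w + b, cw)] = int(
            TissueClass.STROMA
        )
    labels[r : r + h, c : c + w] = int(TissueClass.TUMOR)
    hole_areas = []
    for hr, hc, hh, hw in spec.holes:
        labels[hr : hr + hh, hc : hc + hw] = int(TissueClass.STROMA)
        hole_areas.append(hh * hw)
    tumor_area = h * w - sum(hole_areas)
    assert tumor_area == int((labels == int(TissueClass.TUMOR)).sum())
    score = sum(hole_areas) / tumor_area
    return labels, WsiGroundTruth(tumor_area, tuple(hole_areas), score)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


def _beta_params_from_moments(mean: float, sd: float, scale: float) -> tuple[float, float]:
    """Beta(a, b) on [0, scale] matching a target mean and SD."""
    m = mean / scale
    v = (sd / scale) ** 2
    if not 0 < m < 1:
        raise ValueError("target mean must lie strictly inside (0, scale)")
    if v >= m * (1 - m):
        raise ValueError("target SD too large for a Beta distribution on this support")
    s = m * (1 - m) / v - 1.0
    return m * s, (1 - m) * s


@dataclass(frozen=True)
class CohortSpec:
    """Generative model for a synthetic patient cohort.

    ``logit P(LNM) = beta0 + beta1 * pts_score``; PTS scores follow a Beta
    distribution scaled to [0, ``pts_scale``] with the target mean/SD.
    Invasion flags (LI/PI/VI) are drawn independently given LNM with the
    stated conditional probabilities, then masked to NA at the stated
    rates.  Defaults emulate a colon-cancer cohort of the published size
    and composition.
    """

    n: int = 164
    beta0: float = -1.69
    beta1: float = 3.39  # ln(29.654): the published LNM odds ratio per unit score
    pts_mean: float = 0.380
    pts_sd: float = 0.285
    pts_scale: float = 1.2
    # P(flag = yes | LNM state), estimated from the published contingency counts
    p_li: tuple[float, float] = (11 / 90, 42 / 64)   # (given LNM-, given LNM+)
    p_pi: tuple[float, float] = (12 / 70, 13 / 45)
    p_vi: tuple[float, float] = (13 / 89, 25 / 62)
    na_rates: tuple[float, float, float] = (10 / 164, 49 / 164, 13 / 164)  # LI, PI, VI
    # marginal T-stage distribution over T0..T4
    t_stage_probs: tuple[float, ...] = (1 / 164, 5 / 164, 27 / 164, 116 / 164, 15 / 164)
    age_mean: float = 64.8
    age_sd: float = 13.4
    p_female: float = 0.52

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        probs = [*self.p_li, *self.p_pi, *self.p_vi, *self.na_rates,
                 *self.t_stage_probs, self.p_female]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if abs(sum(self.t_stage_probs) - 1.0) > 1e-9:
            raise ValueError("t_stage_probs must sum to 1")
        _beta_params_from_moments(self.pts_mean, self.pts_sd, self.pts_scale)


def make_cohort(spec: CohortSpec, seed: int) -> pd.DataFrame:
    """Draw a cohort table; columns follow the pipeline's CSV schema.

    Columns: patient_id, age, sex, t_stage, n_stage, lnm, li, pi, vi,
    pts_score.  Flags are "yes"/"no"/NaN.  ``lnm`` is boolean and equals
    (n_stage != "N0") by construction.
    """
    rng = np.random.default_rng(seed)
    n = spec.n
    a, b = _beta_params_from_moments(spec.pts_mean, spec.pts_sd, spec.pts_scale)
    pts = spec.pts_scale * rng.beta(a, b, size=n)
    lnm = rng.random(n) < expit(spec.beta0 + spec.beta1 * pts)
    n_stage = np.where(lnm, np.where(rng.random(n) < 0.7, "N1", "N2"), "N0")
    t_stage = rng.choice(
        ["T0", "T1", "T2", "T3", "T4"], size=n, p=list(spec.t_stage_probs)
    )

    def draw_flag(p_pair: tuple[float, float], na_rate: float) -> np.ndarray:
        p = np.where(lnm, p_pair[1], p_pair[0])
        flag = np.where(rng.random(n) < p, "yes", "no").astype(object)
        flag[rng.random(n) < na_rate] = np.nan
        return flag

    li = draw_flag(spec.p_li, spec.na_rates[0])
    pi = draw_flag(spec.p_pi, spec.na_rates[1])
    vi = draw_flag(spec.p_vi, spec.na_rates[2])

    return pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "age": np.clip(np.rint(rng.normal(spec.age_mean, spec.age_sd, n)), 18, 100),
            "sex": np.where(rng.random(n) < spec.p_female, "F", "M"),
            "t_stage": t_stage,
            "n_stage": n_stage,
            "lnm": lnm,
            "li": li,
            "pi": pi,
            "vi": vi,
            "pts_score": pts,
        }
    )


def render_slide_rgb(
    labels: np.ndarray,
    palette: dict | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Paint an RGB image of a label map using the class palette.

    Background renders as white (glass).  With ``noise_sd`` > 0, Gaussian
    RGB noise is added per pixel.  Used to turn synthetic whole-slide label
    maps into images the segmenter can be run on end to end.
    """
    palette = dict(DEFAULT_PALETTE) if palette is None else palette
    h, w = labels.shape
    lut = np.full((max(int(np.max(labels)), 7) + 1, 3), 255.0)
    for cls, rgb in palette.items():
        lut[int(cls)] = rgb
    img = lut[labels.astype(int)]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=(h, w, 3))
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def make_exclusion_records(
    n_total: int,
    n_rectal: int,
    n_inadequate: int,
    n_metastatic: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Build a pre-filter accession table with exclusion flags.

    The three exclusion reasons (rectal primary, inadequate image, distant
    metastasis) are assigned to disjoint subsets so the sequential filter
    removes exactly the requested counts.
    """
    if n_rectal + n_inadequate + n_metastatic > n_total:
        raise ValueError("exclusion counts exceed the total")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n_total)
    rectal = np.zeros(n_total, dtype=bool)
    inadequate = np.zeros(n_total, dtype=bool)
    metastatic = np.zeros(n_total, dtype=bool)
    rectal[idx[:n_rectal]] = True
    inadequate[idx[n_rectal : n_rectal + n_inadequate]] = True
    metastatic[idx[n_rectal + n_inadequate : n_rectal + n_inadequate + n_metastatic]] = True
    return pd.DataFrame(
        {
            "patient_id": [f"A{i:04d}" for i in range(n_total)],
            "rectal": rectal,
            "inadequate_image": inadequate,
            "distant_metastasis": metastatic,
        }
    )
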