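"""End-to-end orchestration: synth → normalize → train → segment → PTS → stats.

A run is driven by a :class:`PipelineConfig`; every stochastic stage
receives an independent child seed spawned from the single root seed, so
stages are individually reproducible and a rerun with the same config and
seed reproduces every deterministic output bit for bit (proved by the
checksums recorded in the :class:`RunManifest`).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import roc_auc, table1_descriptives, logistic_univariate
from .io import (
    pts_overlay, save_cohort, save_labelmap, save_rgb, save_tile_pairs,
    write_json,
)
from .morphology import StructuringElement, close_tumor_region, compute_pts
from .segmentation import UnetConfig, evaluate_dsc, segment_image, split_dataset, train_segmenter
from .stain import histogram_normalize
from .synthetic import (
    CohortSpec, TileSpec, WsiGeometrySpec, make_cohort, make_labeled_tiles,
    make_wsi_labelmap, render_slide_rgb,
)
from .tissue import TissueClass

__all__ = ["PipelineConfig", "RunManifest", "run_end_to_end", "merge_scores"]

log = logging.getLogger("ptsscore")


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic end-to-end run."""

    output_dir: str = "pts_run"
    seed: int = 0
    n_tiles: int = 70
    tile_spec: TileSpec = field(default_factory=lambda: TileSpec(tile_size=24, noise_sd=0.0, layout="quadrant"))
    unet: UnetConfig = field(default_factory=lambda: UnetConfig(
        input_size=32, depth=3, base_filters=8, max_epochs=20, batch_size=8,
        learning_rate=3e-3))
    n_slides: int = 5
    slide_canvas: tuple[int, int] = (96, 96)
    se_radius: int = 8
    cohort_spec: CohortSpec = field(default_factory=lambda: CohortSpec(n=200))


@dataclass
class RunManifest:
    """Record of a completed run: config hash, timings, output checksums."""

    config_hash: str
    version: str
    stage_seconds: dict
    checksums: dict

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash, "version": self.version,
            "stage_seconds": self.stage_seconds, "checksums": self.checksums,
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    import dataclasses

    # the output location is not part of the scientific configuration
    blob = repr(dataclasses.replace(config, output_dir="")).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def merge_scores(
    cohort: pd.DataFrame,
    scores: pd.DataFrame,
    slide_to_patient: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Attach one PTS score per patient to the cohort table.

    ``scores`` has columns ``slide_id`` and ``score``.  When a patient has
    several scorable slides, the lexicographically first slide ID is the
    representative (logged); patients without any scorable slide keep a
    missing score (warned).
    """
    scores = scores.copy()
    if slide_to_patient is not None:
        scores["patient_id"] = scores["slide_id"].map(slide_to_patient)
    elif "patient_id" not in scores.columns:
        raise ValueError("need a slide→patient mapping or a patient_id column")
    scores = scores.dropna(subset=["patient_id"]).sort_values("slide_id")
    multi = scores["patient_id"].duplicated(keep=False)
    for pid, grp in scores[multi].groupby("patient_id"):
        log.info(
            "patient %s has %d slides; keeping representative %s",
            pid, len(grp), grp["slide_id"].iloc[0],
        )
    rep = scores.drop_duplicates("patient_id", keep="first")
    merged = cohort.merge(
        rep[["patient_id", "score"]].rename(columns={"score": "pts_score"}),
        on="patient_id", how="left", suffixes=("_prior", ""),
    )
    missing = merged["pts_score"].isna()
    if missing.any():
        log.warning("%d patients have no scorable slide; pts_score left missing",
                    int(missing.sum()))
    return merged


def run_end_to_end(config: PipelineConfig) -> RunManifest:
    """Execute the full synthetic workflow and write all reports.

    Stages: tile synthesis → split → U-Net training → synthetic-slide
    segmentation → PTS scoring → cohort statistics.  Each stage's outputs
    are written before the next starts; any failure aborts with the stage
    named.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    stage_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(6)]
    timings: dict[str, float] = {}
    checksums: dict[str, str] = {}
    stage = "synth"
    try:
        t0 = time.perf_counter()
        pairs = make_labeled_tiles(config.tile_spec, config.n_tiles, stage_seeds[0])
        save_tile_pairs(out / "tiles", pairs)
        slides = []
        rng = np.random.default_rng(stage_seeds[1])
        ch, cw = config.slide_canvas
        for k in range(config.n_slides):
            th = int(rng.integers(ch // 2, 3 * ch // 4))
            tw = int(rng.integers(cw // 2, 3 * cw // 4))
            r = int(rng.integers(4, ch - th - 4 + 1))
            c = int(rng.integers(4, cw - tw - 4 + 1))
            hole = (r + th // 3, c + tw // 3, max(th // 6, 2), max(tw // 6, 2))
            spec = WsiGeometrySpec(canvas=(ch, cw), tumor_box=(r, c, th, tw), holes=(hole,))
            labels, truth = make_wsi_labelmap(spec)
            image = render_slide_rgb(labels, noise_sd=config.tile_spec.noise_sd,
                                     seed=stage_seeds[1] + k)
            slide_id = f"S{k:03d}"
            save_labelmap(out / f"{slide_id}_truth.png", labels)
            save_rgb(out / f"{slide_id}.png", image)
            slides.append((slide_id, image, labels, truth))
        timings[stage] = time.perf_counter() - t0

        stage = "train"
        t0 = time.perf_counter()
        train, val, test = split_dataset(pairs, seed=stage_seeds[2])
        model, history = train_segmenter(train, val, config.unet)
        model.save(str(out / "model.npz"), sidecar={"history_best_epoch": history["best_epoch"]})
        report = evaluate_dsc(model, test, input_size=config.unet.input_size)
        write_json(out / "dsc_report.json", report.to_dict())
        timings[stage] = time.perf_counter() - t0

        stage = "segment"
        t0 = time.perf_counter()
        predicted = {}
        for slide_id, image, _, _ in slides:
            pred = segment_image(model, image, window=config.unet.input_size)
            save_labelmap(out / f"{slide_id}_pred.png", pred)
            predicted[slide_id] = pred
        timings[stage] = time.perf_counter() - t0

        stage = "pts"
        t0 = time.perf_counter()
        se = StructuringElement.disk(config.se_radius)
        rows = []
        for slide_id, _, _, truth in slides:
            result = compute_pts(predicted[slide_id], se)
            region = close_tumor_region(
                predicted[slide_id] == int(TissueClass.TUMOR), se)
            save_rgb(out / f"{slide_id}_overlay.png",
                     pts_overlay(predicted[slide_id], region))
            write_json(out / f"{slide_id}_pts.json",
                       {**result.to_dict(), "expected_score": truth.expected_score})
            rows.append({"slide_id": slide_id, "score": result.score})
        pd.DataFrame(rows).to_csv(out / "pts_scores.csv", index=False)
        timings[stage] = time.perf_counter() - t0

        stage = "cohort"
        t0 = time.perf_counter()
        cohort = make_cohort(config.cohort_spec, stage_seeds[3])
        save_cohort(out / "cohort.csv", cohort)
        # attach the slide-derived scores to the first patients (one
        # representative slide per patient) to exercise the merge policy
        mapping = {row["slide_id"]: cohort["patient_id"].iloc[i]
                   for i, row in enumerate(rows) if i < len(cohort)}
        merged = merge_scores(cohort, pd.DataFrame(rows), mapping)
        save_cohort(out / "cohort_with_slide_scores.csv", merged)
        stats = {
            "table1": table1_descriptives(cohort),
            "logistic_lnm_on_pts": logistic_univariate(
                cohort["pts_score"], cohort["lnm"].astype(int)).to_dict(),
            "roc": roc_auc(cohort["pts_score"], cohort["lnm"]).to_dict(),
        }
        write_json(out / "cohort_stats.json", stats)
        timings[stage] = time.perf_counter() - t0
    except Exception as exc:  # annotate failures with the stage name
        raise RuntimeError(f"{stage} stage: {exc}") from exc

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            checksums[str(path.relative_to(out))] = _sha256(path)
    manifest = RunManifest(
        config_hash=_config_hash(config), version=__version__,
        stage_seconds={k: round(v, 3) for k, v in timings.items()},
        checksums=checksums,
    )
    tmp = out / "manifest.json.tmp"
    with open(tmp, "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=2)
    tmp.replace(out / "manifest.json")  # atomic write
    return manifest
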