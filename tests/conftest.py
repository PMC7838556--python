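import numpy as np
import pytest

from ptsscore import (
    PipelineConfig, TileSpec, UnetConfig, make_labeled_tiles, run_end_to_end,
    split_dataset, train_segmenter,
)


@pytest.fixture(scope="session")
def separable_training():
    """A tiny U-Net trained once on zero-noise, color-separable tiles.

    Returned as (model, history, test_pairs, config); shared by the
    segmentation unit tests and the training acceptance check.
    """
    spec = TileSpec(tile_size=24, noise_sd=0.0, layout="quadrant")
    pairs = make_labeled_tiles(spec, 70, seed=7)
    train, val, test = split_dataset(pairs, seed=7)
    config = UnetConfig(
        input_size=32, depth=3, base_filters=8, max_epochs=20,
        batch_size=8, learning_rate=3e-3, seed=0,
    )
    model, history = train_segmenter(train, val, config)
    return model, history, test, config


@pytest.fixture(scope="session")
def e2e_runs(tmp_path_factory):
    """Two identically-seeded end-to-end runs for determinism checks."""
    base = tmp_path_factory.mktemp("e2e")
    manifests = []
    for name in ("first", "second"):
        cfg = PipelineConfig(output_dir=str(base / name), seed=11)
        manifests.append((base / name, run_end_to_end(cfg)))
    return manifests
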