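import numpy as np
import pytest

from egps.pipeline import (
    ModelSection,
    PreprocessSection,
    RunConfig,
    ScoringSection,
    SynthSection,
    TrainSection,
    run_pipeline,
)
from egps.synthetic import SyntheticSpec


@pytest.fixture()
def small_spec() -> SyntheticSpec:
    """Quick cohort spec for unit tests: 4 groups x 2 slides x 2 small tiles."""
    return SyntheticSpec(
        slides_per_group=2,
        tiles_per_slide=2,
        tile_size=64,
        seed=7,
    )


@pytest.fixture(scope="session")
def cohort_run(tmp_path_factory):
    """Full weakly supervised run on a 4-group synthetic cohort.

    4 age groups x 5 slides x 6 tiles of 128x128 with a positive lesion
    density slope, trained for 20 epochs with a width-8 model; shared by
    the end-to-end tests (training dominates the cost, so it runs once).
    """
    out = tmp_path_factory.mktemp("cohort_run")
    config = RunConfig(
        schedule=[8, 16, 20, 32],
        out_dir=str(out),
        seed=0,
        synth=SynthSection(
            slides_per_group=5,
            tiles_per_slide=6,
            tile_size=128,
            base_lesion_density=5.0,
            density_slope=5.0,
        ),
        preprocess=PreprocessSection(tile_size=128, keep_every=1, downsample_factor=1),
        model=ModelSection(base_width=8),
        train=TrainSection(epochs=20, batch_size=6, lr_scale=4.0, holdout_fraction=0.2),
        scoring=ScoringSection(paintings=False),
    )
    artifacts = run_pipeline(config)
    artifacts["config"] = config
    artifacts["out_dir"] = out
    return artifacts


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
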