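import numpy as np
import pytest

from flycourt.synth import ArenaSpec, SimConfig, simulate_assay


@pytest.fixture(scope="session")
def small_arena() -> ArenaSpec:
    """Default-geometry arena rendered at 5-s frame intervals (desk scale)."""
    return ArenaSpec(frame_interval_s=5.0)


@pytest.fixture(scope="session")
def scripted_assay(small_arena):
    """A 600-s assay with one scripted copulation [100, 250] s, plus its
    noise-free twin (same seed, same geometry) for ground-truth masks."""
    import dataclasses

    cfg = SimConfig(
        arena=small_arena,
        duration_s=600.0,
        seed=11,
        scripted_events=(("copulation", 100.0, 250.0),),
        assay_id="scripted",
    )
    rec, log = simulate_assay(cfg)
    rec0, _ = simulate_assay(dataclasses.replace(cfg, noise_sigma=0.0))
    gt_masks = rec0.frames < 128
    assert np.array_equal(rec0.timestamps_s, rec.timestamps_s)
    return cfg, rec, log, gt_masks
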