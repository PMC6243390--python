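import numpy as np
import pytest

from cardioscreen.catalog import load_catalog, validate_catalog
from cardioscreen.imaging import analyze_stack
from cardioscreen.synth import VIDEO_PRESETS, VideoConfig, generate_heart_video


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def validation_report(catalog):
    return validate_catalog(catalog)


@pytest.fixture(scope="session")
def control_video():
    cfg = VideoConfig(seed=42, **VIDEO_PRESETS["control-larva"])
    frames, truth = generate_heart_video(cfg)
    return cfg, frames, truth


@pytest.fixture(scope="session")
def model_group():
    """Eight model-preset larvae (fixed seeds) analysed end to end."""
    out = []
    for k in range(8):
        cfg = VideoConfig(seed=k, **VIDEO_PRESETS["model-larva"])
        frames, truth = generate_heart_video(cfg)
        out.append((analyze_stack(frames, cfg.fps), truth))
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
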