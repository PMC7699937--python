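import numpy as np
import pytest

import drtb


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_fixture():
    """Small rendered micrograph with known planted centers (fast preset
    geometry on a 320 px canvas)."""
    pp = drtb.PointPatternParams(intensity=4e-4, width=320, height=320,
                                 min_separation=22.0, margin=15.0, seed=7)
    pts = drtb.sample_poisson_points(pp)
    rp = drtb.RenderParams(width=320, height=320, defocus_sigma=0.8, seed=8)
    img = drtb.render_stomata_image(pts, rp)
    return img, pts


@pytest.fixture(scope="session")
def fixture_scan_config():
    """Scan configuration matched to the synthetic fixture scale."""
    from drtb.config import RunConfig
    return RunConfig.from_dict(drtb.preset_scan_config()).scan
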