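import datetime as dt

import numpy as np
import pytest

from phenodiel import PhotoperiodSchedule
from phenodiel.synthetic import SceneSpec, generate_session


@pytest.fixture(scope="session")
def schedule_12_12() -> PhotoperiodSchedule:
    return PhotoperiodSchedule(dt.time(8, 0), dt.time(20, 0))


@pytest.fixture(scope="session")
def day_scene():
    """Small tray (2x2 plants), one light + one dark period + 2 h of the next
    morning, default noise and falloff; shared read-only across tests."""
    spec = SceneSpec.wt_like(grid=(2, 2), duration_hours=26.0, rng_seed=7)
    session, truth = generate_session(spec)
    return spec, session, truth


@pytest.fixture
def disk_image():
    """Noiseless piecewise-constant disk: (image, true mask)."""
    yy, xx = np.indices((80, 80))
    disk = (yy - 40) ** 2 + (xx - 40) ** 2 < 20**2
    img = np.where(disk, 200, 50).astype(np.uint8)
    return img, disk
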