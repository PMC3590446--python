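import numpy as np
import pytest

from nodtemplate import (
    GAConfig,
    PhantomConfig,
    PlantedNodule,
    make_phantom,
    space_from_mask,
)


@pytest.fixture(scope="session")
def toy_phantom():
    """32 x 32 x 3 volume with two planted circles and one vessel."""
    cfg = PhantomConfig(
        dims=(32, 32, 3),
        noise_sigma=2.0,
        n_vessels=1,
        seed=5,
        nodules=[
            PlantedNodule("circle", (10, 10, 1), 5),
            PlantedNodule("circle", (24, 22, 1), 6),
        ],
    )
    vol, mask, truth = make_phantom(cfg)
    return vol, mask, truth, space_from_mask(mask)


@pytest.fixture(scope="session")
def toy_ga_config():
    return GAConfig(seed=3, radius_range=(5, 8))


@pytest.fixture(scope="session")
def small_phantom():
    """64 x 64 x 7 phantom with one nodule of each template shape."""
    cfg = PhantomConfig(
        dims=(64, 64, 7),
        noise_sigma=3.0,
        n_vessels=2,
        seed=9,
        nodules=[
            PlantedNodule("circle", (16, 16, 3), 6),
            PlantedNodule("sphere", (44, 20, 3), 9),
            PlantedNodule("semicircle", (20, 46, 3), 8, angle=0.0),
            PlantedNodule("hollow_sphere", (45, 45, 3), 12),
        ],
    )
    vol, mask, truth = make_phantom(cfg)
    return vol, mask, truth


def center_radius_match(records, nodule, center_tol=2.0, radius_tol=2.0):
    """True when some record matches the nodule's center and radius."""
    tc = np.asarray(nodule.center, dtype=float)
    for rec in records:
        if (np.linalg.norm(np.asarray(rec.center, dtype=float) - tc) <= center_tol
                and abs(rec.R - nodule.R) <= radius_tol):
            return True
    return False
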