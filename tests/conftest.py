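import numpy as np
import pytest

from nccount import SampleImage, Template, TemplateLibrary
from nccount.synthetic import SceneParams, derive_library, generate_scene


@pytest.fixture(scope="session")
def default_scene():
    """A default-condition scene: 300x400, 60 cells, noise sigma 3."""
    return generate_scene(SceneParams(seed=7))


@pytest.fixture(scope="session")
def fixture_library(default_scene):
    """12 templates: 4 distinct, 4 exact duplicates, 4 jittered copies."""
    return derive_library(
        default_scene, n_templates=12, duplicate_fraction=1 / 3, jitter_fraction=1 / 3, seed=7
    )


@pytest.fixture(scope="session")
def small_scene():
    """A quicker scene for tests that only need a plausible image."""
    return generate_scene(SceneParams(shape=(160, 220), n_cells=12, seed=5))


@pytest.fixture(scope="session")
def small_library(small_scene):
    return derive_library(small_scene, n_templates=4, seed=5)


@pytest.fixture
def sole_detector_setup():
    """Two planted random patches, each found by exactly one template.

    Random patches have delta-like autocorrelation, so template A never
    fires on patch B's cells and vice versa: both templates are sole
    detectors, which pins down influence and pruning behaviour exactly.
    """
    rng = np.random.default_rng(42)
    pa = rng.uniform(0, 100, (7, 7))
    pb = rng.uniform(0, 100, (7, 7))
    img = np.zeros((40, 60))
    placements = [(8, 10, "a"), (8, 40, "b"), (28, 15, "b"), (28, 45, "a")]
    for r, c, which in placements:
        img[r : r + 7, c : c + 7] += pa if which == "a" else pb
    sample = SampleImage(img)
    library = TemplateLibrary((Template("A", pa), Template("B", pb)))
    return sample, library, placements
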