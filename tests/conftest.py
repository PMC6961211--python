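import numpy as np
import pytest

from mitoqc import DetectionParams
from mitoqc.synth import make_benchmark_suite, random_scene, render_scene

# detection settings used on noiseless fixtures: no filtering is needed when
# there is no noise, and radius 0 keeps disk footprints pixel-exact
NOISELESS_PARAMS = DetectionParams(
    smooth_radius=0.0, ratio_thresh=0.5, red_stddev_offset=0.0
)


@pytest.fixture(scope="session")
def noiseless_scene():
    """One deterministic noiseless scene with 12 disk puncta in 4 cells."""
    spec = random_scene(seed=3, n_puncta=12, name="fixture")
    image, truth, rois = render_scene(spec)
    return image, truth, rois


@pytest.fixture(scope="session")
def bench_dir(tmp_path_factory):
    """A small mixed (induced + control) benchmark folder on disk."""
    out = tmp_path_factory.mktemp("bench")
    truth = make_benchmark_suite(
        out, n_images=4, seed=5, params=NOISELESS_PARAMS, noise_sd=0.0
    )
    return out, truth


@pytest.fixture(scope="session")
def induced_suite(tmp_path_factory):
    """Noiseless all-induced 10-image suite (5-50 puncta per image)."""
    out = tmp_path_factory.mktemp("induced")
    truth = make_benchmark_suite(
        out,
        n_images=10,
        seed=11,
        params=NOISELESS_PARAMS,
        noise_sd=0.0,
        condition_cycle=("dfp",),
    )
    return out, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
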