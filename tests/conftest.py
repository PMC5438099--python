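import numpy as np
import pytest

from mesoconn import ImageStack, Region, SynthConfig, generate_stack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_stack(rng):
    """Unstructured random stack, 60 frames of 8×8 at 30 Hz."""
    return ImageStack(100.0 + rng.standard_normal((60, 8, 8)), fps=30.0)


@pytest.fixture
def two_region_stack():
    """Synthetic stack with two disk regions driven by correlated sources."""
    cfg = SynthConfig(
        height=40,
        width=40,
        n_frames=600,
        regions=[Region((10, 10), 5, 0), Region((30, 30), 5, 1)],
        source_correlations=np.array([[1.0, 0.5], [0.5, 1.0]]),
        seed=7,
    )
    stack, truth = generate_stack(cfg)
    return stack, truth


@pytest.fixture
def roi_csv(tmp_path):
    """The standard 14-area cortical seed table, written as a CSV file."""
    from mesoconn import write_cortical_roi_csv

    path = tmp_path / "rois.csv"
    write_cortical_roi_csv(path)
    return path
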