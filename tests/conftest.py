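import numpy as np
import pytest

from qaamp import (
    PhantomSpec,
    ReaderModel,
    TreeConfig,
    generate_airway_tree,
    rasterize_phantom,
)


@pytest.fixture(scope="session")
def small_tree():
    """Deterministic 5-generation tree that fits a 96^3 grid at 0.5 mm."""
    cfg = TreeConfig(
        seed=2, max_generation=5, root_length=8.0, root_radius=2.5,
        length_ratio=0.8, branch_angle=40.0, jitter_sd=0.05, min_radius=0.5,
    )
    return generate_airway_tree(cfg)


@pytest.fixture(scope="session")
def small_phantom(small_tree):
    """Phantom with two generation-4 plugs (below the lobe-root generation)."""
    spec = PhantomSpec(
        grid_shape=(96, 96, 96), spacing=(0.5, 0.5, 0.5),
        plug_placements=[(16, 0.2, 3.0), (20, 0.1, 2.5)],
    )
    return rasterize_phantom(small_tree, spec, seed=0)


@pytest.fixture
def perfect_reader():
    return ReaderModel(
        miss_probability=0.0, slice_skip_probability=0.0, ellipse_dilation_sd=0.0, seed=0
    )


def random_tree(rng: np.random.Generator, max_generation: int = 6) -> object:
    """A random jittered tree for property tests."""
    cfg = TreeConfig(
        seed=int(rng.integers(1 << 31)),
        max_generation=int(rng.integers(1, max_generation + 1)),
        root_length=float(rng.uniform(10, 30)),
        root_radius=float(rng.uniform(2, 6)),
        length_ratio=float(rng.uniform(0.6, 0.95)),
        radius_ratio=float(rng.uniform(0.7, 0.9)),
        branch_angle=float(rng.uniform(20, 50)),
        jitter_sd=0.1,
        min_radius=0.1,
    )
    return generate_airway_tree(cfg)
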