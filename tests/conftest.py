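from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20210218)


@pytest.fixture
def clean_scene():
    """Small noiseless scene: 8 well-separated cells, no distractors."""
    from clearmorph.synthetic import SceneSpec, generate_stack

    spec = SceneSpec(n_cells=8, noise_sd=0.0, seed=7)
    stack, truth = generate_stack(spec)
    return spec, stack, truth


@pytest.fixture
def mixed_scene():
    """Noiseless scene with cells, neuron-scale blobs and speck artifacts."""
    from clearmorph.synthetic import SceneSpec, generate_stack

    spec = SceneSpec(
        stack_shape=(64, 192, 192),
        n_cells=12,
        n_neuron_blobs=2,
        n_artifacts=6,
        noise_sd=0.0,
        seed=11,
    )
    stack, truth = generate_stack(spec)
    return spec, stack, truth
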