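import numpy as np
import pytest

from gingimetry import ArchParams, generate_arch_pair, register


def _pair(**kw):
    return generate_arch_pair(ArchParams(**kw))


@pytest.fixture(scope="session")
def quiet_pair():
    """Small arch, no noise, no rigid perturbation, no artifacts: the
    closed-form limit where pre and post differ only by the inflation field."""
    return _pair(
        n_teeth=4,
        seed=7,
        noise_sd=0.0,
        max_rotation_deg=0.0,
        max_translation_mm=0.0,
        artifact_probability=0.0,
        mesh_edge_length=0.3,
    )


@pytest.fixture(scope="session")
def perturbed_pair():
    """Noise-free pair with a known rigid perturbation (registration oracle)."""
    return _pair(
        n_teeth=6,
        seed=19,
        noise_sd=0.0,
        max_rotation_deg=8.0,
        max_translation_mm=4.0,
        artifact_probability=0.0,
        mesh_edge_length=0.3,
    )


@pytest.fixture(scope="session")
def noisy_pair():
    """Perturbed pair with scanner-level vertex noise (sd 0.01 mm)."""
    return _pair(
        n_teeth=6,
        seed=23,
        noise_sd=0.01,
        max_rotation_deg=8.0,
        max_translation_mm=4.0,
        artifact_probability=0.0,
        mesh_edge_length=0.3,
    )


@pytest.fixture(scope="session")
def registered_quiet(quiet_pair):
    pre, post, anns, truth = quiet_pair
    return (*quiet_pair, register(post, pre, anns))
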