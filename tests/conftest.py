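import pytest

from hemseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def phantom_case():
    """A default-sized phantom with noise, shared across read-only tests."""
    return generate_phantom(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free phantom: tissue HU means are exact."""
    return generate_phantom(PhantomSpec(seed=11, noise_sd=0.0))


@pytest.fixture(scope="session")
def small_phantom():
    """A small, fast phantom for unit tests that only need plumbing."""
    return generate_phantom(PhantomSpec(shape=(16, 48, 48), spacing=(5.0, 3.0, 3.0),
                                        ich_volume_ml=5.0, phe_rim_mm=5.0, seed=3))


@pytest.fixture(scope="session")
def scaled_run():
    """The desk-scale learning experiment shared by the acceptance tests.

    Trains the tiny dual model once per session (40 training / ~10 held-out
    phantoms, fixed seed) and scores the held-out cases with TTA.
    """
    from hemseg.experiments import scaled_learning_run
    return scaled_learning_run(seed=0, num_epochs=16)
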