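import numpy as np
import pytest

import eqcharge as eq


@pytest.fixture(scope="session")
def elements():
    return eq.default_elements()


@pytest.fixture(scope="session")
def stats():
    return eq.default_error_stats()


@pytest.fixture()
def water():
    """Gas-phase water geometry (Å), O first."""
    return eq.Molecule(
        ("O", "H", "H"),
        np.array(
            [
                [0.0, 0.0, 0.0],
                [0.9572, 0.0, 0.0],
                [-0.2399872, 0.9266272, 0.0],
            ]
        ),
    )


@pytest.fixture(scope="session")
def small_config():
    """Compact CHON descriptor set for fast unit tests."""
    return eq.default_acsf_config(("C", "H", "O", "N"), n_shifts=3)


@pytest.fixture(scope="session")
def oh_config():
    return eq.default_acsf_config(("O", "H"), n_shifts=3)


@pytest.fixture(scope="session")
def trained_oh_bundle(oh_config):
    """A small charge model trained on synthetic water-like clusters."""
    spec = eq.FixtureSpec(composition={"O": 1, "H": 2}, n_molecules=80, seed=5)
    frames = eq.generate_labeled_frames(spec)
    ds = eq.build_dataset(frames, oh_config)
    hp = eq.Hyperparams(hidden_layers=(16,), epochs=200)
    return eq.train_model(ds, hp, seed=3)
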