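import numpy as np
import pytest

import projbench as pb


@pytest.fixture(scope="session")
def small_golfball():
    """Reduced golf ball (nu=5, 252 points) for fast pipeline tests."""
    return pb.generate_golfball(5)


@pytest.fixture(scope="session")
def two_blob_dataset():
    """Two far-apart Gaussian blobs in 3-D (n=200), the separability fixture."""
    rng = np.random.default_rng(7)
    a = rng.normal([0.0, 0.0, 0.0], 0.2, size=(100, 3))
    b = rng.normal([5.0, 5.0, 5.0], 0.2, size=(100, 3))
    return pb.DataSet(
        points=np.vstack([a, b]),
        labels=np.repeat([0, 1], 100),
        name="two_blobs",
    )


@pytest.fixture(scope="session")
def trained_blob_grid(two_blob_dataset):
    """A small trained ESOM on the two-blob fixture (shared across tests)."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        grid = pb.init_grid(two_blob_dataset, rows=20, cols=30, seed=3)
        trained = pb.train_esom(
            two_blob_dataset,
            grid,
            pb.TrainingSchedule(epochs=10, radius_start=10.0, seed=3),
        )
    return grid, trained
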