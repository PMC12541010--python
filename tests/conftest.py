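import numpy as np
import pytest

from acunet import PhantomSpec, generate_samples


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def phantom_arrays(n, shape=(64, 64), seed=7, **kw):
    spec = PhantomSpec(n_samples=n, shape=shape, seed=seed, **kw)
    samples = generate_samples(spec)
    X = np.stack([s.image for s in samples])
    y = np.stack([s.mask for s in samples])
    return X, y


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small learnable phantom set for fast training tests."""
    return phantom_arrays(24, shape=(32, 32), seed=3,
                          wt_radius_range=(5.0, 9.0))


@pytest.fixture(scope="session")
def study_dataset():
    """The phantom study conditions: 200 slices, 64x64, seed 7."""
    return phantom_arrays(200, shape=(64, 64), seed=7)


@pytest.fixture(scope="session")
def study_split(study_dataset):
    """Shared 80/20 train/test split of the study dataset (seed 7)."""
    X, _ = study_dataset
    perm = np.random.default_rng(7).permutation(X.shape[0])
    n_test = max(1, int(round(X.shape[0] * 0.2)))
    return perm[n_test:], perm[:n_test]


@pytest.fixture(scope="session")
def trained_full(study_dataset, study_split):
    """Full-variant segmenter trained for 10 epochs on the study data."""
    from acunet import ACUNetSegmenter

    X, y = study_dataset
    train_idx, _ = study_split
    est = ACUNetSegmenter(variant="full", epochs=10, depth=3, base_width=8,
                          patience=10, seed=7)
    est.fit(X[train_idx], y[train_idx])
    return est


@pytest.fixture(scope="session")
def ablation_run(study_dataset):
    """Baseline vs full ablation on the study dataset, shared across tests.

    Both variants train to convergence (16 epochs) under the identical seed,
    split, preprocessing and loss; the table holds held-out region Dice.
    """
    from acunet.training import run_ablation

    X, y = study_dataset
    params = {"epochs": 16, "depth": 3, "base_width": 8, "patience": 12,
              "seed": 7}
    table, models = run_ablation(X, y, variants=("baseline", "full"),
                                 estimator_params=params, test_fraction=0.2,
                                 seed=7, return_models=True)
    return {"table": table, "models": models, "params": params}
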