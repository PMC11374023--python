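import numpy as np
import pytest

from psnfuse import LabelSet, ModalityConfig, OmicsMatrix, RunConfig


def random_omics(rng, n=6, p=8, kind="continuous", name="mod", prefix="s"):
    """Small random matrix helper for round-trip / property tests."""
    if kind == "counts":
        vals = rng.integers(0, 200, size=(n, p)).astype(float)
    elif kind == "beta":
        vals = rng.uniform(0, 1, size=(n, p))
    else:
        vals = rng.normal(size=(n, p))
    return OmicsMatrix(name, [f"{prefix}{i:03d}" for i in range(n)],
                       [f"{name}_f{j:03d}" for j in range(p)], vals, kind)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_labels():
    return LabelSet([f"s{i:03d}" for i in range(6)],
                    ["A", "A", "A", "B", "B", "B"])


def fast_config(n_modalities_names, seed=0, **overrides):
    """RunConfig scaled for quick unit-test training runs."""
    defaults = dict(
        k_neighbours=5, encoder_hidden=32, latent_dim=8, shared_dim=8,
        gcn_hidden=16, max_epochs=150, patience=25, n_folds=3, seed=seed,
    )
    defaults.update(overrides)
    mods = [ModalityConfig(n, k) for n, k in n_modalities_names]
    return RunConfig(modalities=mods, **defaults)
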