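import numpy as np
import pytest

from plmppi.fixtures import PlantedPairSpec, make_planted_embeddings, make_toy_string


@pytest.fixture(scope="session")
def toy_string(tmp_path_factory):
    """Toy STRING-format inputs with a self-audited expected-counts manifest."""
    out = tmp_path_factory.mktemp("toy_string")
    links, fasta, manifest_path, manifest = make_toy_string(
        n_proteins=12, seed=7, out_dir=out)
    return {"links": links, "fasta": fasta, "manifest_path": manifest_path,
            "manifest": manifest, "dir": out}


@pytest.fixture(scope="session")
def planted_small():
    """A small, clearly separable planted pair dataset for training tests."""
    spec = PlantedPairSpec(n_proteins=80, latent_dim=8, n_pos=40, n_neg=200,
                           noise_sd=0.0, seed=11, dim=64)
    pairs, features = make_planted_embeddings(spec)
    return spec, pairs, features


@pytest.fixture(scope="session")
def planted_default():
    """The default planted study conditions: 300 proteins, 200 pos / 2000 neg."""
    spec = PlantedPairSpec()
    pairs, features = make_planted_embeddings(spec)
    return spec, pairs, features


@pytest.fixture
def rng():
    return np.random.default_rng(20250920)
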