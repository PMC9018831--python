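import numpy as np
import pytest
import scipy.sparse as sp

import microcast as mc
from microcast.model import MicrocImputationModel, ModelConfig
from microcast.preprocess import build_graph
from microcast.core_data import ContactMap

E2E_SEED = 7


@pytest.fixture(scope="session")
def e2e():
    """The full end-to-end experiment: generate, train, impute, score.

    Session-scoped because it is the single most expensive computation in
    the suite; several tests read different facets of it.
    """
    return mc.run_end_to_end(E2E_SEED, n_windows=100)


@pytest.fixture(scope="session")
def bench_dataset(e2e):
    return e2e.dataset


def make_tiny_model(n_features=3, n=40, band_bins=12, seed=0, activation="relu",
                    embed_dim=8, zero_loop_head=False):
    """A small random model + a matching random window sample."""
    rng = np.random.default_rng(seed)
    cfg = ModelConfig(
        feature_names=tuple(f"f{i}" for i in range(n_features)),
        window_bp=n * 200,
        step_bp=n * 200,
        band_bp=band_bins * 200,
        conv_channels=(4, 6),
        conv_kernels=(5, 3),
        gcn_units=(5, 6),
        embed_dim=embed_dim,
        activation=activation,
        seed=seed,
    )
    model = MicrocImputationModel(cfg)
    if zero_loop_head:
        model.params["loop_W"][:] = 0.0
        model.params["loop_b"][:] = 0.0
    X = rng.random((n_features, n))
    dense = np.triu(rng.random((n, n)) * (rng.random((n, n)) > 0.6))
    fine = ContactMap("chrT", 200, sp.coo_matrix(dense), state="oe", n_bins=n)
    graph = build_graph(fine, X)
    sample = mc.WindowSample(
        chrom="chrT", start_bp=0, window_bp=n * 200, X=X, graph=graph,
        band_bp=band_bins * 200, feature_names=cfg.feature_names,
    )
    return model, sample


@pytest.fixture
def tiny_model_sample():
    return make_tiny_model()
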