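import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import kinface as kf  # noqa: E402


@pytest.fixture(scope="session")
def small_population():
    cfg = kf.SimConfig(seed=7, n_seasons=3, n_breeding_females=12,
                       embedding_dim=32)
    return kf.simulate_population(cfg), cfg


@pytest.fixture(scope="session")
def small_embeddings(small_population):
    pop, cfg = small_population
    return kf.simulate_embeddings(pop, cfg)


@pytest.fixture(scope="session")
def verification_model(small_embeddings):
    rng = np.random.default_rng(3)
    same, diff = kf.sample_verification_pairs(small_embeddings, 800, rng)
    return kf.learn_verification_weights(same, diff)


@pytest.fixture(scope="session")
def face_study():
    """Study-scale synthetic dataset: population at default demographic
    parameters, embeddings, learned verification weights, dyadic
    distances, residuals, and association covariate tables."""
    from kinface.pipeline import make_association_tables

    cfg = kf.SimConfig(seed=11, embedding_dim=64)
    pop = kf.simulate_population(cfg)
    emb = kf.simulate_embeddings(pop, cfg)
    rng = np.random.default_rng(101)
    same, diff = kf.sample_verification_pairs(emb, 2000, rng)
    model = kf.learn_verification_weights(same, diff)
    dist = kf.dyad_facial_distances(emb, model)
    resid = kf.residual_facial_distance(dist)
    tables = make_association_tables(pop, resid)
    return {
        "cfg": cfg, "population": pop, "embeddings": emb, "model": model,
        "distances": dist, "residuals": resid, "tables": tables,
    }
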