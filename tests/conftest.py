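import numpy as np
import pytest
from hypothesis import settings

from atlasmap.consensus import knn_consensus
from atlasmap.reference import fit_reference, project_query
from atlasmap.simulate import SyntheticConfig, simulate_cohort, simulate_reference

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cfg():
    """Scaled-down study conditions shared by the unit tests."""
    return SyntheticConfig(
        n_genes=300,
        n_ref_cells=600,
        n_samples_per_group=6,
        n_cells_per_sample=120,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_reference(small_cfg):
    return simulate_reference(small_cfg)


@pytest.fixture(scope="session")
def small_model(small_cfg, small_reference):
    ref, labels, _ = small_reference
    return fit_reference(ref, labels, n_hvg=250, d=10)


@pytest.fixture(scope="session")
def small_cohort(small_cfg, small_reference):
    _, _, programs = small_reference
    return simulate_cohort(small_cfg, programs)


@pytest.fixture(scope="session")
def small_annotations(small_cfg, small_model, small_cohort):
    query, truth = small_cohort
    qe = project_query(query, small_model, regress_cc=True,
                       s_genes=small_cfg.s_genes, g2m_genes=small_cfg.g2m_genes)
    anns = knn_consensus(qe, small_model, k=10, min_votes=5)
    return anns, truth


def random_embedding_problem(rng, n_ref=None, n_query=None, n_states=None, d=None):
    """A random reference embedding + query points for classifier oracle checks."""
    n_ref = n_ref or int(rng.integers(30, 501))
    n_query = n_query or int(rng.integers(5, 201))
    n_states = n_states or int(rng.integers(3, 9))
    d = d or int(rng.integers(2, 8))
    centers = rng.normal(0, 3, (n_states, d))
    ref_state = rng.integers(0, n_states, n_ref)
    ref = centers[ref_state] + rng.normal(0, 1.0, (n_ref, d))
    labels = np.array([f"s{i}" for i in ref_state])
    query = centers[rng.integers(0, n_states, n_query)] + rng.normal(0, 1.2, (n_query, d))
    return ref, labels, query
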