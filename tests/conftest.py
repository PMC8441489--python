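import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from myomac.simulate import SimulationConfig, make_reference, simulate_counts

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


SMALL_SIM_KWARGS = dict(
    n_types=4,
    n_genes=300,
    markers_per_type=10,
    cells_per_sample=(60, 80),
    n_age_effect_genes=20,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A reduced study design (4 macrophage subsets, ~420 cells) that keeps
    unit tests fast while preserving every structural feature."""
    return SimulationConfig(seed=7, **SMALL_SIM_KWARGS)


@pytest.fixture(scope="session")
def small_sim(small_config):
    ref = make_reference(small_config)
    counts, metadata, truth = simulate_counts(ref, small_config)
    return ref, counts, metadata, truth


@pytest.fixture(scope="session")
def default_run():
    """One full-scale simulation + clustering + markers, shared across tests."""
    from myomac import clustering as cl
    from myomac import qc
    from myomac.markers import find_markers

    cfg = SimulationConfig(seed=11)
    ref = make_reference(cfg)
    counts, metadata, truth = simulate_counts(ref, cfg)
    qc_df = qc.compute_qc(counts, truth.mito_genes)
    filtered = qc.filter_cells(counts, qc_df)
    expr = qc.log_normalize(filtered)
    hvg = qc.select_hvg(expr, n_top=1000)
    pca = cl.pca_embed(expr, hvg.genes, n_pcs=20)
    knn = cl.knn_graph(pca.coords, k=20)
    snn = cl.snn_from_knn(knn)
    assignment = cl.modularity_cluster(snn, seed=0)
    markers = find_markers(expr, assignment.labels)
    return {
        "config": cfg, "ref": ref, "counts": counts, "metadata": metadata,
        "truth": truth, "expr": expr, "hvg": hvg, "assignment": assignment,
        "markers": markers,
    }


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
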