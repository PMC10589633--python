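import numpy as np
import pytest

from raremics.simulate import SimulationConfig, simulate_watershed_instances


@pytest.fixture(scope="session")
def small_cohort():
    """A small but structured cohort reused across test modules."""
    cfg = SimulationConfig(n_individuals=60, n_genes=15, seed=7,
                           missing_rate=0.1)
    return simulate_watershed_instances(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def cohort_arrays(cohort):
    """Annotation matrix, status codes and signal names from a cohort."""
    cfg = cohort.config
    names = cfg.true_params.signal_names
    ann = [f"g{i}" for i in range(cfg.n_annotations)]
    G = cohort.instances[ann].to_numpy(float)
    E = cohort.instances[[f"e_{s}" for s in names]].to_numpy(int)
    return G, E, names
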