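import numpy as np
import pandas as pd
import pytest

from airseq.model import CountMatrix, SampleMeta
from airseq.pipeline import RunConfig, run
from airseq.simulate import SimulationConfig


def make_count_matrix(values, cell_type="macrophage", treatments=None, genes=None):
    """CountMatrix from a plain array; one sample per column."""
    values = np.asarray(values)
    n_genes, n_samples = values.shape
    treatments = treatments or ["ctrl"] * n_samples
    genes = genes or [f"g{i}" for i in range(n_genes)]
    seen: dict[str, int] = {}
    samples = []
    for j, tr in enumerate(treatments):
        seen[tr] = seen.get(tr, 0) + 1
        samples.append(SampleMeta(f"s{j}", cell_type, tr, seen[tr]))
    df = pd.DataFrame(values, index=genes, columns=[s.sample_id for s in samples])
    return CountMatrix(df, samples)


@pytest.fixture
def two_group_cm():
    """3 ctrl vs 3 LPS samples, constant means, for contrast plumbing tests."""
    rng = np.random.default_rng(0)
    values = rng.poisson(50, size=(40, 6))
    return make_count_matrix(values, treatments=["ctrl"] * 3 + ["LPS"] * 3)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on simulator defaults, shared across tests."""
    outdir = tmp_path_factory.mktemp("run") / "full"
    config = RunConfig(outdir=str(outdir), seed=1, sim=SimulationConfig(seed=1))
    run(config)
    return outdir


@pytest.fixture(scope="session")
def default_sim():
    from airseq.simulate import simulate_counts

    return simulate_counts(SimulationConfig(seed=1))
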