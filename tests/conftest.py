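import numpy as np
import pandas as pd
import pytest

from ttkin import (
    CountTable,
    LabelingDesign,
    SimulationParams,
    estimate_half_lives,
    estimate_size_factors,
    normalize,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def small_sim():
    """A modest synthetic experiment shared by read-only tests."""
    return simulate_experiment(
        SimulationParams(n_genes=300, n_spikeins=20, seed=11)
    )


@pytest.fixture(scope="session")
def small_halflives(small_sim):
    factors = estimate_size_factors(small_sim.counts)
    norm = normalize(small_sim.counts, factors)
    return estimate_half_lives(
        norm, LabelingDesign(), min_count=10, raw=small_sim.counts
    )


def make_table(counts: np.ndarray, spike_mask, conditions=None, assays=None):
    """Hand-build a CountTable from a genes x samples array."""
    n_genes, n_samples = counts.shape
    genes = [f"g{i}" for i in range(n_genes)]
    sids = [f"s{i}" for i in range(n_samples)]
    samples = pd.DataFrame(
        {
            "condition": conditions or ["WT"] * n_samples,
            "assay": assays or ["total"] * n_samples,
            "replicate": list(range(1, n_samples + 1)),
        },
        index=pd.Index(sids, name="sample_id"),
    )
    return CountTable(
        counts=pd.DataFrame(counts, index=genes, columns=sids),
        samples=samples,
        spikein=pd.Series(list(spike_mask), index=genes),
    )
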