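import numpy as np
import pandas as pd
import pytest

from palmscan.io import GenotypeMatrix, SampleMetadata


def make_matrix(
    calls,
    positions=None,
    scaffold="S000001",
    scaffold_length=None,
    effect_class=None,
):
    """Build a GenotypeMatrix from a (samples x sites) dosage array."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_sites = calls.shape
    if positions is None:
        positions = np.arange(n_sites) * 10
    positions = np.asarray(positions, dtype=np.int64)
    lengths = None
    if scaffold_length is not None:
        lengths = {scaffold: scaffold_length}
    return GenotypeMatrix(
        sample_ids=[f"s{i + 1}" for i in range(n_samples)],
        scaffolds=np.full(n_sites, scaffold, dtype=object),
        positions=positions,
        ref_allele=np.full(n_sites, "A", dtype=object),
        alt_allele=np.full(n_sites, "G", dtype=object),
        calls=calls,
        effect_class=None if effect_class is None else np.array(effect_class, dtype=object),
        scaffold_lengths=lengths,
    )


def make_metadata(sample_ids, populations=None, mean_depth=20.0, **phenotypes):
    populations = populations or ["other"] * len(sample_ids)
    data = {"population": populations, "mean_depth": mean_depth}
    data.update(phenotypes)
    return SampleMetadata(
        pd.DataFrame(data, index=pd.Index(sample_ids, name="sample_id"))
    )


@pytest.fixture(scope="session")
def neutral_two_pop():
    """A plain structured two-population simulation shared across tests."""
    from palmscan.simulate import SimulationConfig, simulate_two_pop

    config = SimulationConfig(
        seed=11, n_pop1=8, n_pop2=8, n_loci=120, locus_len=1000, split_time=1.0
    )
    return simulate_two_pop(config)
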