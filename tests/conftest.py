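import numpy as np
import pandas as pd
import pytest

from ithkit import dna_snv, simulate


@pytest.fixture(scope="session")
def clean_dna_sim():
    """Noise-free DNA simulation: every call is exact."""
    spec = simulate.make_clone_spec(n_fixed_sites=40,
                                    n_polymorphic_sites=30)
    noise = simulate.DnaNoiseModel(mean_depth=100, depth_dispersion=0.0,
                                   error_rate=0.0, ado_rate=0.0)
    return simulate.simulate_dna(spec, noise, 20, seed=42)


@pytest.fixture(scope="session")
def clean_dna_calls(clean_dna_sim):
    sim = clean_dna_sim
    return {
        cell: dna_snv.call_single_cell_snvs(
            pileup, sim.background_pileup, sim.bulk_sites)
        for cell, pileup in sim.cell_pileups.items()
    }


@pytest.fixture(scope="session")
def rna_sim_three_groups():
    """Well-separated three-group expression simulation."""
    spec = simulate.make_rna_spec(seed=11, n_groups=3,
                                  cells_per_group=(30, 30, 30),
                                  group_shift=3.0)
    return simulate.simulate_expression(spec, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_genotypes():
    """Tiny 0/1/NA matrix with a hand-checkable p-distance."""
    data = pd.DataFrame(
        [[1.0, 0.0, np.nan, 1.0],
         [1.0, 1.0, np.nan, 0.0],
         [0.0, 0.0, 0.0, 0.0]],
        index=["c1", "c2", "c3"],
        columns=["s1", "s2", "s3", "s4"])
    return data
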