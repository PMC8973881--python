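"""Shared fixtures: small synthetic datasets reused across module tests."""

import numpy as np
import pandas as pd
import pytest

from ipdkin import (KineticsModelConfig, PlantSpec, aggregate_sites,
                    generate_genome, simulate_reads)
from ipdkin.kinsim import focal_loci


@pytest.fixture(scope="session")
def null_genome():
    """12 kb genome with no planted motifs."""
    genome, planted = generate_genome(12_000, gc_fraction=0.36, seed=101)
    assert not planted
    return genome


@pytest.fixture(scope="session")
def null_sites(null_genome):
    """Aggregated site kinetics from a plant-free native simulation."""
    config = KineticsModelConfig()
    obs = simulate_reads(null_genome, [], config, mode="native", seed=102)
    return aggregate_sites(obs)


@pytest.fixture(scope="session")
def gatc_dataset():
    """20 kb genome with 60 planted GATC sites, focal adenine modified
    8.57-fold in native material; paired native/WGA site tables."""
    spec = PlantSpec("GATC", focal_offset=1, count=60,
                     modification_multiplier=8.57,
                     context_multipliers={1: 1.03})
    genome, planted = generate_genome(20_000, gc_fraction=0.45, plant_specs=[spec],
                                      seed=201)
    config = KineticsModelConfig()
    native = aggregate_sites(simulate_reads(genome, planted, config,
                                            mode="native", seed=202))
    wga = aggregate_sites(simulate_reads(genome, planted, config,
                                         mode="wga", seed=203))
    return {
        "genome": genome,
        "planted": planted,
        "native_sites": native,
        "wga_sites": wga,
        "loci": focal_loci(planted),
    }


def make_sites(values, base="A", contig="chr1", strand="+", valid_count=30):
    """Build a minimal site table from explicit mean IPDs."""
    values = np.asarray(values, dtype=float)
    return pd.DataFrame({
        "contig": contig,
        "pos": np.arange(values.size, dtype=np.int64),
        "strand": strand,
        "ref_base": base,
        "valid_count": valid_count,
        "mean_ipd": values,
        "ipd_err": 0.0,
    })
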