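import numpy as np
import pandas as pd
import pytest

from ase_atlas.simulate import SimulationConfig, simulate_bundle


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_chromosomes=2,
        chrom_length=300_000,
        n_genes=30,
        n_tissues=6,
        snps_per_gene_mean=3.0,
        depth_mean=80.0,
        error_snp_rate=0.05,
        roh_segments=(("chr1", 100_000, 300_000),),
        cluster_runs=((2, 6),),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_bundle(small_config, with_exon_counts=True)


@pytest.fixture()
def counts_frame():
    """Hand-built allele-count rows covering clear-cut regimes."""
    return pd.DataFrame(
        {
            "snp_id": ["s1", "s2", "s3", "s4"],
            "gene_id": ["g1", "g1", "g2", "g2"],
            "tissue": ["t1", "t1", "t1", "t1"],
            "r_m": [25, 80, 50, 95],
            "a_m": [25, 20, 25, 5],
            "r_p": [25, 20, 50, 5],
            "a_p": [25, 80, 25, 95],
        }
    )
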