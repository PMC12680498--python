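import warnings

import numpy as np
import pytest

from vitiscfb.simulate import (
    simulate_pangenome_vcf,
    simulate_reference,
    simulate_single_cell,
    simulate_sv_calls,
)


@pytest.fixture(scope="session")
def reference():
    return simulate_reference(n_chroms=2, chrom_len=100_000, n_genes=50, seed=7)


@pytest.fixture(scope="session")
def panel(reference):
    return simulate_pangenome_vcf(
        reference, n_haplotype_samples=10, n_planted_unique=8,
        n_decoys_per_category=5, seed=7,
    )


@pytest.fixture(scope="session")
def sv_calls(reference):
    return simulate_sv_calls(reference, n_hemi_genes=10, n_near_miss_decoys=6, seed=7)


@pytest.fixture(scope="session")
def sc_data():
    """Small two-type droplet dataset with planted markers, DEGs, bad cells."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_single_cell(
            n_genes=600, cells_per_sample=200, n_types=2, markers_per_type=15,
            n_degs=30, n_bad_cells=2, seed=11,
        )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
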