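import logging

import pytest

from mirpipe.pipeline import run_pipeline
from mirpipe.synthetic import SimulationSpec, simulate_all

logging.getLogger("mirpipe").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def default_study():
    """One default-spec synthetic study shared across the session."""
    return simulate_all(SimulationSpec(rng_seed=1))


@pytest.fixture(scope="session")
def default_result(default_study):
    """Full pipeline output on the shared study."""
    return run_pipeline(study=default_study)


@pytest.fixture(scope="session")
def small_spec():
    """A fast, reduced study spec for tests that re-simulate."""
    return SimulationSpec(
        n_chromosomes=3, chrom_length=30_000, n_known_mirnas=12,
        n_novel_hairpins=2, n_decoy_loci=2, n_ncrna=2, n_cluster_pairs=2,
        depth_per_sample=20_000, n_utrs=12, rng_seed=5,
    )
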