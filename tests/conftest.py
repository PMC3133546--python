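import numpy as np
import pytest

from refscaf.cli import RunConfig, run_pipeline
from refscaf.synthetic import fragment_genome, generate_genome, write_fixture

# The shared acceptance fixture: 150 kb + 60 kb, seed 1, 40 contigs + 5
# contaminants, inversions at 0.3, point mutations at 1%, origin spanner on.
ACCEPTANCE_PARAMS = dict(
    n_contigs=40,
    gap_mean=300,
    inversion_prob=0.3,
    mutation_rate=0.01,
    n_contaminants=5,
    origin_spanner=True,
    seed=1,
)


@pytest.fixture(scope="session")
def acceptance_genome():
    return generate_genome([150_000, 60_000], seed=1)


@pytest.fixture(scope="session")
def acceptance_fixture(acceptance_genome):
    contigs, truth = fragment_genome(acceptance_genome, **ACCEPTANCE_PARAMS)
    return contigs, truth


@pytest.fixture(scope="session")
def acceptance_run(tmp_path_factory, acceptance_genome, acceptance_fixture):
    """One full pipeline run on the acceptance fixture, shared across tests."""
    contigs, truth = acceptance_fixture
    root = tmp_path_factory.mktemp("acceptance")
    write_fixture(acceptance_genome, contigs, truth, root / "fix")
    config = RunConfig(
        contigs=root / "fix" / "contigs.fasta",
        references=[root / "fix" / f"{r.id}.fasta" for r in acceptance_genome],
        outdir=root / "run",
    )
    result = run_pipeline(config)
    return result, contigs, truth, acceptance_genome


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
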