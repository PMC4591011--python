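import numpy as np
import pytest

from tissueresp.quantify import SampleCounts, Transcript, flatten_gene_model, quantify_samples
from tissueresp.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """One deterministic synthetic study shared across tests."""
    return simulate_study(SimulationConfig(n_genes=400, seed=11))


@pytest.fixture(scope="session")
def small_expr(small_study):
    return quantify_samples(small_study.models, small_study.samples)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_model(gene_id, exons, chrom="chr1", strand="+", tx_id=None):
    tx = Transcript(tx_id or f"{gene_id}.t1", chrom, strand,
                    tuple(tuple(e) for e in exons))
    return flatten_gene_model(gene_id, [tx])


def make_sample(tissue, cond, counts, total=1_000_000):
    return SampleCounts(sample_id=(tissue, cond), gene_counts=counts,
                        total_mapped_reads=total)
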