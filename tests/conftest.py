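import numpy as np
import pytest

from pancub.codon_metrics import compute_metrics
from pancub.genetic_code import standard_code
from pancub.pangenome import partition_gene_sets, presence_counts
from pancub.synthetic_data import SyntheticConfig, generate_pangenome


@pytest.fixture(scope="session")
def code():
    return standard_code()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_cds(rng, length_codons: int, code=None) -> str:
    """A random in-frame CDS over the 61 sense codons, terminal stop added."""
    code = code or standard_code()
    sense = code.sense_codons
    body = "".join(rng.choice(sense, size=length_codons))
    return body + "TAA"


@pytest.fixture(scope="session")
def small_pangenome():
    """One medium synthetic pangenome shared by read-only tests."""
    config = SyntheticConfig(n_strains=8, n_families=120, seed=7,
                             length_range=(150, 250))
    return generate_pangenome(config)


@pytest.fixture(scope="session")
def small_metrics(small_pangenome):
    pg = small_pangenome
    records = pg.all_records
    strain_of = {r.gene_id: r.strain_id for r in records}
    profile = presence_counts(pg.clusters, strain_of)
    partition = partition_gene_sets(
        profile, pg.config.n_strains, clusters=pg.clusters
    )
    return compute_metrics(records, partition=partition)


def write_fasta(path, entries):
    """entries: list of (id, description, sequence)."""
    with open(path, "w") as fh:
        for name, desc, seq in entries:
            header = f">{name} {desc}".rstrip()
            fh.write(f"{header}\n{seq}\n")
    return path
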