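import numpy as np
import pytest

from gvtax.io_features import FeatureMatrix, GenomeRecord
from gvtax.synthetic import ContigLengthModel, make_signatures, sample_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """4 orders x 2 families, 12 genomes per family class; well-separated."""
    signatures = make_signatures(
        n_orders=4,
        families_per_order=2,
        gvogs_total=150,
        order_core_size=8,
        family_size=6,
        seed=11,
    )
    return sample_dataset(
        signatures,
        genomes_per_class=12,
        contig_length_model=ContigLengthModel((8_000, 15_000), (1, 3)),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_matrix(small_dataset):
    return small_dataset.feature_matrix()


def random_genome(rng: np.random.Generator, genome_id: str, lengths) -> GenomeRecord:
    contigs = [
        (f"{genome_id}C{i + 1}", "".join(rng.choice(list("ACGT"), size=L)))
        for i, L in enumerate(lengths)
    ]
    return GenomeRecord(genome_id=genome_id, contigs=contigs)


def toy_matrix(values, gvog_names=None, genome_ids=None, gc=0.5):
    """Binary presence matrix with a constant GC column prepended."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    gvog_names = gvog_names or [f"GVOGm{i:04d}" for i in range(m)]
    genome_ids = genome_ids or [f"g{i}" for i in range(n)]
    full = np.column_stack([np.full(n, gc), values])
    return FeatureMatrix(genome_ids, ["gc_content"] + list(gvog_names), full)
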