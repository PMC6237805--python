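import numpy as np
import pytest

from uniqmap import Genome, GenomeSpec, Feature, generate_genome


@pytest.fixture
def toy_genome():
    """Two small chromosomes with a shared 6-mer and an N run."""
    return Genome.from_dict({
        "chr1": "ACGTACGTTTGCAGGNNNACGTTTGCA",
        "chr2": "TTGCAGGACCACCA",
    })


@pytest.fixture
def repeat_genome():
    """5-kb genome with a dispersed repeat, an inverted repeat and an N run."""
    spec = GenomeSpec(
        chrom_lengths=(5000,),
        gc=0.45,
        features=(
            Feature("dispersed_repeat", ((0, 500), (0, 3000)), 200),
            Feature("inverted_repeat", ((0, 1200), (0, 4000)), 150),
            Feature("n_run", ((0, 2200),), 60),
        ),
        seed=7,
    )
    genome, manifest = generate_genome(spec)
    return genome, manifest


def random_genome_factory(seed: int, length: int = 2000, gc: float = 0.41,
                          n_chrom: int = 2) -> Genome:
    spec = GenomeSpec(chrom_lengths=(length,) * n_chrom, gc=gc, seed=seed)
    return generate_genome(spec)[0]


def assert_masks_equal(a, b):
    assert a.k == b.k
    assert set(a.chroms) == set(b.chroms)
    for name in a.chroms:
        np.testing.assert_array_equal(
            a.chroms[name], b.chroms[name],
            err_msg=f"mask mismatch on {name} (k={a.k})",
        )
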