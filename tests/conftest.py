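import numpy as np
import pytest

import promcnn as pc
from promcnn.synthetic_data import minus10_box


@pytest.fixture(scope="session")
def small_corpus():
    """Separable 81-nt bacterial-style corpus: consensus-only -10 box."""
    spec = pc.CorpusSpec(
        n_promoters=300,
        n_nonpromoters=300,
        window_length=81,
        tss_index=61,
        motifs=(minus10_box(weight=1.0, offset=-12),),
        seed=101,
    )
    return spec, pc.generate_corpus(spec)


@pytest.fixture(scope="session")
def small_split(small_corpus):
    _, records = small_corpus
    return pc.split_dataset(records, seed=7)


@pytest.fixture(scope="session")
def small_trained(small_split):
    """A quickly trained model on the separable 81-nt corpus."""
    spec = pc.parse_architecture("16, 7, 2", 81)
    params, history = pc.train(
        spec, small_split, pc.TrainConfig(max_epochs=12, patience=4, seed=7)
    )
    return params, history


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def _random_records(rng, n, length, tss_index=None, label=None, prefix="r"):
    bases = np.array(list("ATGC"))
    return [
        pc.SequenceRecord(
            id=f"{prefix}{i}",
            sequence="".join(bases[rng.integers(0, 4, size=length)]),
            label=label,
            tss_index=tss_index,
        )
        for i in range(n)
    ]


@pytest.fixture()
def random_records():
    """Factory for uniform-random DNA records."""
    return _random_records
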