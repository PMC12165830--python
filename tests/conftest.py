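import numpy as np
import pytest

from pvpkit.embeddings import EmbeddingTable
from pvpkit.synthetic import GaussianSpec, gen_gaussian_embeddings
from pvpkit.train_eval import TrainConfig

AA = list("ACDEFGHIKLMNPQRSTVWY")


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AA, size=length))


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = []
    for ch in seq:
        if rng.random() < rate:
            out.append(rng.choice([a for a in AA if a != ch]))
        else:
            out.append(ch)
    return "".join(out)


def split_table(table: EmbeddingTable, labels, test_fraction=0.2, seed=0):
    """Stratified row split of an embedding table into train/test halves."""
    from sklearn.model_selection import train_test_split

    labels = np.asarray(labels)
    idx = np.arange(len(table))
    tr, te = train_test_split(
        idx, test_size=test_fraction, random_state=seed, stratify=labels
    )
    def sub(rows):
        return (
            EmbeddingTable(table.backend, [table.ids[i] for i in rows], table.values[rows]),
            list(labels[rows]),
        )
    return sub(tr), sub(te)


@pytest.fixture(scope="session")
def small_gaussian():
    """Well-separated 2-class embeddings at unit-test scale (dim 64)."""
    table, labels = gen_gaussian_embeddings(
        GaussianSpec((40, 40), dim=64, separation=8.0, seed=11),
        class_names=["nonPVP", "PVP"],
    )
    return table, labels


@pytest.fixture
def quick_train_config():
    return TrainConfig(max_epochs=5, patience=3, batch_size=32, val_fraction=0.2, seed=5)
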