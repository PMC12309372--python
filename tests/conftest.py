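import numpy as np
import pytest

from cdsno import synthetic


class ConstantClassifier:
    """Returns a fixed probability for every window."""

    def __init__(self, p: float) -> None:
        self.p = p

    def predict(self, seqs):
        return np.full(len(seqs), self.p)


class MotifIndicatorClassifier:
    """p = 1 when the motif occurs in the window, else 0."""

    def __init__(self, motif: str = "ATGATGA") -> None:
        self.motif = motif

    def predict(self, seqs):
        return np.array([1.0 if self.motif in s else 0.0 for s in seqs])


@pytest.fixture
def constant_classifier():
    return ConstantClassifier


@pytest.fixture
def motif_classifier():
    return MotifIndicatorClassifier()


@pytest.fixture(scope="session")
def training_genome():
    """Independent genome used only to train the reference classifiers."""
    return synthetic.generate_genome(n_sno=40, genome_length=80_000, seed=901)


@pytest.fixture(scope="session")
def reference_models(training_genome):
    """(window classifier, subclass classifier) trained on the training genome."""
    record, truth = training_genome
    rng = np.random.default_rng(901)
    first = synthetic.train_reference_classifier(
        synthetic.build_first_model_dataset(record, truth, rng), seed=901
    )
    second = synthetic.train_reference_classifier(
        synthetic.build_second_model_dataset(record, truth, rng), seed=901
    )
    return first, second
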