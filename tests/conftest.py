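import numpy as np
import pytest

from ilcgate.classifier import LabeledTrainingSet
from ilcgate.io_cohort import ClinicalRecord, ExpressionMatrix
from ilcgate.normalize import extract_profile, normalize_counts
from ilcgate.synthetic_data import SimulationConfig, simulate_reference


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    return ExpressionMatrix(
        ("g1", "g2", "g3"), ("s1", "s2"),
        np.array([[1, 2], [3, 4], [5, 6]], dtype=np.int64))


@pytest.fixture
def random_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    counts = rng.poisson(50, size=(20, 3)).astype(np.int64)
    return ExpressionMatrix(
        tuple(f"g{i}" for i in range(20)), ("a", "b", "c"), counts)


def make_training_set(seed: int, **config_kwargs) -> LabeledTrainingSet:
    """Signature-gene logCPM features from a simulated two-class reference."""
    cfg = SimulationConfig(seed=seed, **config_kwargs)
    ref, labels = simulate_reference(cfg)
    norm = extract_profile(normalize_counts(ref), cfg.signature_gene_ids)
    return LabeledTrainingSet.from_normalized(norm, labels)


@pytest.fixture
def training_set() -> LabeledTrainingSet:
    return make_training_set(7)


def make_records(times, events, **kwargs) -> list[ClinicalRecord]:
    return [ClinicalRecord(sample_id=f"p{i}", time=float(t), event=int(e),
                           **kwargs)
            for i, (t, e) in enumerate(zip(times, events))]
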