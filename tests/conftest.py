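import numpy as np
import pytest

from dmflsim import ImageSample, LabeledDataset, generate_synthetic_dataset


@pytest.fixture
def tiny_dataset():
    """60 samples, 3 classes, 16x16, clearly separable."""
    return generate_synthetic_dataset([20, 20, 20], image_size=(16, 16), separability=4.0, seed=11)


@pytest.fixture
def flat_dataset():
    """Pure-noise dataset: separability 0, classes indistinguishable."""
    return generate_synthetic_dataset([60, 60], image_size=(8, 8), separability=0.0, seed=5)


def make_manual_dataset(pixel_rows, labels, num_classes, prefix="m"):
    """Build a LabeledDataset from explicit per-sample pixel arrays."""
    samples = [
        ImageSample(f"{prefix}{i}", np.asarray(px, dtype=float), int(lab))
        for i, (px, lab) in enumerate(zip(pixel_rows, labels))
    ]
    return LabeledDataset(samples, [f"class{k}" for k in range(num_classes)])
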