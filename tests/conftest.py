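import numpy as np
import pytest

from kpcaselect import ExpressionDataset, SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_dataset(rng):
    """8 samples x 5 features, balanced classes, generic Gaussian data."""
    X = rng.normal(size=(8, 5))
    y = np.array([-1, -1, -1, -1, 1, 1, 1, 1])
    return ExpressionDataset(
        X=X,
        y=y,
        sample_ids=[f"s{i}" for i in range(8)],
        feature_ids=[f"g{j}" for j in range(5)],
    )


@pytest.fixture
def shells_dataset():
    """Concentric-shell data: linearly inseparable, radially separable."""
    return generate(SyntheticSpec(structure="radial", effect=1.0, seed=42))


@pytest.fixture
def shifted_dataset():
    """Linearly separable two-cloud data with a strong mean shift."""
    return generate(
        SyntheticSpec(structure="linear-shift", effect=6.0, noise_sd=0.1, seed=42)
    )


def write_csv(path, rows, header):
    path.write_text("\n".join([",".join(header)] + [",".join(map(str, r)) for r in rows]) + "\n")
    return path
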