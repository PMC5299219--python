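import numpy as np
import pytest

from wolfsel.datasets import Dataset, SyntheticSpec, generate_synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_dataset():
    """30 samples x 5 features, mildly separated classes."""
    spec = SyntheticSpec(n_samples=30, n_informative=2, n_redundant=0,
                         n_noise=3, class_separation=1.5, seed=7)
    return generate_synthetic(spec)


@pytest.fixture
def separable_dataset():
    """Wide-margin Gaussian classes: 5 informative + 15 noise, separation 4."""
    spec = SyntheticSpec(n_samples=100, n_informative=5, n_noise=15,
                         class_separation=4.0, seed=11)
    return generate_synthetic(spec)


@pytest.fixture
def benchmark_dataset():
    """The standard recovery benchmark: 100 samples, 5 informative (sep 2), 15 noise."""
    return generate_synthetic(SyntheticSpec(seed=5))


def make_perfect_separator(n_samples=40, n_features=10, sep_index=0, seed=0):
    """One perfectly separating feature; the rest are pure noise at tiny scale.

    Feature ``sep_index`` equals the class label, so any subset containing it
    is linearly separable while subsets without it carry no signal.
    """
    rng = np.random.default_rng(seed)
    labels = np.tile([1, -1], n_samples // 2)
    X = 0.01 * rng.standard_normal((n_samples, n_features))
    X[:, sep_index] = labels
    return Dataset(X, labels, [f"f{i}" for i in range(n_features)])


@pytest.fixture
def perfect_separator_dataset():
    return make_perfect_separator()


def parkinson_like_csv(path, seed=0):
    """A file with the UCI Parkinson column layout (not the UCI data):
    name column, 22 voice-measure columns, binary status, 147 positive and
    48 negative rows."""
    rng = np.random.default_rng(seed)
    n_pos, n_neg = 147, 48
    cols = [f"MDVP:m{i}" for i in range(22)]
    header = "name," + ",".join(cols) + ",status"
    lines = [header]
    status = [1] * n_pos + [0] * n_neg
    for i, s in enumerate(status):
        vals = rng.standard_normal(22) + (0.5 if s else -0.5)
        lines.append(f"rec_{i}," + ",".join(f"{v:.6f}" for v in vals) + f",{s}")
    path.write_text("\n".join(lines) + "\n")
    return path


def wdbc_like_csv(path, seed=0):
    """A file with the UCI WDBC column layout (not the UCI data):
    ID, diagnosis (M/B), 30 features; 357 benign, 212 malignant."""
    rng = np.random.default_rng(seed)
    diagnoses = ["B"] * 357 + ["M"] * 212
    header = "id,diagnosis," + ",".join(f"feat{i}" for i in range(30))
    lines = [header]
    for i, d in enumerate(diagnoses):
        vals = rng.standard_normal(30) + (0.5 if d == "M" else -0.5)
        lines.append(f"{840000 + i},{d}," + ",".join(f"{v:.6f}" for v in vals))
    path.write_text("\n".join(lines) + "\n")
    return path
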