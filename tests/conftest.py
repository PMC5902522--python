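import numpy as np
import pytest

from plausitest import TwoGroupSample, generate_two_group


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def gaussian_sample(rng):
    """Equal-variance Gaussian two-group sample, n = 30/40."""
    return TwoGroupSample(rng.normal(0.0, 1.0, 30), rng.normal(0.3, 1.0, 40))


@pytest.fixture
def csv_factory(tmp_path):
    """Write a two-group sample to CSV/TSV and return the path."""

    def _write(sample: TwoGroupSample, sep: str = ",", name: str = "data.csv",
               value_col: str = "value", group_col: str = "group"):
        path = tmp_path / name
        lines = [f"{value_col}{sep}{group_col}"]
        for v in sample.group1:
            lines.append(f"{float(v)!r}{sep}{sample.labels[0]}")
        for v in sample.group2:
            lines.append(f"{float(v)!r}{sep}{sample.labels[1]}")
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


@pytest.fixture
def delta_sample_factory():
    """Seeded Gaussian sample with a chosen variance ratio."""

    def _make(delta: float, n1: int = 50, n2: int = 50, seed: int = 7):
        rng = np.random.default_rng(seed)
        return generate_two_group(n1, n2, 0.0, 0.0, delta, 1.0, rng)

    return _make
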