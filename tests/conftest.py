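import numpy as np
import pytest

from cvdhybrid.data_io import CleanTable

CLEVELAND_ROWS = [
    "63.0,1.0,1.0,145.0,233.0,1.0,2.0,150.0,0.0,2.3,3.0,0.0,6.0,0",
    "67.0,1.0,4.0,160.0,286.0,0.0,2.0,108.0,1.0,1.5,3.0,3.0,?,2",
    "41.0,0.0,2.0,130.0,204.0,0.0,2.0,172.0,0.0,1.4,1.0,0.0,3.0,1",
]


@pytest.fixture
def cleveland_file(tmp_path):
    path = tmp_path / "cleveland.data"
    path.write_text("\n".join(CLEVELAND_ROWS) + "\n")
    return path


@pytest.fixture
def statlog_file(tmp_path):
    rng = np.random.default_rng(7)
    lines = []
    for i in range(270):
        vals = rng.uniform(0, 10, size=13)
        label = 1 + (i % 2)
        lines.append(" ".join(f"{v:.2f}" for v in vals) + f" {label}")
    path = tmp_path / "statlog.dat"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def balanced_table():
    """10 samples, 4 attributes, balanced binary labels."""
    rng = np.random.default_rng(3)
    X = rng.uniform(0, 1, size=(10, 4))
    y = np.array([0, 1] * 5)
    return CleanTable(X, y, [f"a{j}" for j in range(4)])
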