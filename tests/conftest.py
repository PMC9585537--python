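import numpy as np
import pytest

from cardiodx.datakit import FeatureTable, SyntheticSpec, generate_synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_processed_rows(n, seed=0):
    """Rows in the processed 14-column dialect with plausible value ranges."""
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n):
        fields = [
            str(int(rng.integers(29, 78))),      # age
            str(int(rng.integers(0, 2))),        # sex
            str(int(rng.integers(1, 5))),        # cp
            str(int(rng.integers(94, 201))),     # trestbps
            str(int(rng.integers(126, 565))),    # chol
            str(int(rng.integers(0, 2))),        # fbs
            str(int(rng.integers(0, 3))),        # restecg
            str(int(rng.integers(71, 203))),     # thalach
            str(int(rng.integers(0, 2))),        # exang
            repr(round(float(rng.uniform(0, 6.2)), 1)),  # oldpeak
            str(int(rng.integers(1, 4))),        # slope
            str(int(rng.integers(0, 4))),        # ca
            str(int(rng.choice([3, 6, 7]))),     # thal
            str(int(rng.integers(0, 5))),        # target
        ]
        rows.append(",".join(fields))
    return rows


@pytest.fixture
def cleveland_fixture(tmp_path):
    """303-row file in the processed dialect, with some '?' sentinels."""
    rows = make_processed_rows(303, seed=7)
    rng = np.random.default_rng(8)
    for i in rng.choice(303, size=12, replace=False):
        fields = rows[i].split(",")
        fields[rng.integers(0, 13)] = "?"
        rows[i] = ",".join(fields)
    path = tmp_path / "cleveland.csv"
    path.write_text("\n".join(rows) + "\n")
    return path


@pytest.fixture
def two_gauss_table():
    """Well-separated two-class Gaussian table, no outliers or missing cells."""
    j = 5
    spec = SyntheticSpec(
        n_per_class=(60, 60),
        means=(np.zeros(j), np.full(j, 3.0 / np.sqrt(j))),
        covariances=(np.eye(j), np.eye(j)),
        seed=11,
    )
    return generate_synthetic(spec)


def small_table(X, y):
    X = np.asarray(X, dtype=float)
    return FeatureTable(
        X=X,
        y=np.asarray(y, dtype=int),
        missing=np.zeros_like(X, dtype=bool),
        names=tuple(f"f{i}" for i in range(X.shape[1])),
    )
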