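import numpy as np
import pandas as pd
import pytest

GENES10 = [f"G{i}" for i in range(10)]


def independent_dataset(rng, n_cells=10, genes=GENES10):
    """Expression matrix (cells x genes) with no correlation structure."""
    return pd.DataFrame(rng.normal(size=(n_cells, len(genes))), columns=genes)


def shared_factor_datasets(seed, n_cells=40, strength=0.85, n_factors=3,
                           genes=GENES10):
    """Two datasets whose genes load on the same sparse latent factors.

    Same-factor gene pairs are strongly correlated in *both* datasets
    (signed by the shared loading signs), so their congruency is specific
    to the gene labels and destroyed by label permutation.
    """
    rng = np.random.default_rng(seed)
    k = len(genes)
    factor_of = np.arange(k) % n_factors
    sign = np.where(rng.random(k) < 0.5, 1.0, -1.0)

    def draw():
        F = rng.normal(size=(n_cells, n_factors))
        noise = np.sqrt(1 - strength ** 2) * rng.normal(size=(n_cells, k))
        return pd.DataFrame(strength * sign * F[:, factor_of] + noise,
                            columns=genes)

    return draw(), draw()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_reference():
    """Long-format dCt reference, 40 subjects/day across LH+6..11, one gene."""
    rng = np.random.default_rng(0)
    rows = []
    i = 0
    for day in range(6, 12):
        for _ in range(40):
            i += 1
            rows.append({"subject_id": f"R{i:04d}", "lh_day": day,
                         "gene": "SCARA5",
                         "dct": float(np.clip(rng.normal(6 - 0.3 * (day - 6), 1.2),
                                              0, None))})
    return pd.DataFrame(rows)
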