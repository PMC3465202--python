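import numpy as np
import pytest

from genebeam.io_norm import ExpressionDataset
from genebeam.synthetic import SimConfig, simulate


@pytest.fixture
def toy_dataset() -> ExpressionDataset:
    """4 samples x 3 genes, two classes, deterministic values."""
    return ExpressionDataset(
        sample_ids=("s1", "s2", "s3", "s4"),
        gene_ids=("gA", "gB", "gC"),
        values=np.array(
            [
                [1.0, 10.0, 5.0],
                [2.0, 20.0, 5.0],
                [3.0, 30.0, 5.0],
                [4.0, 40.0, 5.0],
            ]
        ),
        labels=("t", "t", "n", "n"),
    )


@pytest.fixture
def planted_sim():
    """Strong planted signal: 2 classes x 15 samples, 30 genes, 2
    informative at a 3-sigma shift."""
    return simulate(
        SimConfig(
            n_classes=2, n_per_class=15, n_genes=30, n_informative=2,
            effect=3.0, sigma=1.0, seed=11,
        )
    )


@pytest.fixture
def weak_sim():
    """Weak planted signal: classes overlap so no small subset reaches
    100% CV accuracy and the search runs to its depth bound."""
    return simulate(
        SimConfig(
            n_classes=2, n_per_class=15, n_genes=30, n_informative=3,
            effect=0.8, sigma=1.0, seed=23,
        )
    )


@pytest.fixture
def separable_dataset() -> ExpressionDataset:
    """Two classes perfectly separated by genes g1 and g2 jointly (XOR-free
    linear split), with noise genes alongside."""
    rng = np.random.default_rng(5)
    m_per = 12
    n_noise = 8
    x1 = np.r_[rng.normal(0, 0.3, m_per), rng.normal(4, 0.3, m_per)]
    x2 = np.r_[rng.normal(0, 0.3, m_per), rng.normal(4, 0.3, m_per)]
    noise = rng.normal(0, 1, (2 * m_per, n_noise))
    values = np.column_stack([x1, x2, noise])
    return ExpressionDataset(
        sample_ids=tuple(f"s{i}" for i in range(2 * m_per)),
        gene_ids=("g1", "g2") + tuple(f"n{i}" for i in range(n_noise)),
        values=values,
        labels=("a",) * m_per + ("b",) * m_per,
    )
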