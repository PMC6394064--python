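import numpy as np
import pandas as pd
import pytest

from urimark.containers import ExpressionMatrix


def make_matrix(values, gene_ids=None, sample_ids=None, classes=None,
                datasets=None, platforms=None):
    """Build a small ExpressionMatrix from a 2-D array and annotations."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"G{i:03d}" for i in range(1, n_genes + 1)]
    sample_ids = sample_ids or [f"S{i:02d}" for i in range(1, n_samples + 1)]
    classes = classes or ["A"] * n_samples
    datasets = datasets or ["d1"] * n_samples
    platforms = platforms or ["p1"] * n_samples
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                            columns=sample_ids),
        samples=pd.DataFrame(
            {
                "tissue_class": classes,
                "dataset_id": datasets,
                "platform": platforms,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        ),
    )


@pytest.fixture
def two_class_matrix():
    """60 genes x 12 samples, two classes, gene 0 shifted +2 in class A."""
    rng = np.random.default_rng(42)
    values = rng.normal(8.0, 0.3, size=(60, 12))
    values[0, :6] += 2.0
    return make_matrix(
        values,
        classes=["A"] * 6 + ["B"] * 6,
        datasets=["dA"] * 6 + ["dB"] * 6,
    )


@pytest.fixture(scope="session")
def screen_fixture():
    """The default seeded glomerular screening compendium plus its truth."""
    from urimark.simulate import default_screen_config, simulate_compendium

    cfg = default_screen_config(seed=20240901 % (2**31))
    return simulate_compendium(cfg)
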