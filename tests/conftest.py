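import numpy as np
import pandas as pd
import pytest

from coexgalaxy.io import DISEASE, NORMAL, ExpressionMatrix


def make_matrix(values, genes, samples, n_normal):
    """Build an ExpressionMatrix with the first n_normal samples normal."""
    groups = {s: (NORMAL if i < n_normal else DISEASE)
              for i, s in enumerate(samples)}
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), groups)


@pytest.fixture
def small_matrix():
    """4 genes x 8 samples (4 normal, 4 disease), fixed random values."""
    rng = np.random.default_rng(42)
    genes = ["GA", "GB", "GC", "GD"]
    samples = [f"s{i}" for i in range(8)]
    return make_matrix(rng.standard_normal((4, 8)), genes, samples, 4)


@pytest.fixture
def expression_tsv(tmp_path):
    path = tmp_path / "expr.tsv"
    path.write_text(
        "gene_id\ts1\ts2\ts3\ts4\n"
        "G1\t1.0\t2.0\t3.0\t4.0\n"
        "G2\t2.5\t1.5\t0.5\t3.5\n"
        "G3\t0.1\t0.2\t0.3\t0.4\n")
    groups = {"s1": NORMAL, "s2": NORMAL, "s3": DISEASE, "s4": DISEASE}
    return path, groups
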