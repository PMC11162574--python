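import numpy as np
import pandas as pd
import pytest

from dupevol.io import ExpressionMatrix, LOG2P1


@pytest.fixture
def tiny_matrix_tsv(tmp_path):
    """A 3-gene, 4-tissue raw expression TSV on disk."""
    path = tmp_path / "expr.tsv"
    path.write_text(
        "gene_id\tstem\tleaf\tflower\tsilique\n"
        "g1\t0.0\t1.0\t7.0\t3.0\n"
        "g2\t2.5\t2.5\t2.5\t2.5\n"
        "g3\t10.0\t0.0\t0.0\t0.0\n"
    )
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def log_matrix(rows: dict) -> ExpressionMatrix:
    """Build a log2(x+1)-scale matrix from a gene -> 4-vector dict."""
    return ExpressionMatrix(
        values=pd.DataFrame.from_dict(
            rows, orient="index", columns=["stem", "leaf", "flower", "silique"]
        ),
        scale=LOG2P1,
    )
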