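import numpy as np
import pytest
import scipy.sparse as sp

from decontpro.io import ANTIBODY_CAPTURE, GENE_EXPRESSION, CountMatrix


@pytest.fixture
def toy_mtx_dir(tmp_path):
    """Hand-written 3-feature x 2-barcode CellRanger triplet directory
    with entries {(1,1)=5, (3,2)=2} (1-based, features as MTX rows)."""
    d = tmp_path / "toy"
    d.mkdir()
    (d / "matrix.mtx").write_text(
        "%%MatrixMarket matrix coordinate integer general\n"
        "3 2 2\n"
        "1 1 5\n"
        "3 2 2\n"
    )
    (d / "features.tsv").write_text(
        "ENSG1\tGeneA\tGene Expression\n"
        "ENSG2\tGeneB\tGene Expression\n"
        "ADT1\tCD3\tAntibody Capture\n"
    )
    (d / "barcodes.tsv").write_text("AAAC-1\nAAAG-1\n")
    return d


@pytest.fixture
def toy_count_matrix():
    counts = np.array([[5, 0, 0], [0, 0, 2]])
    return CountMatrix(
        sp.csr_matrix(counts),
        np.array(["AAAC-1", "AAAG-1"], dtype=object),
        np.array(["GeneA", "GeneB", "CD3"], dtype=object),
        np.array([GENE_EXPRESSION, GENE_EXPRESSION, ANTIBODY_CAPTURE], dtype=object),
        np.array(["ENSG1", "ENSG2", "ADT1"], dtype=object),
    )


@pytest.fixture
def random_count_matrix():
    rng = np.random.default_rng(42)
    counts = sp.random(
        30, 12, density=0.3, random_state=rng, data_rvs=lambda n: rng.integers(1, 50, n)
    ).astype(np.int64)
    types = np.array(
        [GENE_EXPRESSION] * 8 + [ANTIBODY_CAPTURE] * 4, dtype=object
    )
    return CountMatrix(
        sp.csr_matrix(counts),
        np.array([f"BC{i:03d}-1" for i in range(30)], dtype=object),
        np.array([f"F{j}" for j in range(12)], dtype=object),
        types,
    )
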