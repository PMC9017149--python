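import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import HealthCheck, settings

from linfuse.datamodel import DistanceMatrix, MultimodalDataset

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def condensed(values):
    """Wrap a raw condensed vector as an RNA-tagged DistanceMatrix."""
    values = np.asarray(values, dtype=float)
    n = int(round((1 + np.sqrt(1 + 8 * values.size)) / 2))
    return DistanceMatrix(values, np.arange(n), "RNA")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_dataset():
    """3 genes + 2 ADT features x 4 cells with hand-set counts."""
    rna = sp.csr_matrix(np.array([[0, 1, 2, 3],
                                  [4, 0, 6, 0],
                                  [1, 1, 1, 1]]))
    adt = np.array([[5.0, 0.0, 2.0, 8.0],
                    [1.0, 3.0, 0.0, 2.0]])
    return MultimodalDataset(
        rna=rna, adt=adt,
        gene_ids=np.array(["MT-CO1", "geneB", "geneC"], dtype=object),
        adt_ids=np.array(["CD3", "CD4"], dtype=object),
        cell_barcodes=np.array(["a", "b", "c", "d"], dtype=object),
    )
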