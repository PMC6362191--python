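import numpy as np
import pytest

from dish.panel import (
    Marker,
    MarkerKind,
    MatrixStore,
    ReferencePanel,
    build_matrix_store,
)


def random_panel(
    rng: np.random.Generator,
    n_hap: int = 40,
    n_snp: int = 6,
    n_hla: int = 3,
) -> ReferencePanel:
    """Small random binary panel with guaranteed-polymorphic columns."""
    cols = []
    for j in range(n_snp + n_hla):
        while True:
            col = (rng.random(n_hap) < rng.uniform(0.2, 0.8)).astype(float)
            if 0 < col.sum() < n_hap:
                break
        if j < n_snp:
            mk = Marker(f"rs{j}", MarkerKind.SNP, 100 + j, "A", "G", 0.5)
        else:
            mk = Marker(
                f"HLA_A_{j:02d}", MarkerKind.HLA_1FIELD, 100 + j, "P", "A", 0.5
            )
        cols.append((mk, col))
    return ReferencePanel.from_columns(cols)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def small_store(rng) -> MatrixStore:
    return build_matrix_store(random_panel(rng), maf_min=0.0)


def perfect_proxy_store() -> MatrixStore:
    """Two typed SNPs plus one HLA marker in perfect LD with the first SNP."""
    snp1 = np.array([1, 1, 0, 0, 1, 0, 1, 0], dtype=float)
    snp2 = np.array([1, 0, 1, 0, 0, 1, 0, 1], dtype=float)
    cols = [
        (Marker("rs1", MarkerKind.SNP, 10, "A", "G", 0.5), snp1),
        (Marker("rs2", MarkerKind.SNP, 20, "C", "T", 0.5), snp2),
        (Marker("HLA_A_01", MarkerKind.HLA_1FIELD, 15, "P", "A", 0.5), snp1.copy()),
    ]
    return build_matrix_store(ReferencePanel.from_columns(cols), maf_min=0.0)
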