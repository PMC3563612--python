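import numpy as np
import pytest

from exoncnv import Gene, PriorTable, RDMatrix, TargetSet


@pytest.fixture
def priors():
    return PriorTable.default()


@pytest.fixture
def toy_targets():
    """Three genes on one chromosome, 1 Mb gaps, plus one far gene."""
    return TargetSet([
        Gene("GENE_A", "chr1", 1_000_000, 1_010_000,
             ((1_000_000, 1_004_000), (1_006_000, 1_010_000))),
        Gene("GENE_B", "chr1", 2_010_000, 2_020_000,
             ((2_010_000, 2_020_000),)),
        Gene("GENE_C", "chr1", 3_020_000, 3_030_000,
             ((3_020_000, 3_030_000),)),
        Gene("GENE_D", "chr2", 500_000, 510_000, ((500_000, 510_000),)),
    ])


@pytest.fixture
def small_rd():
    rng = np.random.default_rng(7)
    mrd = rng.uniform(500, 3000, 12)
    affin = np.array([0.8, 1.0, 1.5, 2.0])
    counts = rng.poisson(np.outer(affin, mrd)).astype(np.int64)
    return RDMatrix(counts, ["GENE_A", "GENE_B", "GENE_C", "GENE_D"],
                    [f"S{i:02d}" for i in range(12)])
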