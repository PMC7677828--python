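import numpy as np
import pytest

from haplokit.matrix import GenotypeMatrix
from haplokit.synth import CohortSpec, make_default_panel, simulate_genotypes


@pytest.fixture
def small_panel():
    """Three haplotypes over 5 sites (HAP2 diverges at the first 3)."""
    return make_default_panel(5, 3)


@pytest.fixture
def small_cohort(small_panel):
    """One-stratum cohort with a planted risk haplotype (OR 1.5)."""
    spec = CohortSpec(
        strata=[("EA", 300, 300)],
        haplotype_log_or={"HAP3": np.log(1.5)},
        seed=11,
    )
    return simulate_genotypes(small_panel, spec)


def genotype_matrix(rows, variants=None, positions=None):
    """Build a GenotypeMatrix from a list of per-sample genotype rows."""
    rows = np.asarray(rows, dtype=np.int8)
    n, m = rows.shape
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(n)],
        variants=variants or [f"v{j}" for j in range(m)],
        positions=positions if positions is not None else np.arange(1, m + 1),
        genotypes=rows,
    )
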