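import numpy as np
import pytest

from exwas import CohortSpec, ReadEvidenceSpec, gen_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """400 samples x 10 genes x 10 variants, default frequency spectrum."""
    return gen_cohort(CohortSpec(n_samples=400, n_genes=10, variants_per_gene=10,
                                 seed=42))


@pytest.fixture(scope="session")
def somatic_cohort():
    """Cohort with 10% somatic variants (VAF 0.2, carrier prob rising in age)."""
    spec = CohortSpec(
        n_samples=2000, n_genes=5, variants_per_gene=10, seed=7,
        read_evidence=ReadEvidenceSpec(somatic_fraction=0.1, somatic_vaf=0.2,
                                       somatic_age_slope=0.25,
                                       somatic_age_midpoint=60.0,
                                       somatic_max_prob=0.25),
    )
    return gen_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
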