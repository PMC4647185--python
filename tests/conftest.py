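import numpy as np
import pytest

import bpscreen as b


@pytest.fixture(scope="session")
def small_cohort():
    """n=2000 development-style cohort with complete visit data."""
    cfg = b.alspac_like_config(n=2000, seed=11)
    return b.generate_cohort(cfg), cfg


@pytest.fixture(scope="session")
def small_derived(small_cohort):
    cohort, _ = small_cohort
    return b.derive_table(cohort)


@pytest.fixture(scope="session")
def small_normograms(small_cohort, small_derived):
    cohort, _ = small_cohort
    return b.fit_normograms(cohort, small_derived, seed=7)


@pytest.fixture(scope="session")
def dev_pipeline():
    """Shared large development pipeline: cohort, derived table, normograms,
    complete-data model registry.  Reused by the discrimination, screening
    and missing-data acceptance checks."""
    cfg = b.alspac_like_config(n=13000, seed=101)
    cohort = b.generate_cohort(cfg)
    derived = b.derive_table(cohort)
    fits = b.fit_normograms(cohort, derived, subsample=2500, seed=3)
    imp = b.passive_normative(b.complete_data_set(derived), fits)
    registry = b.build_all_models(imp, outcomes=("pe",))
    return {"config": cfg, "cohort": cohort, "derived": derived,
            "normograms": fits, "imputation": imp, "registry": registry}


@pytest.fixture
def rng():
    return np.random.default_rng(42)
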