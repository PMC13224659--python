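import numpy as np
import pytest

import coda24 as c


def random_composition(rng, names, total=1440.0):
    """Random strictly-positive composition closed to `total`."""
    parts = rng.uniform(0.05, 1.0, size=len(names))
    return c.close(dict(zip(names, parts)), total)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_cohort():
    """400 children, clean record-level generation (continuous outcomes)."""
    records, truth = c.generate_records(c.GeneratorConfig(n=400, seed=11))
    return records, truth


@pytest.fixture(scope="session")
def fitted_total(small_cohort):
    """Total-difficulties fit (sleep dominant) plus the cohort base day."""
    records, truth = small_cohort
    spec = c.DesignSpec(outcome="total_difficulties",
                        behaviours=c.BEHAVIOURS_4, dominant="sleep")
    fit = c.fit_compositional_lm(records, spec)
    base = c.reference_composition(records)
    return fit, base, truth
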