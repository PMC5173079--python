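import numpy as np
import pandas as pd
import pytest

from mirpanel import CohortSpec, generate_cohort, u6_normalize, zscore_fit_apply


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded cohort with the package's default study conditions."""
    return generate_cohort(CohortSpec(seed=11))


@pytest.fixture(scope="session")
def pc_cp_expression(default_cohort):
    """Standardized PC/CP expression (z-scores fit on all PC/CP samples)."""
    c = default_cohort
    ids = list(c.labels.index[c.labels.isin(["PC", "CP"])])
    expr = u6_normalize(c.ct.loc[ids])
    return zscore_fit_apply(expr, fit_on=ids), c.labels.loc[ids]


def two_group_spec(n_a, n_b, delta, n_mirnas=1, seed=0, names=None, **kw):
    """Minimal two-cohort spec: one shifted marker 'M1' plus pure-noise markers."""
    names = names or tuple(f"M{i + 1}" for i in range(n_mirnas))
    informative = {names[0]: {"A": float(delta)}} if delta else {}
    return CohortSpec(
        n_per_group={"A": n_a, "B": n_b},
        mirna_names=names,
        informative=informative,
        ca199_log_mean=None,
        seed=seed,
        **kw,
    )


@pytest.fixture
def toy_expr():
    """Tiny unstandardized expression frame with hand-checkable values."""
    return pd.DataFrame(
        {"m1": [1.0, 2.0, 3.0, 4.0], "m2": [0.0, 1.0, -1.0, 2.0]},
        index=["s1", "s2", "s3", "s4"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
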