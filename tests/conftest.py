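import math

import numpy as np
import pytest

from surrogacy import ComparisonRecord, Dataset, fixture_table1
from surrogacy.trial_data import Z95


@pytest.fixture(scope="session")
def table1() -> Dataset:
    return fixture_table1()


def make_dataset(x, y, n, tclass=None, subgroup="overall", se=0.1):
    """Build a Dataset whose log-HRs are exactly (x, y) with weights n.

    CIs are reconstructed from a nominal ``se`` so that effect_from_ci
    recovers the intended log effects exactly.
    """
    x, y, n = np.asarray(x, float), np.asarray(y, float), np.asarray(n)
    if tclass is None:
        tclass = ["ici_alone"] * len(x)
    recs = []
    for i, (xi, yi, ni, ti) in enumerate(zip(x, y, n, tclass)):
        recs.append(
            ComparisonRecord(
                trial_id=f"toy-{i}",
                comparison_id=f"toy-{i}",
                subgroup=subgroup,
                treatment_class=ti,
                n_randomized=int(ni),
                hr_os=math.exp(yi),
                hr_os_lo=math.exp(yi - Z95 * se),
                hr_os_hi=math.exp(yi + Z95 * se),
                hr_pfs=math.exp(xi),
                hr_pfs_lo=math.exp(xi - Z95 * se),
                hr_pfs_hi=math.exp(xi + Z95 * se),
            )
        )
    return Dataset(records=tuple(recs), provenance="toy")


@pytest.fixture
def toy_dataset():
    """Four non-collinear points with unequal weights, both treatment classes."""
    return make_dataset(
        x=[-0.6, -0.3, -0.1, 0.1],
        y=[-0.5, -0.35, -0.05, 0.05],
        n=[300, 500, 250, 400],
        tclass=["ici_alone", "ici_chemo", "ici_alone", "ici_chemo"],
    )
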