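import numpy as np
import pandas as pd
import pytest

from methsilence import SynthConfig, generate_bundle
from methsilence.io import BetaMatrix


@pytest.fixture(scope="session")
def zero_noise_bundle():
    """Fully deterministic bundle: planted signal with no measurement noise."""
    cfg = SynthConfig(beta_noise_sd=0.0, expr_noise_sd=0.0, seed=11)
    return generate_bundle(cfg)


@pytest.fixture(scope="session")
def noisy_bundle():
    """Bundle at the default noise levels."""
    return generate_bundle(SynthConfig(seed=1))


@pytest.fixture()
def toy_matrix():
    """Two probes x four samples with replicated conditions."""
    values = pd.DataFrame(
        {
            "s1": [0.1, 0.5],
            "s2": [0.2, 0.5],
            "r1": [0.7, 0.5],
            "r2": [0.8, 0.5],
        },
        index=pd.Index(["cg1", "cg2"], name="probe_id"),
    )
    conditions = pd.Series(
        ["sensitive", "sensitive", "resistant", "resistant"],
        index=["s1", "s2", "r1", "r2"],
    )
    return BetaMatrix(values=values, conditions=conditions)


def mann_whitney_enumeration_p(x, y):
    """Brute-force two-sided exact Mann-Whitney p over all label arrangements.

    Independent of the package implementation: U is computed by direct
    pair counting for every way of choosing which pooled values belong
    to the first sample; the two-sided p doubles the smaller tail.
    """
    from itertools import combinations

    x = list(map(float, x))
    y = list(map(float, y))
    pooled = x + y
    n1 = len(x)

    def u_stat(a, b):
        return sum(
            1.0 if ai > bj else 0.5 if ai == bj else 0.0 for ai in a for bj in b
        )

    u_obs = u_stat(x, y)
    us = []
    for idx in combinations(range(len(pooled)), n1):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(u_stat(a, b))
    us = np.asarray(us)
    total = len(us)
    cdf = np.sum(us <= u_obs + 1e-12) / total
    sf = np.sum(us >= u_obs - 1e-12) / total
    return min(1.0, 2.0 * min(cdf, sf))
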