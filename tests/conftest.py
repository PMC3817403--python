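import itertools

import numpy as np
import pytest

import eptlmap as e


@pytest.fixture(scope="session")
def yeast_map():
    return e.GeneticMap.yeast_default()


@pytest.fixture(scope="session")
def donor_genome(yeast_map):
    return e.HaplotypeGenome.uniform(yeast_map, "donor")


@pytest.fixture(scope="session")
def recipient_genome(yeast_map):
    return e.HaplotypeGenome.uniform(yeast_map, "recipient")


def brute_force_mannwhitney(x, y):
    """Independent oracle: exact two-sided Mann-Whitney P by enumerating
    every assignment of the pooled observations into groups of sizes
    (len(x), len(y)) and counting U = #{pairs x_i > y_j} + 0.5 #ties.

    Works directly on values (no ranks), so it is valid with ties.
    """
    x, y = list(x), list(y)
    pooled = x + y
    n = len(x)

    def u_stat(xs, ys):
        u = 0.0
        for a in xs:
            for b in ys:
                if a > b:
                    u += 1.0
                elif a == b:
                    u += 0.5
        return u

    u_obs = u_stat(x, y)
    n_le = n_ge = total = 0
    eps = 1e-9
    for idx in itertools.combinations(range(len(pooled)), n):
        idx = set(idx)
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_stat(xs, ys)
        total += 1
        n_le += u <= u_obs + eps
        n_ge += u >= u_obs - eps
    return u_obs, min(1.0, 2.0 * min(n_le, n_ge) / total)


@pytest.fixture(scope="session")
def mw_oracle():
    return brute_force_mannwhitney


def binomial_3se_interval(p, n):
    se = np.sqrt(p * (1 - p) / n)
    return p - 3 * se, p + 3 * se
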