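import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def full_enumeration():
    from acepep import enumerate_tetrapeptides

    return enumerate_tetrapeptides()


@pytest.fixture(scope="session")
def default_landscape():
    """Seeded synthetic docking-score landscape over the full library."""
    from acepep.synthetic import ScoreLandscapeConfig, gen_score_landscape

    return gen_score_landscape(ScoreLandscapeConfig(seed=20230407))


def random_transaction_db(rng, n_items_max=12, n_trans_max=200):
    """Small random transaction DB for oracle-equivalence checks."""
    n_items = rng.integers(3, n_items_max + 1)
    items = [f"i{k}" for k in range(n_items)]
    n_trans = rng.integers(5, n_trans_max + 1)
    db = []
    for _ in range(n_trans):
        size = rng.integers(1, n_items + 1)
        db.append(frozenset(rng.choice(items, size=size, replace=False)))
    return db


def brute_force_itemsets(db, min_support):
    """Exhaustive subset-enumeration oracle via bitmask counting.

    Counts occurrences of every subset of the item universe with a
    subset-sum (zeta) transform, independent of the FP-tree code path.
    """
    universe = sorted({i for t in db for i in t})
    m = len(universe)
    index = {item: k for k, item in enumerate(universe)}
    counts = np.zeros(2**m, dtype=np.int64)
    for t in db:
        mask = 0
        for item in t:
            mask |= 1 << index[item]
        counts[mask] += 1
    # zeta transform: counts[s] <- number of transactions containing s
    for k in range(m):
        bit = 1 << k
        masks = np.arange(2**m)
        has = (masks & bit).astype(bool)
        counts[~has] += counts[masks[~has] | bit]
    n = len(db)
    out = {}
    for mask in range(1, 2**m):
        if counts[mask] / n >= min_support - 1e-9:
            items = frozenset(
                universe[k] for k in range(m) if mask & (1 << k)
            )
            out[items] = counts[mask] / n
    return out
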