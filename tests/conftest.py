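import numpy as np
import pandas as pd
import pytest

from hoppertraits import make_species_pool, gen_plants


@pytest.fixture(scope="session")
def pool14():
    """Field-design species pool: 14 species, 4 subfamilies."""
    return make_species_pool(14, seed=3)


@pytest.fixture(scope="session")
def traits14(pool14):
    return pool14.trait_table()


@pytest.fixture(scope="session")
def plants16():
    return gen_plants(16, seed=3)


@pytest.fixture
def traits5():
    """Tiny hand-checkable trait table: 5 species, 2 subfamilies."""
    return pd.DataFrame(
        {
            "subfamily": ["A", "A", "B", "B", "B"],
            "body_volume": [100.0, 200.0, 400.0, 800.0, 1600.0],
            "incisor_strength": [1.0, 2.0, 4.0, 8.0, 16.0],
            "cn_ratio": [3.0, 4.0, 5.0, 6.0, 7.0],
        },
        index=pd.Index([f"s{i}" for i in range(5)], name="species_id"),
    )


def gower_oracle(traits, trait_set, log_transform=True):
    """Brute-force double-loop Gower distance, independent of the library."""
    numeric = {
        "all": ["body_volume", "incisor_strength", "cn_ratio"],
        "body_volume": ["body_volume"],
        "incisor_strength": ["incisor_strength"],
        "cn_ratio": ["cn_ratio"],
        "subfamily": [],
    }[trait_set]
    logged = {"body_volume", "incisor_strength"}
    cols = {}
    for name in numeric:
        v = traits[name].astype(float)
        cols[name] = np.log(v) if (log_transform and name in logged) else v
    n = len(traits)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            parts = []
            if trait_set == "subfamily":
                parts.append(
                    0.0 if traits["subfamily"].iloc[i] == traits["subfamily"].iloc[j] else 1.0
                )
            for name in numeric:
                v = cols[name]
                rng = v.max() - v.min()
                parts.append(abs(v.iloc[i] - v.iloc[j]) / rng if rng > 0 else 0.0)
            d[i, j] = sum(parts) / len(parts)
    return d


def raos_oracle(abund, dist):
    """O(S^2) double-sum Rao's quadratic entropy."""
    p = np.asarray(abund, float) / np.sum(abund)
    q = 0.0
    for i in range(len(p)):
        for j in range(len(p)):
            q += p[i] * p[j] * dist[i, j]
    return q
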