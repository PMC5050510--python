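import numpy as np
import pandas as pd
import pytest

from stressrep import CortisolSimConfig, CountSimConfig, simulate_cortisol, simulate_counts


@pytest.fixture
def toy_phenotypes() -> pd.DataFrame:
    """2 families x 2 fish x 2 occasions, hand-built."""
    rows = []
    values = {
        ("f1", "a"): [10.0, 12.0],
        ("f1", "b"): [20.0, 18.0],
        ("f2", "c"): [30.0, 33.0],
        ("f2", "d"): [40.0, 41.0],
    }
    for (fam, fish), vals in values.items():
        for occ, v in enumerate(vals, start=1):
            rows.append({"fish_id": fish, "family_id": fam,
                         "occasion": occ, "cortisol": v})
    return pd.DataFrame(rows)


@pytest.fixture
def default_cohort() -> pd.DataFrame:
    return simulate_cortisol(CortisolSimConfig(seed=1234))


@pytest.fixture
def planted_counts():
    """Count matrix with 169/161 planted group-exclusive transcripts."""
    cfg = CountSimConfig(seed=2024)
    return simulate_counts(cfg)


def random_unbalanced_phenotypes(rng: np.random.Generator) -> pd.DataFrame:
    """Random small unbalanced nested design for brute-force oracles."""
    n_fam = rng.integers(2, 5)
    rows = []
    fish_counter = 0
    for f in range(n_fam):
        n_ind = rng.integers(2, 5)
        for _ in range(n_ind):
            fish_counter += 1
            n_occ = rng.integers(1, 5)
            occs = rng.choice(np.arange(1, 7), size=n_occ, replace=False)
            for occ in occs:
                rows.append({
                    "fish_id": f"fish{fish_counter}",
                    "family_id": f"fam{f}",
                    "occasion": int(occ),
                    "cortisol": float(rng.gamma(4.0, 25.0)),
                })
    return pd.DataFrame(rows)
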