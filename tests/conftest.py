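"""Shared fixtures: small hand-built cohort tables and expansion helpers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_dataset(rows, item_ids=("x",)):
    """Build a cohort-table DataFrame from (item values..., prior, outcome, split) rows."""
    records = []
    for i, row in enumerate(rows):
        *items, prior, outcome, split = row
        rec = {"person_id": f"p{i:03d}", "cohort": "c1", "age": 70,
               "prior_use": prior, "outcome": outcome, "split": split}
        rec.update(dict(zip(item_ids, items)))
        records.append(rec)
    return pd.DataFrame(records)


def dataset_from_table(a, b, c, d, split="derivation", item_id="x", seed=None):
    """Expand 2x2 counts (a,b,c,d) into person-level records."""
    xs = [1] * (a + b) + [0] * (c + d)
    ys = [1] * a + [0] * b + [1] * c + [0] * d
    n = len(xs)
    df = pd.DataFrame({
        "person_id": [f"p{i:05d}" for i in range(n)],
        "cohort": "c1",
        "age": 75,
        "prior_use": 0,
        "outcome": ys,
        item_id: xs,
        "split": split,
    })
    if seed is not None:
        df = df.sample(frac=1.0, random_state=seed).reset_index(drop=True)
    return df


@pytest.fixture
def six_record_dataset():
    """3 exposed (2 events), 3 unexposed (1 event) -> table (2,1,1,2)."""
    rows = [
        (1, 0, 1, "derivation"),
        (1, 0, 1, "derivation"),
        (1, 0, 0, "derivation"),
        (0, 0, 1, "derivation"),
        (0, 0, 0, "derivation"),
        (0, 0, 0, "derivation"),
    ]
    return make_dataset(rows)


def random_logistic_dataset(rng, n, n_cov, intercept=None, betas=None):
    """Random all-binary design with a random planted logistic outcome."""
    prev = rng.uniform(0.2, 0.6, size=n_cov)
    X = (rng.random((n, n_cov)) < prev).astype(np.int8)
    if intercept is None:
        intercept = rng.uniform(-1.0, 0.5)
    if betas is None:
        betas = rng.uniform(-1.0, 1.0, size=n_cov)
    eta = intercept + X @ np.asarray(betas)
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(np.int8)
    cols = [f"x{j}" for j in range(n_cov)]
    df = pd.DataFrame(X, columns=cols)
    df.insert(0, "person_id", [f"p{i:05d}" for i in range(n)])
    df["outcome"] = y
    df["prior_use"] = 0
    df["cohort"] = "c1"
    df["age"] = 70
    df["split"] = "derivation"
    return df, cols
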