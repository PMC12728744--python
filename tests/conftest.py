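import numpy as np
import pandas as pd
import pytest

import faerspv as f


@pytest.fixture
def vocab():
    return f.VocabularyMap(
        {
            "Nausea": "Gastrointestinal disorders",
            "Vomiting": "Gastrointestinal disorders",
            "Fall": "Injury, poisoning and procedural complications",
            "Bradycardia": "Cardiac disorders",
            "Syncope": "Nervous system disorders",
        }
    )


@pytest.fixture
def minimal_extract():
    return f.generate(f.preset("minimal", seed=11))


@pytest.fixture
def written_bundle(tmp_path):
    """A small synthetic quarter with duplicates and deletions, on disk."""
    cfg = f.preset("minimal", seed=7).model_copy(
        update={"duplicate_rate": 0.15, "deletion_rate": 0.03}
    )
    extract = f.generate(cfg)
    paths = extract.write(str(tmp_path / "q1"))
    return extract, paths, tmp_path


def random_tables(rng, n, max_cell=2000, nondegenerate=True):
    """Random fourfold tables; nondegenerate means all cells >= 1."""
    lo = 1 if nondegenerate else 0
    return rng.integers(lo, max_cell, size=(n, 4))


def independence_tables(rng, n):
    """Random tables satisfying a/(a+b) = c/(c+d) exactly: rows are
    (k*p, k*q, m*p, m*q) for integer scale factors."""
    p = rng.integers(1, 20, size=n)
    q = rng.integers(1, 20, size=n)
    k = rng.integers(1, 30, size=n)
    m = rng.integers(1, 30, size=n)
    return np.stack([k * p, k * q, m * p, m * q], axis=1)
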