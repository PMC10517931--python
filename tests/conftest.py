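"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from expertdt import CohortConfig, generate_cohort
from expertdt.labels import SENTINELS
from expertdt.pipeline import train_baseline, train_tree, training_tiles


def brute_force_refine(labels: np.ndarray, inactive: frozenset = frozenset()) -> np.ndarray:
    """Independent re-count of every 3x3 window (the refine oracle)."""
    sentinels = SENTINELS | inactive
    n, m = labels.shape
    out = labels.copy()
    for i in range(n):
        for j in range(m):
            if labels[i, j] in sentinels:
                continue
            votes: dict[str, int] = {}
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    r, c = i + di, j + dj
                    if 0 <= r < n and 0 <= c < m and labels[r, c] not in sentinels:
                        votes[labels[r, c]] = votes.get(labels[r, c], 0) + 1
            best = max(votes.values())
            winners = [lab for lab, v in votes.items() if v == best]
            if len(winners) == 1:
                out[i, j] = winners[0]
    return out


def random_label_map(
    rng: np.random.Generator,
    max_size: int = 20,
    n_labels: int | None = None,
    sentinel_rate: float = 0.2,
) -> np.ndarray:
    """Random masked label map for oracle-equivalence checks."""
    n = int(rng.integers(1, max_size + 1))
    m = int(rng.integers(1, max_size + 1))
    k = n_labels or int(rng.integers(2, 6))
    alphabet = [f"L{i}" for i in range(k)]
    labels = rng.choice(alphabet, size=(n, m)).astype(object)
    mask = rng.random((n, m)) < sentinel_rate
    labels[mask] = "BACKGROUND"
    return labels


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete cohort: 3 patients per subtype, 320 px slides."""
    return generate_cohort(
        CohortConfig(n_per_subtype=3, image_size=320, seed=11)
    )


@pytest.fixture(scope="session")
def small_tiles(small_cohort):
    return training_tiles(small_cohort)


@pytest.fixture(scope="session")
def small_expert_tree(small_cohort, small_tiles):
    return train_tree(small_cohort, "expert", seed=3, tiles=small_tiles)


@pytest.fixture(scope="session")
def small_baseline(small_cohort, small_tiles):
    return train_baseline(small_cohort, seed=3, tiles=small_tiles)
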