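"""Shared helpers: random model/matrix generators used across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from rnadomains import BasePairProbabilityMatrix, FoldingModel

RNA = np.array(list("ACGU"))


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(RNA, size=length))


def random_model(rng: np.random.Generator) -> FoldingModel:
    """A random but valid folding model (weights, loop size, stacking)."""
    return FoldingModel(
        pair_weight={
            "GC": float(rng.uniform(0.3, 3.0)),
            "AU": float(rng.uniform(0.3, 3.0)),
            "GU": float(rng.uniform(0.3, 3.0)),
        },
        min_loop=int(rng.integers(1, 4)),
        stacking_bonus=float(rng.uniform(0.5, 2.0)),
    )


def random_matrix(
    rng: np.random.Generator, length: int, n_entries: int, high: float = 0.9
) -> BasePairProbabilityMatrix:
    """A sparse random probability matrix respecting the row-sum bound."""
    m = np.zeros((length, length))
    for _ in range(n_entries):
        i = int(rng.integers(0, length - 1))
        j = int(rng.integers(i + 1, length))
        m[i, j] += rng.uniform(0.0, high)
    # rescale rows that exceed the one-partner bound
    for _ in range(4):
        rows = m.sum(axis=0) + m.sum(axis=1)
        worst = rows.max()
        if worst <= 1.0:
            break
        scale = 0.95 / worst
        m *= scale
    return BasePairProbabilityMatrix(length, m)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
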